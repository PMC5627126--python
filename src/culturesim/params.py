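"""Model parameters and transmission-mode labels.

The simulated population has a fixed size ``N``, five 10-year age classes and
five discrete cultural traits per individual.  Each trait is bound to one
transmission mode: vertical (parent to offspring at birth only), horizontal
(same age group), oblique (strictly older individuals, excluding the parent),
age-neutral (anyone, i.e. unbiased drift) and mixed (a per-event mixture of
horizontal and oblique).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import yaml

N_AGE_GROUPS = 5
N_VARIANTS = 5


class TransmissionMode(str, Enum):
    """The five transmission pathways, in trait-slot order."""

    VERTICAL = "vertical"
    HORIZONTAL = "horizontal"
    OBLIQUE = "oblique"
    AGE_NEUTRAL = "age_neutral"
    MIXED = "mixed"

    @property
    def slot(self) -> int:
        """Index of this mode's trait slot in array-based state."""
        return MODE_ORDER.index(self)

    @classmethod
    def coerce(cls, value: "TransmissionMode | str") -> "TransmissionMode":
        if isinstance(value, cls):
            return value
        key = str(value).lower()
        aliases = {"v": "vertical", "h": "horizontal", "o": "oblique",
                   "n": "age_neutral", "m": "mixed"}
        return cls(aliases.get(key, key))


MODE_ORDER: tuple[TransmissionMode, ...] = tuple(TransmissionMode)

#: non-vertical modes, which have lifetime transmission events
LIFETIME_MODES: tuple[TransmissionMode, ...] = MODE_ORDER[1:]


class ConfigurationError(ValueError):
    """Raised when a parameter set violates its invariants."""


@dataclass(frozen=True)
class ParameterSet:
    """All constants of one simulation scenario.

    Parameters
    ----------
    N
        Population size (held constant by the demography).
    mu
        Mutation probability per transmission event: with probability ``mu``
        the copied variant is replaced by a random variant.
    p_w
        Per-time-step probability that an individual engages in a lifetime
        transmission event (per non-vertical trait).
    p_mix
        Probability that a mixed-mode event is oblique rather than horizontal.
    b
        Conformity-bias strength (0 = unbiased copying).
    p_death
        Per-time-step death hazard for individuals that have not yet aged out
        of the oldest class.  Default 0.1 per 10-year step, a plausible flat
        adult hazard for the stylized demography.
    burn_in_steps
        Time steps discarded before recording; default 100 (several complete
        population turnovers, enough to erase the initial uniform age
        distribution).
    recorded_steps
        Length of the recorded window (default 200 steps).
    seed
        Seed for the single per-run random generator.
    mutation_includes_current
        If True (default), a mutation draws uniformly from all five variants,
        so a copy is retained with probability ``1 - mu + mu/5``; if False the
        draw is uniform over the other four variants.
    conformity_khat_global
        If True (default), the variant count ``k_hat`` in the conformity bias
        is the number of variants present in the whole population; if False it
        is counted within the partner set.
    """

    N: int = 50
    mu: float = 0.1
    p_w: float = 1.0
    p_mix: float = 0.5
    b: float = 0.0
    p_death: float = 0.1
    burn_in_steps: int = 100
    recorded_steps: int = 200
    seed: int = 0
    mutation_includes_current: bool = True
    conformity_khat_global: bool = True

    n_age_groups: int = dataclasses.field(default=N_AGE_GROUPS, init=False, repr=False)
    n_variants: int = dataclasses.field(default=N_VARIANTS, init=False, repr=False)

    def __post_init__(self) -> None:
        if not (isinstance(self.N, (int,)) and self.N >= 1):
            raise ConfigurationError(f"N must be an integer >= 1, got {self.N!r}")
        for name in ("mu", "p_w", "p_mix", "p_death"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must lie in [0, 1], got {v!r}")
        if self.b < 0:
            raise ConfigurationError(f"b must be >= 0, got {self.b!r}")
        if self.burn_in_steps < 0:
            raise ConfigurationError("burn_in_steps must be non-negative")
        if self.recorded_steps < 1:
            raise ConfigurationError("recorded_steps must be >= 1")

    def replace(self, **changes) -> "ParameterSet":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d.pop("n_age_groups")
        d.pop("n_variants")
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        known = {f.name for f in dataclasses.fields(cls) if f.init}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown parameter(s): {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ParameterSet":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"{path}: expected a flat key-value mapping")
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)
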