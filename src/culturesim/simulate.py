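"""Population state, single-run simulation, and the individual-level rules.

The readable, object-level API lives here; `run_simulation` and the step
functions delegate to the compiled kernels in `_kernels`, which operate on the
same array state held by :class:`Population`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .params import (MODE_ORDER, N_AGE_GROUPS, N_VARIANTS, ParameterSet,
                     TransmissionMode)


@dataclass
class Population:
    """Array-of-records population state.

    ``ages`` are age-group labels 1..5; ``parents`` holds the current index of
    each individual's living parent (-1 for founders or once the parent has
    died); ``variants`` has shape (5 trait slots, N) with variant labels 1..5,
    slots ordered as ``MODE_ORDER``.
    """

    ages: np.ndarray
    parents: np.ndarray
    variants: np.ndarray
    born_in_sim: np.ndarray = field(default=None)  # type: ignore[assignment]
    n_events: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        n = self.size
        if self.born_in_sim is None:
            self.born_in_sim = np.zeros(n, bool)
        if self.n_events is None:
            self.n_events = np.zeros(n, np.int64)

    @property
    def size(self) -> int:
        return int(self.ages.shape[0])

    @property
    def age_counts(self) -> np.ndarray:
        """[n_1, ..., n_5], the number of individuals per age group."""
        return np.bincount(self.ages, minlength=N_AGE_GROUPS + 1)[1:]

    def variants_for(self, mode: TransmissionMode | str) -> np.ndarray:
        return self.variants[TransmissionMode.coerce(mode).slot]

    def count_table(self) -> np.ndarray:
        """Counts with shape (slot, age group, variant)."""
        return _kernels.count_table(self.ages.astype(np.int64),
                                    self.variants.astype(np.int64))


class Extinct:
    """Sentinel outcome: all potential parents died before reproducing."""

    def __repr__(self) -> str:  # pragma: no cover
        return "Extinct"

    def __bool__(self) -> bool:
        return False


EXTINCT = Extinct()


def initialize_population(params: ParameterSet, rng: np.random.Generator) -> Population:
    """Founders: ages uniform over the five groups, every trait fixed on
    variant 1, no parent links."""
    n = params.N
    return Population(
        ages=rng.integers(1, N_AGE_GROUPS + 1, n).astype(np.int64),
        parents=np.full(n, -1, np.int64),
        variants=np.ones((len(MODE_ORDER), n), np.int64),
    )


def partner_set(pop: Population, focal: int,
                mode: TransmissionMode | str) -> np.ndarray:
    """Indices of the focal individual's potential interaction partners.

    Horizontal: same age group, excluding the focal.  Oblique: strictly older,
    excluding the focal's living parent.  Age-neutral: everyone but the focal.
    Vertical: empty (no lifetime events).  The mixed mode resolves per event
    to horizontal or oblique and has no partner set of its own.
    """
    mode = TransmissionMode.coerce(mode)
    idx = np.arange(pop.size)
    if mode is TransmissionMode.VERTICAL:
        return idx[:0]
    if mode is TransmissionMode.MIXED:
        raise ValueError("mixed mode resolves per event to horizontal or oblique")
    if mode is TransmissionMode.HORIZONTAL:
        mask = pop.ages == pop.ages[focal]
        mask[focal] = False
    elif mode is TransmissionMode.OBLIQUE:
        mask = pop.ages > pop.ages[focal]
        p = pop.parents[focal]
        if p >= 0:
            mask[p] = False
    else:  # age-neutral
        mask = np.ones(pop.size, bool)
        mask[focal] = False
    return idx[mask]


def variant_choice_probabilities(partner_variants: np.ndarray, k_hat: int,
                                 b: float) -> np.ndarray:
    """Adoption probabilities over the five variants within a partner set.

    With conformity strength ``b``, the raw weight of variant k is
    ``n*_k/N* + b * (k_hat * n*_k/N* - 1)`` where ``n*_k`` counts partners
    carrying k and ``N*`` is the partner-set size; negative weights are
    clamped at zero and the vector renormalized.  With ``b = 0`` this is
    exactly the partner-set relative frequencies.
    """
    partner_variants = np.asarray(partner_variants)
    if partner_variants.size == 0:
        raise ValueError("empty partner set has no choice probabilities")
    if k_hat < 1 or b < 0:
        raise ValueError("require k_hat >= 1 and b >= 0")
    freq = np.bincount(partner_variants, minlength=N_VARIANTS + 1)[1:]
    freq = freq / partner_variants.size
    if b == 0:
        return freq
    w = np.clip(freq + b * (k_hat * freq - 1.0), 0.0, None)
    total = w.sum()
    if total <= 0:
        raise ValueError("conformity weights vanished for every variant")
    return w / total


def mutate(variant: int, mu: float, rng: np.random.Generator,
           include_current: bool = True) -> int:
    """Return the copied variant, replaced by a random one with probability mu."""
    if mu > 0 and rng.random() < mu:
        if include_current:
            return int(rng.integers(1, N_VARIANTS + 1))
        v = int(rng.integers(1, N_VARIANTS))
        return v + 1 if v >= variant else v
    return int(variant)


def demographic_step(pop: Population, params: ParameterSet,
                     seed: int) -> Population | Extinct:
    """Ageing, hazard deaths and births restoring size N (compiled kernel)."""
    _kernels.seed_rng(seed)
    completed = np.zeros(pop.size, np.int64)
    (age, parent, variants, born, n_events, _nc, extinct) = \
        _kernels.demographic_step(
            pop.ages.astype(np.int64), pop.parents.astype(np.int64),
            pop.variants.astype(np.int64), pop.born_in_sim, pop.n_events,
            params.p_death, params.mu, params.mutation_includes_current,
            completed, 0)
    if extinct:
        return EXTINCT
    return Population(age, parent, variants, born, n_events)


def transmission_step(pop: Population, params: ParameterSet,
                      seed: int) -> Population:
    """One asynchronous round of lifetime transmission events (compiled kernel).

    Mutates nothing: returns a new Population.
    """
    age = pop.ages.astype(np.int64)
    parent = pop.parents.astype(np.int64)
    variants = pop.variants.astype(np.int64).copy()
    n_events = pop.n_events.copy()
    _kernels.seed_rng(seed)
    _kernels.transmission_step(age, parent, variants, n_events,
                               params.p_w, params.p_mix, params.mu, params.b,
                               params.mutation_includes_current,
                               params.conformity_khat_global)
    return Population(age, parent, variants, pop.born_in_sim.copy(), n_events)


@dataclass
class Trajectory:
    """Raw output of one surviving run.

    ``counts`` has shape (recorded_steps, 5 trait slots, 5 variants); each
    (step, slot) vector sums to N.  ``final_age_counts`` is the
    (slot, age group, variant) table at the last recorded step, used for
    within-age-group diversity.  ``lifetime_events`` holds, for every
    individual that completed all five age classes during the run, its number
    of age-neutral transmission events.
    """

    params: ParameterSet
    counts: np.ndarray
    final_age_counts: np.ndarray
    lifetime_events: np.ndarray
    survived: bool = True

    def counts_for(self, mode: TransmissionMode | str) -> np.ndarray:
        """(recorded_steps, 5) count matrix for one mode's trait."""
        return self.counts[:, TransmissionMode.coerce(mode).slot, :]

    def to_frame(self) -> pd.DataFrame:
        """Tidy table: one row per (step, mode, variant); step is 1-based."""
        steps, n_modes, n_var = self.counts.shape
        rows = {
            "step": np.repeat(np.arange(1, steps + 1), n_modes * n_var),
            "mode": np.tile(np.repeat([m.value for m in MODE_ORDER], n_var), steps),
            "variant": np.tile(np.arange(1, n_var + 1), steps * n_modes),
            "count": self.counts.ravel(),
        }
        return pd.DataFrame(rows)


def run_simulation(params: ParameterSet,
                   seed: int | None = None) -> Trajectory | Extinct:
    """Run one simulation: burn-in plus recorded window.

    Each time step is a demographic step followed by a transmission step.
    Returns :data:`EXTINCT` if the population dies at any point, otherwise a
    :class:`Trajectory` covering the recorded window.
    """
    if seed is None:
        seed = params.seed
    capacity = params.N * (params.burn_in_steps + params.recorded_steps)
    traj, final_counts, completed, survived = _kernels.simulate(
        params.N, params.mu, params.p_w, params.p_mix, params.b,
        params.p_death, params.burn_in_steps, params.recorded_steps,
        int(seed) % 2**31, params.mutation_includes_current,
        params.conformity_khat_global, capacity)
    if not survived:
        return EXTINCT
    return Trajectory(params=params, counts=traj,
                      final_age_counts=final_counts,
                      lifetime_events=completed, survived=True)
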