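"""Population-level summary statistics.

For a trait bound to mode x the statistics are: the joint variant frequencies
[p_1, ..., p_5]; the frequency of the most common variant p_max; the variant
richness k (number of variants present); the Shannon diversity
d_s = -sum_k p_k ln p_k (in nats); and t_max, the average number of
consecutive time steps a variant stays the most common variant.

Composition statistics are taken from a single snapshot (by convention the
final recorded step of a run); t_max is computed over the whole recorded
window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import entropy as _shannon_entropy

from . import _kernels
from .params import (MODE_ORDER, N_AGE_GROUPS, N_VARIANTS, ParameterSet,
                     TransmissionMode)
from .simulate import Trajectory

STATISTIC_NAMES = ("p_max", "k", "d_s", "t_max")


@dataclass(frozen=True)
class CompositionSnapshot:
    """Variant composition of the population at one point in time."""

    counts: np.ndarray
    frequencies: np.ndarray
    k_hat: int


def snapshot_from_counts(counts) -> CompositionSnapshot:
    counts = np.asarray(counts, dtype=np.int64)
    if counts.ndim != 1 or counts.shape[0] != N_VARIANTS:
        raise ValueError(f"expected a length-{N_VARIANTS} count vector")
    if (counts < 0).any():
        raise ValueError("counts must be non-negative")
    total = counts.sum()
    if total == 0:
        raise ValueError("all-zero count vector has no composition")
    return CompositionSnapshot(counts=counts, frequencies=counts / total,
                               k_hat=int((counts > 0).sum()))


def p_max(s: CompositionSnapshot) -> float:
    """Frequency of the most common variant."""
    return float(s.frequencies.max())


def richness(s: CompositionSnapshot) -> int:
    """Number of variants present."""
    return s.k_hat


def shannon_diversity(s: CompositionSnapshot) -> float:
    """Shannon diversity index in nats; 0*ln(0) terms contribute zero."""
    return float(_shannon_entropy(s.counts))


def most_common_series(mode_counts: np.ndarray) -> np.ndarray:
    """Per-step most common variant (1-based); ties break to the lowest label."""
    mode_counts = np.asarray(mode_counts)
    return mode_counts.argmax(axis=1) + 1


def t_max(most_common: np.ndarray) -> float:
    """Mean length (in steps) of the maximal constant runs of the series.

    The first and last runs, censored by the recording window, are included,
    so the value equals window length divided by the number of runs.
    """
    most_common = np.asarray(most_common)
    if most_common.size == 0:
        raise ValueError("empty most-common-variant series")
    n_runs = 1 + int((np.diff(most_common) != 0).sum())
    return most_common.size / n_runs


def summarize_run(traj: Trajectory) -> pd.DataFrame:
    """One row per mode: p_max, k, d_s at the final recorded step; t_max over
    the whole window."""
    rows = []
    for mode in MODE_ORDER:
        counts = traj.counts_for(mode)
        snap = snapshot_from_counts(counts[-1])
        rows.append({
            "mode": mode.value,
            "p_max": p_max(snap),
            "k": richness(snap),
            "d_s": shannon_diversity(snap),
            "t_max": t_max(most_common_series(counts)),
        })
    return pd.DataFrame(rows)


def age_group_diversity(age_counts: np.ndarray,
                        mode: TransmissionMode | str) -> tuple[np.ndarray, float]:
    """Shannon diversity within each age group, plus the whole population.

    ``age_counts`` is a (slot, age group, variant) table such as
    ``Trajectory.final_age_counts`` or ``Population.count_table()``.  Empty
    age groups yield NaN.
    """
    slot = TransmissionMode.coerce(mode).slot
    table = np.asarray(age_counts)[slot]
    per_group = np.full(N_AGE_GROUPS, np.nan)
    for a in range(N_AGE_GROUPS):
        if table[a].sum() > 0:
            per_group[a] = _shannon_entropy(table[a])
    whole = float(_shannon_entropy(table.sum(axis=0)))
    return per_group, whole


def mutant_spread_distribution(params: ParameterSet,
                               mode: TransmissionMode | str,
                               introducer_age: int, reps: int,
                               seed: int = 0) -> np.ndarray:
    """Monte-Carlo distribution of a mutant's frequency after one time step.

    The starting population is monomorphic on variant 1 for the given mode's
    trait except for one individual of age group ``introducer_age`` carrying
    variant 2 (background ages drawn uniformly over the groups, as at
    initialization).  One full time step (demography, then transmission) is
    applied and the variant-2 count recorded; the returned vector over
    frequencies 0..N sums to 1.  Runs that go extinct count as frequency 0.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    if not 1 <= introducer_age <= N_AGE_GROUPS:
        raise ValueError("introducer_age must be an age group 1..5")
    slot = TransmissionMode.coerce(mode).slot
    n = params.N
    rng = np.random.default_rng(seed)
    hist = np.zeros(n + 1, np.int64)
    for _ in range(reps):
        ages = rng.integers(1, N_AGE_GROUPS + 1, n).astype(np.int64)
        ages[0] = introducer_age
        variants = np.ones((N_VARIANTS, n), np.int64)
        variants[slot, 0] = 2
        counts, extinct = _kernels.one_step(
            ages, np.full(n, -1, np.int64), variants,
            params.p_death, params.mu, params.p_w, params.p_mix, params.b,
            params.mutation_includes_current, params.conformity_khat_global,
            int(rng.integers(2**31)))
        freq = 0 if extinct else int(counts[slot, :, 1].sum())
        hist[freq] += 1
    return hist / reps


def mutant_survival_probability(spread: np.ndarray) -> float:
    """P(mutant still present after one step) from a spread distribution."""
    return float(1.0 - spread[0])
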