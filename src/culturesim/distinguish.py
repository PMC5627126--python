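"""Distinguishability of transmission modes from ensembles of statistics.

Two modes are compared through the area of overlap O_xy between the ensemble
distributions of a statistic: for unimodal-crossing densities
O_xy = 1 - K_xy, where K_xy is the Kolmogorov-Smirnov distance between the
empirical distribution functions.  Modes are declared distinguishable when
O_xy falls below a threshold (default 0.2, the conventional 80% power
cut-off).  Given an observed statistic value z, posterior mode probabilities
P(y|z) = f(z|y) P(y) / sum_g f(z|g) P(g) are estimated either from histogram
densities or by (multinomial) logistic regression.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.linear_model import LogisticRegression

from .params import ParameterSet, TransmissionMode

DEFAULT_OVERLAP_THRESHOLD = 0.2


@dataclass
class EmpiricalDistribution:
    """Per-run values of one statistic under one mode."""

    statistic_name: str
    mode: TransmissionMode | str
    samples: np.ndarray
    params: ParameterSet | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.size == 0:
            raise ValueError("empirical distribution requires samples")

    def ecdf(self, z) -> np.ndarray:
        """Right-continuous ECDF evaluated at z."""
        s = np.sort(self.samples)
        return np.searchsorted(s, np.asarray(z, dtype=float), side="right") / s.size


@dataclass
class JointDistribution:
    """Per-run final-step variant count vectors under one mode."""

    mode: TransmissionMode | str
    samples: np.ndarray
    params: ParameterSet | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.int64)
        if self.samples.ndim != 2 or self.samples.shape[0] == 0:
            raise ValueError("expected a non-empty (runs, variants) array")

    @property
    def N(self) -> int:
        return int(self.samples[0].sum())


@dataclass(frozen=True)
class OverlapResult:
    O_xy: float
    K_xy: float
    z_star: float | None
    threshold: float = DEFAULT_OVERLAP_THRESHOLD

    @property
    def distinguishable(self) -> bool:
        return self.O_xy < self.threshold


def ks_distance(dist_x: EmpiricalDistribution,
                dist_y: EmpiricalDistribution) -> tuple[float, float]:
    """Sup-distance between the two ECDFs over the pooled sample points.

    Returns (K_xy, z_star); on ties z_star is the lowest attaining value.
    """
    if dist_x.statistic_name != dist_y.statistic_name:
        raise ValueError(
            f"statistic mismatch: {dist_x.statistic_name!r} vs "
            f"{dist_y.statistic_name!r}")
    grid = np.unique(np.concatenate([dist_x.samples, dist_y.samples]))
    gaps = np.abs(dist_x.ecdf(grid) - dist_y.ecdf(grid))
    sup = float(gaps.max())
    # lowest attaining z; ECDF gaps are rationals evaluated in floats, so
    # ties are resolved up to rounding noise
    i = int(np.argmax(gaps >= sup - 1e-12))
    return sup, float(grid[i])


def overlap_area(dist_x: EmpiricalDistribution, dist_y: EmpiricalDistribution,
                 threshold: float = DEFAULT_OVERLAP_THRESHOLD) -> OverlapResult:
    """Area of overlap O_xy = 1 - K_xy between the two ensembles."""
    k, z_star = ks_distance(dist_x, dist_y)
    return OverlapResult(O_xy=1.0 - k, K_xy=k, z_star=z_star,
                         threshold=threshold)


def joint_overlap(jd_x: JointDistribution, jd_y: JointDistribution,
                  threshold: float = DEFAULT_OVERLAP_THRESHOLD) -> OverlapResult:
    """Overlap of the joint variant-frequency distributions.

    Count vectors are sorted descending (removing variant-label symmetry) and
    treated as cells of the discrete simplex; the overlap coefficient
    sum_cells min(f_x, f_y) equals 1 minus the total-variation distance.
    """
    if jd_x.N != jd_y.N:
        raise ValueError(f"population size mismatch: {jd_x.N} vs {jd_y.N}")

    def _cells(samples: np.ndarray) -> pd.Series:
        ordered = np.sort(samples, axis=1)[:, ::-1]
        frame = pd.DataFrame(ordered)
        return frame.value_counts(normalize=True)

    fx, fy = _cells(jd_x.samples), _cells(jd_y.samples)
    common = fx.index.intersection(fy.index)
    o = float(np.minimum(fx.loc[common], fy.loc[common]).sum()) if len(common) else 0.0
    return OverlapResult(O_xy=o, K_xy=1.0 - o, z_star=None, threshold=threshold)


@dataclass
class PosteriorModel:
    """P(mode | statistic value) over a set of candidate modes."""

    modes: list
    priors: np.ndarray
    method: str
    statistic_name: str
    bin_edges: np.ndarray | None = None
    densities: np.ndarray | None = None  # (mode, bin) conditional densities
    classifier: LogisticRegression | None = field(default=None, repr=False)

    @property
    def fitted(self) -> bool:
        if self.method == "histogram":
            return self.densities is not None
        return self.classifier is not None


def fit_posterior_model(ensembles: dict, priors=None,
                        method: str = "histogram") -> PosteriorModel:
    """Fit P(mode | z) from one EmpiricalDistribution per candidate mode.

    ``histogram`` estimates the conditional densities f(z|y) on a common grid
    (bin count = ceil(sqrt(smallest sample size)) over the pooled range) and
    applies Bayes' rule; ``logistic`` fits a (multinomial) logistic regression
    of mode label on z with samples weighted to the priors.
    """
    if len(ensembles) < 2:
        raise ValueError("need at least two candidate modes")
    modes = list(ensembles)
    stat_names = {d.statistic_name for d in ensembles.values()}
    if len(stat_names) != 1:
        raise ValueError(f"mixed statistics: {sorted(stat_names)}")
    sizes = {m: ensembles[m].samples.size for m in modes}
    for m, n in sizes.items():
        if n < 2:
            raise ValueError(f"mode {m}: need at least 2 samples, got {n}")
        if n < 30:
            import warnings
            warnings.warn(f"mode {m}: only {n} samples; density estimates "
                          "will be unstable", stacklevel=2)
    if priors is None:
        priors = np.full(len(modes), 1.0 / len(modes))
    priors = np.asarray(priors, dtype=float)
    if priors.shape != (len(modes),) or not math.isclose(priors.sum(), 1.0,
                                                         rel_tol=1e-9):
        raise ValueError("priors must be one per mode and sum to 1")

    model = PosteriorModel(modes=modes, priors=priors, method=method,
                           statistic_name=stat_names.pop())
    pooled = np.concatenate([ensembles[m].samples for m in modes])
    if method == "histogram":
        n_bins = max(1, math.ceil(math.sqrt(min(sizes.values()))))
        lo, hi = float(pooled.min()), float(pooled.max())
        if hi <= lo:
            hi = lo + 1e-9
        edges = np.linspace(lo, hi, n_bins + 1)
        dens = np.stack([
            np.histogram(ensembles[m].samples, bins=edges, density=True)[0]
            for m in modes])
        model.bin_edges = edges
        model.densities = dens
    elif method == "logistic":
        z = pooled.reshape(-1, 1)
        labels = np.concatenate([
            np.full(sizes[m], i) for i, m in enumerate(modes)])
        # weight each mode's samples to its prior mass (mean weight 1 so the
        # unpenalized likelihood is well scaled)
        weights = np.concatenate([
            np.full(sizes[m], priors[i] * len(pooled) / sizes[m])
            for i, m in enumerate(modes)])
        # unpenalized MLE: regularization flattens the posterior curves
        clf = LogisticRegression(C=np.inf, max_iter=1000)
        clf.fit(z, labels, sample_weight=weights)
        model.classifier = clf
    else:
        raise ValueError(f"unknown method {method!r}")
    return model


def posterior_probability(model: PosteriorModel, z) -> tuple[np.ndarray, np.ndarray]:
    """P(mode | z) for scalar or array z.

    Returns (probabilities, in_support): probabilities has one column per
    candidate mode and sums to 1 row-wise; where z falls outside every mode's
    estimated support (histogram method) the posterior falls back to the
    priors and in_support is False there.
    """
    if not model.fitted:
        raise ValueError("model is not fitted")
    z_arr = np.atleast_1d(np.asarray(z, dtype=float))
    if model.method == "histogram":
        edges = model.bin_edges
        idx = np.clip(np.searchsorted(edges, z_arr, side="right") - 1, 0,
                      len(edges) - 2)
        inside = (z_arr >= edges[0]) & (z_arr <= edges[-1])
        lik = model.densities[:, idx].T * inside[:, None]
        num = lik * model.priors
        total = num.sum(axis=1)
        in_support = total > 0
        probs = np.where(in_support[:, None], num / np.where(
            total[:, None] == 0, 1.0, total[:, None]), model.priors)
    else:
        probs = model.classifier.predict_proba(z_arr.reshape(-1, 1))
        # reorder to model.modes (classes are label-encoded 0..n-1 already)
        order = np.argsort(model.classifier.classes_)
        probs = probs[:, order]
        in_support = np.ones(z_arr.size, bool)
    if np.isscalar(z) or np.asarray(z).ndim == 0:
        return probs[0], in_support[0]
    return probs, in_support


def posterior_curve(model: PosteriorModel, z_grid) -> pd.DataFrame:
    """Posterior probabilities tabulated over a grid of statistic values."""
    probs, in_support = posterior_probability(model, np.asarray(z_grid))
    frame = pd.DataFrame(probs, columns=[str(getattr(m, "value", m))
                                         for m in model.modes])
    frame.insert(0, "z", np.asarray(z_grid, dtype=float))
    frame["in_support"] = in_support
    return frame
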