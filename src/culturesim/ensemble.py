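"""Ensemble orchestration: many seeded runs, parameter sweeps and reports.

One simulation carries all five mode-bound traits, so a single run yields one
sample of each statistic per mode; runs that go extinct are discarded without
replacement.  Per-run seeds are ``base_seed + run_index`` so any ensemble is
reproducible byte-for-byte from its spec.
"""

from __future__ import annotations

import hashlib
import itertools
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import stats as sstats
from .distinguish import (DEFAULT_OVERLAP_THRESHOLD, EmpiricalDistribution,
                          JointDistribution, OverlapResult, overlap_area)
from .params import MODE_ORDER, ParameterSet, TransmissionMode
from .simulate import run_simulation

DEFAULT_N_RUNS = 3000  # scaled-down default; increase via spec for precision


@dataclass(frozen=True)
class EnsembleSpec:
    """What to simulate: a parameter constellation plus run bookkeeping."""

    params: ParameterSet
    n_runs: int = DEFAULT_N_RUNS
    base_seed: int = 0
    modes: tuple = MODE_ORDER
    statistics: tuple = sstats.STATISTIC_NAMES

    def __post_init__(self) -> None:
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if not self.modes:
            raise ValueError("modes must be non-empty")


@dataclass
class EnsembleResult:
    """Distributions of the summary statistics across surviving runs."""

    spec: EnsembleSpec
    summary: pd.DataFrame          # columns: run, mode, p_max, k, d_s, t_max
    joint: dict                    # mode -> (n_surviving, 5) final-step counts
    age_tables: np.ndarray         # (n_surviving, slot, age, variant)
    n_extinct: int
    wall_time_s: float = 0.0

    @property
    def n_surviving(self) -> int:
        return self.summary["run"].nunique()

    def distribution(self, statistic: str,
                     mode: TransmissionMode | str) -> EmpiricalDistribution:
        mode = TransmissionMode.coerce(mode)
        values = self.summary.loc[self.summary["mode"] == mode.value, statistic]
        return EmpiricalDistribution(statistic_name=statistic, mode=mode,
                                     samples=values.to_numpy(),
                                     params=self.spec.params)

    def joint_distribution(self, mode: TransmissionMode | str) -> JointDistribution:
        mode = TransmissionMode.coerce(mode)
        return JointDistribution(mode=mode, samples=self.joint[mode.value],
                                 params=self.spec.params)

    def provenance(self) -> dict:
        return {
            "params": self.spec.params.to_dict(),
            "n_runs": self.spec.n_runs,
            "base_seed": self.spec.base_seed,
            "modes": [TransmissionMode.coerce(m).value for m in self.spec.modes],
            "n_extinct": self.n_extinct,
            "n_surviving": self.n_surviving,
            "wall_time_s": round(self.wall_time_s, 3),
        }


def run_ensemble(spec: EnsembleSpec, keep_age_tables: bool = True) -> EnsembleResult:
    """Execute ``n_runs`` independent simulations with seeds base_seed + i."""
    t0 = time.perf_counter()
    frames = []
    joint: dict[str, list] = {TransmissionMode.coerce(m).value: []
                              for m in spec.modes}
    age_tables = []
    n_extinct = 0
    run_id = 0
    for i in range(spec.n_runs):
        traj = run_simulation(spec.params, seed=spec.base_seed + i)
        if not traj:
            n_extinct += 1
            continue
        summary = sstats.summarize_run(traj)
        summary = summary[summary["mode"].isin(joint)]
        summary.insert(0, "run", run_id)
        summary.insert(1, "seed", spec.base_seed + i)
        frames.append(summary)
        for mode_value in joint:
            slot = TransmissionMode(mode_value).slot
            joint[mode_value].append(traj.counts[-1, slot, :])
        if keep_age_tables:
            age_tables.append(traj.final_age_counts)
        run_id += 1
    if run_id == 0:
        raise RuntimeError(
            f"all {spec.n_runs} runs went extinct under {spec.params}; "
            "check p_death and N")
    return EnsembleResult(
        spec=spec,
        summary=pd.concat(frames, ignore_index=True),
        joint={m: np.asarray(v) for m, v in joint.items()},
        age_tables=np.asarray(age_tables) if keep_age_tables else np.empty((0,)),
        n_extinct=n_extinct,
        wall_time_s=time.perf_counter() - t0,
    )


def _constellation_tag(params: ParameterSet, n_runs: int, base_seed: int) -> str:
    payload = json.dumps({**params.to_dict(), "n_runs": n_runs,
                          "base_seed": base_seed}, sort_keys=True)
    digest = hashlib.sha1(payload.encode()).hexdigest()[:8]
    return (f"N{params.N}_mu{params.mu}_pw{params.p_w}_b{params.b}"
            f"_pmix{params.p_mix}_{digest}")


def save_ensemble(result: EnsembleResult, out_dir: str | Path) -> Path:
    """Write summary.csv, joint_<mode>.csv and manifest.json to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    result.summary.to_csv(out / "summary.csv", index=False)
    for mode_value, counts in result.joint.items():
        pd.DataFrame(counts, columns=[f"variant_{k}" for k in range(1, 6)]) \
            .to_csv(out / f"joint_{mode_value}.csv", index=False)
    with open(out / "manifest.json", "w") as fh:
        json.dump(result.provenance(), fh, indent=2)
    return out


def sweep(grid: dict, base_params: ParameterSet | None = None,
          n_runs: int = DEFAULT_N_RUNS, base_seed: int = 0,
          out_dir: str | Path | None = None) -> list[EnsembleResult]:
    """Run one ensemble per parameter constellation in the cartesian grid.

    ``grid`` maps ParameterSet field names to value lists.  With ``out_dir``
    each constellation is cached to its own subdirectory and a completed
    constellation (manifest present) is skipped on resume.
    """
    if not grid:
        raise ValueError("empty parameter grid")
    base = base_params or ParameterSet()
    keys = sorted(grid)
    results = []
    for values in itertools.product(*(grid[k] for k in keys)):
        params = base.replace(**dict(zip(keys, values)))
        tag = _constellation_tag(params, n_runs, base_seed)
        target = Path(out_dir) / tag if out_dir is not None else None
        if target is not None and (target / "manifest.json").exists():
            continue
        result = run_ensemble(EnsembleSpec(params=params, n_runs=n_runs,
                                           base_seed=base_seed),
                              keep_age_tables=False)
        if target is not None:
            save_ensemble(result, target)
        results.append(result)
    return results


def pairwise_report(result: EnsembleResult, statistic: str,
                    threshold: float = DEFAULT_OVERLAP_THRESHOLD) -> pd.DataFrame:
    """Symmetric matrix of overlap areas O_xy between all mode pairs.

    ``statistic`` is one of p_max, k, d_s, t_max, or "joint" for the joint
    variant-frequency distribution.
    """
    modes = [TransmissionMode.coerce(m) for m in result.spec.modes]
    if statistic != "joint" and statistic not in result.summary.columns:
        raise ValueError(f"statistic {statistic!r} not in ensemble result")
    labels = [m.value for m in modes]
    matrix = pd.DataFrame(np.eye(len(modes)), index=labels, columns=labels)
    for i, x in enumerate(modes):
        for y in modes[i + 1:]:
            if statistic == "joint":
                from .distinguish import joint_overlap
                res = joint_overlap(result.joint_distribution(x),
                                    result.joint_distribution(y), threshold)
            else:
                res = overlap_area(result.distribution(statistic, x),
                                   result.distribution(statistic, y), threshold)
            matrix.loc[x.value, y.value] = res.O_xy
            matrix.loc[y.value, x.value] = res.O_xy
    return matrix


def format_matrix(matrix: pd.DataFrame,
                  threshold: float = DEFAULT_OVERLAP_THRESHOLD) -> str:
    """Aligned plain-text rendering; cells below the threshold are starred."""
    lines = [f"overlap area O_xy (* = distinguishable at O < {threshold})"]
    width = max(len(c) for c in matrix.columns) + 2
    header = " " * width + "".join(f"{c:>{width}}" for c in matrix.columns)
    lines.append(header)
    for row_label, row in matrix.iterrows():
        cells = "".join(
            f"{v:>{width - 1}.2f}{'*' if (v < threshold and c != row_label) else ' '}"
            for c, v in row.items())
        lines.append(f"{row_label:<{width}}{cells}")
    return "\n".join(lines)


def conformity_report(mode: TransmissionMode | str, b_values, params: ParameterSet,
                      n_runs: int = 2000, base_seed: int = 0,
                      statistics: tuple = ("d_s", "t_max")) -> pd.DataFrame:
    """Overlap between the unbiased (b=0) and conformist ensembles of a mode.

    Returns one row per (statistic, b > 0) with the overlap area against the
    b = 0 baseline and the ensemble means of the statistic at both b levels.
    """
    mode = TransmissionMode.coerce(mode)
    if mode is TransmissionMode.VERTICAL:
        import warnings
        warnings.warn("vertical transmission is unaffected by conformity bias",
                      stacklevel=2)
    b_values = sorted(set(float(b) for b in b_values))
    if 0.0 not in b_values:
        raise ValueError("b_values must include 0 (the unbiased baseline)")
    ensembles = {}
    for b in b_values:
        spec = EnsembleSpec(params=params.replace(b=b), n_runs=n_runs,
                            base_seed=base_seed, modes=(mode,))
        ensembles[b] = run_ensemble(spec, keep_age_tables=False)
    rows = []
    base = ensembles[0.0]
    for stat in statistics:
        base_dist = base.distribution(stat, mode)
        for b in b_values:
            if b == 0.0:
                continue
            res: OverlapResult = overlap_area(base_dist,
                                              ensembles[b].distribution(stat, mode))
            rows.append({
                "mode": mode.value, "statistic": stat, "b": b,
                "overlap_vs_b0": res.O_xy,
                "mean_b0": float(base_dist.samples.mean()),
                "mean_b": float(ensembles[b].distribution(stat, mode)
                                .samples.mean()),
            })
    return pd.DataFrame(rows)
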