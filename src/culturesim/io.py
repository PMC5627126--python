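"""Reading and writing the delimited text formats used by the tool."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .params import MODE_ORDER, N_VARIANTS, TransmissionMode
from .simulate import Trajectory


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """One row per (step, mode, variant) with a count column; 1-based steps."""
    traj.to_frame().to_csv(path, index=False)


def read_counts_table(path: str | Path) -> dict[str, np.ndarray]:
    """Read a trajectory table back into per-mode (steps, variants) matrices.

    Accepts any delimited table with columns step, mode, variant, count (the
    format written by :func:`write_trajectory`), so user-supplied frequency
    time series can be fed to the statistics modules.
    """
    frame = pd.read_csv(path)
    required = {"step", "mode", "variant", "count"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    out = {}
    for mode_value, group in frame.groupby("mode"):
        pivot = group.pivot_table(index="step", columns="variant",
                                  values="count", aggfunc="sum")
        pivot = pivot.reindex(columns=range(1, N_VARIANTS + 1), fill_value=0)
        out[str(mode_value)] = pivot.sort_index().to_numpy()
    return out


def summary_from_table(path: str | Path) -> pd.DataFrame:
    """Summary statistics (p_max, k, d_s, t_max) from a counts table on disk."""
    from . import stats as sstats

    rows = []
    for mode_value, counts in read_counts_table(path).items():
        snap = sstats.snapshot_from_counts(counts[-1].astype(np.int64))
        rows.append({
            "mode": mode_value,
            "p_max": sstats.p_max(snap),
            "k": sstats.richness(snap),
            "d_s": sstats.shannon_diversity(snap),
            "t_max": sstats.t_max(sstats.most_common_series(counts)),
        })
    return pd.DataFrame(rows)
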