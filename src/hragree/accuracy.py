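"""Measurement-error indices of the test device against the reference.

MAE is the mean absolute between-device difference over paired epochs and is
judged against a clinically acceptable difference (CAD, default 10 bpm, from
the cardiac-monitor standard's permitted readout error); MAPE is the mean
absolute difference as a percentage of the reference reading, judged against
a 10% threshold.  Confidence intervals for MAE come from the subject-level
BCa cluster bootstrap — epoch-level resampling would ignore within-subject
correlation and understate the interval.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io_align import MERGED_PHASES, validate_paired
from .resampling import bca_interval, cluster_bootstrap, jackknife_clusters

__all__ = ["mae", "mape", "accuracy_by_phase"]

DEFAULT_CAD = 10.0
DEFAULT_MAPE_THRESHOLD = 10.0


def _abs_err(paired: pd.DataFrame) -> np.ndarray:
    return np.abs(paired["diff"].to_numpy(dtype=float))


def mae(paired: pd.DataFrame, B: int = 5000, seed: int = 0,
        level: float = 0.95):
    """Mean absolute error with SD and cluster-bootstrap BCa CI.

    Returns (MAE, SD of |diff|, (ci_lower, ci_upper)).  With fewer than two
    subjects the CI is returned as (nan, nan).
    """
    if len(paired) < 2:
        raise ValueError("need at least 2 paired epochs")
    ae = _abs_err(paired)
    point = float(ae.mean())
    sd = float(ae.std(ddof=1))
    stat = lambda df: float(np.abs(df["diff"]).mean())  # noqa: E731
    if paired["subject"].nunique() < 2 or B < 100:
        return point, sd, (np.nan, np.nan)
    reps = cluster_bootstrap(paired, stat, B=B, seed=seed)
    jk = jackknife_clusters(paired, stat)
    return point, sd, bca_interval(point, reps, jk, level=level)


def mape(paired: pd.DataFrame) -> float:
    """Mean absolute percentage error, in percent of the reference reading."""
    ref = paired["hr_ref"].to_numpy(dtype=float)
    if np.any(ref <= 0):
        raise ValueError("hr_ref must be positive for MAPE")
    return float(np.mean(np.abs(paired["diff"].to_numpy(dtype=float)) / ref)
                 * 100.0)


def accuracy_by_phase(paired: pd.DataFrame, cad: float = DEFAULT_CAD,
                      mape_threshold: float = DEFAULT_MAPE_THRESHOLD,
                      B: int = 5000, seed: int = 0) -> pd.DataFrame:
    """Per-phase and overall accuracy table with pass/fail flags.

    One row per phase plus an "overall" row pooling all epochs.  A row
    passes when MAE < cad and MAPE < mape_threshold.  Phases observed in
    fewer than 2 subjects get their CI marked unavailable (NaN).
    """
    validate_paired(paired)
    if paired["phase"].nunique() < 2:
        raise ValueError("need at least 2 phases for the accuracy report")
    rows = []
    order = [p for p in MERGED_PHASES if p in set(paired["phase"])]
    for label, sub in [(p, paired[paired["phase"] == p]) for p in order] + \
                      [("overall", paired)]:
        m, sd, ci = mae(sub, B=B, seed=seed)
        mp = mape(sub)
        rows.append({
            "phase": label, "mae": m, "sd_abs_err": sd,
            "ci_lower": ci[0], "ci_upper": ci[1], "mape_pct": mp,
            "n_epochs": len(sub), "n_subjects": sub["subject"].nunique(),
            "pass_accuracy": bool(m < cad and mp < mape_threshold),
        })
    out = pd.DataFrame(rows)
    out.attrs["cad"] = cad
    out.attrs["mape_threshold"] = mape_threshold
    return out
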