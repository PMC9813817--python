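"""Seeded subject-level (cluster) bootstrap with BCa confidence intervals.

Repeated-measures data violate the i.i.d. assumption of the ordinary
bootstrap: epochs within a subject are correlated, so resampling epochs
understates uncertainty.  Here the resampling unit is the subject — a
replicate dataset draws whole subjects with replacement and keeps all of a
drawn subject's epochs, relabelling duplicates as distinct subjects so that
downstream mixed models treat them as independent clusters.

Interval construction follows the standard bias-corrected and accelerated
(BCa) recipe: the bias correction z0 comes from the fraction of replicates
below the point estimate (ties counted half), the acceleration from the
skewness of leave-one-subject-out jackknife values, and the endpoints are
order statistics of the replicate vector — never extrapolations beyond it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BootstrapResult",
    "cluster_bootstrap",
    "jackknife_clusters",
    "bca_interval",
    "percentile_interval",
    "bootstrap_ci",
    "draw_cluster_counts",
]


@dataclass
class BootstrapResult:
    point: float
    replicates: np.ndarray
    ci_lower: float
    ci_upper: float
    method: str
    B: int
    seed: int


def draw_cluster_counts(n_clusters: int, B: int,
                        rng: np.random.Generator) -> np.ndarray:
    """B multinomial rows counting how often each cluster is redrawn."""
    draws = rng.integers(0, n_clusters, size=(B, n_clusters))
    counts = np.zeros((B, n_clusters), dtype=np.int64)
    for b in range(B):
        counts[b] = np.bincount(draws[b], minlength=n_clusters)
    return counts


def cluster_bootstrap(dataset: pd.DataFrame, statistic, B: int, seed: int,
                      cluster_col: str = "subject",
                      max_failures: float = 0.01) -> np.ndarray:
    """B replicates of ``statistic`` under subject resampling.

    ``statistic`` receives a DataFrame with the same columns as ``dataset``;
    in a replicate the cluster column holds fresh integer labels so that a
    subject drawn twice counts as two independent subjects.  Deterministic
    given ``seed``.  If the statistic raises on more than ``max_failures`` of
    replicates, the whole bootstrap is abandoned with a failure census.
    """
    codes, _ = pd.factorize(dataset[cluster_col], sort=True)
    n_sub = codes.max() + 1
    if n_sub < 2:
        raise ValueError("cluster bootstrap needs at least 2 subjects")
    row_idx = [np.flatnonzero(codes == i) for i in range(n_sub)]
    sizes = np.array([r.size for r in row_idx])
    rng = np.random.default_rng(seed)
    reps, failures = [], []
    for b in range(B):
        chosen = rng.integers(0, n_sub, size=n_sub)
        rows = np.concatenate([row_idx[c] for c in chosen])
        resampled = dataset.take(rows).reset_index(drop=True)
        resampled[cluster_col] = np.repeat(np.arange(n_sub), sizes[chosen])
        try:
            reps.append(statistic(resampled))
        except Exception as exc:  # noqa: BLE001 - census, then re-raise policy
            failures.append((b, repr(exc)))
            reps.append(np.nan)
    if len(failures) > max_failures * B:
        census = "; ".join(msg for _, msg in failures[:5])
        raise RuntimeError(
            f"statistic failed on {len(failures)}/{B} replicates "
            f"(first failures: {census})")
    return np.asarray(reps, dtype=float)


def jackknife_clusters(dataset: pd.DataFrame, statistic,
                       cluster_col: str = "subject") -> np.ndarray:
    """Leave-one-subject-out values of ``statistic``."""
    codes, _ = pd.factorize(dataset[cluster_col], sort=True)
    vals = []
    for i in range(codes.max() + 1):
        vals.append(statistic(dataset[codes != i]))
    return np.asarray(vals, dtype=float)


def percentile_interval(replicates: np.ndarray,
                        level: float = 0.95) -> tuple[float, float]:
    reps = np.sort(replicates[np.isfinite(replicates)])
    alpha = (1.0 - level) / 2.0
    return (_order_stat(reps, alpha), _order_stat(reps, 1.0 - alpha))


def bca_interval(point: float, replicates: np.ndarray,
                 jackknife_values: np.ndarray,
                 level: float = 0.95) -> tuple[float, float]:
    """Bias-corrected and accelerated interval from bootstrap replicates.

    Falls back to a degenerate (point, point) interval with a warning when
    every replicate is identical (z0 undefined).
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    reps = np.sort(replicates[np.isfinite(replicates)])
    B = reps.size
    if B < 100:
        raise ValueError("need at least 100 replicates for a CI")
    if np.ptp(reps) == 0.0:
        if reps[0] != point:
            warnings.warn("all bootstrap replicates identical; degenerate CI",
                          RuntimeWarning, stacklevel=2)
        return (float(point), float(point))
    # z0: fraction of replicates below the point, ties counted half
    frac = (np.sum(reps < point) + 0.5 * np.sum(reps == point)) / B
    frac = min(max(frac, 1.0 / (2 * B)), 1.0 - 1.0 / (2 * B))
    z0 = stats.norm.ppf(frac)
    # acceleration from jackknife skewness
    jk = np.asarray(jackknife_values, dtype=float)
    d = jk.mean() - jk
    denom = np.sum(d ** 2) ** 1.5
    a = np.sum(d ** 3) / (6.0 * denom) if denom > 0 else 0.0
    alpha = (1.0 - level) / 2.0
    out = []
    for q in (alpha, 1.0 - alpha):
        zq = stats.norm.ppf(q)
        adj = stats.norm.cdf(z0 + (z0 + zq) / (1.0 - a * (z0 + zq)))
        out.append(_order_stat(reps, adj))
    lo, hi = min(out), max(out)
    return (lo, hi)


def _order_stat(sorted_reps: np.ndarray, q: float) -> float:
    """The order statistic nearest rank q*B (no interpolation beyond data)."""
    B = sorted_reps.size
    k = int(np.clip(np.floor(q * B), 0, B - 1))
    return float(sorted_reps[k])


def bootstrap_ci(dataset: pd.DataFrame, statistic, B: int = 5000,
                 seed: int = 0, level: float = 0.95, method: str = "bca",
                 cluster_col: str = "subject") -> BootstrapResult:
    """Point estimate plus cluster-bootstrap CI in one call."""
    point = float(statistic(dataset))
    reps = cluster_bootstrap(dataset, statistic, B=B, seed=seed,
                             cluster_col=cluster_col)
    if method == "bca":
        jk = jackknife_clusters(dataset, statistic, cluster_col=cluster_col)
        lo, hi = bca_interval(point, reps, jk, level=level)
    elif method == "percentile":
        lo, hi = percentile_interval(reps, level=level)
    else:
        raise ValueError(f"unknown method {method!r}")
    return BootstrapResult(point=point, replicates=reps, ci_lower=lo,
                           ci_upper=hi, method=method, B=B, seed=seed)
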