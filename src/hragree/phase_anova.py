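"""Mixed-effects test of heart-rate differences across protocol phases.

For a single device's epoch series the model is

    bpm_spt = mu + phase_p + a_s + g_sp + e_spt

with phase a fixed effect and subject (a_s) and subject-by-phase (g_sp)
random, fit by bounded REML.  The omnibus phase test uses a Wald F with
Satterthwaite denominator degrees of freedom; its effect size is partial
eta-squared with a 90% CI by noncentral-F inversion.  Post hoc pairwise
phase contrasts are Tukey-adjusted on the studentized-range distribution at
each contrast's Satterthwaite df.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .io_align import HRSeries, MERGED_PHASES
from .lmm import VarianceComponentsModel, VCFit, _theta_cov, \
    satterthwaite_f, satterthwaite_t

__all__ = [
    "VarianceComponents",
    "MixedFitResult",
    "OmnibusResult",
    "fit_phase_model",
    "omnibus_test",
    "pairwise_contrasts",
]


@dataclass
class VarianceComponents:
    sigma2_subject: float
    sigma2_interaction: float
    sigma2_resid: float
    sigma2_phase_spread: float | None = None  # dispersion of the fixed phase means

    def as_dict(self) -> dict[str, float]:
        d = {"sigma2_subject": self.sigma2_subject,
             "sigma2_interaction": self.sigma2_interaction,
             "sigma2_resid": self.sigma2_resid}
        if self.sigma2_phase_spread is not None:
            d["sigma2_phase_spread"] = self.sigma2_phase_spread
        return d


@dataclass
class MixedFitResult:
    phase_means: dict[str, float]  # estimated marginal mean bpm per phase
    vc: VarianceComponents
    loglik: float
    n_obs: int
    n_subjects: int
    phases: list[str]
    fit: VCFit
    converged: bool


@dataclass
class OmnibusResult:
    F: float
    df_num: int
    df_den: float
    p: float
    eta2_partial: float
    eta2_ci90: tuple[float, float]


def _to_frame(labeled_series) -> pd.DataFrame:
    if isinstance(labeled_series, pd.DataFrame):
        df = labeled_series
        for col in ("subject", "phase", "bpm"):
            if col not in df.columns:
                raise ValueError(f"input frame lacks column {col!r}")
        return df[["subject", "phase", "bpm"]].copy()
    rows = []
    for s in labeled_series:
        if not isinstance(s, HRSeries) or not s.labeled:
            raise ValueError("expected phase-labeled HRSeries")
        rows.append(pd.DataFrame({"subject": s.subject, "phase": s.phases,
                                  "bpm": s.bpm}))
    return pd.concat(rows, ignore_index=True)


def fit_phase_model(labeled_series) -> MixedFitResult:
    """REML fit of bpm ~ phase with random subject and subject-by-phase.

    Accepts either a list of labeled :class:`HRSeries` for one device or a
    long DataFrame with columns (subject, phase, bpm).
    """
    df = _to_frame(labeled_series)
    phases = [p for p in MERGED_PHASES if p in set(df["phase"])]
    phases += sorted(set(df["phase"]) - set(phases))
    if df["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    if len(phases) < 2:
        raise ValueError("need at least 2 phases")
    cell_counts = df.groupby(["subject", "phase"], observed=True).size()
    if (cell_counts < 2).any():
        thin = cell_counts[cell_counts < 2].index.tolist()[:3]
        raise ValueError(f"need >= 2 observations per subject-phase cell "
                         f"(thin cells: {thin})")

    y = df["bpm"].to_numpy(dtype=float)
    X, x_names = _phase_design(df["phase"].to_numpy(), phases)
    cell = df["subject"].astype(str) + "//" + df["phase"].astype(str)
    model = VarianceComponentsModel(
        y, X, df["subject"].to_numpy(),
        vc_terms={"subject": df["subject"].to_numpy(),
                  "subject_phase": cell.to_numpy()},
        x_names=x_names)
    fit = model.fit()

    means = {phases[0]: fit.beta[0]}
    for j, ph in enumerate(phases[1:], start=1):
        means[ph] = fit.beta[0] + fit.beta[j]
    spread = float(np.var(list(means.values()), ddof=1))
    vc = VarianceComponents(
        sigma2_subject=fit.vc["subject"],
        sigma2_interaction=fit.vc["subject_phase"],
        sigma2_resid=fit.s2e,
        sigma2_phase_spread=spread)
    return MixedFitResult(phase_means=means, vc=vc, loglik=fit.loglik,
                          n_obs=fit.n_obs, n_subjects=fit.n_subjects,
                          phases=phases, fit=fit, converged=fit.converged)


def _phase_design(phase_col: np.ndarray, phases: list[str]):
    X = np.ones((phase_col.size, len(phases)))
    for j, ph in enumerate(phases[1:], start=1):
        X[:, j] = (phase_col == ph).astype(float)
    names = ["intercept"] + [f"phase[{p}]" for p in phases[1:]]
    return X, names


def omnibus_test(result: MixedFitResult) -> OmnibusResult:
    """Satterthwaite F test of the phase fixed effect with partial eta^2."""
    fit = result.fit
    total = fit.s2e + sum(fit.vc.values())
    if fit.degenerate or fit.s2e <= 1e-6 * max(total, 1e-12):
        raise ValueError("degenerate fit: residual variance is zero")
    q = len(result.phases) - 1
    L = np.zeros((q, len(fit.beta)))
    L[:, 1:] = np.eye(q)
    F, df_num, df_den, p = satterthwaite_f(fit, L)
    eta2 = F * df_num / (F * df_num + df_den)
    ci = _eta2_ci(F, df_num, df_den, level=0.90)
    return OmnibusResult(F=F, df_num=df_num, df_den=df_den, p=p,
                         eta2_partial=float(eta2), eta2_ci90=ci)


def _eta2_ci(F: float, dfn: float, dfd: float,
             level: float = 0.90) -> tuple[float, float]:
    """Noncentrality-inversion CI for partial eta^2 (Steiger's method)."""
    alpha = (1.0 - level) / 2.0

    def bound(target_cdf: float) -> float:
        if stats.ncf.cdf(F, dfn, dfd, 0.0) < target_cdf:
            return 0.0
        hi = 10.0
        while stats.ncf.cdf(F, dfn, dfd, hi) > target_cdf and hi < 1e7:
            hi *= 2.0
        if stats.ncf.cdf(F, dfn, dfd, hi) > target_cdf:
            return hi / (hi + dfn + dfd + 1.0)  # effectively eta2 -> 1
        nc = optimize.brentq(
            lambda l: stats.ncf.cdf(F, dfn, dfd, l) - target_cdf, 0.0, hi)
        return nc / (nc + dfn + dfd + 1.0)

    return (bound(1.0 - alpha), bound(alpha))


def pairwise_contrasts(result: MixedFitResult) -> pd.DataFrame:
    """All pairwise phase differences with Tukey-adjusted p-values.

    With fewer than 3 phases the studentized-range adjustment degenerates;
    unadjusted p-values are returned with a warning.
    """
    fit = result.fit
    phases = result.phases
    k = len(phases)
    adjust = k >= 3
    if not adjust:
        warnings.warn("fewer than 3 phases: p-values are unadjusted",
                      RuntimeWarning, stacklevel=2)
    A = np.zeros((len(fit.theta),) * 2) if fit.degenerate else _theta_cov(fit)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            ell = np.zeros(len(fit.beta))
            if i > 0:
                ell[i] = -1.0
            if j > 0:
                ell[j] = 1.0
            # estimate is phase_j - phase_i on the dummy scale; report i - j
            est, se, df = satterthwaite_t(fit, -ell, theta_cov=A)
            if se == 0:
                t, p = 0.0, 1.0
            else:
                t = est / se
                if adjust:
                    p = float(stats.studentized_range.sf(
                        abs(t) * np.sqrt(2.0), k, df))
                else:
                    p = float(2.0 * stats.t.sf(abs(t), df))
            rows.append((phases[i], phases[j], est, se, df, t,
                         min(max(p, 0.0), 1.0)))
    return pd.DataFrame(rows, columns=["phase_i", "phase_j", "estimate",
                                       "se", "df", "t", "adjusted_p"])
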