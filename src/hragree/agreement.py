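"""Repeated-measures agreement between a test and a reference device.

All metrics derive from mixed-model variance components on the paired
epochs.  Writing D = test - reference:

* **bias / LoA** — a mixed model on D with random subject and
  subject-by-phase effects gives the mean bias mu_d and the total variance
  of D; the 95% limits of agreement are mu_d +/- 1.96 * sqrt(Var D).
* **MSD** — mean squared deviation E[D^2] = mu_d^2 + Var D.
* **CP** — coverage probability P(|D| <= CAD) under D ~ N(mu_d, MSD - mu_d^2).
* **TDI** — total deviation index, the half-width containing p*100% of |D|;
  normal approximation z_{(1+p)/2} * sqrt(MSD).
* **CIA** — coefficient of individual agreement 2*sigma2_e / MSD, the
  within-device replication disagreement (numerator: expected squared
  difference of two replicates on the same device, 2*sigma2_e) relative to
  the between-device disagreement (MSD); 1 means devices interchangeable at
  the individual level.
* **RC** — repeatability coefficient 1.96 * sqrt(2*sigma2_e).
* **CCC** — concordance correlation coefficient from the variance components
  of the stacked two-device model (Carrasco-Jover form), with the squared
  fixed device offset entering the denominator as beta^2/2.

The replication variance sigma2_e in CIA and RC is the residual of the
stacked two-device model.  Confidence intervals use the subject-level BCa
cluster bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io_align import MERGED_PHASES, validate_paired
from .lmm import ConvergenceError, VarianceComponentsModel, VCFit
from .resampling import bca_interval, draw_cluster_counts

__all__ = [
    "DifferenceModelFit",
    "CCCResult",
    "AgreementReport",
    "fit_difference_model",
    "loa_mixed",
    "msd",
    "coverage_probability",
    "total_deviation_index",
    "repeatability_coefficient",
    "cia",
    "ccc_vc",
    "classify_ccc",
    "agreement_report",
    "agreement_by_phase",
]

Z975 = 1.959964  # standard-normal 97.5% quantile, as used in 95% limits


@dataclass
class DifferenceModelFit:
    """Mixed model on the between-device differences."""

    bias: float
    vc_diff: dict[str, float]  # subject, subject_phase, resid components of D
    total_var_diff: float
    fit: VCFit | None = field(default=None, repr=False)

    @property
    def sd_diff(self) -> float:
        return float(np.sqrt(self.total_var_diff))


@dataclass
class CCCResult:
    ccc: float
    ci: tuple[float, float] | None
    band: str
    components: dict[str, float]
    device_offset: float  # fixed-effect difference test - ref


def fit_difference_model(paired: pd.DataFrame) -> DifferenceModelFit:
    """REML fit of D ~ 1 with random subject and subject-by-phase effects.

    With a single phase present the subject-by-phase term is confounded with
    the subject term and is dropped (its component reported as 0).
    """
    validate_paired(paired)
    n_sub = paired["subject"].nunique()
    if n_sub < 2:
        raise ValueError("need at least 2 subjects for the difference model")
    counts = paired.groupby("subject").size()
    if (counts < 2).any():
        raise ValueError("every subject needs at least 2 paired epochs")
    y = paired["diff"].to_numpy(dtype=float)
    X = np.ones((y.size, 1))
    subj = paired["subject"].to_numpy()
    multi_phase = paired["phase"].nunique() > 1
    terms: dict[str, np.ndarray] = {"subject": subj}
    if multi_phase:
        cell = paired["subject"].astype(str) + "//" + paired["phase"].astype(str)
        terms["subject_phase"] = cell.to_numpy()
    model = VarianceComponentsModel(y, X, subj, vc_terms=terms,
                                    x_names=["bias"])
    fit = model.fit()
    vc = {"subject": fit.vc["subject"],
          "subject_phase": fit.vc.get("subject_phase", 0.0),
          "resid": fit.s2e if not fit.degenerate else 0.0}
    return DifferenceModelFit(bias=float(fit.beta[0]), vc_diff=vc,
                              total_var_diff=float(sum(vc.values())), fit=fit)


def loa_mixed(fit: DifferenceModelFit, level: float = 0.95):
    """Limits of agreement (bias, lower, upper) at the given level."""
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * fit.sd_diff
    return fit.bias, fit.bias - half, fit.bias + half


def msd(fit: DifferenceModelFit) -> float:
    """Mean squared deviation E[D^2] = bias^2 + Var(D)."""
    return float(fit.bias ** 2 + fit.total_var_diff)


def coverage_probability(bias: float, msd: float, cad: float) -> float:
    """P(|D| <= cad) under D ~ Normal(bias, msd - bias^2)."""
    if cad <= 0:
        raise ValueError("cad must be positive")
    var = msd - bias ** 2
    if var < -1e-12 * max(msd, 1.0):
        raise ValueError("msd must be at least bias^2")
    sigma = np.sqrt(max(var, 0.0))
    if sigma == 0.0:
        return float(abs(bias) <= cad)
    return float(stats.norm.cdf((cad - bias) / sigma)
                 - stats.norm.cdf((-cad - bias) / sigma))


def total_deviation_index(msd: float, p: float = 0.95) -> float:
    """Normal-approximation TDI: z_{(1+p)/2} * sqrt(msd)."""
    if msd < 0:
        raise ValueError("msd must be non-negative")
    if not 0.0 < p < 1.0:
        raise ValueError("p must be in (0, 1)")
    return float(stats.norm.ppf(0.5 + p / 2.0) * np.sqrt(msd))


def repeatability_coefficient(sigma2_resid: float) -> float:
    """Bland-Altman repeatability coefficient 1.96 * sqrt(2 * sigma2_e)."""
    if sigma2_resid < 0:
        raise ValueError("sigma2_resid must be non-negative")
    return float(Z975 * np.sqrt(2.0 * sigma2_resid))


def cia(sigma2_resid: float, msd: float) -> float:
    """Coefficient of individual agreement 2*sigma2_e / MSD.

    A zero MSD means the devices never disagree: with zero replication
    variance that is perfect individual agreement (1.0); with positive
    replication variance the ratio is undefined and raises.
    """
    if sigma2_resid < 0:
        raise ValueError("sigma2_resid must be non-negative")
    if msd == 0.0:
        if sigma2_resid > 0.0:
            raise ValueError("CIA undefined: msd is 0 with positive "
                             "replication variance")
        return 1.0
    if msd < 0:
        raise ValueError("msd must be non-negative")
    return float(2.0 * sigma2_resid / msd)


def classify_ccc(value: float) -> str:
    """Interpretation bands: <0.90 poor, 0.90-0.95 moderate,
    0.95-0.99 substantial, >0.99 perfect."""
    if value < 0.90:
        return "poor"
    if value < 0.95:
        return "moderate"
    if value <= 0.99:
        return "substantial"
    return "perfect"


# ------------------------------------------------------------------- CCC fit

def _stack(paired: pd.DataFrame) -> pd.DataFrame:
    long = pd.concat([
        pd.DataFrame({"subject": paired["subject"], "phase": paired["phase"],
                      "epoch_index": paired["epoch_index"], "device": "ref",
                      "bpm": paired["hr_ref"]}),
        pd.DataFrame({"subject": paired["subject"], "phase": paired["phase"],
                      "epoch_index": paired["epoch_index"], "device": "test",
                      "bpm": paired["hr_test"]}),
    ], ignore_index=True)
    return long


def _ccc_model(paired: pd.DataFrame):
    """Build the stacked two-device variance-components model."""
    long = _stack(paired)
    phases = [p for p in MERGED_PHASES if p in set(long["phase"])]
    phases += sorted(set(long["phase"]) - set(phases))
    multi_phase = len(phases) > 1
    X_cols = [np.ones(len(long)), (long["device"] == "test").to_numpy(float)]
    names = ["intercept", "device[test]"]
    for ph in phases[1:]:
        X_cols.append((long["phase"] == ph).to_numpy(float))
        names.append(f"phase[{ph}]")
    X = np.column_stack(X_cols)
    subj = long["subject"].to_numpy()
    terms: dict[str, np.ndarray] = {"subject": subj}
    if multi_phase:
        terms["subject_phase"] = (long["subject"].astype(str) + "//"
                                  + long["phase"].astype(str)).to_numpy()
    cell_dev = long.groupby(["subject", "device"]).size()
    if (cell_dev >= 2).all():
        terms["subject_device"] = (long["subject"].astype(str) + "//"
                                   + long["device"].astype(str)).to_numpy()
    else:
        warnings.warn("subject-by-device component inestimable with <2 "
                      "epochs per cell; term dropped", RuntimeWarning,
                      stacklevel=3)
    return VarianceComponentsModel(long["bpm"].to_numpy(float), X, subj,
                                   vc_terms=terms, x_names=names)


def _ccc_from_fit(fit: VCFit) -> tuple[float, dict[str, float], float]:
    s_subj = fit.vc.get("subject", 0.0)
    s_sp = fit.vc.get("subject_phase", 0.0)
    s_sd = fit.vc.get("subject_device", 0.0)
    beta_dev = float(fit.beta[fit.x_names.index("device[test]")])
    s_beta = beta_dev ** 2 / 2.0
    s_e = fit.s2e if not fit.degenerate else 0.0
    denom = s_subj + s_sp + s_sd + s_beta + s_e
    value = 1.0 if denom == 0.0 else (s_subj + s_sp) / denom
    comps = {"subject": s_subj, "subject_phase": s_sp,
             "subject_device": s_sd, "device_offset_sq_half": s_beta,
             "resid": s_e}
    return float(value), comps, beta_dev


def ccc_vc(paired: pd.DataFrame, B: int = 0, seed: int = 0,
           level: float = 0.95) -> CCCResult:
    """Concordance correlation coefficient from variance components.

    CCC = (s2_subject + s2_subject_phase) /
          (s2_subject + s2_subject_phase + s2_subject_device
           + (device offset)^2 / 2 + s2_resid).

    Identical device columns short-circuit to CCC = 1 (the moment
    definition of concordance is exactly 1 there, whereas the
    variance-components ratio would charge shared within-cell fluctuation
    against two indistinguishable devices).  Set ``B`` >= 100 for a
    subject-level BCa bootstrap CI.
    """
    validate_paired(paired)
    if paired["subject"].nunique() < 2:
        raise ValueError("need at least 2 subjects")
    if np.allclose(paired["hr_ref"], paired["hr_test"]):
        return CCCResult(ccc=1.0, ci=None, band=classify_ccc(1.0),
                         components={}, device_offset=0.0)
    model = _ccc_model(paired)
    fit = model.fit()
    value, comps, beta_dev = _ccc_from_fit(fit)
    ci = None
    if B >= 100:
        rng = np.random.default_rng(seed)
        counts = draw_cluster_counts(model.n_subjects, B, rng)
        reps = np.empty(B)
        jk = np.empty(model.n_subjects)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for b in range(B):
                try:
                    reps[b] = _ccc_from_fit(
                        model.fit(weights=counts[b], start=fit.theta))[0]
                except (ConvergenceError, np.linalg.LinAlgError):
                    reps[b] = np.nan
            for i in range(model.n_subjects):
                w = np.ones(model.n_subjects)
                w[i] = 0.0
                jk[i] = _ccc_from_fit(model.fit(weights=w,
                                                start=fit.theta))[0]
        ci = bca_interval(value, reps, jk, level=level)
    return CCCResult(ccc=value, ci=ci, band=classify_ccc(value),
                     components=comps, device_offset=beta_dev)


# ------------------------------------------------------------------- reports

@dataclass
class AgreementReport:
    bias: float
    bias_ci: tuple[float, float] | None
    loa_lower: float
    loa_upper: float
    loa_lower_ci: tuple[float, float] | None
    loa_upper_ci: tuple[float, float] | None
    msd: float
    msd_ci: tuple[float, float] | None
    cp: float
    cp_ci: tuple[float, float] | None
    tdi: float
    tdi_ci: tuple[float, float] | None
    ccc: float
    ccc_ci: tuple[float, float] | None
    ccc_band: str
    cia: float
    cia_ci: tuple[float, float] | None
    rc: float
    cad: float
    tdi_p: float
    level: float
    vc_diff: dict[str, float]
    per_phase: pd.DataFrame | None = None
    B: int = 0
    seed: int = 0

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "per_phase"}
        for k, v in list(d.items()):
            if isinstance(v, tuple):
                d[k] = list(v)
        if self.per_phase is not None:
            d["per_phase"] = self.per_phase.to_dict(orient="records")
        return d


_METRICS = ["bias", "loa_lower", "loa_upper", "msd", "cp", "tdi", "cia", "ccc"]


def _point_metrics(diff_fit: DifferenceModelFit, s2e_stacked: float,
                   ccc_value: float, cad: float, tdi_p: float,
                   level: float) -> dict[str, float]:
    bias, lo, hi = loa_mixed(diff_fit, level=level)
    m = msd(diff_fit)
    if m == 0.0:  # devices literally never disagree
        cia_val = 1.0
    else:
        cia_val = cia(s2e_stacked, m)
    return {"bias": bias, "loa_lower": lo, "loa_upper": hi, "msd": m,
            "cp": coverage_probability(bias, m, cad),
            "tdi": total_deviation_index(m, tdi_p),
            "cia": cia_val, "ccc": ccc_value}


def agreement_report(paired: pd.DataFrame, cad: float = 10.0,
                     tdi_p: float = 0.95, level: float = 0.95,
                     B: int = 5000, seed: int = 0,
                     per_phase: bool = True) -> AgreementReport:
    """Full agreement panel with subject-level BCa bootstrap CIs.

    Set ``B`` = 0 to skip confidence intervals (point estimates only).
    Bootstrap replicates reuse each model's per-subject sufficient
    statistics via resampling weights, so a replicate costs one REML
    optimisation, not a dataset rebuild.
    """
    validate_paired(paired)
    diff_fit = fit_difference_model(paired)
    perfect = np.allclose(paired["hr_ref"], paired["hr_test"])
    if perfect:
        s2e_stacked = 0.0
        ccc_value = 1.0
        ccc_model = None
    else:
        ccc_model = _ccc_model(paired)
        ccc_full = ccc_model.fit()
        ccc_value, _, _ = _ccc_from_fit(ccc_full)
        s2e_stacked = ccc_full.s2e if not ccc_full.degenerate else 0.0
    pts = _point_metrics(diff_fit, s2e_stacked, ccc_value, cad, tdi_p, level)
    rc = repeatability_coefficient(s2e_stacked)

    cis: dict[str, tuple[float, float] | None] = {m: None for m in _METRICS}
    if B >= 100 and not perfect:
        diff_model = diff_fit.fit.model
        n_sub = diff_model.n_subjects
        rng = np.random.default_rng(seed)
        counts = draw_cluster_counts(n_sub, B, rng)

        def replicate(w) -> list[float]:
            dfit = diff_model.fit(weights=w, start=diff_fit.fit.theta)
            vc = {"subject": dfit.vc["subject"],
                  "subject_phase": dfit.vc.get("subject_phase", 0.0),
                  "resid": dfit.s2e if not dfit.degenerate else 0.0}
            dres = DifferenceModelFit(bias=float(dfit.beta[0]), vc_diff=vc,
                                      total_var_diff=float(sum(vc.values())))
            cfit = ccc_model.fit(weights=w, start=ccc_full.theta)
            cval, _, _ = _ccc_from_fit(cfit)
            s2e_b = cfit.s2e if not cfit.degenerate else 0.0
            p = _point_metrics(dres, s2e_b, cval, cad, tdi_p, level)
            return [p[m] for m in _METRICS]

        reps = np.full((B, len(_METRICS)), np.nan)
        jack = np.empty((n_sub, len(_METRICS)))
        failures = 0
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            for b in range(B):
                try:
                    reps[b] = replicate(counts[b])
                except (ConvergenceError, np.linalg.LinAlgError, ValueError):
                    failures += 1
            if failures > 0.01 * B:
                raise RuntimeError(
                    f"bootstrap failed on {failures}/{B} replicates")
            for i in range(n_sub):
                w = np.ones(n_sub)
                w[i] = 0.0
                jack[i] = replicate(w)
        for j, m in enumerate(_METRICS):
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                cis[m] = bca_interval(pts[m], reps[:, j], jack[:, j],
                                      level=level)

    phase_table = None
    if per_phase and paired["phase"].nunique() > 1:
        phase_table = agreement_by_phase(paired, cad=cad, tdi_p=tdi_p,
                                         level=level, B=B, seed=seed)

    return AgreementReport(
        bias=pts["bias"], bias_ci=cis["bias"],
        loa_lower=pts["loa_lower"], loa_upper=pts["loa_upper"],
        loa_lower_ci=cis["loa_lower"], loa_upper_ci=cis["loa_upper"],
        msd=pts["msd"], msd_ci=cis["msd"], cp=pts["cp"], cp_ci=cis["cp"],
        tdi=pts["tdi"], tdi_ci=cis["tdi"], ccc=pts["ccc"],
        ccc_ci=cis["ccc"], ccc_band=classify_ccc(pts["ccc"]),
        cia=pts["cia"], cia_ci=cis["cia"], rc=rc, cad=cad, tdi_p=tdi_p,
        level=level, vc_diff=diff_fit.vc_diff, per_phase=phase_table,
        B=B, seed=seed)


def agreement_by_phase(paired: pd.DataFrame, cad: float = 10.0,
                       tdi_p: float = 0.95, level: float = 0.95,
                       B: int = 0, seed: int = 0) -> pd.DataFrame:
    """Recompute every agreement metric within each phase.

    Within a phase the subject-by-phase term is confounded with subject, so
    the difference model carries a subject intercept only.  Phases failing
    the fit preconditions yield a row of NaNs (marked unavailable).
    """
    validate_paired(paired)
    rows = []
    order = [p for p in MERGED_PHASES if p in set(paired["phase"])]
    for ph in order:
        sub = paired[paired["phase"] == ph]
        row: dict = {"phase": ph, "available": True}
        try:
            rep = agreement_report(sub, cad=cad, tdi_p=tdi_p, level=level,
                                   B=B, seed=seed, per_phase=False)
            row.update({m: getattr(rep, m) for m in _METRICS})
            row["rc"] = rep.rc
            for m in _METRICS:
                ci = getattr(rep, f"{m}_ci")
                if ci is not None:
                    row[f"{m}_lo"], row[f"{m}_hi"] = ci
        except (ValueError, ConvergenceError) as exc:
            row["available"] = False
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
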