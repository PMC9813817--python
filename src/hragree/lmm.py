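"""Linear mixed models with i.i.d. variance components, fit by bounded REML.

This is the numerical core shared by the phase ANOVA, the between-device
difference model and the variance-components concordance model.  The model is

    y = X beta + sum_k Z_k u_k + e,    u_k ~ N(0, s2_k I),   e ~ N(0, s2_e I),

where every random term is a set of independent scalar effects indexed by a
grouping factor nested within subject (subject itself, subject x phase,
subject x device, ...).  Because all random factors are nested within subject,
the marginal covariance is block-diagonal by subject and each block is handled
with the Woodbury identity, so a likelihood evaluation costs O(m^3) per
subject with m = number of random-effect levels inside that subject (a handful
here).  Per-subject cross-products are precomputed once, which also makes the
subject-resampling bootstrap cheap: a resampled dataset only changes the
non-negative integer weight attached to each subject's contribution.

Variances are optimised directly under non-negativity bounds (L-BFGS-B), so
singular fits sit on the boundary instead of failing.  Satterthwaite
denominator degrees of freedom are computed from the REML variance-parameter
covariance (inverse observed information) by the eigen-decomposition method
used for multi-degree-of-freedom fixed-effect tests in mixed models.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import linalg, optimize, stats

__all__ = [
    "ConvergenceError",
    "VCFit",
    "VarianceComponentsModel",
    "satterthwaite_f",
    "satterthwaite_t",
]

_LOG2PI = np.log(2.0 * np.pi)


class ConvergenceError(RuntimeError):
    """REML optimisation failed; carries the optimizer's trace message."""


@dataclass
class _SubjectBlock:
    n: int
    yty: float
    Xty: np.ndarray
    XtX: np.ndarray
    Zty: np.ndarray
    ZtX: np.ndarray
    ZtZ: np.ndarray
    col_term: np.ndarray  # term index of each Z column


@dataclass
class VCFit:
    """Result of a bounded-REML fit.

    ``vc`` maps each random-term name to its variance estimate (bpm^2 here);
    ``s2e`` is the residual variance.  ``cov_beta`` is the GLS covariance of
    the fixed effects at the REML estimates.
    """

    beta: np.ndarray
    x_names: list[str]
    vc: dict[str, float]
    s2e: float
    cov_beta: np.ndarray
    loglik: float
    n_obs: int
    n_subjects: int
    converged: bool
    degenerate: bool = False
    model: "VarianceComponentsModel | None" = field(default=None, repr=False)
    weights: np.ndarray | None = field(default=None, repr=False)

    @property
    def theta(self) -> np.ndarray:
        return np.array(list(self.vc.values()) + [self.s2e])

    def fixef(self) -> dict[str, float]:
        return dict(zip(self.x_names, self.beta))


class VarianceComponentsModel:
    """REML estimation of i.i.d. variance components nested within subjects.

    Parameters
    ----------
    y : response vector.
    X : fixed-effects design matrix (full column rank).
    subjects : per-row subject labels; the covariance is block-diagonal in
        these and they are the bootstrap resampling unit.
    vc_terms : mapping term-name -> per-row level codes (any hashable labels).
        Each term contributes one variance; levels must be nested within
        subject (e.g. subject, subject-phase cell, subject-device cell).
    """

    def __init__(self, y, X, subjects, vc_terms: dict[str, np.ndarray],
                 x_names: list[str] | None = None):
        y = np.asarray(y, dtype=float)
        X = np.asarray(X, dtype=float)
        if X.ndim == 1:
            X = X[:, None]
        if y.shape[0] != X.shape[0]:
            raise ValueError("y and X have incompatible lengths")
        self.y, self.X = y, X
        self.n, self.p = X.shape
        self.x_names = list(x_names) if x_names is not None else [
            f"x{j}" for j in range(self.p)]
        self.term_names = list(vc_terms)
        self.k = len(self.term_names)

        subj = np.asarray(subjects)
        subj_codes, self.subject_labels = _factorize(subj)
        term_codes = [_factorize(np.asarray(c))[0] for c in vc_terms.values()]
        for name, codes in zip(self.term_names, term_codes):
            if codes.shape[0] != self.n:
                raise ValueError(f"vc term {name!r} has wrong length")

        blocks: list[_SubjectBlock] = []
        for i in range(len(self.subject_labels)):
            rows = np.flatnonzero(subj_codes == i)
            yi, Xi = y[rows], X[rows]
            zcols, col_term = [], []
            for t, codes in enumerate(term_codes):
                local = codes[rows]
                for lev in np.unique(local):
                    zcols.append((local == lev).astype(float))
                    col_term.append(t)
            Z = np.column_stack(zcols) if zcols else np.empty((len(rows), 0))
            blocks.append(_SubjectBlock(
                n=len(rows), yty=float(yi @ yi), Xty=Xi.T @ yi,
                XtX=Xi.T @ Xi, Zty=Z.T @ yi, ZtX=Z.T @ Xi, ZtZ=Z.T @ Z,
                col_term=np.array(col_term, dtype=int)))
        self.n_subjects = len(blocks)
        # batch subjects that share a random-effect layout so a likelihood
        # evaluation is a handful of stacked linear solves, not a per-subject
        # Python loop (balanced designs collapse to a single batch)
        self._groups = []
        by_layout: dict[tuple, list[int]] = {}
        for i, b in enumerate(blocks):
            by_layout.setdefault(tuple(b.col_term), []).append(i)
        for layout, idx in by_layout.items():
            bs = [blocks[i] for i in idx]
            self._groups.append({
                "idx": np.array(idx, dtype=int),
                "col_term": np.array(layout, dtype=int),
                "n": np.array([b.n for b in bs], dtype=float),
                "yty": np.array([b.yty for b in bs]),
                "Xty": np.stack([b.Xty for b in bs]),
                "XtX": np.stack([b.XtX for b in bs]),
                "Zty": np.stack([b.Zty for b in bs]),
                "ZtX": np.stack([b.ZtX for b in bs]),
                "ZtZ": np.stack([b.ZtZ for b in bs]),
            })
        # scale for optimizer conditioning and degenerate detection
        beta_ols, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta_ols
        self._beta_ols = beta_ols
        self._s2_ols = float(resid @ resid / max(self.n - self.p, 1))
        self._scale = max(self._s2_ols, 1e-12)

    # ------------------------------------------------------------------ REML

    def _accumulate(self, theta: np.ndarray, weights: np.ndarray):
        """Return (logdetV, XtVX, XtVy, yVy, n_eff) across weighted subjects."""
        s2 = np.asarray(theta[:-1], dtype=float)
        s2e = float(theta[-1])
        if s2e <= 0:
            raise ValueError("residual variance must be positive")
        logdet = 0.0
        XtVX = np.zeros((self.p, self.p))
        XtVy = np.zeros(self.p)
        yVy = 0.0
        n_eff = 0.0
        for grp in self._groups:
            w = weights[grp["idx"]]
            if not np.any(w):
                continue
            g = s2[grp["col_term"]] if grp["col_term"].size else np.empty(0)
            act = np.flatnonzero(g > 0)
            ld = grp["n"] * np.log(s2e)
            if act.size:
                ga = g[act]
                ZtZa = grp["ZtZ"][np.ix_(np.arange(len(w)), act, act)]
                B = ZtZa / s2e + np.diag(1.0 / ga)
                sign, ldB = np.linalg.slogdet(B)
                if np.any(sign <= 0):
                    raise np.linalg.LinAlgError("inner system not PD")
                ld = ld + ldB + np.sum(np.log(ga))
                ZX = grp["ZtX"][:, act, :]
                Zy = grp["Zty"][:, act]
                rhs = np.concatenate([ZX, Zy[:, :, None]], axis=2)
                sol = np.linalg.solve(B, rhs)
                U, v = sol[:, :, :-1], sol[:, :, -1]
                XtVX_i = (grp["XtX"]
                          - np.einsum("bmp,bmq->bpq", ZX, U) / s2e) / s2e
                XtVy_i = (grp["Xty"]
                          - np.einsum("bmp,bm->bp", ZX, v) / s2e) / s2e
                yVy_i = (grp["yty"]
                         - np.einsum("bm,bm->b", Zy, v) / s2e) / s2e
            else:
                XtVX_i = grp["XtX"] / s2e
                XtVy_i = grp["Xty"] / s2e
                yVy_i = grp["yty"] / s2e
            logdet += float(w @ ld)
            XtVX += np.einsum("b,bpq->pq", w, XtVX_i)
            XtVy += w @ XtVy_i
            yVy += float(w @ yVy_i)
            n_eff += float(w @ grp["n"])
        return logdet, XtVX, XtVy, yVy, n_eff

    def neg2_reml(self, theta: np.ndarray, weights: np.ndarray | None = None) -> float:
        w = self._weights(weights)
        logdet, XtVX, XtVy, yVy, n_eff = self._accumulate(theta, w)
        beta = np.linalg.solve(XtVX, XtVy)
        yPy = yVy - XtVy @ beta
        sign, ldXVX = np.linalg.slogdet(XtVX)
        if sign <= 0:
            return np.inf
        return float(logdet + ldXVX + yPy + (n_eff - self.p) * _LOG2PI)

    def _weights(self, weights):
        if weights is None:
            return np.ones(self.n_subjects)
        w = np.asarray(weights, dtype=float)
        if w.shape[0] != self.n_subjects:
            raise ValueError("weights must have one entry per subject")
        return w

    def cov_beta(self, theta: np.ndarray, weights: np.ndarray | None = None) -> np.ndarray:
        _, XtVX, *_ = self._accumulate(theta, self._weights(weights))
        return np.linalg.inv(XtVX)

    def fit(self, weights: np.ndarray | None = None,
            start: np.ndarray | None = None) -> VCFit:
        """Bounded REML fit; variance components constrained to be >= 0.

        A response with (numerically) zero residual variation short-circuits
        to the obvious degenerate fit: OLS fixed effects, all components zero.
        """
        w = self._weights(weights)
        if self._s2_ols <= 1e-10 * max(1.0, float(np.var(self.y))) or \
                self._s2_ols <= 1e-12:
            vc = {name: 0.0 for name in self.term_names}
            return VCFit(beta=self._beta_ols.copy(), x_names=self.x_names,
                         vc=vc, s2e=float(self._s2_ols) or 1e-12,
                         cov_beta=np.zeros((self.p, self.p)), loglik=np.nan,
                         n_obs=self.n, n_subjects=int(np.sum(w > 0)),
                         converged=True, degenerate=True, model=self,
                         weights=w)

        sc = self._scale
        lb = np.r_[np.zeros(self.k), 1e-8]
        if start is not None:
            u0 = np.maximum(np.asarray(start, dtype=float) / sc, lb)
        else:
            u0 = np.r_[np.full(self.k, 0.5 / max(self.k, 1)), 0.5]

        def obj(u):
            try:
                return self.neg2_reml(u * sc, w)
            except (np.linalg.LinAlgError, ValueError):
                return np.inf

        res = optimize.minimize(obj, u0, method="L-BFGS-B",
                                bounds=[(lo, None) for lo in lb],
                                options={"maxiter": 500, "ftol": 1e-12,
                                         "gtol": 1e-8})
        if not res.success or not np.isfinite(res.fun):
            # one restart from an inflated-components corner
            res2 = optimize.minimize(obj, np.r_[np.full(self.k, 1.0), 0.3],
                                     method="L-BFGS-B",
                                     bounds=[(lo, None) for lo in lb],
                                     options={"maxiter": 800})
            if res2.success and res2.fun <= res.fun:
                res = res2
            elif not res.success and not np.isfinite(res.fun):
                raise ConvergenceError(
                    f"REML optimisation failed: {res.message!r} "
                    f"(fun={res.fun}, nit={res.nit})")
        theta = res.x * sc
        # snap tiny boundary-adjacent components to exactly zero
        tiny = 1e-8 * sc
        theta[:-1] = np.where(theta[:-1] < tiny, 0.0, theta[:-1])
        logdet, XtVX, XtVy, yVy, n_eff = self._accumulate(theta, w)
        beta = np.linalg.solve(XtVX, XtVy)
        vc = dict(zip(self.term_names, theta[:-1]))
        if any(v == 0.0 for v in vc.values()):
            warnings.warn("singular fit: one or more variance components "
                          "estimated at the zero boundary", RuntimeWarning,
                          stacklevel=2)
        return VCFit(beta=beta, x_names=self.x_names, vc=vc,
                     s2e=float(theta[-1]), cov_beta=np.linalg.inv(XtVX),
                     loglik=-0.5 * self.neg2_reml(theta, w), n_obs=self.n,
                     n_subjects=int(np.sum(w > 0)), converged=True,
                     model=self, weights=w)


# ------------------------------------------------------------- Satterthwaite

def _theta_cov(fit: VCFit) -> np.ndarray:
    """Asymptotic covariance of the variance parameters: 2 * H^-1 of -2*REML.

    Numerical Hessian with forward stencils at the non-negativity boundary so
    evaluation never leaves the parameter domain; boundary directions get a
    pseudo-inverse (their contribution to Satterthwaite df is conservative).
    """
    model, w, theta = fit.model, fit.weights, fit.theta
    m = theta.size
    h = np.maximum(1e-3 * theta, 1e-5 * model._scale)

    def f(t):
        try:
            return model.neg2_reml(t, w)
        except (np.linalg.LinAlgError, ValueError):
            return np.nan

    # central stencil around a base shifted off the zero boundary; the O(h)
    # base shift is negligible against the sampling noise this feeds into
    base = np.maximum(theta, h * (1 + 1e-9))
    base[-1] = max(theta[-1], 2 * h[-1])
    H = np.empty((m, m))
    for i in range(m):
        for j in range(i, m):
            ei = np.zeros(m); ei[i] = h[i]
            ej = np.zeros(m); ej[j] = h[j]
            fpp = f(base + ei + ej)
            fpm = f(base + ei - ej)
            fmp = f(base - ei + ej)
            fmm = f(base - ei - ej)
            H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
    if not np.all(np.isfinite(H)):
        H = np.where(np.isfinite(H), H, 0.0)
    return 2.0 * linalg.pinvh(H)


def _grad_var_contrast(fit: VCFit, ell: np.ndarray) -> np.ndarray:
    """Gradient of Var(ell' beta_hat) = ell' C(theta) ell wrt theta."""
    model, w, theta = fit.model, fit.weights, fit.theta
    m = theta.size
    h = np.maximum(1e-3 * theta, 1e-5 * model._scale)
    g = np.empty(m)
    for i in range(m):
        e = np.zeros(m); e[i] = h[i]
        if theta[i] - h[i] >= 0:
            vp = ell @ model.cov_beta(theta + e, w) @ ell
            vm = ell @ model.cov_beta(theta - e, w) @ ell
            g[i] = (vp - vm) / (2 * h[i])
        else:
            vp = ell @ model.cov_beta(theta + e, w) @ ell
            v0 = ell @ model.cov_beta(theta, w) @ ell
            g[i] = (vp - v0) / h[i]
    return g


def satterthwaite_t(fit: VCFit, ell: np.ndarray,
                    theta_cov: np.ndarray | None = None):
    """One-df contrast: (estimate, se, Satterthwaite df)."""
    ell = np.asarray(ell, dtype=float)
    est = float(ell @ fit.beta)
    var = float(ell @ fit.cov_beta @ ell)
    se = np.sqrt(var)
    A = theta_cov if theta_cov is not None else _theta_cov(fit)
    g = _grad_var_contrast(fit, ell)
    denom = float(g @ A @ g)
    df_cap = max(fit.n_obs - len(fit.beta), 1)
    df = 2.0 * var ** 2 / denom if denom > 1e-30 * max(var, 1e-30) ** 2 else df_cap
    return est, se, float(np.clip(df, 1.0, df_cap))


def satterthwaite_f(fit: VCFit, L: np.ndarray):
    """Multi-df Wald F test of L beta = 0 with Satterthwaite denominator df.

    Eigen-decomposes the contrast covariance, computes a one-df Satterthwaite
    df for each principal contrast and moment-matches the combination.
    Returns (F, df_num, df_den, p).
    """
    L = np.atleast_2d(np.asarray(L, dtype=float))
    q = L.shape[0]
    M = L @ fit.cov_beta @ L.T
    vals, vecs = np.linalg.eigh(M)
    if np.any(vals <= 0):
        raise ValueError("contrast covariance is singular "
                         "(degenerate residual variance?)")
    A = _theta_cov(fit)
    Fsum = 0.0
    nus = []
    for j in range(q):
        pj = vecs[:, j] @ L  # principal 1-df contrast in beta
        est = float(pj @ fit.beta)
        Fsum += est ** 2 / vals[j]
        g = _grad_var_contrast(fit, pj)
        denom = float(g @ A @ g)
        df_cap = max(fit.n_obs - len(fit.beta), 1)
        nu = 2.0 * vals[j] ** 2 / denom if denom > 0 else df_cap
        nus.append(float(np.clip(nu, 1.0 + 1e-8, df_cap)))
    F = Fsum / q
    E = sum(nu / (nu - 2.0) for nu in nus if nu > 2.0)
    if E > q:
        df_den = 2.0 * E / (E - q)
    else:
        df_den = float(min(nus))
    p = float(stats.f.sf(F, q, df_den))
    return float(F), q, float(df_den), p


def _factorize(values: np.ndarray):
    labels, codes = np.unique(values, return_inverse=True)
    return codes, labels
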