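"""REML variance-component estimation and BLUP prediction for kernel
("animal") models.

Univariate model: y = X b + u + e with u ~ N(0, sigma2_r K) and
e ~ N(0, sigma2_e I), where K is a relationship matrix (GRM for additive
genetic effects -> heritability; MRM for microbial effects ->
microbiability) and there is one record per animal. The restricted
likelihood is profiled over lambda = sigma2_r / sigma2_e after rotating by
the eigenvectors of K, so each evaluation is O(n p) and the maximisation
is a one-dimensional bounded search.

Bivariate model: the adjusted chamber trait y* and its metagenome-derived
proxy m-hat share additive genetic effects with covariance G (x) B and
residuals I (x) C (2x2 B and C). Rotating both traits by the eigenvectors
of G factorises the restricted likelihood into n independent bivariate
normal terms with covariance d_k B + C. B and C are parameterised through
their Cholesky factors, which enforces positive semidefiniteness, and a
per-trait general mean is fitted.

Standard errors come from the inverse observed information (central
finite differences of the REML log-likelihood in the variance-component
coordinates); ratios and correlations get delta-method standard errors.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize, minimize_scalar

from .kinship import RelationshipMatrix

LOG2PI = math.log(2.0 * math.pi)
_LOGLAM_BOUNDS = (-12.0, 12.0)


class ConvergenceError(RuntimeError):
    """REML optimisation failed to converge."""


def _as_kernel(K) -> tuple[np.ndarray, pd.Index | None]:
    if isinstance(K, RelationshipMatrix):
        return K.values, K.ids
    return np.asarray(K, dtype=float), None


def _psd_eigh(K: np.ndarray, tol: float = 0.05):
    """Eigendecomposition of a kernel with nearest-PSD projection.

    Mildly negative eigenvalues are expected (a pairwise-complete VanRaden
    GRM need not be PSD) and are clipped to zero, which projects K onto
    the PSD cone in its own eigenbasis. A matrix whose most negative
    eigenvalue exceeds ``tol`` of the largest is treated as genuinely
    indefinite and rejected."""
    Ks = (K + K.T) / 2.0
    d, U = np.linalg.eigh(Ks)
    scale = max(abs(d[-1]), 1.0)
    if d[0] < -tol * scale:
        raise ValueError(
            f"kernel is not positive semidefinite (min eigenvalue {d[0]:.3g} "
            f"vs max {d[-1]:.3g})"
        )
    return np.clip(d, 0.0, None), U


@dataclass
class UnivariateFit:
    kind: str
    sigma2_r: float
    sigma2_e: float
    ratio: float
    se_sigma2_r: float
    se_sigma2_e: float
    se_ratio: float
    loglik: float
    beta: np.ndarray
    effect_names: list[str]
    ids: pd.Index | None
    resid_gls: np.ndarray  # y - X beta-hat on the training animals
    u: np.ndarray  # BLUP of the random effect for the training animals
    converged: bool = True

    def summary(self) -> pd.DataFrame:
        label = "h2" if self.kind == "GRM" else "m2" if self.kind == "MRM" else "ratio"
        return pd.DataFrame(
            {
                "estimate": [self.sigma2_r, self.sigma2_e, self.ratio],
                "se": [self.se_sigma2_r, self.se_sigma2_e, self.se_ratio],
            },
            index=["sigma2_random", "sigma2_residual", label],
        )


def _univariate_nll(yt: np.ndarray, Xt: np.ndarray, v: np.ndarray,
                    n: int, p: int) -> float:
    """-2/(-2)... negative REML log-likelihood with V = diag(v) in the
    rotated basis."""
    Xv = Xt / v[:, None]
    A = Xt.T @ Xv
    sign, ldA = np.linalg.slogdet(A)
    if sign <= 0:
        return 1e12
    rhs = Xv.T @ yt
    beta = np.linalg.solve(A, rhs)
    quad = float(yt @ (yt / v) - rhs @ beta)
    ll = -0.5 * (np.log(v).sum() + ldA + quad + (n - p) * LOG2PI)
    return -ll


def reml_loglik_univariate(y, X, K, sigma2_r: float, sigma2_e: float) -> float:
    """REML log-likelihood at fixed variance components (rotation route).

    Convention: -1/2 [log|V| + log|X'V^-1 X| + y'Py + (n-p) log 2pi]."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        X = X.T
    Kv, _ = _as_kernel(K)
    d, U = _psd_eigh(Kv)
    yt, Xt = U.T @ y, U.T @ X
    v = sigma2_r * d + sigma2_e
    return -_univariate_nll(yt, Xt, v, len(y), X.shape[1])


def reml_univariate(y, X, K, kind: str | None = None,
                    ids=None) -> UnivariateFit:
    """Fit the univariate kernel model by REML.

    ``X`` may be a FixedEffectsDesign, a 2-D array, or None (intercept
    only). ``K`` may be a RelationshipMatrix or a square array aligned
    with y.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    effect_names = ["intercept"]
    if X is None:
        Xm = np.ones((n, 1))
    elif hasattr(X, "X"):
        Xm, effect_names = np.asarray(X.X, dtype=float), list(X.names)
    else:
        Xm = np.atleast_2d(np.asarray(X, dtype=float))
        if Xm.shape[0] != n:
            Xm = Xm.T
        effect_names = [f"b{j}" for j in range(Xm.shape[1])]
    p = Xm.shape[1]
    if n <= p:
        raise ValueError("more records than fixed effects required")

    Kv, kids = _as_kernel(K)
    if kids is not None and ids is None:
        ids = kids
    if Kv.shape[0] != n:
        raise ValueError("kernel dimension does not match trait length")
    if kind is None:
        kind = K.kind if isinstance(K, RelationshipMatrix) else "kernel"

    d, U = _psd_eigh(Kv)
    yt, Xt = U.T @ y, U.T @ Xm

    def profile_nll(loglam: float) -> float:
        lam = math.exp(loglam)
        w = lam * d + 1.0
        Xw = Xt / w[:, None]
        A = Xt.T @ Xw
        sign, ldA = np.linalg.slogdet(A)
        if sign <= 0:
            return 1e12
        rhs = Xw.T @ yt
        beta = np.linalg.solve(A, rhs)
        q = float(yt @ (yt / w) - rhs @ beta)
        if q <= 0:
            return 1e12
        s2e = q / (n - p)
        ll = -0.5 * (
            (n - p) * math.log(s2e) + np.log(w).sum() + ldA
            + (n - p) + (n - p) * LOG2PI
        )
        return -ll

    res = minimize_scalar(profile_nll, bounds=_LOGLAM_BOUNDS,
                          method="bounded", options={"xatol": 1e-10})
    if not res.success:
        raise ConvergenceError(f"profile REML search failed: {res.message}")
    # The bounded search can stall at an interior point when the optimum is
    # at a bound; compare with the bound values explicitly.
    cands = [res.x, _LOGLAM_BOUNDS[0], _LOGLAM_BOUNDS[1]]
    loglam = min(cands, key=profile_nll)
    lam = math.exp(loglam)

    w = lam * d + 1.0
    Xw = Xt / w[:, None]
    A = Xt.T @ Xw
    rhs = Xw.T @ yt
    beta = np.linalg.solve(A, rhs)
    q = float(yt @ (yt / w) - rhs @ beta)
    s2e = q / (n - p)
    s2r = lam * s2e
    loglik = -profile_nll(loglam)
    at_boundary = loglam <= _LOGLAM_BOUNDS[0] + 1e-6

    resid = y - Xm @ beta
    resid_t = U.T @ resid
    shrink = s2r * d / (s2r * d + s2e)
    u = U @ (shrink * resid_t)

    se_s2r, se_s2e, se_ratio = _univariate_ses(yt, Xt, d, n, p, s2r, s2e)
    ratio = s2r / (s2r + s2e)
    if at_boundary:
        ratio = 0.0 if lam < 1e-4 else ratio

    return UnivariateFit(
        kind=kind, sigma2_r=s2r, sigma2_e=s2e, ratio=ratio,
        se_sigma2_r=se_s2r, se_sigma2_e=se_s2e, se_ratio=se_ratio,
        loglik=loglik, beta=beta, effect_names=effect_names,
        ids=pd.Index(ids) if ids is not None else None,
        resid_gls=resid, u=u, converged=True,
    )


def _univariate_ses(yt, Xt, d, n, p, s2r, s2e):
    """Observed-information SEs in (sigma2_r, sigma2_e) plus a delta-method
    SE for the ratio sigma2_r / (sigma2_r + sigma2_e)."""
    theta = np.array([s2r, s2e])

    def nll(th):
        v = th[0] * d + th[1]
        if np.any(v <= 0):
            return 1e12
        return _univariate_nll(yt, Xt, v, n, p)

    H = _numerical_hessian(nll, theta)
    cov = _safe_inverse(H)
    if cov is None:
        return math.nan, math.nan, math.nan
    tot = s2r + s2e
    grad = np.array([s2e, -s2r]) / tot**2
    var_ratio = float(grad @ cov @ grad)
    return (
        math.sqrt(max(cov[0, 0], 0.0)),
        math.sqrt(max(cov[1, 1], 0.0)),
        math.sqrt(max(var_ratio, 0.0)),
    )


def _numerical_hessian(f, theta, rel_step: float = 1e-4):
    """Central-difference Hessian with per-coordinate relative steps."""
    k = len(theta)
    scale = np.maximum(np.abs(theta), 1e-3 * max(np.abs(theta).max(), 1.0))
    h = rel_step * scale
    H = np.empty((k, k))
    f0 = f(theta)
    for i in range(k):
        for j in range(i, k):
            if i == j:
                tp, tm = theta.copy(), theta.copy()
                tp[i] += h[i]
                tm[i] -= h[i]
                H[i, i] = (f(tp) - 2.0 * f0 + f(tm)) / h[i] ** 2
            else:
                tpp, tpm, tmp, tmm = (theta.copy() for _ in range(4))
                tpp[[i, j]] += [h[i], h[j]]
                tpm[i] += h[i]
                tpm[j] -= h[j]
                tmp[i] -= h[i]
                tmp[j] += h[j]
                tmm[[i, j]] -= [h[i], h[j]]
                H[i, j] = H[j, i] = (
                    f(tpp) - f(tpm) - f(tmp) + f(tmm)
                ) / (4.0 * h[i] * h[j])
    return H


def _safe_inverse(H):
    try:
        cov = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        return None
    if not np.all(np.isfinite(cov)):
        return None
    if np.any(np.diag(cov) < 0):
        warnings.warn("observed information is not positive definite; "
                      "standard errors may be unreliable (boundary estimate)",
                      stacklevel=3)
        cov = np.abs(np.diag(np.diag(cov)))
    return cov


def blup_predict(fit: UnivariateFit, K_full, training_ids,
                 target_ids) -> pd.Series:
    """Predict random effects for target animals from a trained fit.

    u_target = s2r * K[target, train] (s2r K[train, train] + s2e I)^-1
    (y_train - X_train b-hat). Training and target sets must be disjoint.
    """
    training_ids = pd.Index(training_ids)
    target_ids = pd.Index(target_ids)
    if len(training_ids.intersection(target_ids)):
        raise ValueError("training and target id sets overlap")
    if isinstance(K_full, RelationshipMatrix):
        K_tt = K_full.submatrix(training_ids)
        K_vt = K_full.submatrix(target_ids, training_ids)
    else:
        raise TypeError("K_full must be a RelationshipMatrix for id lookup")
    if fit.ids is None:
        raise ValueError("fit carries no animal ids; refit with ids")
    order = fit.ids.get_indexer(training_ids)
    if (order < 0).any():
        raise KeyError("training ids missing from the fitted model")
    resid = fit.resid_gls[order]
    n = len(training_ids)
    V = fit.sigma2_r * K_tt + fit.sigma2_e * np.eye(n)
    u = fit.sigma2_r * (K_vt @ np.linalg.solve(V, resid))
    return pd.Series(u, index=target_ids, name="u_hat")


# --------------------------------------------------------------------------
# Bivariate proxy-trait model
# --------------------------------------------------------------------------

@dataclass
class BivariateFit:
    B: np.ndarray  # 2x2 additive genetic (co)variance matrix
    C: np.ndarray  # 2x2 residual (co)variance matrix
    rho_g: float
    rho_p: float
    h2_1: float
    h2_2: float
    se_rho_g: float
    se_rho_p: float
    se_h2_1: float
    se_h2_2: float
    loglik: float
    means: np.ndarray
    n: int
    converged: bool = True

    @property
    def phenotypic_var(self) -> np.ndarray:
        return np.diag(self.B) + np.diag(self.C)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "estimate": [self.h2_1, self.h2_2, self.phenotypic_var[0],
                             self.phenotypic_var[1], self.rho_p, self.rho_g],
                "se": [self.se_h2_1, self.se_h2_2, math.nan, math.nan,
                       self.se_rho_p, self.se_rho_g],
            },
            index=["h2_trait1", "h2_trait2", "phen_var1", "phen_var2",
                   "phen_corr", "gen_corr"],
        )


def _biv_core(y1t, y2t, xt, d, B, C, n):
    """REML log-likelihood of the rotated bivariate model at fixed (B, C).

    Per eigenvalue d_k the 2x2 covariance is d_k B + C; a per-trait mean
    is profiled out by GLS. Returns (loglik, means) or (None, None) if any
    2x2 block is singular."""
    a = d * B[0, 0] + C[0, 0]
    b = d * B[0, 1] + C[0, 1]
    c = d * B[1, 1] + C[1, 1]
    det = a * c - b * b
    if np.any(det <= 0) or np.any(a <= 0) or np.any(c <= 0):
        return None, None
    i00 = c / det
    i01 = -b / det
    i11 = a / det
    x2 = xt * xt
    A = np.array([
        [np.sum(x2 * i00), np.sum(x2 * i01)],
        [np.sum(x2 * i01), np.sum(x2 * i11)],
    ])
    rhs = np.array([
        np.sum(xt * (i00 * y1t + i01 * y2t)),
        np.sum(xt * (i01 * y1t + i11 * y2t)),
    ])
    signA, ldA = np.linalg.slogdet(A)
    if signA <= 0:
        return None, None
    mu = np.linalg.solve(A, rhs)
    yVy = float(np.sum(i00 * y1t**2 + 2.0 * i01 * y1t * y2t + i11 * y2t**2))
    quad = yVy - float(rhs @ mu)
    ll = -0.5 * (np.log(det).sum() + ldA + quad + (2 * n - 2) * LOG2PI)
    return ll, mu


def reml_loglik_bivariate(y1, y2, G, B, C) -> float:
    """Bivariate REML log-likelihood at fixed (B, C) via the rotation route
    (per-trait general means profiled out)."""
    y1 = np.asarray(y1, dtype=float)
    y2 = np.asarray(y2, dtype=float)
    Gv, _ = _as_kernel(G)
    d, U = _psd_eigh(Gv)
    n = len(y1)
    y1t, y2t = U.T @ y1, U.T @ y2
    xt = U.T @ np.ones(n)
    ll, _ = _biv_core(y1t, y2t, xt, d, np.asarray(B, float),
                      np.asarray(C, float), n)
    if ll is None:
        raise ValueError("(B, C) leave a singular 2x2 covariance block")
    return ll


def _chol_from_theta(theta6):
    lb = np.array([[theta6[0], 0.0], [theta6[1], theta6[2]]])
    lc = np.array([[theta6[3], 0.0], [theta6[4], theta6[5]]])
    return lb @ lb.T, lc @ lc.T


def reml_bivariate(y1, y2, G, ids=None, n_starts: int = 3,
                   max_iter: int = 200) -> BivariateFit:
    """Fit the bivariate proxy-trait model by REML.

    ``y1`` is the adjusted chamber trait (y*), ``y2`` the predicted
    microbial proxy (m-hat), observed on the same animals; ``G`` is the
    GRM on those animals. Returns genetic/phenotypic correlations,
    per-trait heritabilities and delta-method standard errors.
    """
    y1 = pd.Series(y1)
    y2 = pd.Series(y2)
    if ids is None and isinstance(G, RelationshipMatrix):
        ids = G.ids
    if hasattr(y1, "index") and hasattr(y2, "index"):
        if not y1.index.equals(y2.index):
            if set(y1.index) != set(y2.index):
                raise ValueError("traits observed on mismatched animal sets")
            y2 = y2.reindex(y1.index)
    yv1 = y1.to_numpy(dtype=float)
    yv2 = y2.to_numpy(dtype=float)
    n = len(yv1)
    if isinstance(G, RelationshipMatrix):
        Gv = G.submatrix(y1.index) if not G.ids.equals(y1.index) else G.values
    else:
        Gv = np.asarray(G, dtype=float)
    if Gv.shape[0] != n:
        raise ValueError("GRM dimension does not match trait length")

    d, U = _psd_eigh(Gv)
    y1t, y2t = U.T @ yv1, U.T @ yv2
    xt = U.T @ np.ones(n)

    def nll(theta6):
        B, C = _chol_from_theta(theta6)
        ll, _ = _biv_core(y1t, y2t, xt, d, B, C, n)
        return 1e12 if ll is None else -ll

    # Starts from the two univariate fits, with varying genetic correlation.
    f1 = reml_univariate(yv1, None, Gv, kind="GRM")
    f2 = reml_univariate(yv2, None, Gv, kind="GRM")
    v1, e1 = max(f1.sigma2_r, 1e-4 * yv1.var()), max(f1.sigma2_e, 1e-4 * yv1.var())
    v2, e2 = max(f2.sigma2_r, 1e-4 * yv2.var()), max(f2.sigma2_e, 1e-4 * yv2.var())
    starts = []
    for rg, re in [(0.0, 0.0), (0.5, 0.3), (-0.5, -0.3)][:n_starts]:
        B0 = np.array([[v1, rg * math.sqrt(v1 * v2)],
                       [rg * math.sqrt(v1 * v2), v2]])
        C0 = np.array([[e1, re * math.sqrt(e1 * e2)],
                       [re * math.sqrt(e1 * e2), e2]])
        lb, lc = np.linalg.cholesky(B0), np.linalg.cholesky(C0)
        starts.append(np.array([lb[0, 0], lb[1, 0], lb[1, 1],
                                lc[0, 0], lc[1, 0], lc[1, 1]]))

    best = None
    for x0 in starts:
        res = minimize(nll, x0, method="L-BFGS-B",
                       options={"maxiter": max_iter, "ftol": 1e-12,
                                "gtol": 1e-8})
        if best is None or res.fun < best.fun:
            best = res
    if best is None or not np.isfinite(best.fun):
        raise ConvergenceError("bivariate REML failed from all starts")
    converged = bool(best.success)
    if not converged:
        warnings.warn(f"bivariate REML optimiser stopped early: "
                      f"{best.message}", stacklevel=2)

    B, C = _chol_from_theta(best.x)
    ll, mu = _biv_core(y1t, y2t, xt, d, B, C, n)

    theta = np.array([B[0, 0], B[0, 1], B[1, 1], C[0, 0], C[0, 1], C[1, 1]])

    def nll_components(th):
        Bm = np.array([[th[0], th[1]], [th[1], th[2]]])
        Cm = np.array([[th[3], th[4]], [th[4], th[5]]])
        l, _ = _biv_core(y1t, y2t, xt, d, Bm, Cm, n)
        return 1e12 if l is None else -l

    H = _numerical_hessian(nll_components, theta)
    cov6 = _safe_inverse(H)

    def transforms(th):
        vu1, vu12, vu2, ve1, ve12, ve2 = th
        p1, p2 = vu1 + ve1, vu2 + ve2
        tiny = 1e-300
        return np.array([
            vu12 / max(math.sqrt(max(vu1 * vu2, 0.0)), tiny),
            (vu12 + ve12) / max(math.sqrt(max(p1 * p2, 0.0)), tiny),
            vu1 / max(p1, tiny),
            vu2 / max(p2, tiny),
        ])

    vals = transforms(theta)
    if cov6 is not None:
        J = _numerical_jacobian(transforms, theta)
        cov_t = J @ cov6 @ J.T
        ses = np.sqrt(np.clip(np.diag(cov_t), 0.0, None))
    else:
        ses = np.full(4, math.nan)

    return BivariateFit(
        B=B, C=C,
        rho_g=float(vals[0]), rho_p=float(vals[1]),
        h2_1=float(vals[2]), h2_2=float(vals[3]),
        se_rho_g=float(ses[0]), se_rho_p=float(ses[1]),
        se_h2_1=float(ses[2]), se_h2_2=float(ses[3]),
        loglik=float(ll), means=mu, n=n, converged=converged,
    )


def _numerical_jacobian(f, theta, rel_step: float = 1e-5):
    scale = np.maximum(np.abs(theta), 1e-3 * max(np.abs(theta).max(), 1.0))
    h = rel_step * scale
    f0 = f(theta)
    J = np.empty((len(f0), len(theta)))
    for j in range(len(theta)):
        tp, tm = theta.copy(), theta.copy()
        tp[j] += h[j]
        tm[j] -= h[j]
        J[:, j] = (f(tp) - f(tm)) / (2.0 * h[j])
    return J
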