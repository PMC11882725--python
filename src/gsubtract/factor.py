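"""Single-common-factor model for a genetic covariance matrix.

The measurement model is ``Sigma(theta) = lambda lambda' + diag(u)`` with the
latent (general-factor) variance fixed at 1 for identification. Parameters
are estimated by minimizing the diagonally weighted least squares criterion

    F(theta) = (s - sigma(theta))' W (s - sigma(theta)),
    s = vech(S),  W = diag(V)^-1,

with the full sampling covariance V entering only the sandwich parameter
covariance

    cov(theta) = (D'WD)^-1 D'W V W D (D'WD)^-1,   D = d sigma / d theta,

the standard arrangement for structural models fit to LDSC-derived matrices.
A maximum-likelihood criterion is available as an alternative estimator.

The reported solution is standardized per trait by its model-implied total
genetic variance (so loading^2 + residual = 1 exactly), with standard errors
mapped through the delta method, and the factor is oriented so the mean
loading is positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats

from .ldsc import GeneticCovariance, vech_indices


class FactorModelError(RuntimeError):
    pass


@dataclass
class FactorSolution:
    """Estimated one-factor solution.

    ``loadings``/``resid_var`` are the standardized values (per-trait genetic
    variance normalized to 1); ``loadings_cov``/``resid_cov`` are on the raw
    covariance scale of S, which the per-SNP residualization step consumes.
    ``param_cov`` is the sandwich covariance of the raw parameter vector
    (lambda_1..k, u_1..k).
    """

    traits: list
    loadings: np.ndarray
    loadings_se: np.ndarray
    resid_var: np.ndarray
    resid_var_se: np.ndarray
    loadings_cov: np.ndarray
    resid_cov: np.ndarray
    param_cov: np.ndarray
    chisq: float
    df: int
    pvalue: float
    cfi: float
    srmr: float
    estimator: str
    converged: bool
    objective: float
    n_restarts: int
    heywood: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.traits)

    @property
    def variance_shares(self) -> np.ndarray:
        """Per-trait share of genetic variance carried by the factor."""
        return self.loadings ** 2

    @property
    def mean_loading(self) -> float:
        return float(self.loadings.mean())

    def to_dict(self) -> dict:
        return {
            "traits": list(self.traits),
            "loadings": self.loadings, "loadings_se": self.loadings_se,
            "resid_var": self.resid_var, "resid_var_se": self.resid_var_se,
            "loadings_cov": self.loadings_cov, "resid_cov": self.resid_cov,
            "variance_shares": self.variance_shares,
            "mean_loading": self.mean_loading,
            "fit": {"chisq": self.chisq, "df": self.df, "pvalue": self.pvalue,
                    "cfi": self.cfi, "srmr": self.srmr},
            "estimator": self.estimator, "converged": self.converged,
            "heywood": self.heywood,
        }


# ---------------------------------------------------------------------------
# model algebra


def _vech(M: np.ndarray) -> np.ndarray:
    k = M.shape[0]
    return np.array([M[i, j] for i, j in vech_indices(k)])


def _implied_vech(lam: np.ndarray, u: np.ndarray, pairs) -> np.ndarray:
    return np.array([lam[i] * lam[j] + (u[i] if i == j else 0.0)
                     for i, j in pairs])


def _jacobian(lam: np.ndarray, pairs) -> np.ndarray:
    """d vech(Sigma) / d (lambda, u): p × 2k, analytic."""
    k = len(lam)
    p = len(pairs)
    D = np.zeros((p, 2 * k))
    for r, (i, j) in enumerate(pairs):
        D[r, i] += lam[j]
        D[r, j] += lam[i]
        if i == j:
            D[r, k + i] = 1.0
    return D


def _dwls_objective(theta, s, w, pairs, k):
    lam, u = theta[:k], theta[k:]
    r = s - _implied_vech(lam, u, pairs)
    f = float(r @ (w * r))
    D = _jacobian(lam, pairs)
    grad = -2.0 * D.T @ (w * r)
    return f, grad


def _ml_objective(theta, S, k):
    lam, u = theta[:k], theta[k:]
    Sigma = np.outer(lam, lam) + np.diag(u)
    sign, logdet = np.linalg.slogdet(Sigma)
    if sign <= 0:
        return 1e12, np.zeros(2 * k)
    Sinv = np.linalg.inv(Sigma)
    sign_s, logdet_s = np.linalg.slogdet(S)
    f = logdet + float(np.trace(S @ Sinv)) - logdet_s - k
    G = Sinv - Sinv @ S @ Sinv          # dF/dSigma
    grad_lam = 2.0 * (G @ lam)
    grad_u = np.diag(G).copy()
    return float(f), np.concatenate([grad_lam, grad_u])


def _start_values(S: np.ndarray, rng: np.random.Generator | None = None,
                  flat: bool = False):
    """Start vector for (lambda, u) on the covariance metric of S.

    Default: leading eigenpair of the standardized S (a principal-axis
    start, robust to heterogeneous loadings). ``flat`` falls back to equal
    loadings at sqrt(mean off-diagonal correlation); ``rng`` jitters either.
    """
    k = S.shape[0]
    d = np.sqrt(np.clip(np.diag(S), 1e-6, None))
    corr = S / np.outer(d, d)
    if flat:
        iu = np.triu_indices(k, 1)
        mean_off = float(np.clip(np.mean(corr[iu]), 0.01, 0.9))
        lam_std = np.full(k, np.sqrt(mean_off))
    else:
        evals, evecs = np.linalg.eigh(corr)
        v = evecs[:, -1]
        if v.sum() < 0:
            v = -v
        lam_std = np.clip(v * np.sqrt(max(evals[-1], 0.1)), -0.95, 0.95)
    if rng is not None:
        lam_std = np.clip(lam_std + rng.normal(0, 0.1, k), -0.95, 0.95)
    lam = lam_std * d
    u = np.clip(np.diag(S) - lam ** 2, 1e-4, None)
    return np.concatenate([lam, u])


# ---------------------------------------------------------------------------
# fitting


def fit_common_factor(gc: GeneticCovariance, estimator: str = "dwls",
                      bound_residuals: bool = False,
                      tol: float = 1e-10, max_restarts: int = 3) -> FactorSolution:
    """Fit the one-factor model to a GeneticCovariance.

    ``estimator`` is "dwls" (default) or "ml"; sandwich standard errors use
    the full V in either case. Residual variances may be bounded at 0
    (``bound_residuals``) to forbid Heywood cases; by default a negative
    residual is flagged, not constrained.
    """
    k = gc.k
    if k < 3:
        raise FactorModelError(f"one-factor model needs k >= 3 traits, got {k}")
    S, V = gc.S, gc.V
    pairs = vech_indices(k)
    s = _vech(S)
    w = 1.0 / np.maximum(np.diag(V), 1e-14)

    if estimator == "dwls":
        def fun(theta):
            return _dwls_objective(theta, s, w, pairs, k)
    elif estimator == "ml":
        def fun(theta):
            return _ml_objective(theta, S, k)
    else:
        raise FactorModelError(f"unknown estimator {estimator!r}")

    bounds = None
    if bound_residuals:
        bounds = [(None, None)] * k + [(0.0, None)] * k

    rng = np.random.default_rng(12345)
    best = None
    n_restarts = 0
    # principal-axis and flat starts always; jittered restarts on top if
    # neither converges (DWLS surfaces can hold local optima)
    starts = [_start_values(S), _start_values(S, flat=True)]
    starts += [_start_values(S, rng) for _ in range(max_restarts)]
    for attempt, theta0 in enumerate(starts):
        res = optimize.minimize(fun, theta0, jac=True, method="L-BFGS-B",
                                bounds=bounds,
                                options={"maxiter": 2000, "ftol": tol,
                                         "gtol": 1e-10})
        if best is None or (res.success and not best.success) \
                or (res.success == best.success and res.fun < best.fun):
            best = res
        if attempt >= 1 and best.success and best.fun < 1e8:
            break
        n_restarts = attempt
    if best is None or not np.isfinite(best.fun) or best.fun >= 1e8:
        raise FactorModelError(
            f"factor model failed to converge after {n_restarts} restarts: "
            f"{getattr(best, 'message', 'no solution')}")

    theta = best.x
    lam, u = theta[:k].copy(), theta[k:].copy()

    # sandwich covariance of (lambda, u) on the covariance scale of S
    D = _jacobian(lam, pairs)
    DW = D * w[:, None]                     # W D, W diagonal
    bread = np.linalg.pinv(D.T @ DW)
    meat = DW.T @ V @ DW
    param_cov = bread @ meat @ bread
    param_cov = (param_cov + param_cov.T) / 2.0

    # orient the factor: mean loading positive
    if lam.mean() < 0:
        lam = -lam
        F = np.diag(np.concatenate([-np.ones(k), np.ones(k)]))
        param_cov = F @ param_cov @ F

    heywood = [gc.traits[t] for t in range(k) if u[t] < 0]

    # standardized solution: divide by model-implied total variance
    total = lam ** 2 + u
    if np.any(total <= 0):
        raise FactorModelError("non-positive model-implied trait variance")
    lam_std = lam / np.sqrt(total)
    u_std = u / total
    # delta method: J_std maps (lam, u) -> (lam_std, u_std)
    J = np.zeros((2 * k, 2 * k))
    for t in range(k):
        t32 = total[t] ** 1.5
        J[t, t] = u[t] / t32                      # d lam*/d lam
        J[t, k + t] = -lam[t] / (2.0 * t32)       # d lam*/d u
        J[k + t, t] = -2.0 * lam[t] * u[t] / total[t] ** 2
        J[k + t, k + t] = lam[t] ** 2 / total[t] ** 2
    std_cov = J @ param_cov @ J.T
    lam_se = np.sqrt(np.maximum(np.diag(std_cov)[:k], 0.0))
    u_se = np.sqrt(np.maximum(np.diag(std_cov)[k:], 0.0))

    chisq, df, pval, cfi, srmr = _fit_statistics(S, V, lam, u, pairs)

    return FactorSolution(
        traits=list(gc.traits),
        loadings=lam_std, loadings_se=lam_se,
        resid_var=u_std, resid_var_se=u_se,
        loadings_cov=lam, resid_cov=u, param_cov=param_cov,
        chisq=chisq, df=df, pvalue=pval, cfi=cfi, srmr=srmr,
        estimator=estimator, converged=bool(best.success),
        objective=float(best.fun), n_restarts=n_restarts, heywood=heywood)


def _fit_statistics(S, V, lam, u, pairs):
    """Descriptive fit: chi-square-type statistic r' V^+ r, CFI against the
    independence (diagonal) model, and SRMR on the correlation metric."""
    k = S.shape[0]
    p = len(pairs)
    s = _vech(S)
    resid = s - _implied_vech(lam, u, pairs)
    Vinv = np.linalg.pinv(V)
    chisq = float(resid @ Vinv @ resid)
    df = p - 2 * k
    pval = float(stats.chi2.sf(chisq, df)) if df > 0 else float("nan")

    resid0 = s - _vech(np.diag(np.diag(S)))
    chisq0 = float(resid0 @ Vinv @ resid0)
    df0 = p - k
    num = max(chisq - df, 0.0)
    den = max(chisq0 - df0, num, np.finfo(float).eps)
    cfi = 1.0 - num / den

    d = np.sqrt(np.clip(np.diag(S), 1e-12, None))
    scale = np.array([d[i] * d[j] for i, j in pairs])
    srmr = float(np.sqrt(np.mean((resid / scale) ** 2)))
    return chisq, df, pval, cfi, srmr


def variance_decomposition(sol: FactorSolution) -> dict:
    """Per-trait and mean shares of genetic variance on vs off the factor.

    Shares sum to 1 per trait by construction of the standardized solution.
    """
    g_share = sol.variance_shares
    specific = sol.resid_var
    return {
        "traits": list(sol.traits),
        "g_share": g_share,
        "specific_share": specific,
        "mean_g_share": float(g_share.mean()),
        "mean_specific_share": float(specific.mean()),
    }
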