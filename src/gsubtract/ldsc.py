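"""LD score regression: SNP heritabilities, cross-trait genetic covariances,
and the genetic covariance matrix S with its joint sampling covariance V.

For a pair of traits (a, b) the regression is

    z_aj * z_bj  ~  intercept + slope * l_j

over variants j with LD score ``l_j``; the genetic covariance on the observed
scale is ``slope * M / sqrt(n_a * n_b)`` (the univariate case a == b reduces
to the chi-square regression and ``h2 = slope * M / n``). Standard errors come
from a delete-one-block jackknife over contiguous variant blocks; V for the
whole S matrix is the covariance of the leave-one-block-out estimates of all
k(k+1)/2 entries computed on the SAME block partition, so cross-entry sampling
dependence is captured.

Weights follow the canonical two-step scheme: a first-pass unweighted slope
supplies a provisional heritability for the heteroskedasticity term, then

    w_j = 1 / ( l_j * (1 + n_a h2_a l_j / M) * (1 + n_b h2_b l_j / M) )

with l floored at 1 and the provisional h2 clipped to [0, 1].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .sumstats_io import SumstatsPanel


class LdscError(ValueError):
    pass


def vech_indices(k: int) -> list:
    """Row-major upper-triangle (i, j) pairs; the entry order of vech(S)."""
    return [(i, j) for i in range(k) for j in range(i, k)]


def vech_index(k: int, a: int, b: int) -> int:
    i, j = min(a, b), max(a, b)
    return i * k - i * (i - 1) // 2 + (j - i)


def assign_blocks(m: int, n_blocks: int) -> np.ndarray:
    """Block id per variant: contiguous, near-equal blocks in panel order."""
    if n_blocks < 2:
        raise LdscError("need at least 2 jackknife blocks")
    if m < n_blocks:
        raise LdscError(f"fewer variants ({m}) than jackknife blocks ({n_blocks})")
    return (np.arange(m) * n_blocks // m).astype(np.int64)


def effective_n_blocks(m: int, n_blocks: int = 200) -> int:
    """Auto-reduce the block count to floor(m / 50) for small panels."""
    return max(2, min(n_blocks, m // 50))


@dataclass
class LdscFit:
    """One LD-score regression with jackknife uncertainty.

    ``est`` is on the genetic (co)variance scale — ``slope * M / denom`` with
    denom = n for a univariate fit and sqrt(n_a n_b) for a cross-trait fit.
    ``delete_est`` holds the leave-one-block-out estimates of ``est``.
    """

    traits: tuple
    kind: str                 # "h2" | "cov"
    slope: float
    intercept: float
    est: float
    est_se: float
    intercept_se: float
    n_blocks: int
    n_variants: int
    delete_est: np.ndarray
    flags: list = field(default_factory=list)


@dataclass
class RgMatrix:
    """Genetic correlation matrix with jackknife SEs.

    Entries involving a non-positive heritability are NaN and listed in
    ``undefined`` rather than fabricated.
    """

    traits: list
    rg: np.ndarray
    se: np.ndarray
    undefined: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.traits)

    def offdiag_values(self) -> np.ndarray:
        iu = np.triu_indices(self.k, 1)
        return self.rg[iu]

    def mean_offdiag(self) -> float:
        vals = self.offdiag_values()
        return float(np.nanmean(vals))


@dataclass
class GeneticCovariance:
    """k×k genetic covariance matrix S and sampling covariance V of vech(S).

    ``S`` is the (optionally PSD-smoothed) matrix handed to the structural
    model; ``S_raw`` the direct regression assembly. ``delete`` is the
    (n_blocks, p) matrix of leave-one-block-out vech(S) estimates from which
    V was formed — kept so downstream ratios (genetic correlations) can be
    jackknifed on the identical partition.
    """

    traits: list
    S: np.ndarray
    S_raw: np.ndarray
    V: np.ndarray
    intercepts: np.ndarray       # k×k LDSC intercepts
    n_blocks: int
    n_variants: int
    delete: np.ndarray           # (n_blocks, p)
    mean_n: np.ndarray           # per-trait mean sample size
    M: float
    smoothing: dict = field(default_factory=dict)

    @property
    def k(self) -> int:
        return len(self.traits)

    def entry_se(self) -> np.ndarray:
        """k×k matrix of jackknife SEs of the S entries."""
        se = np.sqrt(np.diag(self.V))
        out = np.empty((self.k, self.k))
        for a in range(self.k):
            for b in range(self.k):
                out[a, b] = se[vech_index(self.k, a, b)]
        return out


def genetic_covariance_from_matrices(S: np.ndarray, V: np.ndarray,
                                     traits: list | None = None,
                                     mean_n: np.ndarray | None = None,
                                     M: float = 0.0) -> GeneticCovariance:
    """Wrap externally supplied S and V (e.g. an exactly constructed model
    matrix) for the structural-model stage; no jackknife history attached."""
    k = S.shape[0]
    traits = traits or [f"trait{i + 1}" for i in range(k)]
    p = k * (k + 1) // 2
    if V.shape != (p, p):
        raise LdscError(f"V must be {p}×{p} for k={k}")
    return GeneticCovariance(
        traits=list(traits), S=S.copy(), S_raw=S.copy(), V=V.copy(),
        intercepts=np.ones((k, k)), n_blocks=0, n_variants=0,
        delete=np.zeros((0, p)),
        mean_n=np.ones(k) if mean_n is None else np.asarray(mean_n, float),
        M=M)


# ---------------------------------------------------------------------------
# core weighted regression with block jackknife


def _block_sums(l, y, w, block_id, n_blocks):
    """Per-block weighted sufficient statistics of the regression y ~ 1 + l."""
    def agg(v):
        return np.bincount(block_id, weights=v, minlength=n_blocks)
    return (agg(w * l * l), agg(w * l), agg(w), agg(w * l * y), agg(w * y))


def _solve_2x2(a11, a12, a22, c1, c2):
    det = a11 * a22 - a12 * a12
    slope = (a22 * c1 - a12 * c2) / det
    intercept = (-a12 * c1 + a11 * c2) / det
    return slope, intercept


def _wls_line_jackknife(l, y, w, block_id, n_blocks):
    """Weighted regression of y on l with delete-one-block estimates.

    Returns (slope, intercept, slope_deletes, intercept_deletes); the deleted
    fits reuse the full-sample weights (fixed-weight jackknife).
    """
    wll, wl, ws, wly, wy = _block_sums(l, y, w, block_id, n_blocks)
    A11, A12, A22 = wll.sum(), wl.sum(), ws.sum()
    C1, C2 = wly.sum(), wy.sum()
    slope, intercept = _solve_2x2(A11, A12, A22, C1, C2)
    sl_d, ic_d = _solve_2x2(A11 - wll, A12 - wl, A22 - ws, C1 - wly, C2 - wy)
    return slope, intercept, sl_d, ic_d


def _jackknife_se(deletes: np.ndarray) -> float:
    B = len(deletes)
    d = deletes - deletes.mean()
    return float(np.sqrt((B - 1) / B * np.sum(d * d)))


def _first_pass_h2(l, chi2, M: float, n: float) -> float:
    """Unweighted slope of chi2 on l, converted to h2 and clipped to [0, 1]
    for use inside the heteroskedasticity weights only."""
    lc = l - l.mean()
    slope = float(np.dot(lc, chi2 - chi2.mean()) / np.dot(lc, lc))
    return float(np.clip(slope * M / n, 0.0, 1.0))


def pair_weights(l: np.ndarray, na: float, nb: float,
                 h2a: float, h2b: float, M: float) -> np.ndarray:
    l = np.maximum(l, 1.0)
    return 1.0 / (l * (1.0 + na * h2a * l / M) * (1.0 + nb * h2b * l / M))


def _ldsc_pair(panel: SumstatsPanel, a: int, b: int, block_id, n_blocks) -> LdscFit:
    za, zb = panel.Z[:, a], panel.Z[:, b]
    valid = np.isfinite(za) & np.isfinite(zb)
    if valid.sum() < 2 * n_blocks:
        raise LdscError(
            f"pair ({panel.traits[a]}, {panel.traits[b]}): too few variants "
            f"({int(valid.sum())}) for {n_blocks} blocks")
    l = np.maximum(panel.ld[valid], 1.0)
    za, zb = za[valid], zb[valid]
    na = float(np.nanmean(panel.N[valid, a]))
    nb = float(np.nanmean(panel.N[valid, b]))
    bid = block_id[valid]

    h2a = _first_pass_h2(l, za * za, panel.M, na)
    h2b = h2a if a == b else _first_pass_h2(l, zb * zb, panel.M, nb)
    w = pair_weights(l, na, nb, h2a, h2b, panel.M)

    y = za * zb
    slope, intercept, sl_d, ic_d = _wls_line_jackknife(l, y, w, bid, n_blocks)
    denom = na if a == b else float(np.sqrt(na * nb))
    est = slope * panel.M / denom
    delete_est = sl_d * panel.M / denom

    flags = []
    if a == b and est < 0:
        flags.append("negative_h2")
    return LdscFit(traits=(panel.traits[a], panel.traits[b]),
                   kind="h2" if a == b else "cov",
                   slope=float(slope), intercept=float(intercept),
                   est=float(est), est_se=_jackknife_se(delete_est),
                   intercept_se=_jackknife_se(ic_d),
                   n_blocks=n_blocks, n_variants=int(valid.sum()),
                   delete_est=delete_est, flags=flags)


# ---------------------------------------------------------------------------
# public operations


def h2_regression(panel: SumstatsPanel, trait: str, n_blocks: int = 200) -> LdscFit:
    """SNP heritability of one trait: chi-square regressed on LD scores."""
    a = panel.trait_index(trait)
    nb = effective_n_blocks(panel.m, n_blocks)
    return _ldsc_pair(panel, a, a, assign_blocks(panel.m, nb), nb)


def cross_trait_regression(panel: SumstatsPanel, trait_a: str, trait_b: str,
                           n_blocks: int = 200) -> LdscFit:
    """Genetic covariance between two traits: z_a * z_b on LD scores.

    The intercept absorbs sample overlap; with trait_b == trait_a this is
    exactly the heritability regression.
    """
    a, b = panel.trait_index(trait_a), panel.trait_index(trait_b)
    nb = effective_n_blocks(panel.m, n_blocks)
    return _ldsc_pair(panel, a, b, assign_blocks(panel.m, nb), nb)


def smooth_psd(S: np.ndarray, tol: float = 1e-8):
    """Eigenvalue-floor S at 0 when its minimum eigenvalue < -tol.

    Returns (smoothed matrix, report dict with the max element change).
    """
    evals, evecs = np.linalg.eigh(S)
    if evals.min() >= -tol:
        return S.copy(), {"applied": False, "min_eigenvalue": float(evals.min()),
                          "max_element_change": 0.0}
    Ss = (evecs * np.maximum(evals, 0.0)) @ evecs.T
    Ss = (Ss + Ss.T) / 2.0
    return Ss, {"applied": True, "min_eigenvalue": float(evals.min()),
                "max_element_change": float(np.abs(Ss - S).max())}


def build_S_V(panel: SumstatsPanel, n_blocks: int = 200,
              smooth: bool = True) -> GeneticCovariance:
    """Assemble S from all k(k+1)/2 pairwise regressions and V from the joint
    delete-one-block jackknife on a single shared block partition."""
    k = panel.k
    nb = effective_n_blocks(panel.m, n_blocks)
    block_id = assign_blocks(panel.m, nb)
    pairs = vech_indices(k)
    p = len(pairs)

    S = np.empty((k, k))
    intercepts = np.empty((k, k))
    delete = np.empty((nb, p))
    for idx, (a, b) in enumerate(pairs):
        try:
            fit = _ldsc_pair(panel, a, b, block_id, nb)
        except LdscError as err:
            raise LdscError(f"regression failed for pair "
                            f"({panel.traits[a]}, {panel.traits[b]}): {err}") from err
        S[a, b] = S[b, a] = fit.est
        intercepts[a, b] = intercepts[b, a] = fit.intercept
        delete[:, idx] = fit.delete_est

    d = delete - delete.mean(axis=0)
    V = (nb - 1) / nb * (d.T @ d)
    V = (V + V.T) / 2.0

    S_raw = S.copy()
    smoothing = {"applied": False, "max_element_change": 0.0}
    if smooth:
        S, smoothing = smooth_psd(S)

    return GeneticCovariance(
        traits=list(panel.traits), S=S, S_raw=S_raw, V=V,
        intercepts=intercepts, n_blocks=nb, n_variants=panel.m,
        delete=delete, mean_n=np.nanmean(panel.N, axis=0), M=panel.M,
        smoothing=smoothing)


def rg_matrix(gc: GeneticCovariance, use_raw: bool = True) -> RgMatrix:
    """Genetic correlation matrix r_ab = S_ab / sqrt(S_aa S_bb) with SEs from
    jackknifing the ratio on the stored block partition.

    Correlations are formed from the un-smoothed S entries (``use_raw``) so a
    pair's correlation is exactly its pairwise LDSC estimate; entries with a
    non-positive heritability are NaN and flagged.
    """
    k = gc.k
    S = gc.S_raw if use_raw else gc.S
    rg = np.full((k, k), np.nan)
    se = np.full((k, k), np.nan)
    undefined = []
    np.fill_diagonal(rg, 1.0)
    np.fill_diagonal(se, 0.0)
    for a in range(k):
        for b in range(a + 1, k):
            if S[a, a] <= 0 or S[b, b] <= 0:
                undefined.append((gc.traits[a], gc.traits[b]))
                continue
            rg[a, b] = rg[b, a] = S[a, b] / np.sqrt(S[a, a] * S[b, b])
            d_ab = gc.delete[:, vech_index(k, a, b)]
            d_aa = gc.delete[:, vech_index(k, a, a)]
            d_bb = gc.delete[:, vech_index(k, b, b)]
            with np.errstate(invalid="ignore"):
                r_del = d_ab / np.sqrt(d_aa * d_bb)
            if np.isfinite(r_del).all():
                se[a, b] = se[b, a] = _jackknife_se(r_del)
            else:  # some deleted block flips a diagonal negative
                se[a, b] = se[b, a] = np.nan
    return RgMatrix(traits=list(gc.traits), rg=rg, se=se, undefined=undefined)
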