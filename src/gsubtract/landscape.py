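"""Pre- vs post-correction genetic correlation landscape.

Given the genetic correlation matrix among the original traits and the one
among their g-corrected counterparts, this module computes the change
(delta) matrix, per-test correlation profiles, off-diagonal means, sign-flip
counts and the loading-difference analysis: across all unordered trait
pairs, does the absolute difference in factor loadings predict how much the
pair's genetic correlation changed after correction? A correlation near zero
says the reshaping of the landscape is not a mechanical consequence of
differential loadings.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import ldsc as _ldsc
from .factor import FactorSolution
from .ldsc import RgMatrix
from .sumstats_io import SumstatsPanel


class LandscapeError(ValueError):
    pass


@dataclass
class LandscapeComparison:
    traits: list
    rg_pre: np.ndarray
    rg_post: np.ndarray
    se_pre: np.ndarray
    se_post: np.ndarray
    delta: np.ndarray                 # rg_post - rg_pre, zero diagonal
    mean_pre: float
    mean_post: float
    sign_flips_raw: int
    sign_flips_robust: int            # both |estimate| > 1 jackknife SE
    n_undefined_pairs: int = 0

    @property
    def k(self) -> int:
        return len(self.traits)

    def profile(self, trait: str) -> pd.DataFrame:
        """One test's genetic correlations with the other k-1 tests, pre and
        post correction — one line pair of the profile figure."""
        i = self.traits.index(trait)
        others = [t for j, t in enumerate(self.traits) if j != i]
        sel = [j for j in range(self.k) if j != i]
        return pd.DataFrame({"other": others,
                             "rg_pre": self.rg_pre[i, sel],
                             "rg_post": self.rg_post[i, sel]})

    def to_dict(self) -> dict:
        return {"traits": list(self.traits),
                "mean_rg_pre": self.mean_pre, "mean_rg_post": self.mean_post,
                "mean_delta": self.mean_post - self.mean_pre,
                "sign_flips_raw": self.sign_flips_raw,
                "sign_flips_robust": self.sign_flips_robust,
                "n_undefined_pairs": self.n_undefined_pairs}


@dataclass
class LoadingDeltaResult:
    """Correlation of per-pair |loading difference| with per-pair rg change."""

    correlation: float
    n_pairs: int
    degenerate: bool = False          # all loadings equal: undefined, not 0


def compare_landscapes(rg_pre: RgMatrix, rg_post: RgMatrix) -> LandscapeComparison:
    """Assemble the full pre/post comparison; matrices must share traits.

    Off-diagonal means are unweighted over the defined unique pairs. Sign
    flips are counted raw (any sign change) and robustly (both the pre and
    post estimate exceed one jackknife SE in magnitude).
    """
    if list(rg_pre.traits) != list(rg_post.traits):
        raise LandscapeError(
            f"trait labels differ: {rg_pre.traits} vs {rg_post.traits}")
    k = rg_pre.k
    delta = rg_post.rg - rg_pre.rg
    np.fill_diagonal(delta, 0.0)

    iu = np.triu_indices(k, 1)
    pre, post = rg_pre.rg[iu], rg_post.rg[iu]
    se_pre_v, se_post_v = rg_pre.se[iu], rg_post.se[iu]
    defined = np.isfinite(pre) & np.isfinite(post)

    flips = defined & (np.sign(pre) != np.sign(post)) & (pre != 0) & (post != 0)
    robust = flips & (np.abs(pre) > se_pre_v) & (np.abs(post) > se_post_v)

    return LandscapeComparison(
        traits=list(rg_pre.traits),
        rg_pre=rg_pre.rg, rg_post=rg_post.rg,
        se_pre=rg_pre.se, se_post=rg_post.se, delta=delta,
        mean_pre=float(np.nanmean(pre)), mean_post=float(np.nanmean(post)),
        sign_flips_raw=int(flips.sum()), sign_flips_robust=int(robust.sum()),
        n_undefined_pairs=int((~defined).sum()))


def loading_delta_test(solution: FactorSolution,
                       comparison: LandscapeComparison) -> LoadingDeltaResult:
    """Product-moment correlation, over the k(k-1)/2 unordered pairs, between
    |lambda_a - lambda_b| and the pair's change in genetic correlation.

    Invariant to trait relabelling and to a global sign flip of the factor.
    All-equal loadings make the correlation undefined; that is reported as a
    degenerate result, not as a number.
    """
    if list(solution.traits) != list(comparison.traits):
        raise LandscapeError("solution and comparison cover different traits")
    k = solution.k
    if k < 3:
        raise LandscapeError("need k >= 3 traits (at least 3 pairs)")
    iu = np.triu_indices(k, 1)
    lam = solution.loadings
    x = np.abs(lam[iu[0]] - lam[iu[1]])
    y = comparison.delta[iu]
    ok = np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3 or np.ptp(x) < 1e-12 or np.ptp(y) < 1e-12:
        return LoadingDeltaResult(correlation=float("nan"), n_pairs=len(x),
                                  degenerate=True)
    r = float(np.corrcoef(x, y)[0, 1])
    return LoadingDeltaResult(correlation=r, n_pairs=len(x))


# ---------------------------------------------------------------------------
# external-trait profiles


def _orient_external(external: pd.DataFrame, panel: SumstatsPanel) -> tuple:
    """Align an external sumstats frame to the panel's variant grid and
    reference alleles; returns (z, n) arrays with NaN where unmatched."""
    ref = panel.variants
    merged = ref.merge(external[["SNP", "A1", "A2", "Z", "N"]],
                       on="SNP", how="left", suffixes=("", "_x"))
    match = (merged["A1_x"] == merged["A1"]) & (merged["A2_x"] == merged["A2"])
    flipped = (merged["A1_x"] == merged["A2"]) & (merged["A2_x"] == merged["A1"])
    z = np.where(match, merged["Z"],
                 np.where(flipped, -merged["Z"], np.nan))
    n = np.where(match | flipped, merged["N"], np.nan)
    return z.astype(float), n.astype(float)


def external_profile(panel: SumstatsPanel, corrected: dict,
                     external: pd.DataFrame, external_label: str = "external",
                     n_blocks: int = 200,
                     min_overlap: int = 200) -> pd.DataFrame:
    """Genetic correlation of one external trait with every test, before and
    after g-correction.

    ``corrected`` maps trait -> CorrectedSumstats (as from
    :func:`gsubtract.subtract.correct_all`). Returns a per-test frame with
    rg/SE pre and post, an ``undefined`` flag where a heritability is
    non-positive or overlap insufficient, and ``ci_distinct`` where the pre
    and post 95% intervals exclude each other's estimate.
    """
    from .sumstats_io import SumstatsPanel as _Panel

    z_x, n_x = _orient_external(external, panel)
    rows = []
    for trait in panel.traits:
        j = panel.trait_index(trait)
        corr = corrected[trait]
        # align corrected stats back onto the panel grid
        pos = pd.Series(np.arange(panel.m), index=panel.variants["SNP"])
        idx = pos[corr.variants["SNP"]].to_numpy()
        z_corr = np.full(panel.m, np.nan)
        z_corr[idx] = corr.z
        n_corr = np.full(panel.m, np.nan)
        n_corr[idx] = corr.n_eff

        row = {"trait": trait}
        for tag, z_t, n_t in (("pre", panel.Z[:, j], panel.N[:, j]),
                              ("post", z_corr, n_corr)):
            sub = _Panel(traits=[external_label, trait],
                         variants=panel.variants,
                         Z=np.column_stack([z_x, z_t]),
                         N=np.column_stack([n_x, n_t]),
                         ld=panel.ld, M=panel.M)
            ok = np.isfinite(sub.Z).all(axis=1)
            if ok.sum() < min_overlap:
                row[f"rg_{tag}"], row[f"se_{tag}"] = np.nan, np.nan
                row[f"undefined_{tag}"] = True
                continue
            gc = _ldsc.build_S_V(sub, n_blocks=n_blocks, smooth=False)
            rg = _ldsc.rg_matrix(gc)
            row[f"rg_{tag}"] = rg.rg[0, 1]
            row[f"se_{tag}"] = rg.se[0, 1]
            row[f"undefined_{tag}"] = bool(not np.isfinite(rg.rg[0, 1]))
        pre, post = row.get("rg_pre"), row.get("rg_post")
        se_pre, se_post = row.get("se_pre"), row.get("se_post")
        if all(np.isfinite(v) for v in (pre, post, se_pre, se_post)):
            row["ci_distinct"] = bool(
                abs(pre - post) > 1.96 * se_pre and abs(pre - post) > 1.96 * se_post)
        else:
            row["ci_distinct"] = False
        rows.append(row)
    return pd.DataFrame(rows)
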