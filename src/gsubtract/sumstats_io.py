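"""Reading, quality control, allele harmonization and writing of GWAS summary statistics.

Summary statistics are carried as pandas DataFrames with the canonical columns
``SNP, CHR, BP, A1, A2, Z, N, FRQ`` (optionally ``INFO``), where ``A1`` is the
effect allele and ``Z`` the signed association statistic referring to ``A1``.
A multi-trait panel aligned on a shared, allele-consistent variant grid is held
in :class:`SumstatsPanel`, the container every downstream stage consumes.

Variant matching is by ID only (the LD-score-regression convention); positions
are carried through but never used in computation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

VALID_ALLELES = frozenset("ACGT")
AMBIGUOUS_PAIRS = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}

#: canonical column order of the corrected-sumstats output dialect
CORRECTED_COLUMNS = ["SNP", "CHR", "BP", "A1", "A2", "BETA", "SE", "Z", "N_eff", "FRQ"]

DEFAULT_COLUMN_MAP = {
    "SNP": "SNP", "CHR": "CHR", "BP": "BP", "A1": "A1", "A2": "A2",
    "Z": "Z", "N": "N", "FRQ": "FRQ", "INFO": "INFO",
    "BETA": "BETA", "SE": "SE",
}


class SumstatsError(ValueError):
    """Fatal condition while reading or harmonizing summary statistics."""


@dataclass
class QCReport:
    """Per-filter rejection counts; counts always sum to rows_in - rows_out."""

    rows_in: int = 0
    rows_out: int = 0
    counts: dict = field(default_factory=dict)

    def add(self, reason: str, n: int) -> None:
        if n:
            self.counts[reason] = self.counts.get(reason, 0) + int(n)

    @property
    def rows_dropped(self) -> int:
        return sum(self.counts.values())

    def to_dict(self) -> dict:
        return {"rows_in": self.rows_in, "rows_out": self.rows_out,
                "dropped": dict(self.counts)}


@dataclass
class LDScoreTable:
    """Per-variant LD scores plus the reference-panel SNP count M.

    ``M`` is the denominator in h2 = slope * M / N and may exceed the number
    of scored variants retained after QC.
    """

    table: pd.DataFrame  # columns SNP, L2
    M: float

    def __post_init__(self) -> None:
        if self.M < len(self.table):
            raise SumstatsError(
                f"reference SNP count M={self.M} smaller than scored variants "
                f"({len(self.table)})")

    def scores_for(self, snps: pd.Series | np.ndarray) -> np.ndarray:
        """LD scores aligned to ``snps``, floored at 1; NaN where unscored."""
        s = self.table.set_index("SNP")["L2"].reindex(np.asarray(snps))
        return np.maximum(s.to_numpy(dtype=float), 1.0)


@dataclass
class SumstatsPanel:
    """Harmonized per-SNP association statistics for k traits on a shared variant grid.

    All traits' Z signs refer to the panel's reference effect allele (variants.A1).
    ``Z``/``N`` are (m, k) arrays; missing entries are NaN (union-mode panels only).
    """

    traits: list
    variants: pd.DataFrame          # SNP CHR BP A1 A2 FRQ, reset positional index
    Z: np.ndarray                   # (m, k)
    N: np.ndarray                   # (m, k)
    ld: np.ndarray                  # (m,) LD scores, floored at 1
    M: float                        # reference SNP count for LDSC
    log: list = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.traits)

    @property
    def m(self) -> int:
        return len(self.variants)

    def trait_index(self, trait: str) -> int:
        try:
            return self.traits.index(trait)
        except ValueError:
            raise SumstatsError(f"trait {trait!r} not in panel {self.traits}") from None

    def mean_n(self, trait: str) -> float:
        return float(np.nanmean(self.N[:, self.trait_index(trait)]))

    def trait_frame(self, trait: str) -> pd.DataFrame:
        """Single-trait canonical sumstats frame (complete cases only)."""
        j = self.trait_index(trait)
        df = self.variants.copy()
        df["Z"] = self.Z[:, j]
        df["N"] = self.N[:, j]
        return df.dropna(subset=["Z"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# reading


def read_sumstats(path, column_map: dict | None = None):
    """Read a delimited sumstats file into the canonical frame.

    ``column_map`` maps canonical names (SNP, A1, A2, Z or BETA+SE, N, ...) to
    the file's column names; unmapped canonical names default to themselves.
    If Z is absent but BETA and SE are mapped, Z = BETA / SE.

    Returns ``(frame, QCReport)``; malformed rows (non-ACGT alleles,
    non-finite statistics, non-positive N) are dropped and counted, never
    silently discarded.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)

    raw = pd.read_csv(path, sep=r"\s+", dtype=str, comment="#")
    report = QCReport(rows_in=len(raw))

    def col(name):
        return cmap.get(name, name)

    for required in ("SNP", "A1", "A2"):
        if col(required) not in raw.columns:
            raise SumstatsError(f"required column {required!r} "
                                f"(mapped to {col(required)!r}) missing in {path}")

    has_z = col("Z") in raw.columns
    has_beta = col("BETA") in raw.columns and col("SE") in raw.columns
    if not (has_z or has_beta):
        raise SumstatsError(f"no Z nor BETA+SE columns found in {path}")
    if col("N") not in raw.columns:
        raise SumstatsError(f"required column 'N' (mapped to {col('N')!r}) "
                            f"missing in {path}")

    df = pd.DataFrame({"SNP": raw[col("SNP")].astype(str)})
    df["CHR"] = raw[col("CHR")] if col("CHR") in raw.columns else "NA"
    df["BP"] = pd.to_numeric(raw[col("BP")], errors="coerce") \
        if col("BP") in raw.columns else 0
    df["A1"] = raw[col("A1")].astype(str).str.upper()
    df["A2"] = raw[col("A2")].astype(str).str.upper()
    if has_z:
        df["Z"] = pd.to_numeric(raw[col("Z")], errors="coerce")
    else:
        beta = pd.to_numeric(raw[col("BETA")], errors="coerce")
        se = pd.to_numeric(raw[col("SE")], errors="coerce")
        df["Z"] = beta / se
    df["N"] = pd.to_numeric(raw[col("N")], errors="coerce")
    df["FRQ"] = pd.to_numeric(raw[col("FRQ")], errors="coerce") \
        if col("FRQ") in raw.columns else np.nan
    if col("INFO") in raw.columns:
        df["INFO"] = pd.to_numeric(raw[col("INFO")], errors="coerce")

    bad_allele = ~(df["A1"].isin(VALID_ALLELES) & df["A2"].isin(VALID_ALLELES))
    report.add("non_acgt_allele", bad_allele.sum())
    df = df[~bad_allele]

    same_allele = df["A1"] == df["A2"]
    report.add("identical_alleles", same_allele.sum())
    df = df[~same_allele]

    bad_z = ~np.isfinite(df["Z"])
    report.add("nonfinite_statistic", bad_z.sum())
    df = df[~bad_z]

    bad_n = ~(df["N"] > 0)
    report.add("nonpositive_n", bad_n.sum())
    df = df[~bad_n]

    dup = df["SNP"].duplicated(keep="first")
    report.add("duplicate_id", dup.sum())
    df = df[~dup]

    df = df.reset_index(drop=True)
    report.rows_out = len(df)
    return df, report


def read_ldscores(path, M: float | None = None) -> LDScoreTable:
    """Read an LD-score table (columns SNP, L2).

    ``M`` defaults to the value in a ``<path>.M`` sidecar file, falling back
    to the number of scored variants.
    """
    tab = pd.read_csv(path, sep=r"\s+")
    if not {"SNP", "L2"}.issubset(tab.columns):
        raise SumstatsError(f"LD-score file {path} must have SNP and L2 columns")
    if M is None:
        sidecar = Path(str(path) + ".M")
        M = float(sidecar.read_text().split()[0]) if sidecar.exists() else float(len(tab))
    return LDScoreTable(tab[["SNP", "L2"]].copy(), float(M))


# ---------------------------------------------------------------------------
# quality control


def qc_filter(df: pd.DataFrame, maf_min: float = 0.01, info_min: float = 0.9,
              chi2_max: float = 80.0, drop_ambiguous: bool = True):
    """Standard munging filters; returns ``(filtered frame, QCReport)``.

    Filters: strand-ambiguous allele pairs (A/T, C/G), effect-allele frequency
    outside ``[maf_min, 1 - maf_min]``, imputation INFO below ``info_min``
    (only when an INFO column is present), and chi-square ``Z**2 > chi2_max``.
    Variants with missing FRQ are retained (frequency unknown, not extreme).
    """
    report = QCReport(rows_in=len(df))
    keep = pd.Series(True, index=df.index)

    if drop_ambiguous:
        amb = (df["A1"] + df["A2"]).isin({a + b for a, b in AMBIGUOUS_PAIRS})
        report.add("strand_ambiguous", (keep & amb).sum())
        keep &= ~amb

    if "FRQ" in df.columns:
        frq = df["FRQ"]
        bad_frq = frq.notna() & ~((frq >= maf_min) & (frq <= 1 - maf_min))
        report.add("maf", (keep & bad_frq).sum())
        keep &= ~bad_frq

    if "INFO" in df.columns:
        bad_info = df["INFO"].notna() & (df["INFO"] < info_min)
        report.add("info", (keep & bad_info).sum())
        keep &= ~bad_info

    bad_chi2 = df["Z"] ** 2 > chi2_max
    report.add("chi2", (keep & bad_chi2).sum())
    keep &= ~bad_chi2

    out = df[keep].reset_index(drop=True)
    report.rows_out = len(out)
    if len(out) == 0:
        raise SumstatsError("no variants survive QC")
    return out, report


# ---------------------------------------------------------------------------
# harmonization


def harmonize(tables: dict, ld_table: LDScoreTable, mode: str = "intersection",
              min_variants: int = 5000, default_n: dict | None = None) -> SumstatsPanel:
    """Align per-trait sumstats tables onto one allele-consistent variant grid.

    The reference (A1, A2) orientation per variant is taken from the first
    trait carrying it; a trait whose alleles are swapped relative to the
    reference has its Z negated (and FRQ complemented); a trait whose allele
    pair cannot be reconciled causes the variant to be dropped and logged.
    The grid is restricted to variants with an LD score, sorted by (CHR, BP,
    SNP) so jackknife blocks downstream are genomically contiguous.
    """
    if len(tables) < 2:
        raise SumstatsError("harmonization needs at least 2 traits")
    if mode not in ("intersection", "union"):
        raise SumstatsError(f"unknown harmonization mode {mode!r}")

    traits = list(tables)
    log: list = []

    snp_sets = [set(t["SNP"]) for t in tables.values()]
    shared = set.intersection(*snp_sets) if mode == "intersection" \
        else set.union(*snp_sets)
    n_before_ld = len(shared)
    shared &= set(ld_table.table["SNP"])
    log.append(f"{n_before_ld - len(shared)} variants dropped for missing LD score")

    # reference orientation: first trait that carries the variant
    ref = None
    for name in traits:
        t = tables[name]
        t = t[t["SNP"].isin(shared)]
        cols = t[["SNP", "CHR", "BP", "A1", "A2", "FRQ"]]
        ref = cols if ref is None else pd.concat(
            [ref, cols[~cols["SNP"].isin(ref["SNP"])]])
    ref = ref.sort_values(["CHR", "BP", "SNP"], kind="mergesort").reset_index(drop=True)

    m = len(ref)
    k = len(traits)
    Z = np.full((m, k), np.nan)
    N = np.full((m, k), np.nan)
    drop_mask = np.zeros(m, dtype=bool)
    pos_of = pd.Series(np.arange(m), index=ref["SNP"])

    for j, name in enumerate(traits):
        t = tables[name]
        t = t[t["SNP"].isin(shared)]
        idx = pos_of[t["SNP"]].to_numpy()
        a1 = t["A1"].to_numpy()
        a2 = t["A2"].to_numpy()
        r1 = ref["A1"].to_numpy()[idx]
        r2 = ref["A2"].to_numpy()[idx]
        match = (a1 == r1) & (a2 == r2)
        flipped = (a1 == r2) & (a2 == r1)
        bad = ~(match | flipped)
        if bad.any():
            drop_mask[idx[bad]] = True
            log.append(f"{name}: {int(bad.sum())} variants irreconcilable with "
                       "reference alleles")
        z = t["Z"].to_numpy(dtype=float).copy()
        z[flipped] *= -1.0
        Z[idx, j] = z
        n_col = t["N"].to_numpy(dtype=float)
        if np.isnan(n_col).any():
            fallback = (default_n or {}).get(name)
            if fallback is None:
                raise SumstatsError(f"{name}: missing per-SNP N and no default_n")
            log.append(f"{name}: substituted default N={fallback} for "
                       f"{int(np.isnan(n_col).sum())} variants")
            n_col = np.where(np.isnan(n_col), fallback, n_col)
        N[idx, j] = n_col
        if flipped.any():
            log.append(f"{name}: {int(flipped.sum())} variants allele-flipped")

    if mode == "intersection":
        drop_mask |= np.isnan(Z).any(axis=1)
    keep = ~drop_mask
    n_dropped = int(drop_mask.sum())
    if n_dropped:
        log.append(f"{n_dropped} variants dropped during allele reconciliation")

    ref = ref[keep].reset_index(drop=True)
    Z, N = Z[keep], N[keep]
    if len(ref) < min_variants:
        raise SumstatsError(
            f"only {len(ref)} variants overlap after harmonization "
            f"(minimum {min_variants})")

    ld = ld_table.scores_for(ref["SNP"])
    return SumstatsPanel(traits=traits, variants=ref, Z=Z, N=N,
                         ld=ld, M=ld_table.M, log=log)


# ---------------------------------------------------------------------------
# writing


def write_sumstats(df: pd.DataFrame, path) -> None:
    """Write a canonical sumstats frame as tab-delimited text."""
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")


def write_ldscores(ld_table: LDScoreTable, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    ld_table.table.to_csv(path, sep="\t", index=False, float_format="%.10g")
    Path(str(path) + ".M").write_text(f"{ld_table.M:.10g}\n")


def write_corrected_sumstats(corrected, path) -> None:
    """Write g-corrected sumstats: SNP CHR BP A1 A2 BETA SE Z N_eff FRQ.

    Round-trippable by :func:`read_sumstats` with
    ``column_map={"N": "N_eff"}``. An empty result set produces a header-only
    file and a log entry.
    """
    df = corrected.to_frame()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    if len(df) == 0:
        Path(path).write_text("\t".join(CORRECTED_COLUMNS) + "\n")
        return
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")


def write_panel(panel: SumstatsPanel, path) -> None:
    """Persist a harmonized panel as one wide tab-delimited table plus a JSON
    sidecar (traits, M, provenance log)."""
    df = panel.variants.copy()
    df["LD"] = panel.ld
    for j, t in enumerate(panel.traits):
        df[f"Z.{t}"] = panel.Z[:, j]
        df[f"N.{t}"] = panel.N[:, j]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format="%.10g", na_rep="NA")
    write_json({"traits": list(panel.traits), "M": panel.M, "log": panel.log},
               Path(str(path) + ".json"))


def read_panel(path) -> SumstatsPanel:
    meta = json.loads(Path(str(path) + ".json").read_text())
    df = pd.read_csv(path, sep="\t", na_values="NA")
    traits = meta["traits"]
    Z = df[[f"Z.{t}" for t in traits]].to_numpy(dtype=float)
    N = df[[f"N.{t}" for t in traits]].to_numpy(dtype=float)
    return SumstatsPanel(
        traits=list(traits),
        variants=df[["SNP", "CHR", "BP", "A1", "A2", "FRQ"]].copy(),
        Z=Z, N=N, ld=df["LD"].to_numpy(dtype=float), M=float(meta["M"]),
        log=list(meta.get("log", [])))


def write_json(obj: dict, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON-serializable: {type(o)}")
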