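"""Reading, validation, harmonization and writing of GWAS summary statistics.

A study's per-variant association records are held in a :class:`SumStats`
container: a pandas DataFrame with one row per variant, indexed by the
canonical variant id ``chrom:pos:ref:alt`` (GRCh37, 1-based positions, ``ref``
the non-effect allele and ``alt`` the effect allele).  p-values are carried as
``log10p`` (= log10(p), hence non-positive) so that associations far beyond
float underflow (P ~ 1e-117 and smaller are routine in large meta-analyses)
survive every transformation; the ``p`` column is kept alongside for
readability and round-trips through text files.

The quality-control rules implemented here are the standard curation steps for
published summary statistics: drop records with missing or invalid statistics,
drop multiallelic sites, orient every record to a reference panel (flipping
the effect direction and effect-allele frequency where the alleles are
swapped), and split variants into common and low-frequency/rare by MAF.
"""
from __future__ import annotations

import gzip
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import FormatError, UsageError

log = logging.getLogger(__name__)

#: The 9 ancestry labels used throughout, plus "TA" for trans-ancestry results.
ANCESTRIES = (
    "AA",    # African American or Afro-Caribbean
    "AF",    # African unspecified
    "SSAF",  # Sub-Saharan African
    "EU",    # European
    "EA",    # East Asian
    "SA",    # South Asian
    "HS",    # Hispanic or Latin American
    "GME",   # Greater Middle Eastern
    "TA",    # trans-ancestry
)

#: Canonical column order of the summary-statistics table.
COLUMNS = ("chrom", "pos", "ref", "alt", "eaf", "beta", "se", "p", "log10p", "n")

REQUIRED_INPUT = ("chrom", "pos", "ref", "alt", "beta", "se", "p")

# log10 of the smallest positive double; used to remap p == 0 in input.
_LOG10_TINY = math.log10(5e-324)

GENOME_WIDE_P = 5e-8


def variant_ids(df: pd.DataFrame) -> pd.Index:
    """Canonical ``chrom:pos:ref:alt`` ids for the rows of ``df``."""
    pos = df["pos"].astype("Int64").astype(str)
    return pd.Index(
        df["chrom"].astype(str) + ":" + pos + ":" + df["ref"].astype(str)
        + ":" + df["alt"].astype(str)
    )


def chrom_sort_key(chrom: str) -> int:
    """Numeric sort key for chromosome labels 1-22, X, Y, MT."""
    c = str(chrom)
    if c.isdigit():
        return int(c)
    return {"X": 23, "Y": 24, "MT": 25, "M": 25}.get(c, 26)


@dataclass
class StudyMeta:
    """Dataset-level metadata for one study."""

    study_id: str
    trait: str
    ancestry: str
    n_total: float
    is_published_trans: bool = False

    def __post_init__(self) -> None:
        if self.n_total <= 0:
            raise UsageError(f"study {self.study_id}: n_total must be > 0")


@dataclass
class SumStats:
    """One study's summary statistics for one trait and ancestry."""

    study_id: str
    trait: str
    ancestry: str
    n_total: float
    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        if self.ancestry and self.ancestry not in ANCESTRIES:
            raise UsageError(
                f"unknown ancestry label {self.ancestry!r}; expected one of {ANCESTRIES}"
            )

    def __len__(self) -> int:
        return len(self.df)

    @property
    def ids(self) -> pd.Index:
        return self.df.index

    def with_df(self, df: pd.DataFrame) -> "SumStats":
        return replace(self, df=df)

    def copy(self) -> "SumStats":
        return self.with_df(self.df.copy())


def _finish_table(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce dtypes, fill derived columns and set the variant-id index."""
    out = pd.DataFrame(index=df.index)
    out["chrom"] = df["chrom"].astype(str).str.replace("^chr", "", regex=True)
    out["pos"] = pd.to_numeric(df["pos"], errors="coerce").astype("Int64")
    out["ref"] = df["ref"].astype(str).str.upper()
    out["alt"] = df["alt"].astype(str).str.upper()
    for col in ("eaf", "beta", "se", "p", "log10p", "n"):
        if col in df.columns:
            out[col] = pd.to_numeric(df[col], errors="coerce")
        else:
            out[col] = np.nan

    # log10p from p unless an explicit (finite) log10 column was supplied;
    # p == 0 underflows text parsing and is remapped to the smallest positive
    # double, keeping the record usable downstream.
    p = out["p"].to_numpy(dtype=float)
    l10 = out["log10p"].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        from_p = np.log10(p)
    zero_p = np.isnan(l10) & (p == 0)
    if zero_p.any():
        log.warning("%d records with p == 0 remapped to smallest positive double", zero_p.sum())
        from_p[zero_p] = _LOG10_TINY
    l10 = np.where(np.isnan(l10), from_p, l10)
    out["log10p"] = l10
    with np.errstate(over="ignore"):
        out["p"] = np.where(np.isnan(l10), np.nan, np.power(10.0, np.clip(l10, -320, 0)))

    bad_pos = out["pos"].isna() | (out["pos"] < 1)
    out.loc[bad_pos, "pos"] = pd.NA
    keep = ~bad_pos
    if (~keep).any():
        log.warning("%d records with unparseable/invalid position dropped", (~keep).sum())
        out = out[keep]
    out.index = variant_ids(out)
    return out[list(COLUMNS)]


def read_sumstats(
    path,
    column_map: Mapping[str, str] | None = None,
    *,
    study_id: str = "",
    trait: str = "",
    ancestry: str = "",
    n_total: float | None = None,
    sep: str = "\t",
) -> SumStats:
    """Read a delimited summary-statistics file (optionally gzipped).

    ``column_map`` maps canonical field names (``chrom``, ``pos``, ``ref``,
    ``alt``, ``eaf``, ``beta``, ``se``, ``p``, ``log10p``, ``n``) to the
    source file's header names; identity is assumed for unmapped fields.
    Rows with unparseable numeric fields are retained with NaN values —
    removing them is :func:`qc_filter`'s job.
    """
    try:
        raw = pd.read_csv(path, sep=sep, compression="infer", dtype=str,
                          na_values=["NA", "NaN", "nan", ""], keep_default_na=True)
    except (pd.errors.EmptyDataError, gzip.BadGzipFile) as exc:
        raise FormatError(f"{path}: empty or unreadable summary-statistics file") from exc
    if column_map:
        rename = {src: std for std, src in column_map.items() if src in raw.columns}
        raw = raw.rename(columns=rename)
    missing = [c for c in REQUIRED_INPUT if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {', '.join(missing)}")
    if raw.empty:
        raise FormatError(f"{path}: no data rows")
    df = _finish_table(raw)
    if n_total is None:
        n_total = float(np.nanmax(df["n"].to_numpy(dtype=float))) if df["n"].notna().any() else 0.0
    return SumStats(study_id=study_id or str(path), trait=trait,
                    ancestry=ancestry, n_total=float(n_total), df=df)


def from_arrays(
    *,
    study_id: str,
    trait: str,
    ancestry: str,
    n_total: float,
    chrom,
    pos,
    ref,
    alt,
    beta,
    se,
    eaf=None,
    p=None,
    log10p=None,
    n=None,
) -> SumStats:
    """Build a SumStats directly from arrays (used by the simulator and tests)."""
    df = pd.DataFrame({
        "chrom": np.asarray(chrom, dtype=object),
        "pos": np.asarray(pos),
        "ref": ref if not np.isscalar(ref) else np.repeat(ref, len(np.atleast_1d(pos))),
        "alt": alt if not np.isscalar(alt) else np.repeat(alt, len(np.atleast_1d(pos))),
        "beta": beta,
        "se": se,
    })
    df["eaf"] = eaf if eaf is not None else np.nan
    df["p"] = p if p is not None else np.nan
    df["log10p"] = log10p if log10p is not None else np.nan
    df["n"] = n if n is not None else n_total
    out = _finish_table(df)
    return SumStats(study_id=study_id, trait=trait, ancestry=ancestry,
                    n_total=float(n_total), df=out)


def qc_filter(s: SumStats) -> tuple[SumStats, dict]:
    """Remove records with invalid statistics, multiallelic sites and duplicates.

    Removal reasons, applied in order: ``missing_p``, ``missing_beta``,
    ``missing_se``, ``invalid_se`` (se <= 0), ``invalid_p`` (p outside (0, 1]),
    ``invalid_af`` (eaf outside [0, 1]; a missing eaf is allowed),
    ``multiallelic`` (all records at a chrom:pos carrying more than one
    distinct allele pair), ``duplicate_key`` (same variant twice: the record
    with the smallest p is kept).  Idempotent.
    """
    df = s.df
    report: dict[str, int] = {"n_input": len(df)}
    reasons = [
        ("missing_p", df["log10p"].isna()),
        ("missing_beta", df["beta"].isna()),
        ("missing_se", df["se"].isna()),
        ("invalid_se", df["se"].notna() & (df["se"] <= 0)),
        ("invalid_p", df["log10p"].notna() & (df["log10p"] > 0)),
        ("invalid_af", df["eaf"].notna() & ((df["eaf"] < 0) | (df["eaf"] > 1))),
    ]
    bad = pd.Series(False, index=df.index)
    for name, mask in reasons:
        new = mask & ~bad
        report[name] = int(new.sum())
        bad |= mask
    df = df[~bad]

    # Multiallelic: more than one distinct unordered allele pair at a site.
    if len(df):
        lo = np.minimum(df["ref"].to_numpy(dtype=object), df["alt"].to_numpy(dtype=object))
        hi = np.maximum(df["ref"].to_numpy(dtype=object), df["alt"].to_numpy(dtype=object))
        pair = pd.Series(lo + ":" + hi, index=df.index)
        site = df["chrom"].astype(str) + ":" + df["pos"].astype(str)
        multi = pair.groupby(site.to_numpy()).transform("nunique") > 1
        report["multiallelic"] = int(multi.sum())
        df = df[~multi.to_numpy()]
    else:
        report["multiallelic"] = 0

    dup = df.index.duplicated(keep=False)
    if dup.any():
        log.warning("%d duplicate variant keys; keeping smallest p", int(dup.sum()))
        order = df.assign(_l10=df["log10p"]).sort_values("_l10", kind="stable")
        keep_ids = ~order.index.duplicated(keep="first")
        kept = order[keep_ids].drop(columns="_l10")
        report["duplicate_key"] = len(df) - len(kept)
        df = kept.sort_values(["chrom", "pos"], key=lambda c: c.map(chrom_sort_key) if c.name == "chrom" else c,
                              kind="stable")
    else:
        report["duplicate_key"] = 0
    report["n_removed"] = report["n_input"] - len(df)
    report["n_output"] = len(df)
    return s.with_df(df), report


_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def is_strand_ambiguous(ref: str, alt: str) -> bool:
    """A/T and C/G variants read identically on both strands."""
    return len(ref) == 1 and len(alt) == 1 and _COMPLEMENT.get(ref) == alt


def harmonize_alleles(s: SumStats, panel, *, drop_ambiguous: bool = False) -> tuple[SumStats, dict]:
    """Orient records to the panel's (ref, alt) at each site.

    Matching orientation passes through unchanged; swapped orientation gets the
    alleles swapped, the effect direction flipped and eaf replaced by 1 - eaf;
    irreconcilable alleles at a panel site are dropped (counted in the report);
    sites absent from the panel pass through unchanged.  Harmonization is by
    allele identity only — no frequency-based strand inference — so
    strand-ambiguous (A/T, C/G) variants are kept unless ``drop_ambiguous``.
    """
    df = s.df.copy()
    report = {"n_input": len(df), "flipped": 0, "dropped_mismatch": 0, "dropped_ambiguous": 0}
    if drop_ambiguous:
        amb = df.apply(lambda r: is_strand_ambiguous(r["ref"], r["alt"]), axis=1) if len(df) else pd.Series(dtype=bool)
        report["dropped_ambiguous"] = int(amb.sum()) if len(df) else 0
        df = df[~amb] if len(df) else df

    orient = panel.variants[["chrom", "pos", "ref", "alt"]].rename(
        columns={"ref": "_pref", "alt": "_palt"}
    ).drop_duplicates(subset=["chrom", "pos"])
    merged = df.assign(_pos=df["pos"].astype("int64")).merge(
        orient.assign(_pos=orient["pos"].astype("int64")).drop(columns="pos"),
        left_on=["chrom", "_pos"], right_on=["chrom", "_pos"], how="left",
    ).drop(columns="_pos")
    merged.index = df.index
    absent = merged["_pref"].isna()
    match = (merged["ref"] == merged["_pref"]) & (merged["alt"] == merged["_palt"])
    swapped = (merged["ref"] == merged["_palt"]) & (merged["alt"] == merged["_pref"])
    mismatch = ~(absent | match | swapped)

    merged.loc[swapped, ["ref", "alt"]] = merged.loc[swapped, ["_pref", "_palt"]].to_numpy()
    merged.loc[swapped, "beta"] = -merged.loc[swapped, "beta"]
    flip_eaf = swapped & merged["eaf"].notna()
    merged.loc[flip_eaf, "eaf"] = 1.0 - merged.loc[flip_eaf, "eaf"]

    report["flipped"] = int(swapped.sum())
    report["dropped_mismatch"] = int(mismatch.sum())
    if report["dropped_mismatch"]:
        log.warning("%d records with alleles irreconcilable with the panel dropped",
                    report["dropped_mismatch"])
    df = merged[~mismatch].drop(columns=["_pref", "_palt"])
    df.index = variant_ids(df)
    return s.with_df(df), report


def partition_by_maf(s: SumStats, threshold: float = 0.05) -> tuple[SumStats, SumStats, SumStats]:
    """Split records into (common, rare, no_eaf) by MAF = min(eaf, 1 - eaf).

    MAF strictly above ``threshold`` is common; MAF <= threshold (boundary
    inclusive) is rare; records without an effect-allele frequency form the
    third bucket (the pipeline routes them down the rare, largest-study path).
    """
    eaf = s.df["eaf"]
    maf = np.minimum(eaf, 1.0 - eaf)
    has = eaf.notna()
    common = has & (maf > threshold)
    rare = has & ~common
    return s.with_df(s.df[common]), s.with_df(s.df[rare]), s.with_df(s.df[~has])


def _format_p(l10: float) -> str:
    """Scientific-notation p string that survives extreme magnitudes."""
    if np.isnan(l10):
        return "NA"
    if l10 > -300:
        return f"{10.0 ** l10:.6e}"
    frac, whole = math.modf(l10)
    mant = 10.0 ** (1.0 + frac) if frac else 1.0
    exp = int(whole) - 1 if frac else int(whole)
    return f"{mant:.6g}e{exp}"


def write_sumstats(s: SumStats, path) -> None:
    """Write a tab-separated summary-statistics file (gzip if path ends .gz).

    Floats are written with 17 significant digits so a read/write round trip
    preserves every field; ``log10p`` is authoritative for extreme p-values.
    """
    df = s.df.copy()
    df["p"] = [_format_p(v) for v in df["log10p"].to_numpy(dtype=float)]
    cols = [c for c in df.columns if c in COLUMNS] + [c for c in df.columns if c not in COLUMNS]
    df[cols].to_csv(path, sep="\t", index=False, float_format="%.17g", na_rep="NA")
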