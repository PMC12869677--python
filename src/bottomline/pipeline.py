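"""The bottom-line procedure: one consensus estimate per variant per trait.

Per ancestry, variants are split by minor allele frequency.  Common variants
(MAF > 5%) present in several studies are combined by overlap-corrected
fixed-effects meta-analysis; low-frequency/rare variants (MAF <= 5%) take
their statistics verbatim from the largest dataset carrying them, since rare
variants are poorly represented in LD reference panels and most sensitive to
between-study artifacts.  A variant classified common in one dataset and
rare in another resolves to the verbatim record of the largest dataset
containing it.  Ancestries are then combined by an uncorrected fixed-effects
meta-analysis (samples assumed disjoint across ancestries), and per variant
the trans-ancestry record is kept from either that meta-analysis or a
published trans-ancestry study — whichever has the larger sample size.
Signals are enumerated by adaptive LD clumping per ancestry, with panel-
absent significant variants appended as singletons, and merged across
ancestries into trans-ancestry signals wherever clumps share a variant.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clump import (DEFAULT_KB, DEFAULT_MIN_CLUMPS, DEFAULT_P1, DEFAULT_P2,
                    DEFAULT_R2, Clump, Signal, adaptive_clump,
                    append_singletons, clumps_to_signals,
                    merge_by_shared_variants)
from .errors import UsageError
from .ldpanel import LDPanel
from .meta import OverlapModel, estimate_overlap_matrix, meta_fixed_effects, meta_trans_ancestry
from .sumstats import SumStats, harmonize_alleles, partition_by_maf, qc_filter

log = logging.getLogger(__name__)


@dataclass
class ClumpConfig:
    p1: float = DEFAULT_P1
    p2: float = DEFAULT_P2
    r2: float = DEFAULT_R2
    kb: float = DEFAULT_KB
    min_clumps: int = DEFAULT_MIN_CLUMPS


@dataclass
class TraitBundle:
    """All inputs for one trait: per-ancestry studies, panels, optional
    published trans-ancestry summary statistics."""

    trait: str
    per_ancestry: dict = field(default_factory=dict)   # ancestry -> [SumStats]
    panels: dict = field(default_factory=dict)         # ancestry -> LDPanel
    published_trans: SumStats | None = None

    def __post_init__(self) -> None:
        for anc, studies in self.per_ancestry.items():
            for s in studies:
                if s.trait and s.trait != self.trait:
                    raise UsageError(
                        f"study {s.study_id} trait {s.trait!r} != bundle trait {self.trait!r}")
                if s.ancestry and s.ancestry != anc:
                    raise UsageError(
                        f"study {s.study_id} ancestry {s.ancestry} filed under {anc}")


@dataclass
class BottomLineResult:
    trait: str
    per_ancestry: dict          # ancestry -> SumStats with provenance column
    trans: SumStats | None
    per_ancestry_clumps: dict   # ancestry -> [Clump]
    per_ancestry_signals: dict  # ancestry -> [Signal]
    trans_signals: list
    info: dict                  # stage diagnostics (overlap matrices, p1 used, QC)


def bottom_line_single_ancestry(
    studies: list[SumStats],
    *,
    maf_threshold: float = 0.05,
    overlap_kwargs: dict | None = None,
) -> tuple[SumStats, dict]:
    """Combine one ancestry's studies into a single per-variant record.

    Returns the consensus SumStats with a ``provenance`` column in
    {overlap_meta, largest_rare, single_study} and a diagnostics dict.
    """
    if not studies:
        raise UsageError("bottom_line_single_ancestry: empty study list")
    overlap_kwargs = overlap_kwargs or {}
    info: dict = {}

    commons, rares = [], []
    for s in studies:
        c, r, no_eaf = partition_by_maf(s, maf_threshold)
        commons.append(c)
        # Records without eaf go down the conservative largest-study path.
        rares.append(r.with_df(pd.concat([r.df, no_eaf.df])))
    info["n_common"] = int(sum(len(c) for c in commons))
    info["n_rare_or_no_eaf"] = int(sum(len(r) for r in rares))

    # Common path: overlap-corrected meta when >= 2 studies carry variants.
    commons_nonempty = [c for c in commons if len(c)]
    if len(commons_nonempty) >= 2:
        model = estimate_overlap_matrix(commons_nonempty, **overlap_kwargs)
        info["overlap_model"] = model
        meta = meta_fixed_effects(commons_nonempty, model, study_id="BOTTOM_LINE")
        common_df = meta.df.copy()
        common_df["provenance"] = np.where(common_df["k"] >= 2, "overlap_meta", "single_study")
        common_df = common_df.drop(columns="k")
    elif len(commons_nonempty) == 1:
        info["overlap_model"] = None
        common_df = commons_nonempty[0].df.copy()
        common_df["provenance"] = "single_study"
    else:
        info["overlap_model"] = None
        common_df = studies[0].df.iloc[0:0].copy()
        common_df["provenance"] = pd.Series(dtype=str)

    # Rare path: verbatim record from the largest dataset carrying the variant.
    order = sorted(range(len(studies)), key=lambda i: (-studies[i].n_total, studies[i].study_id))
    rare_frames = [rares[i].df.assign(_src=studies[i].study_id) for i in order if len(rares[i])]
    if rare_frames:
        rare_df = pd.concat(rare_frames)
        rare_df = rare_df[~rare_df.index.duplicated(keep="first")]
        rare_df["provenance"] = "largest_rare"
    else:
        rare_df = common_df.iloc[0:0].copy()

    # A variant in both MAF categories across datasets resolves to the
    # largest dataset containing it, taken verbatim.
    conflict = common_df.index.intersection(rare_df.index)
    info["n_both_category"] = len(conflict)
    for vid in conflict:
        rare_holder = rare_df.at[vid, "_src"] if "_src" in rare_df.columns else None
        rare_n = next(s.n_total for s in studies if s.study_id == rare_holder)
        carriers = [s for s in studies if vid in s.df.index]
        largest = min(carriers, key=lambda s: (-s.n_total, s.study_id))
        if largest.n_total > rare_n:
            # largest carrier called it common: take its verbatim record
            row = largest.df.loc[[vid]].copy()
            row["_src"] = largest.study_id
            row["provenance"] = "largest_rare"
            rare_df.loc[vid, row.columns] = row.iloc[0]
    common_df = common_df.drop(index=conflict)

    out = pd.concat([common_df, rare_df.drop(columns="_src", errors="ignore")])
    out = out.sort_index()
    n_total = max(s.n_total for s in studies)
    result = SumStats(study_id="BOTTOM_LINE", trait=studies[0].trait,
                      ancestry=studies[0].ancestry, n_total=n_total, df=out)
    return result, info


def bottom_line_trans(
    per_ancestry: list[SumStats],
    published_trans: SumStats | None = None,
) -> SumStats:
    """Trans-ancestry bottom line: uncorrected cross-ancestry meta-analysis,
    reconciled per variant with a published trans-ancestry study by sample
    size (larger n wins)."""
    if not per_ancestry and published_trans is None:
        raise UsageError("bottom_line_trans: no inputs")
    if not per_ancestry:
        df = published_trans.df.copy()
        df["provenance"] = "published_trans"
        return published_trans.with_df(df)

    stripped = [s.with_df(s.df.drop(columns=[c for c in ("provenance", "k", "source_study")
                                             if c in s.df.columns]))
                for s in per_ancestry]
    meta = meta_trans_ancestry(stripped)
    df = meta.df.drop(columns="k")
    df["provenance"] = "trans_meta"
    if published_trans is None:
        return meta.with_df(df)

    pub = published_trans.df.copy()
    pub["provenance"] = "published_trans"
    pub["n"] = pub["n"].fillna(published_trans.n_total)

    shared = df.index.intersection(pub.index)
    keep_pub = pub.loc[shared][pub.loc[shared, "n"] > df.loc[shared, "n"]].index
    meta_part = df.drop(index=keep_pub)
    pub_part = pub.loc[pub.index.difference(df.index).union(keep_pub)]
    out = pd.concat([meta_part, pub_part[meta_part.columns.intersection(pub_part.columns)]])
    out = out[~out.index.duplicated(keep="first")].sort_index()
    n_total = max(meta.n_total, published_trans.n_total)
    return SumStats(study_id="BOTTOM_LINE_TRANS", trait=meta.trait, ancestry="TA",
                    n_total=n_total, df=out)


def run_bottom_line(bundle: TraitBundle, clump_cfg: ClumpConfig | None = None,
                    *, maf_threshold: float = 0.05,
                    overlap_kwargs: dict | None = None,
                    qc: bool = True) -> BottomLineResult:
    """Execute the full bottom-line procedure for one trait bundle."""
    if not bundle.per_ancestry and bundle.published_trans is None:
        raise UsageError(f"trait {bundle.trait}: bundle contains no studies")
    cfg = clump_cfg or ClumpConfig()
    info: dict = {"qc": {}, "harmonize": {}, "overlap": {}, "p1_used": {}}

    per_anc_bl: dict[str, SumStats] = {}
    per_anc_clumps: dict[str, list[Clump]] = {}
    per_anc_signals: dict[str, list[Signal]] = {}

    for anc, studies in bundle.per_ancestry.items():
        panel = bundle.panels.get(anc)
        prepped = []
        for s in studies:
            if qc:
                s, rep = qc_filter(s)
                info["qc"][s.study_id] = rep
                if panel is not None:
                    s, hrep = harmonize_alleles(s, panel)
                    info["harmonize"][s.study_id] = hrep
            prepped.append(s)
        log.info("trait %s ancestry %s: combining %d studies", bundle.trait, anc, len(prepped))
        bl, anc_info = bottom_line_single_ancestry(
            prepped, maf_threshold=maf_threshold, overlap_kwargs=overlap_kwargs)
        per_anc_bl[anc] = bl
        model = anc_info.get("overlap_model")
        info["overlap"][anc] = model.R.tolist() if isinstance(model, OverlapModel) else None

        if panel is not None:
            clump_input = bl.with_df(bl.df.drop(columns="provenance"))
            clumps, p1_used = adaptive_clump(clump_input, panel, cfg.min_clumps,
                                             cfg.p1, cfg.p2, cfg.r2, cfg.kb)
            clumps = append_singletons(clumps, clump_input, panel, p1_used)
            per_anc_clumps[anc] = clumps
            per_anc_signals[anc] = clumps_to_signals(clumps, anc)
            info["p1_used"][anc] = p1_used
            log.info("trait %s ancestry %s: %d clumps at p1=%g",
                     bundle.trait, anc, len(clumps), p1_used)

    trans = None
    if per_anc_bl or bundle.published_trans is not None:
        trans = bottom_line_trans(list(per_anc_bl.values()), bundle.published_trans)
    trans_signals = merge_by_shared_variants(per_anc_clumps) if per_anc_clumps else []

    return BottomLineResult(
        trait=bundle.trait,
        per_ancestry=per_anc_bl,
        trans=trans,
        per_ancestry_clumps=per_anc_clumps,
        per_ancestry_signals=per_anc_signals,
        trans_signals=trans_signals,
        info=info,
    )
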