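"""Consensus-estimation approaches and leave-one-out replication validation.

Four approaches to a per-variant consensus across several published GWAS of
one trait and ancestry are compared:

``any``
    each variant takes the record with the lowest p-value across studies
    (the implicit rule behind literature / catalog searches);
``largest``
    the full summary statistics of the single largest study;
``meta_uncorrected``
    fixed-effects IVW meta-analysis ignoring sample overlap;
``meta_corrected``
    covariance-aware IVW with the inter-study correlation estimated from
    shared null variants.

Validation holds out the largest study as a gold standard, re-runs each
approach on the remaining studies, clumps the results, and scores a signal as
a true positive when its variant set intersects any gold-standard signal.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clump import (DEFAULT_P1, Signal, adaptive_clump, clumps_to_signals,
                    greedy_clump)
from .errors import UsageError
from .ldpanel import LDPanel
from .meta import estimate_overlap_matrix, meta_fixed_effects
from .sumstats import SumStats, partition_by_maf

APPROACHES = ("any", "largest", "meta_uncorrected", "meta_corrected")


@dataclass
class ReplicationReport:
    approach: str
    total: int
    true_positives: int

    @property
    def false_positives(self) -> int:
        return self.total - self.true_positives

    @property
    def rate(self) -> float | None:
        """TP / total; undefined (None) when no signals were produced."""
        return self.true_positives / self.total if self.total else None

    def as_dict(self) -> dict:
        return {"approach": self.approach, "total": self.total,
                "true_positives": self.true_positives,
                "false_positives": self.false_positives, "rate": self.rate}


def consensus_any_gwas(studies: list[SumStats]) -> SumStats:
    """Per variant, the record with the smallest p across all studies.

    Ties on p go to the study with the larger declared sample size, then to
    the lexicographically smallest study id for determinism.  The winning
    study id is recorded in a ``source_study`` column.
    """
    if not studies:
        raise UsageError("consensus_any_gwas requires at least one study")
    frames = []
    for s in studies:
        f = s.df.copy()
        f["source_study"] = s.study_id
        f["_n_total"] = s.n_total
        frames.append(f)
    cat = pd.concat(frames)
    cat = cat.sort_values(["log10p", "_n_total", "source_study"],
                          ascending=[True, False, True], kind="stable")
    best = cat[~cat.index.duplicated(keep="first")].drop(columns="_n_total")
    best = best.sort_index()
    n_total = max(s.n_total for s in studies)
    return SumStats(study_id="ANY", trait=studies[0].trait,
                    ancestry=studies[0].ancestry, n_total=n_total, df=best)


def consensus_largest(studies: list[SumStats]) -> SumStats:
    """The summary statistics of the largest study, verbatim.

    Ties on n_total resolve to the lexicographically smallest study id.
    """
    if not studies:
        raise UsageError("consensus_largest requires at least one study")
    winner = min(studies, key=lambda s: (-s.n_total, s.study_id))
    return winner.copy()


def replication_metrics(signals: list[Signal], gold: list[Signal],
                        approach: str = "") -> ReplicationReport:
    """Score signals against gold-standard signals by variant-set overlap."""
    gold_variants: set = set()
    for g in gold:
        gold_variants |= g.variants
    tp = sum(1 for sig in signals if sig.variants & gold_variants)
    return ReplicationReport(approach=approach, total=len(signals), true_positives=tp)


def _build_approach(approach: str, studies: list[SumStats],
                    overlap_kwargs: dict) -> SumStats:
    if approach == "any":
        return consensus_any_gwas(studies)
    if approach == "largest":
        return consensus_largest(studies)
    if approach == "meta_uncorrected":
        return meta_fixed_effects(studies, None, study_id="META_UNCORRECTED")
    if approach == "meta_corrected":
        model = estimate_overlap_matrix(studies, **overlap_kwargs)
        return meta_fixed_effects(studies, model, study_id="META_CORRECTED")
    raise UsageError(f"unknown approach {approach!r}; expected one of {APPROACHES}")


def leave_one_out_validate(
    studies: list[SumStats],
    panel: LDPanel,
    approaches=APPROACHES,
    *,
    p1: float = DEFAULT_P1,
    maf_threshold: float = 0.05,
    log10p_bins=(-np.inf, -12, -10, -8),
    overlap_kwargs: dict | None = None,
    clump_kwargs: dict | None = None,
) -> dict:
    """Hold out the largest study as gold standard; score each approach.

    Requires at least three studies so that two remain after the hold-out;
    otherwise returns ``{"status": "excluded"}``.  All inputs are first
    restricted to common variants (MAF above ``maf_threshold``), since LD
    panels cover common variants.  Gold signals come from adaptive clumping
    of the held-out study; approaches are clumped at the fixed genome-wide
    ``p1`` (no adaptive relaxation, which would change the false-positive
    semantics).  Reports include a breakdown of signal counts by lead
    -log10 p bin for the borderline-significance stratification.
    """
    if len(studies) < 3:
        return {"status": "excluded",
                "reason": f"{len(studies)} studies; need >= 3 so 2 remain after hold-out"}
    overlap_kwargs = overlap_kwargs or {}
    clump_kwargs = clump_kwargs or {}

    common = []
    for s in studies:
        c, _, _ = partition_by_maf(s, maf_threshold)
        c = SumStats(study_id=s.study_id, trait=s.trait, ancestry=s.ancestry,
                     n_total=s.n_total, df=c.df)
        common.append(c)

    gold_study = min(common, key=lambda s: (-s.n_total, s.study_id))
    rest = [s for s in common if s.study_id != gold_study.study_id]
    gold_clumps, gold_p1 = adaptive_clump(gold_study, panel, **clump_kwargs)
    gold_signals = clumps_to_signals(gold_clumps, "gold")
    greedy_kwargs = {k: v for k, v in clump_kwargs.items() if k in ("p2", "r2", "kb")}

    reports = {}
    for approach in approaches:
        cons = _build_approach(approach, rest, overlap_kwargs)
        clumps = greedy_clump(cons, panel, p1=p1, **greedy_kwargs)
        signals = clumps_to_signals(clumps, approach)
        rep = replication_metrics(signals, gold_signals, approach)
        edges = list(log10p_bins) + [0.0]
        by_bin = {}
        for lo, hi in zip(edges[:-1], edges[1:]):
            in_bin = [sig for sig in signals
                      if any(lo <= lp < hi for lps in sig.leads.values() for _, lp in lps)]
            key = f"[{lo},{hi})"
            by_bin[key] = replication_metrics(in_bin, gold_signals, approach).as_dict()
        reports[approach] = {**rep.as_dict(), "by_lead_log10p_bin": by_bin}

    return {"status": "ok", "gold_study": gold_study.study_id, "gold_p1": gold_p1,
            "n_gold_signals": len(gold_signals), "reports": reports}
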