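"""Machinery for comparing downstream (post-GWAS) results of two GWAS.

Covers: grouping lead SNPs from two analyses into shared 1-Mb association
regions; matching fine-mapping credible sets by their shared posterior
inclusion probability (PIP) mass; Benjamini-Hochberg FDR; paired concordance
correlations; through-origin regression for relative bias; and a
permutation-calibrated enrichment-walk score for comparing ranked gene-set
results (an unweighted GSEA-style running sum).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import UsageError
from .sumstats import chrom_sort_key

COMPLETE_MATCH_THRESHOLD = 0.6
MIN_PIP_SUM = 0.99
REGION_WIDTH = 1_000_000


def _pos_of(key) -> tuple[str, int]:
    """(chrom, pos) from a ``chrom:pos:ref:alt`` id or a (chrom, pos, ...) tuple."""
    if isinstance(key, str):
        parts = key.split(":")
        return parts[0], int(parts[1])
    return str(key[0]), int(key[1])


@dataclass
class Region:
    chrom: str
    start: int
    trait: str = ""
    leads: list = field(default_factory=list)  # [(key, label)] sorted by pos

    @property
    def shared(self) -> bool:
        return len({label for _, label in self.leads}) >= 2


def assign_regions(leads) -> list[Region]:
    """Group lead SNPs into contiguous association regions.

    Leads (``(key, source_label)`` pairs) are sorted by chromosome and
    position; the first lead's position starts the first region, and each
    subsequent lead joins the current region iff it is on the same chromosome
    and less than 1 Mb from the region start, otherwise it starts a new
    region at its own position.  A region is shared when leads from both
    source labels fall in it.
    """
    entries = sorted(
        ((_pos_of(k), k, label) for k, label in leads),
        key=lambda t: (chrom_sort_key(t[0][0]), t[0][1]),
    )
    regions: list[Region] = []
    for (chrom, pos), key, label in entries:
        cur = regions[-1] if regions else None
        if cur is not None and cur.chrom == chrom and pos - cur.start < REGION_WIDTH:
            cur.leads.append((key, label))
        else:
            regions.append(Region(chrom=chrom, start=pos, leads=[(key, label)]))
    return regions


@dataclass
class CredibleSet:
    """A fine-mapped signal: lead variant plus per-variant PIPs (sum >= 0.99)."""

    source: str
    lead: str
    pips: dict  # variant id -> PIP
    cs_id: str = ""

    def __post_init__(self) -> None:
        if self.lead not in self.pips:
            raise UsageError(f"credible set {self.cs_id or self.lead}: lead not in PIP map")
        total = sum(self.pips.values())
        if total < MIN_PIP_SUM - 1e-9:
            raise UsageError(
                f"credible set {self.cs_id or self.lead}: PIP sum {total:.4f} < {MIN_PIP_SUM}")
        if any(not 0.0 <= p <= 1.0 for p in self.pips.values()):
            raise UsageError("PIPs must lie in [0, 1]")
        if not self.cs_id:
            self.cs_id = f"{self.source}:{self.lead}"


@dataclass
class MatchResult:
    cs_a: str
    cs_b: str
    shared_pip_sum: float
    klass: str  # complete | partial | non_match


def _classify(shared_sum: float) -> str:
    if shared_sum > COMPLETE_MATCH_THRESHOLD:
        return "complete"
    return "partial" if shared_sum > 0 else "non_match"


def match_credible_sets(a: list[CredibleSet], b: list[CredibleSet]) -> tuple[list[MatchResult], dict]:
    """All cross pairs of credible sets scored by shared PIP sum.

    For each pair the shared PIP sum is the smaller of the two sides' PIP
    totals over the variants present in both sets; a pair is a complete match
    above 0.6, a partial match in (0, 0.6], and a non-match at 0.  The
    summary reports whether any complete/partial match exists in the region
    and a greedy one-to-one best-match assignment (largest shared sums first).
    """
    results = []
    for ca in a:
        for cb in b:
            shared = set(ca.pips) & set(cb.pips)
            sum_a = sum(ca.pips[v] for v in shared)
            sum_b = sum(cb.pips[v] for v in shared)
            s = min(sum_a, sum_b)
            results.append(MatchResult(ca.cs_id, cb.cs_id, s, _classify(s)))
    ordered = sorted(results, key=lambda m: -m.shared_pip_sum)
    used_a: set = set()
    used_b: set = set()
    best = []
    for m in ordered:
        if m.shared_pip_sum > 0 and m.cs_a not in used_a and m.cs_b not in used_b:
            best.append(m)
            used_a.add(m.cs_a)
            used_b.add(m.cs_b)
    summary = {
        "any_complete": any(m.klass == "complete" for m in results),
        "any_partial": any(m.klass == "partial" for m in results),
        "best_matches": best,
    }
    return results, summary


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving with the input."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any(np.isnan(p)) or np.any(p <= 0) or np.any(p > 1):
        raise UsageError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def paired_concordance(x, y, method: str = "pearson") -> tuple[float, float]:
    """Pearson or Spearman correlation with two-sided asymptotic p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise UsageError("paired_concordance needs two equal-length vectors of size >= 2")
    if method == "pearson":
        r = stats.pearsonr(x, y)
    elif method == "spearman":
        r = stats.spearmanr(x, y)
    else:
        raise UsageError(f"unknown method {method!r}")
    return float(r.statistic), float(r.pvalue)


def through_origin_slope(x, y) -> float:
    """Least-squares slope with the intercept fixed at zero: sum(xy)/sum(x²).

    The relative bias of y against x is reported as 1 - slope by callers.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 1:
        raise UsageError("through_origin_slope needs equal-length vectors of size >= 1")
    denom = float(np.sum(x * x))
    if denom == 0:
        raise UsageError("all x are zero; slope undefined")
    return float(np.sum(x * y) / denom)


def _walk_scores(hit_matrix: np.ndarray, n_ref: int) -> np.ndarray:
    """Enrichment-walk scores for each row of a boolean (runs, N) hit matrix."""
    n = hit_matrix.shape[1]
    steps = np.where(hit_matrix, 1.0 / n_ref, -1.0 / (n - n_ref))
    running = np.cumsum(steps, axis=1)
    return np.clip(running.max(axis=1), 0.0, None)


def enrichment_walk(ranking, reference) -> float:
    """Unweighted running-sum enrichment of ``reference`` in ``ranking``.

    Walking the ranking from most to least significant, the sum rises by
    1/|reference| at each reference member and falls by 1/(N - |reference|)
    otherwise; the score is the maximum positive deviation, in [0, 1].
    """
    ranking = list(ranking)
    reference = set(reference)
    n = len(ranking)
    if not 0 < len(reference) < n:
        raise UsageError("reference must be a non-empty proper subset of the ranking")
    if not reference <= set(ranking):
        raise UsageError("reference contains ids absent from the ranking")
    hits = np.fromiter((g in reference for g in ranking), dtype=bool, count=n)
    return float(_walk_scores(hits[None, :], len(reference))[0])


def permutation_enrichment(ranking, reference, B: int = 1000, seed=None) -> tuple[float, float]:
    """Observed walk score with a permutation p-value.

    ``B`` reference sets of the same size are drawn uniformly without
    replacement from the ranking; the p-value uses the plus-one estimator
    p = (1 + #{permuted >= observed}) / (1 + B), bounded below by 1/(B+1).
    """
    if B < 1:
        raise UsageError("B must be >= 1")
    ranking = list(ranking)
    observed = enrichment_walk(ranking, reference)
    n = len(ranking)
    m = len(set(reference))
    rng = np.random.default_rng(seed)
    hit_matrix = np.zeros((B, n), dtype=bool)
    for b in range(B):
        hit_matrix[b, rng.choice(n, size=m, replace=False)] = True
    perm = _walk_scores(hit_matrix, m)
    p = (1.0 + int(np.sum(perm >= observed - 1e-12))) / (1.0 + B)
    return observed, p
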