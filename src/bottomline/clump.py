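"""Greedy LD clumping, adaptive lead threshold, and signal merging.

A clump is a lead variant (the most significant unassigned variant below the
lead threshold ``p1``) together with every unassigned variant below the
member threshold ``p2`` that lies within the window around the lead and is in
LD with it (r² at or above the clump r² threshold).  The defaults mirror the
established clumping tool's flags: p1 = 5e-8, p2 = 5e-6, r² = 0.01,
kb = 5000, the kb value meaning a ±2.5 Mb window around the lead.

When a trait has no genome-wide-significant variant, the lead threshold is
relaxed in 10-fold increments until at least ``min_clumps`` clumps are found,
but never beyond ``p2``.  Significant variants absent from the LD panel are
appended as single-variant clumps when they fall outside every existing clump
span.  Clumps from several sources (ancestries or consensus approaches) are
merged into signals by connected components over shared variants: two signals
are the same signal iff their variant sets intersect.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx

from .errors import UsageError
from .ldpanel import LDPanel
from .sumstats import SumStats, chrom_sort_key

DEFAULT_P1 = 5e-8
DEFAULT_P2 = 5e-6
DEFAULT_R2 = 0.01
DEFAULT_KB = 5000.0
DEFAULT_MIN_CLUMPS = 50


@dataclass
class Clump:
    lead: str                     # variant id chrom:pos:ref:alt
    lead_log10p: float
    members: frozenset
    chrom: str
    span: tuple[int, int]         # [min member pos, max member pos]
    ancestry: str = ""
    label: str = ""

    def __len__(self) -> int:
        return len(self.members)


@dataclass
class Signal:
    """A merged association signal: union of overlapping clumps."""

    variants: frozenset
    labels: frozenset
    leads: dict = field(default_factory=dict)  # label -> [(lead id, lead_log10p)]


def _vid_sort_key(vid: str, pos_lookup) -> tuple:
    chrom, pos, ref, alt = vid.split(":")
    return (chrom_sort_key(chrom), int(pos), ref, alt)


def greedy_clump(
    s: SumStats,
    panel: LDPanel,
    p1: float = DEFAULT_P1,
    p2: float = DEFAULT_P2,
    r2: float = DEFAULT_R2,
    kb: float = DEFAULT_KB,
) -> list[Clump]:
    """Enumerate clumps by the greedy lead-first procedure.

    Leads are panel-covered variants with p < p1, taken in increasing p
    (ties broken by chromosome, position, alleles); members are unassigned
    panel variants with p < p2 within ±kb/2 kilobases of the lead and with
    r² >= ``r2`` to it.  Each variant joins at most one clump.
    """
    if not (0 < p1 <= p2):
        raise UsageError("require 0 < p1 <= p2")
    if panel.ancestry and s.ancestry and panel.ancestry != s.ancestry:
        raise UsageError(f"panel ancestry {panel.ancestry} != study ancestry {s.ancestry}")

    df = s.df
    l10 = df["log10p"]
    covered = df.index.isin(panel.variants.index)
    lead_thr = math.log10(p1)
    member_thr = math.log10(p2)
    half_window = kb * 500.0  # kb flag -> ±kb/2 * 1000 bp around the lead

    cand = df[covered & (l10 < lead_thr)]
    order = sorted(
        cand.index,
        key=lambda vid: (cand.at[vid, "log10p"],) + _vid_sort_key(vid, None),
    )
    eligible_members = set(df.index[covered & (l10 < member_thr)])

    assigned: set = set()
    clumps: list[Clump] = []
    pos_of = df["pos"]
    chrom_of = df["chrom"]
    for lead in order:
        if lead in assigned:
            continue
        lead_pos = int(pos_of.at[lead])
        lead_chrom = chrom_of.at[lead]
        members = {lead}
        for other, rr in panel.neighbors(lead).items():
            if rr < r2 or other in assigned or other not in eligible_members:
                continue
            if chrom_of.at[other] != lead_chrom:
                continue
            if abs(int(pos_of.at[other]) - lead_pos) > half_window:
                continue
            members.add(other)
        assigned |= members
        positions = [int(pos_of.at[m]) for m in members]
        clumps.append(Clump(
            lead=lead,
            lead_log10p=float(l10.at[lead]),
            members=frozenset(members),
            chrom=str(lead_chrom),
            span=(min(positions), max(positions)),
            ancestry=s.ancestry,
        ))
    return clumps


def adaptive_clump(
    s: SumStats,
    panel: LDPanel,
    min_clumps: int = DEFAULT_MIN_CLUMPS,
    p1: float = DEFAULT_P1,
    p2: float = DEFAULT_P2,
    r2: float = DEFAULT_R2,
    kb: float = DEFAULT_KB,
) -> tuple[list[Clump], float]:
    """Clump, relaxing p1 in 10-fold increments (capped at p2) until at least
    ``min_clumps`` clumps exist.  Returns (clumps, p1 actually used)."""
    p1_used = p1
    clumps = greedy_clump(s, panel, p1_used, p2, r2, kb)
    while len(clumps) < min_clumps and p1_used < p2:
        p1_used = min(p1_used * 10.0, p2)
        clumps = greedy_clump(s, panel, p1_used, p2, r2, kb)
    return clumps, p1_used


def append_singletons(
    clumps: list[Clump],
    s: SumStats,
    panel: LDPanel,
    p1_used: float = DEFAULT_P1,
) -> list[Clump]:
    """Append panel-absent significant variants as single-variant clumps.

    Variants with p < p1_used that the panel does not cover (typically rare
    variants absent from the reference) become singleton clumps when their
    position falls outside every existing clump span on their chromosome;
    those inside a span are attached as members of the covering clump
    (nearest lead when spans overlap).
    """
    thr = math.log10(p1_used)
    df = s.df
    sig = df[(df["log10p"] < thr) & ~df.index.isin(panel.variants.index)]
    out = list(clumps)
    for vid, row in sig.iterrows():
        pos = int(row["pos"])
        chrom = str(row["chrom"])
        covering = [
            (i, c) for i, c in enumerate(out)
            if c.chrom == chrom and c.span[0] <= pos <= c.span[1]
        ]
        if covering:
            i, c = min(
                covering,
                key=lambda ic: abs(int(ic[1].lead.split(":")[1]) - pos),
            )
            out[i] = replace(
                c,
                members=c.members | {vid},
                span=(min(c.span[0], pos), max(c.span[1], pos)),
            )
        else:
            out.append(Clump(
                lead=vid,
                lead_log10p=float(row["log10p"]),
                members=frozenset({vid}),
                chrom=chrom,
                span=(pos, pos),
                ancestry=s.ancestry,
            ))
    return out


def merge_by_shared_variants(clump_sets) -> list[Signal]:
    """Merge labeled clump collections into signals via connected components.

    ``clump_sets`` maps a source label (approach id or ancestry) to its list
    of clumps.  Variants are graph vertices; co-membership within any clump
    connects them; each connected component is one signal, annotated with the
    contributing labels and each label's lead(s) within the component.
    """
    g = nx.Graph()
    lead_info: dict[str, list] = {}
    for label, clumps in clump_sets.items():
        for c in clumps:
            g.add_node(c.lead)
            for m in c.members:
                if m != c.lead:
                    g.add_edge(c.lead, m)
            lead_info.setdefault(label, []).append((c.lead, c.lead_log10p))
    signals = []
    for comp in nx.connected_components(g):
        labels = set()
        leads: dict[str, list] = {}
        for label, entries in lead_info.items():
            hits = [(lead, lp) for lead, lp in entries if lead in comp]
            if hits:
                labels.add(label)
                leads[label] = sorted(hits, key=lambda t: t[1])
        signals.append(Signal(variants=frozenset(comp), labels=frozenset(labels), leads=leads))
    signals.sort(key=lambda sig: min(_vid_sort_key(v, None) for v in sig.variants))
    return signals


def clumps_to_signals(clumps: list[Clump], label: str) -> list[Signal]:
    """Wrap one source's clumps as signals without cross-source merging."""
    return merge_by_shared_variants({label: clumps})
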