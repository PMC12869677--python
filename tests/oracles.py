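"""Independent reference implementations used as test oracles.

These are deliberately written in the most direct style possible (explicit
loops, re-scans, no shared code with the package) so that agreement with the
package implementations is meaningful.
"""
import math


def ivw_meta(betas, ses):
    """Textbook inverse-variance-weighted fixed-effects combination."""
    w = [1.0 / s**2 for s in ses]
    beta = sum(wi * bi for wi, bi in zip(w, betas)) / sum(w)
    se = math.sqrt(1.0 / sum(w))
    return beta, se


def _chrom_key(c):
    return int(c) if str(c).isdigit() else 23


def brute_force_clump(df, panel, p1, p2, r2, kb):
    """Greedy clumping by repeated full re-scan: sort by p, assign, repeat.

    ``df`` is indexed by variant id with columns chrom, pos, log10p.
    Returns a list of (lead, frozenset(members)) in clump order.
    """
    lead_thr = math.log10(p1)
    member_thr = math.log10(p2)
    half = kb * 500.0

    def vid_key(v):
        c, p, r, a = v.split(":")
        return (_chrom_key(c), int(p), r, a)

    unassigned = set(df.index)
    clumps = []
    while True:
        cands = [v for v in unassigned
                 if panel.contains(v) and df.at[v, "log10p"] < lead_thr]
        if not cands:
            break
        lead = min(cands, key=lambda v: (df.at[v, "log10p"],) + vid_key(v))
        members = {lead}
        for v in list(unassigned):
            if v == lead or not panel.contains(v):
                continue
            if df.at[v, "log10p"] >= member_thr:
                continue
            if str(df.at[v, "chrom"]) != str(df.at[lead, "chrom"]):
                continue
            if abs(int(df.at[v, "pos"]) - int(df.at[lead, "pos"])) > half:
                continue
            if panel.r2(lead, v) < r2:
                continue
            members.add(v)
        unassigned -= members
        clumps.append((lead, frozenset(members)))
    return clumps


def union_find_components(clump_member_sets):
    """Connected components over variants via a hand-rolled union-find."""
    parent = {}

    def find(x):
        parent.setdefault(x, x)
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a, b):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[ra] = rb

    for members in clump_member_sets:
        members = list(members)
        for m in members[1:]:
            union(members[0], m)
        if len(members) == 1:
            find(members[0])
    comps = {}
    for x in parent:
        comps.setdefault(find(x), set()).add(x)
    return sorted((frozenset(c) for c in comps.values()),
                  key=lambda c: sorted(c))


def bh_stepup(pvalues):
    """Benjamini-Hochberg q-values straight from the step-up definition:
    q_(i) = min_{j >= i} m * p_(j) / j over the sorted p-values."""
    m = len(pvalues)
    order = sorted(range(m), key=lambda i: pvalues[i])
    q_sorted = [0.0] * m
    running_min = float("inf")
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running_min = min(running_min, m * pvalues[idx] / rank)
        q_sorted[rank - 1] = min(running_min, 1.0)
    out = [0.0] * m
    for rank, idx in enumerate(order):
        out[idx] = q_sorted[rank]
    return out
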