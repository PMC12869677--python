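"""Ancestry-specific LD reference panel: variant map plus sparse pairwise r².

The panel plays two roles: it fixes the reference allele orientation used to
harmonize summary statistics, and it provides the pairwise r² lookups that
drive LD clumping.  Pairs absent from the table have r² = 0; r²(v, v) = 1 for
every panel variant.  Files are plain TSV (optionally gzipped): a variant map
``id chrom pos ref alt eaf`` and a pair table ``id_a id_b r2``.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import FormatError, UsageError

VARIANT_COLUMNS = ("id", "chrom", "pos", "ref", "alt", "eaf")


@dataclass
class LDPanel:
    ancestry: str
    variants: pd.DataFrame = field(repr=False)  # indexed by variant id
    _adj: dict = field(default_factory=dict, repr=False)  # id -> {id: r2}

    @classmethod
    def build(cls, ancestry: str, variants: pd.DataFrame, pairs) -> "LDPanel":
        """``pairs`` is an iterable of (id_a, id_b, r2) or a 3-column DataFrame."""
        v = variants.copy()
        if "id" in v.columns:
            v = v.set_index("id")
        v["pos"] = v["pos"].astype("int64")
        v["chrom"] = v["chrom"].astype(str)
        adj: dict = {}
        if isinstance(pairs, pd.DataFrame):
            pairs = pairs.itertuples(index=False)
        for a, b, r2 in pairs:
            r2 = float(r2)
            if not 0.0 <= r2 <= 1.0:
                raise UsageError(f"r2 out of [0, 1] for pair ({a}, {b}): {r2}")
            if a == b:
                continue
            adj.setdefault(a, {})[b] = r2
            adj.setdefault(b, {})[a] = r2
        return cls(ancestry=ancestry, variants=v, _adj=adj)

    def __contains__(self, vid: str) -> bool:
        return vid in self.variants.index

    def contains(self, vid: str) -> bool:
        return vid in self.variants.index

    def r2(self, a: str, b: str) -> float:
        if a == b:
            return 1.0 if a in self.variants.index else 0.0
        return self._adj.get(a, {}).get(b, 0.0)

    def neighbors(self, vid: str) -> dict:
        """All panel variants with recorded r² to ``vid`` (excluding itself)."""
        return self._adj.get(vid, {})

    # -- file round trip -----------------------------------------------------

    def to_files(self, variants_path, pairs_path) -> None:
        out = self.variants.reset_index(names="id")
        out[list(VARIANT_COLUMNS)].to_csv(variants_path, sep="\t", index=False,
                                          float_format="%.17g")
        rows = []
        for a, nbrs in self._adj.items():
            for b, r2 in nbrs.items():
                if a < b:
                    rows.append((a, b, r2))
        pd.DataFrame(rows, columns=["id_a", "id_b", "r2"]).to_csv(
            pairs_path, sep="\t", index=False, float_format="%.17g")

    @classmethod
    def from_files(cls, variants_path, pairs_path, ancestry: str) -> "LDPanel":
        v = pd.read_csv(variants_path, sep="\t", compression="infer",
                        dtype={"chrom": str, "id": str})
        missing = [c for c in VARIANT_COLUMNS if c not in v.columns]
        if missing:
            raise FormatError(f"{variants_path}: missing column(s) {', '.join(missing)}")
        p = pd.read_csv(pairs_path, sep="\t", compression="infer", dtype={"id_a": str, "id_b": str})
        for col in ("id_a", "id_b", "r2"):
            if col not in p.columns:
                raise FormatError(f"{pairs_path}: missing column {col}")
        return cls.build(ancestry, v, p)
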