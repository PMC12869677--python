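"""Manifest parsing: a YAML file describing one trait's datasets and panels."""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import FormatError, UsageError
from .ldpanel import LDPanel
from .pipeline import ClumpConfig, TraitBundle
from .sumstats import ANCESTRIES, read_sumstats


@dataclass
class DatasetEntry:
    path: str
    study_id: str
    ancestry: str
    n_total: float
    is_published_trans: bool = False
    column_map: dict = field(default_factory=dict)


@dataclass
class Manifest:
    trait: str
    datasets: list
    panels: dict            # ancestry -> {"variants": path, "pairs": path}
    clump: ClumpConfig
    overlap: dict           # kwargs for estimate_overlap_matrix
    seed: int = 0

    @classmethod
    def load(cls, path) -> "Manifest":
        path = Path(path)
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if not isinstance(raw, dict) or "trait" not in raw:
            raise FormatError(f"{path}: manifest must be a mapping with a 'trait' key")
        base = path.parent

        datasets = []
        for d in raw.get("datasets", []):
            entry = DatasetEntry(
                path=str(base / d["path"]),
                study_id=d.get("study_id", Path(d["path"]).stem),
                ancestry=d["ancestry"],
                n_total=float(d["n_total"]),
                is_published_trans=bool(d.get("is_published_trans", False)),
                column_map=d.get("column_map", {}) or {},
            )
            if entry.ancestry not in ANCESTRIES:
                raise UsageError(f"{path}: dataset {entry.study_id}: "
                                 f"unknown ancestry {entry.ancestry!r}")
            if not Path(entry.path).exists():
                raise UsageError(f"{path}: dataset file not found: {entry.path}")
            datasets.append(entry)

        panels = {}
        for anc, p in (raw.get("panels") or {}).items():
            spec = {"variants": str(base / p["variants"]), "pairs": str(base / p["pairs"])}
            for k, v in spec.items():
                if not Path(v).exists():
                    raise UsageError(f"{path}: panel {k} file not found: {v}")
            panels[anc] = spec

        params = raw.get("params") or {}
        clump = ClumpConfig(**(params.get("clump") or {}))
        overlap = dict(params.get("overlap") or {})
        return cls(trait=str(raw["trait"]), datasets=datasets, panels=panels,
                   clump=clump, overlap=overlap, seed=int(raw.get("seed", 0)))

    def to_bundle(self) -> TraitBundle:
        """Load every dataset and panel into a TraitBundle."""
        per_ancestry: dict = {}
        published = None
        for d in self.datasets:
            s = read_sumstats(d.path, d.column_map or None, study_id=d.study_id,
                              trait=self.trait, ancestry=d.ancestry, n_total=d.n_total)
            if d.is_published_trans or d.ancestry == "TA":
                if published is not None:
                    raise UsageError("more than one published trans-ancestry dataset")
                published = s
            else:
                per_ancestry.setdefault(d.ancestry, []).append(s)
        panels = {anc: LDPanel.from_files(p["variants"], p["pairs"], anc)
                  for anc, p in self.panels.items()}
        return TraitBundle(trait=self.trait, per_ancestry=per_ancestry,
                           panels=panels, published_trans=published)
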