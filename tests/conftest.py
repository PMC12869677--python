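import numpy as np
import pandas as pd
import pytest

from bottomline import LDPanel, SimConfig, from_arrays
from bottomline.meta import log10p_from_z


def make_study(records, *, study_id="S1", trait="T", ancestry="EU", n_total=10_000):
    """Build a SumStats from a list of per-variant dicts.

    Each record needs chrom, pos, and either (beta, se, p) or z (converted
    assuming se = 1/sqrt(n_total)); ref/alt default to A/G, eaf to 0.3.
    """
    rows = []
    for r in records:
        r = dict(r)
        r.setdefault("ref", "A")
        r.setdefault("alt", "G")
        r.setdefault("eaf", 0.3)
        if "z" in r:
            se = 1.0 / np.sqrt(r.get("n", n_total))
            r.setdefault("se", se)
            r.setdefault("beta", r.pop("z") * r["se"])
        z = r["beta"] / r["se"]
        r.setdefault("log10p", float(log10p_from_z(z)))
        r.setdefault("p", 10.0 ** max(r["log10p"], -320))
        rows.append(r)
    df = pd.DataFrame(rows)
    return from_arrays(
        study_id=study_id, trait=trait, ancestry=ancestry, n_total=n_total,
        chrom=[str(r["chrom"]) for r in rows],
        pos=df["pos"], ref=df["ref"], alt=df["alt"],
        beta=df["beta"], se=df["se"], eaf=df["eaf"],
        p=df["p"], log10p=df["log10p"],
        n=df["n"] if "n" in df else None,
    )


def make_panel(variants, pairs=(), ancestry="EU"):
    """Panel from (chrom, pos[, ref, alt]) tuples and (vid_a, vid_b, r2) pairs."""
    rows = []
    for v in variants:
        chrom, pos = str(v[0]), int(v[1])
        ref, alt = (v[2], v[3]) if len(v) > 2 else ("A", "G")
        rows.append({"id": f"{chrom}:{pos}:{ref}:{alt}", "chrom": chrom,
                     "pos": pos, "ref": ref, "alt": alt, "eaf": 0.3})
    return LDPanel.build(ancestry, pd.DataFrame(rows), list(pairs))


def overlap_pair_config(seed, n_variants, n1, n2, n_shared, **kwargs):
    ov = np.array([[n1, n_shared], [n_shared, n2]], dtype=float)
    return SimConfig(seed=seed, n_variants=n_variants,
                     studies=((n1, "EU"), (n2, "EU")), overlap=ov, **kwargs)


def validation_corpus_config(seed):
    """Heavy-overlap multi-study corpus with study-private artifacts.

    Five studies of one trait with sample sizes spanning the range seen
    across published GWAS, fully nested overlap (each smaller study a subset
    of the larger ones), sparse causal effects detectable by the largest
    study, and 15 artifact signals private to the smallest study.
    """
    ns = (200_000, 100_000, 90_000, 85_000, 80_000)
    k = len(ns)
    ov = np.zeros((k, k))
    for i in range(k):
        for j in range(k):
            ov[i, j] = min(ns[i], ns[j])
    return SimConfig(
        seed=seed, n_variants=20_000, block_size=5, ld_rho=0.7,
        causal_fraction=0.00125, effect_size=0.02,
        studies=tuple((n, "EU") for n in ns), overlap=ov,
        rare_fraction=0.1, artifacts={4: 15}, artifact_z=7.0,
    )


@pytest.fixture
def tiny_study():
    return make_study([
        {"chrom": 1, "pos": 100, "beta": 0.1, "se": 0.02, "eaf": 0.25},
        {"chrom": 1, "pos": 200, "beta": -0.05, "se": 0.01, "eaf": 0.6},
        {"chrom": 2, "pos": 300, "beta": 0.02, "se": 0.015, "eaf": 0.03},
    ])
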