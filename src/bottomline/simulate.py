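"""Synthetic multi-study GWAS generator with known LD and sample overlap.

The generator draws per-variant association z-statistics directly, under the
standard large-sample model for standardized genotypes and phenotypes:

* study i's z at variant v is normal with mean sqrt(n_i) * lambda_v and unit
  variance, where lambda_v is the per-allele standardized effect (0 at null
  variants);
* two studies sharing n_o individuals have Corr(z_i, z_j) = n_o/sqrt(n_i n_j)
  at null variants — the generative law the overlap estimator must recover;
* within an LD block, cross-variant correlation of z equals the genotype
  correlation rho (so pairwise r² = rho²); blocks are independent.

The joint draw factorizes per block as (LD correlation) x (study
correlation), i.e. E = A_C G A_R' with G iid standard normal.  Effect sizes
convert as beta = z * se with se = 1/sqrt(n): the standardized-genotype
scale absorbs allele frequency, and the generated eaf column exists for
MAF-partitioning, not for the sampling variance.  Optionally, study-private
"artifact" signals (large |z| in exactly one study) are planted to emulate
study-specific noise that a consensus procedure should not replicate.

Sample sizes across studies of one trait are allowed to span orders of
magnitude, as they do across published GWAS of well-studied traits.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import UsageError
from .ldpanel import LDPanel
from .meta import log10p_from_z
from .sumstats import SumStats

_VARIANTS_PER_CHROM = 2000


@dataclass
class SimConfig:
    """Study conditions for one simulated trait."""

    seed: int = 0
    n_variants: int = 1000
    block_size: int = 1                 # uniform LD block size
    ld_rho: float = 0.0                 # within-block genotype correlation
    causal_fraction: float = 0.0
    effect_size: float = 0.0            # |lambda| of causal variants
    studies: tuple = ((10_000, "EU"),)  # (n_i, ancestry)
    overlap: np.ndarray | None = None   # K x K shared-individual counts
    rare_fraction: float = 0.1          # fraction of variants with MAF <= 5%
    spacing: int = 100_000              # bp between adjacent variants
    artifacts: dict = field(default_factory=dict)  # study index -> count
    artifact_z: float = 7.0
    trait: str = "SIM"
    block_sizes: tuple | None = None    # explicit block sizes (overrides block_size)

    def __post_init__(self) -> None:
        if not 0.0 <= self.ld_rho < 1.0:
            raise UsageError("ld_rho must lie in [0, 1)")
        if self.block_sizes is not None and sum(self.block_sizes) != self.n_variants:
            raise UsageError("block sizes must sum to n_variants")
        ns = [n for n, _ in self.studies]
        if any(n <= 0 for n in ns):
            raise UsageError("study sample sizes must be positive")
        if self.overlap is not None:
            o = np.asarray(self.overlap, dtype=float)
            k = len(self.studies)
            if o.shape != (k, k) or not np.allclose(o, o.T):
                raise UsageError("overlap must be a symmetric K x K matrix")
            for i in range(k):
                for j in range(k):
                    if not 0 <= o[i, j] <= min(ns[i], ns[j]):
                        raise UsageError(
                            f"overlap[{i},{j}]={o[i, j]} outside [0, min(n_i, n_j)]")
            self.overlap = o

    @property
    def blocks(self) -> list[int]:
        if self.block_sizes is not None:
            return list(self.block_sizes)
        full, rem = divmod(self.n_variants, self.block_size)
        return [self.block_size] * full + ([rem] if rem else [])

    def study_correlation(self) -> np.ndarray:
        ns = np.array([n for n, _ in self.studies], dtype=float)
        if self.overlap is None:
            return np.eye(len(ns))
        R = self.overlap / np.sqrt(np.outer(ns, ns))
        np.fill_diagonal(R, 1.0)
        return R


def _rng_named(cfg: SimConfig, code: int) -> np.random.Generator:
    # fixed stream codes keep the panel, effects and z draws independent
    # yet fully determined by the seed
    return np.random.default_rng([cfg.seed, code])


_STREAM_VARIANTS, _STREAM_EFFECTS, _STREAM_Z, _STREAM_ARTIFACTS = 11, 13, 17, 19


def _variant_table(cfg: SimConfig) -> pd.DataFrame:
    """Deterministic variant map shared by the panel and the studies."""
    rng = _rng_named(cfg, _STREAM_VARIANTS)
    n = cfg.n_variants
    chroms, positions = [], []
    i = 0
    for size in cfg.blocks:
        # keep each LD block on one chromosome
        if i % _VARIANTS_PER_CHROM + size > _VARIANTS_PER_CHROM and i % _VARIANTS_PER_CHROM:
            i += _VARIANTS_PER_CHROM - i % _VARIANTS_PER_CHROM
        for _ in range(size):
            chrom = 1 + (i // _VARIANTS_PER_CHROM)
            chroms.append(str((chrom - 1) % 22 + 1))
            positions.append(cfg.spacing * (i % _VARIANTS_PER_CHROM + 1))
            i += 1
    rare = rng.random(n) < cfg.rare_fraction
    eaf = np.where(rare, rng.uniform(0.002, 0.05, size=n), rng.uniform(0.06, 0.94, size=n))
    df = pd.DataFrame({"chrom": chroms, "pos": positions, "ref": "A", "alt": "G",
                       "eaf": eaf})
    df["id"] = df["chrom"] + ":" + df["pos"].astype(str) + ":A:G"
    return df


def simulate_ld_panel(cfg: SimConfig) -> LDPanel:
    """LD panel matching the simulated variants: within-block r² = rho²,
    zero across blocks."""
    table = _variant_table(cfg)
    pairs = []
    r2 = cfg.ld_rho**2
    if r2 > 0:
        start = 0
        ids = table["id"].to_numpy()
        for size in cfg.blocks:
            for a in range(start, start + size):
                for b in range(a + 1, start + size):
                    pairs.append((ids[a], ids[b], r2))
            start += size
    ancestry = cfg.studies[0][1] if cfg.studies else "EU"
    return LDPanel.build(ancestry, table, pairs)


def true_effects(cfg: SimConfig) -> np.ndarray:
    """Per-variant standardized effects lambda_v (deterministic given seed)."""
    rng = _rng_named(cfg, _STREAM_EFFECTS)
    n = cfg.n_variants
    lam = np.zeros(n)
    causal = rng.random(n) < cfg.causal_fraction
    lam[causal] = cfg.effect_size * rng.choice([-1.0, 1.0], size=int(causal.sum()))
    return lam


def _matrix_sqrt(C: np.ndarray) -> np.ndarray:
    """Symmetric square root robust to semi-definite inputs (e.g. full overlap)."""
    w, v = np.linalg.eigh(C)
    return v * np.sqrt(np.clip(w, 0.0, None))


def simulate_studies(cfg: SimConfig) -> list[SumStats]:
    """Draw every study's summary statistics under the generative law above."""
    table = _variant_table(cfg)
    lam = true_effects(cfg)
    ns = np.array([n for n, _ in cfg.studies], dtype=float)
    k = len(ns)
    R = cfg.study_correlation()
    A_R = _matrix_sqrt(R)

    rng = _rng_named(cfg, _STREAM_Z)
    z = np.empty((cfg.n_variants, k))
    start = 0
    for size in cfg.blocks:
        if cfg.ld_rho > 0 and size > 1:
            C = np.full((size, size), cfg.ld_rho)
            np.fill_diagonal(C, 1.0)
            A_C = np.linalg.cholesky(C)
        else:
            A_C = None
        g = rng.standard_normal((size, k))
        e = g if A_C is None else A_C @ g
        z[start:start + size] = e @ A_R.T
        start += size
    z += np.sqrt(ns)[None, :] * lam[:, None]

    if cfg.artifacts:
        arng = _rng_named(cfg, _STREAM_ARTIFACTS)
        null_idx = np.flatnonzero(lam == 0)
        for study_idx, count in cfg.artifacts.items():
            picks = arng.choice(null_idx, size=count, replace=False)
            signs = arng.choice([-1.0, 1.0], size=count)
            z[picks, study_idx] += signs * cfg.artifact_z

    out = []
    for j, (n_j, ancestry) in enumerate(cfg.studies):
        se = 1.0 / np.sqrt(float(n_j))
        beta = z[:, j] * se
        l10 = log10p_from_z(z[:, j])
        with np.errstate(over="ignore"):
            p = np.power(10.0, np.clip(l10, -320, 0))
        df = pd.DataFrame({
            "chrom": table["chrom"].to_numpy(),
            "pos": table["pos"].astype("Int64").to_numpy(),
            "ref": "A", "alt": "G",
            "eaf": table["eaf"].to_numpy(),
            "beta": beta, "se": se, "p": p, "log10p": l10,
            "n": float(n_j),
        })
        df.index = pd.Index(table["id"])
        out.append(SumStats(study_id=f"study{j + 1}", trait=cfg.trait,
                            ancestry=ancestry, n_total=float(n_j), df=df))
    return out


def simulate_credible_set_pairs(n_regions: int, jitter: float = 0.1,
                                mode: str = "perturbed", seed=None,
                                variants_per_set: int = 5):
    """Paired credible sets for the matching machinery.

    ``identical`` pairs share variants and PIPs; ``perturbed`` pairs share
    variants with PIP mass re-allocated by ``jitter``; ``disjoint`` pairs
    share no variants.  Every set's PIP sum is 0.995 (>= the 0.99 floor).
    """
    from .concordance import CredibleSet

    if n_regions < 1:
        raise UsageError("n_regions must be >= 1")
    if mode not in ("identical", "perturbed", "disjoint"):
        raise UsageError(f"unknown mode {mode!r}")
    rng = np.random.default_rng(seed)
    total = 0.995
    side_a, side_b = [], []
    for r in range(n_regions):
        chrom = str(r % 22 + 1)
        base = 1_000_000 * (r + 1)
        vids = [f"{chrom}:{base + 1000 * j}:A:G" for j in range(2 * variants_per_set)]
        pool = vids[:variants_per_set]
        pips = rng.dirichlet(np.ones(variants_per_set)) * total
        lead = pool[int(np.argmax(pips))]
        side_a.append(CredibleSet("A", lead, dict(zip(pool, pips)), cs_id=f"A:r{r}"))
        if mode == "identical":
            side_b.append(CredibleSet("B", lead, dict(zip(pool, pips)), cs_id=f"B:r{r}"))
        elif mode == "perturbed":
            noise = rng.dirichlet(np.ones(variants_per_set)) * total
            bp = (1.0 - jitter) * pips + jitter * noise
            blead = pool[int(np.argmax(bp))]
            side_b.append(CredibleSet("B", blead, dict(zip(pool, bp)), cs_id=f"B:r{r}"))
        else:  # disjoint
            other = vids[variants_per_set:]
            bp = rng.dirichlet(np.ones(variants_per_set)) * total
            blead = other[int(np.argmax(bp))]
            side_b.append(CredibleSet("B", blead, dict(zip(other, bp)), cs_id=f"B:r{r}"))
    return side_a, side_b


def simulate_ranked_genesets(n_sets: int, signal_overlap: float, seed=None,
                             top_k: int = 50):
    """Two ranked gene-set p-value tables with controlled top-k overlap.

    A fraction ``signal_overlap`` of ranking A's top ``top_k`` sets also
    receive top-ranked p-values in table B; the rest of B is uniform noise.
    """
    if n_sets < 100:
        raise UsageError("n_sets must be >= 100")
    if not 0.0 <= signal_overlap <= 1.0:
        raise UsageError("signal_overlap must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    ids = np.array([f"gs{i:05d}" for i in range(n_sets)])
    p_a = rng.uniform(1e-12, 1.0, size=n_sets)
    a = pd.DataFrame({"gene_set": ids, "p": p_a}).sort_values("p", kind="stable")
    n_shared = int(round(signal_overlap * top_k))
    shared = a["gene_set"].to_numpy()[:n_shared]
    p_b = rng.uniform(1e-12, 1.0, size=n_sets)
    b = pd.DataFrame({"gene_set": ids, "p": p_b})
    b.loc[b["gene_set"].isin(shared), "p"] = rng.uniform(1e-12, 1e-6, size=n_shared)
    b = b.sort_values("p", kind="stable")
    return a.reset_index(drop=True), b.reset_index(drop=True)
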