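"""Sample-overlap estimation and covariance-aware fixed-effects meta-analysis.

Published GWAS of one trait routinely share cohorts, so their association
z-statistics are correlated at null variants: two studies of sizes n1, n2
sharing n_o individuals have Corr(z1, z2) ~ n_o / sqrt(n1 * n2).  Ignoring
this inflates combined test statistics.  The correction implemented here is
the Lin-Sullivan covariance-aware inverse-variance-weighted (IVW) estimator:

    with per-study weights v_i = 1 / se_i**2 and Sigma_ij = R_ij se_i se_j,

        beta_hat = sum(v_i b_i) / sum(v_i)
        var(beta_hat) = (v' Sigma v) / (sum v_i)**2

where R is the inter-study correlation matrix of z-statistics, estimated
empirically from variants that are null (|z| below a cutoff) in both members
of each pair.  With R = I this reduces exactly to textbook IVW — the
"uncorrected" meta-analysis; trans-ancestry combination uses the identity
model because samples are assumed disjoint across ancestries.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy import stats

from .errors import UsageError
from .sumstats import SumStats

log = logging.getLogger(__name__)

_LN10 = math.log(10.0)


def log10p_from_z(z):
    """Two-sided normal log10 p-value, accurate far into the tail."""
    z = np.asarray(z, dtype=float)
    return (math.log(2.0) + stats.norm.logsf(np.abs(z))) / _LN10


@dataclass
class OverlapModel:
    """Estimated inter-study correlation of association z-statistics."""

    study_ids: list[str]
    R: np.ndarray = field(repr=False)
    n_null: np.ndarray = field(repr=False)  # per-pair null-variant counts
    z_cutoff: float = 1.96

    def __post_init__(self) -> None:
        k = len(self.study_ids)
        self.R = np.asarray(self.R, dtype=float)
        if self.R.shape != (k, k):
            raise UsageError("R shape does not match study_ids")
        if not np.allclose(self.R, self.R.T):
            raise UsageError("R must be symmetric")

    @classmethod
    def identity(cls, study_ids) -> "OverlapModel":
        k = len(study_ids)
        return cls(list(study_ids), np.eye(k), np.zeros((k, k), dtype=int))

    def submatrix(self, idx) -> np.ndarray:
        return self.R[np.ix_(idx, idx)]

    def to_tsv(self, path) -> None:
        pd.DataFrame(self.R, index=self.study_ids, columns=self.study_ids).to_csv(
            path, sep="\t", float_format="%.17g")

    @classmethod
    def from_tsv(cls, path, z_cutoff: float = 1.96) -> "OverlapModel":
        df = pd.read_csv(path, sep="\t", index_col=0)
        k = len(df)
        return cls(list(df.columns), df.to_numpy(dtype=float),
                   np.zeros((k, k), dtype=int), z_cutoff)


def _project_psd(R: np.ndarray) -> np.ndarray:
    """Nearest-PSD repair by eigenvalue clipping, diagonal renormalized to 1."""
    w, v = np.linalg.eigh((R + R.T) / 2.0)
    if w.min() >= 0:
        return R
    w = np.clip(w, 0.0, None)
    fixed = (v * w) @ v.T
    d = np.sqrt(np.clip(np.diag(fixed), 1e-12, None))
    fixed = fixed / np.outer(d, d)
    np.fill_diagonal(fixed, 1.0)
    return (fixed + fixed.T) / 2.0


@lru_cache(maxsize=8)
def _truncation_map(z_cutoff: float, n_grid: int = 61, n_quad: int = 48):
    """Correlation of a bivariate standard normal doubly truncated to
    |x| < c and |y| < c, tabulated as a function of the untruncated rho.

    Restricting to null variants (|z| < c in both studies) attenuates the
    Pearson correlation; this map is inverted to de-attenuate the estimate.
    Moments are computed by 2-D Gauss-Legendre quadrature on [-c, c]^2.
    """
    x, w = leggauss(n_quad)
    x = x * z_cutoff
    w = w * z_cutoff
    X, Y = np.meshgrid(x, x)
    WW = np.outer(w, w)
    rhos = np.linspace(0.0, 0.999, n_grid)
    trunc = np.empty_like(rhos)
    for i, rho in enumerate(rhos):
        det = 1.0 - rho**2
        dens = np.exp(-(X**2 - 2 * rho * X * Y + Y**2) / (2 * det)) / (
            2 * np.pi * math.sqrt(det))
        mass = float((dens * WW).sum())
        exy = float((X * Y * dens * WW).sum()) / mass
        exx = float((X * X * dens * WW).sum()) / mass
        trunc[i] = exy / exx  # E[X^2] = E[Y^2] by symmetry
    return rhos, trunc


def _deattenuate(r_trunc: float, z_cutoff: float) -> float:
    """Map an observed truncated-null correlation back to the full-scale rho."""
    rhos, trunc = _truncation_map(z_cutoff)
    return float(np.interp(r_trunc, trunc, rhos))


def estimate_overlap_matrix(
    studies: list[SumStats],
    z_cutoff: float = 1.96,
    min_null: int = 1000,
) -> OverlapModel:
    """Estimate R from the correlation of z = beta/se over shared null variants.

    For each study pair, r is the Pearson correlation of z over variants
    present in both with |z| < ``z_cutoff`` in both, de-attenuated for the
    double truncation that the null restriction imposes (see
    :func:`_truncation_map`) and clipped to [0, 1] — overlap cannot
    de-correlate studies of one trait.  Pairs with fewer than ``min_null``
    shared null variants get r = 0 with a warning.  The assembled matrix is
    projected to the nearest PSD correlation matrix.
    """
    if len(studies) < 2:
        raise UsageError("overlap estimation requires at least 2 studies")
    ids = [s.study_id for s in studies]
    zs = [pd.Series(s.df["beta"] / s.df["se"], index=s.df.index) for s in studies]
    nulls = [z.abs() < z_cutoff for z in zs]
    k = len(studies)
    R = np.eye(k)
    n_null = np.zeros((k, k), dtype=int)
    for i in range(k):
        for j in range(i + 1, k):
            zi, zj = zs[i].align(zs[j], join="inner")
            mask = nulls[i].reindex(zi.index, fill_value=False) & \
                nulls[j].reindex(zj.index, fill_value=False)
            m = int(mask.sum())
            n_null[i, j] = n_null[j, i] = m
            if m < min_null:
                log.warning("pair (%s, %s): only %d shared null variants (< %d); r set to 0",
                            ids[i], ids[j], m, min_null)
                r = 0.0
            else:
                a = zi[mask].to_numpy()
                b = zj[mask].to_numpy()
                if np.allclose(a, b):
                    r = 1.0  # identical z vectors (duplicated study)
                else:
                    r = float(np.corrcoef(a, b)[0, 1])
                    if np.isnan(r):
                        r = 0.0
                    r = _deattenuate(float(np.clip(r, 0.0, 1.0)), z_cutoff)
                r = float(np.clip(r, 0.0, 1.0))
            R[i, j] = R[j, i] = r
    return OverlapModel(ids, _project_psd(R), n_null, z_cutoff)


def effective_sample_size(ns, R: np.ndarray) -> float:
    """Independent-sample size with the same precision as the correlated set.

    With w_i = sqrt(n_i): N_eff = (sum n_i)**2 / (w' R w).  Equals sum(n_i)
    at R = I and max(n_i) when two equal studies fully overlap.
    """
    ns = np.asarray(ns, dtype=float)
    R = np.asarray(R, dtype=float)
    if R.shape != (len(ns), len(ns)):
        raise UsageError("dimension mismatch between ns and R")
    if np.any(ns <= 0):
        raise UsageError("sample sizes must be positive")
    w = np.sqrt(ns)
    return float(ns.sum() ** 2 / (w @ R @ w))


def _meta_pattern(beta, se, n, R_sub):
    """Vectorized covariance-aware IVW for rows sharing one study pattern."""
    v = 1.0 / se**2                      # (rows, k)
    u = 1.0 / se                         # v_i * se_i
    W = v.sum(axis=1)
    beta_meta = (v * beta).sum(axis=1) / W
    quad = np.einsum("ij,jk,ik->i", u, R_sub, u)
    var = quad / W**2
    bad = ~(var > 0)
    if bad.any():
        log.warning("%d variants with non-positive combined variance; identity fallback",
                    int(bad.sum()))
        var[bad] = 1.0 / W[bad]
    se_meta = np.sqrt(var)
    w = np.sqrt(n)
    neff = n.sum(axis=1) ** 2 / np.einsum("ij,jk,ik->i", w, R_sub, w)
    return beta_meta, se_meta, neff


def meta_fixed_effects(
    studies: list[SumStats],
    model: OverlapModel | None = None,
    *,
    study_id: str = "META",
) -> SumStats:
    """Fixed-effects meta-analysis across studies, overlap-aware if given a model.

    Per variant, the combination runs over the subset of studies containing
    it, with the global R restricted to that subset.  ``model=None`` uses the
    identity matrix (uncorrected meta-analysis).  Variants present in exactly
    one study pass through with their original statistics verbatim.  The
    output carries the effective sample size in ``n`` and the number of
    contributing studies in ``k``.
    """
    if not studies:
        raise UsageError("meta_fixed_effects requires at least one study")
    ids = [s.study_id for s in studies]
    if model is None:
        model = OverlapModel.identity(ids)
    missing = [i for i in ids if i not in model.study_ids]
    if missing:
        raise UsageError(f"overlap model does not cover studies: {missing}")
    order = [model.study_ids.index(i) for i in ids]

    k = len(studies)
    all_ids = pd.Index([])
    for s in studies:
        all_ids = all_ids.union(s.df.index)
    nvar = len(all_ids)
    beta = np.full((nvar, k), np.nan)
    se = np.full((nvar, k), np.nan)
    nmat = np.full((nvar, k), np.nan)
    for j, s in enumerate(studies):
        loc = all_ids.get_indexer(s.df.index)
        beta[loc, j] = s.df["beta"].to_numpy(dtype=float)
        se[loc, j] = s.df["se"].to_numpy(dtype=float)
        nj = s.df["n"].to_numpy(dtype=float)
        nmat[loc, j] = np.where(np.isnan(nj), s.n_total, nj)

    present = ~np.isnan(se)
    out_beta = np.empty(nvar)
    out_se = np.empty(nvar)
    out_neff = np.empty(nvar)
    out_k = present.sum(axis=1)

    # Group variants by their study-presence pattern for vectorized math.
    codes = present @ (1 << np.arange(k))
    for code in np.unique(codes):
        rows = np.flatnonzero(codes == code)
        cols = np.flatnonzero((code >> np.arange(k)) & 1)
        if len(cols) == 0:
            continue
        if len(cols) == 1:
            j = cols[0]
            out_beta[rows] = beta[rows, j]
            out_se[rows] = se[rows, j]
            out_neff[rows] = nmat[rows, j]
            continue
        R_sub = model.R[np.ix_([order[c] for c in cols], [order[c] for c in cols])]
        b, s_, neff = _meta_pattern(beta[np.ix_(rows, cols)], se[np.ix_(rows, cols)],
                                    nmat[np.ix_(rows, cols)], R_sub)
        out_beta[rows] = b
        out_se[rows] = s_
        out_neff[rows] = neff

    z = out_beta / out_se
    l10 = log10p_from_z(z)

    # Carry positional/allele/eaf metadata from the contributing studies;
    # eaf is the sample-size-weighted mean where several studies contribute.
    frames = []
    for s in studies:
        f = s.df[["chrom", "pos", "ref", "alt", "eaf"]].copy()
        f["_w"] = np.where(s.df["n"].notna(), s.df["n"], s.n_total)
        frames.append(f)
    cat = pd.concat(frames)
    meta_cols = cat.groupby(level=0).agg(chrom=("chrom", "first"), pos=("pos", "first"),
                                         ref=("ref", "first"), alt=("alt", "first"))
    weighted = cat.assign(_we=cat["eaf"] * cat["_w"]).groupby(level=0)[["_we", "_w"]].sum(min_count=1)
    meta_cols["eaf"] = weighted["_we"] / weighted["_w"]
    meta_cols = meta_cols.reindex(all_ids)

    df = meta_cols.copy()
    df["beta"] = out_beta
    df["se"] = out_se
    df["log10p"] = l10
    with np.errstate(over="ignore"):
        df["p"] = np.power(10.0, np.clip(l10, -320, 0))
    df["n"] = out_neff
    df["k"] = out_k

    # Single-study variants keep their original record verbatim.
    single = out_k == 1
    if single.any():
        for j, s in enumerate(studies):
            rows = all_ids[single & present[:, j]]
            take = s.df.loc[s.df.index.intersection(rows)]
            for col in ("beta", "se", "p", "log10p", "eaf"):
                df.loc[take.index, col] = take[col]

    df = df[["chrom", "pos", "ref", "alt", "eaf", "beta", "se", "p", "log10p", "n", "k"]]
    anc = studies[0].ancestry if len({s.ancestry for s in studies}) == 1 else "TA"
    return SumStats(study_id=study_id, trait=studies[0].trait, ancestry=anc,
                    n_total=float(np.nansum([s.n_total for s in studies])), df=df)


def meta_trans_ancestry(per_ancestry: list[SumStats]) -> SumStats:
    """Fixed-effects combination across ancestries (identity overlap model).

    Samples are assumed disjoint across ancestry groups, so no correction is
    applied; a variant observed in a single ancestry passes through with its
    statistics and sample size unchanged.
    """
    labels = [s.ancestry for s in per_ancestry]
    if len(labels) != len(set(labels)):
        raise UsageError(f"duplicate ancestry label among inputs: {labels}")
    relabeled = [
        SumStats(study_id=s.study_id or f"anc_{s.ancestry}", trait=s.trait,
                 ancestry=s.ancestry, n_total=s.n_total, df=s.df)
        for s in per_ancestry
    ]
    out = meta_fixed_effects(relabeled, None, study_id="TRANS_META")
    return SumStats(study_id=out.study_id, trait=out.trait, ancestry="TA",
                    n_total=out.n_total, df=out.df)
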