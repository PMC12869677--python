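# Methods

This note documents the statistical model, the procedural rules, the
synthetic-data generator, and the numerical and design choices behind
`bottomline`. Everything quantitative stated here is computed by the test
suite or by `scripts/acceptance.py`; nothing is quoted from external data.

## Overlap-aware fixed-effects meta-analysis

**Model.** For one variant observed in studies i = 1..k with effect
estimates βᵢ and standard errors seᵢ, the estimates are treated as jointly
normal around a shared true effect with covariance Σᵢⱼ = Rᵢⱼ seᵢ seⱼ, where
R is the correlation matrix of the studies' association z-statistics.
Shared individuals induce R off-diagonals: two studies of sizes n₁, n₂
sharing n₀ participants of one quantitative-trait cohort have
Corr(z₁, z₂) ≈ n₀/√(n₁n₂) at null variants. The combined estimate keeps the
usual inverse-variance weights (vᵢ = 1/seᵢ²) and widens only the variance:

    β̂ = Σvᵢβᵢ / Σvᵢ,   Var(β̂) = (vᵀΣv)/(Σvᵢ)² = (uᵀRu)/(Σvᵢ)²,  uᵢ = 1/seᵢ

(the Lin–Sullivan estimator). At R = I this is textbook IVW — the
"uncorrected" path — and at R = **1** (a study duplicated) the combination
returns the original (β, se): duplicated data add no information. The
package asserts both identities in its tests. p-values are computed from
z = β̂/se via the normal log-survival function, carried as log10(p)
throughout, so results beyond double-precision underflow (|log₁₀p| of
several thousand) survive I/O and arithmetic.

**Estimating R.** For each study pair, R̂ᵢⱼ is the Pearson correlation of
z over variants shared by the pair with |z| < 1.96 in *both* studies.
Restricting to that null box truncates both margins of a bivariate normal,
which attenuates the correlation (at ρ = 0.5 the truncated correlation is
≈ 0.34). The estimate is therefore de-attenuated by inverting the analytic
map ρ → Corr(X, Y | |X|,|Y| < c), tabulated by two-dimensional
Gauss–Legendre quadrature on [−c, c]² (61-point ρ grid, 48-point rule) and
interpolated. Negative estimates are clipped to zero — shared samples
cannot de-correlate two studies of one trait — and pairs with fewer than
`min_null` (default 1000) shared null variants fall back to 0 with a
warning. The assembled matrix is projected to the nearest positive
semi-definite correlation matrix by eigenvalue clipping with the diagonal
renormalized to 1. Per-variant study subsets reuse the global R restricted
to the subset; R is not re-estimated per variant (stability).

**Effective sample size.** N_eff = (Σnᵢ)²/(wᵀRw), wᵢ = √nᵢ: the
independent-sample size with the same precision. It equals Σnᵢ for
independent studies and max nᵢ for a fully duplicated pair. For binary
traits the user-declared n is used as supplied; converting to
4/(1/n_cases + 1/n_controls) is the caller's choice.

## Summary-statistics QC and harmonization

Records with missing or invalid p, β or se, se ≤ 0, p outside (0, 1], or
allele frequency outside [0, 1] are removed and counted per reason. A site
carrying more than one distinct unordered allele pair is multiallelic and
removed entirely; the swapped-orientation pair {(A,G),(G,A)} is *not*
multiallelic — it is an orientation conflict resolved by harmonization and
the duplicate rule (smallest p wins, with a warning). p = 0 in input is
remapped to the smallest positive double and flagged. Harmonization orients
each record to the panel's (ref, alt): swapped records get alleles swapped,
β negated and eaf → 1 − eaf; irreconcilable alleles are dropped and counted;
variants absent from the panel pass through. Strand-ambiguous (A/T, C/G)
variants are harmonized by allele identity only — no frequency-based strand
inference — with an optional flag to drop them. Both QC and harmonization
are idempotent, which the tests assert.

MAF partition: maf = min(eaf, 1 − eaf); maf > 0.05 is common, maf ≤ 0.05
(boundary inclusive) is rare. Records without eaf cannot be partitioned and
are routed down the conservative rare path (largest study wins); they are
returned as a third bucket so the partition is verifiably exhaustive.

## LD clumping and signal merging

Greedy clumping with the established tool's parameter semantics:
`p1 = 5e-8` (lead threshold), `p2 = 5e-6` (member threshold), `r2 = 0.01`,
`kb = 5000` interpreted as a ±2.5 Mb window around the lead. The most
significant unassigned panel-covered variant below p1 leads; unassigned
panel variants below p2 within the window and with r² ≥ 0.01 to the lead
join it; each variant belongs to at most one clump. Ties on p break by
(chromosome, position, ref, alt). p2 thresholds *members* — the standard
semantics — even though lead candidacy is sometimes loosely described at
p2. When a trait yields fewer than `min_clumps` (50) clumps, p1 relaxes in
ten-fold increments, capped at p2. Significant variants the panel does not
cover (typically rare variants) are appended as single-variant clumps when
outside every clump span; inside a span they attach to the covering clump
(nearest lead if spans overlap) — the interior case is this package's
choice, as only the exterior rule is standard. Implementation equivalence
with an independently written re-scan reference is asserted on 200 random
instances.

Clumps from several sources (consensus approaches, or ancestries for
trans-ancestry signals) merge into **signals** by connected components of
the graph whose vertices are variants and whose edges are co-membership:
two signals are the same signal iff their variant sets intersect. The
component analysis (networkx) is checked against a hand-written union-find.
Per-ancestry clumping runs first, then merging; singleton appending precedes
merging.

## Consensus approaches and leave-one-out validation

Four per-variant consensus rules are compared: **any** (record with the
smallest p across studies; ties to the larger study, then lexicographic
study id), **largest** (the largest study verbatim; ties lexicographic),
**uncorrected meta** (R = I) and **corrected meta** (R estimated). The
validation holds out the largest study of a trait-ancestry pair as the gold
standard (requiring ≥ 3 studies so ≥ 2 remain), restricts to common
variants, clumps the gold study adaptively, runs each approach on the rest,
clumps it at the fixed genome-wide p1 (adaptive relaxation inside validation
would change what counts as a false positive), and scores a signal as a true
positive when its variant set intersects any gold signal. The replication
rate is TP/total, undefined at zero signals. Reports include a breakdown by
lead log₁₀p bin for the borderline-significance stratification.

## Bottom-line record rules

Per ancestry: common variants present in ≥ 2 studies → corrected meta
(provenance `overlap_meta`); present in 1 → that record verbatim
(`single_study`); rare or eaf-less variants → the verbatim record of the
largest dataset carrying them (`largest_rare`). A variant classified common
in one dataset and rare in another resolves to the verbatim record of the
largest dataset containing it, where "largest" means the declared dataset
n_total, not per-variant n (the dataset-level reading; a per-variant
alternative would be a one-line change). Trans-ancestry: uncorrected
fixed-effects across the per-ancestry bottom lines (ancestries assumed
sample-disjoint); per variant, the meta record or a published trans-ancestry
record wins by per-variant sample size (n_eff vs published n); with no
single-ancestry data the published study passes through verbatim. Every
output variant carries exactly one record and one provenance value.

## The synthetic-data generator

`simulate_studies` draws z-statistics directly under the large-sample
standardized model: z ~ N(√n·λ, 1) per variant and study, with cross-study
null covariance n₀/√(nᵢnⱼ) and within-block cross-variant correlation ρ
(so pairwise r² = ρ² in the matching panel; blocks independent; a block
never straddles a chromosome). The joint draw factorizes per block as
(LD correlation) ⊗ (study correlation). β = z·se with se = 1/√n — the
standardized-genotype scale absorbs allele frequency — and the generated
eaf (rare fraction 0.1 by default) exists for MAF partitioning, not for the
sampling variance. Causal variants are Bernoulli(causal fraction) with
effect ±λ; the mean is placed on the causal variant only, not propagated
through LD to block-mates. Optional study-private artifacts add |z| = 7 at
null variants of one study, emulating study-specific noise.

What the generator does *not* emulate: LD-propagated effect means,
frequency-dependent power, imputation quality, allelic heterogeneity across
ancestries, case-control liability scaling, or per-variant missingness
beyond whole-study membership. Passing tests therefore demonstrate the
procedure's correctness under the stated generative law, not robustness to
every artifact of real summary statistics.

Study conditions used by the validation corpora: five studies per trait
with n from 80,000 to 200,000 (published studies of one trait commonly span
one to two orders of magnitude), fully nested overlap, causal fraction
0.00125 at λ = 0.02 over 20,000 variants in blocks of 5 (ρ = 0.7), and 15
artifacts private to the smallest study. Under these conditions the mean
leave-one-out replication rates reproduce the qualitative ordering
corrected ≥ largest ≥ any ≥ uncorrected, with the uncorrected meta-analysis
far below the rest — the regime that motivates overlap correction.

## Post-GWAS concordance machinery

Association regions: lead SNPs from two analyses are sorted by chromosome
and position; the first lead starts a region at its exact position and each
subsequent lead joins iff less than 1 Mb from the region start, else starts
a new region; a region is shared when both sources contribute a lead.
Credible sets carry per-variant posterior inclusion probabilities summing
to ≥ 0.99; for each cross pair the shared PIP sum is the smaller of the two
sides' sums over the intersection — complete match above 0.6, partial in
(0, 0.6], non-match at 0. All cross pairs are reported plus a greedy
one-to-one best-match summary (largest shared sums first), since reducing
multiple matches to "the" pair is otherwise ambiguous. BH-FDR is the
step-up procedure (delegated to statsmodels, verified against the
definition); concordance correlations are Pearson/Spearman with asymptotic
two-sided p; relative bias between paired estimates is 1 − slope of the
through-origin regression Σxy/Σx². A quality predicate drops enrichment
coefficients with |β| > 100 before concordance.

The gene-set enrichment comparison uses an unweighted running-sum score:
walking a ranking from most to least significant, +1/|ref| at reference
members, −1/(N−|ref|) otherwise; the score is the maximum positive
deviation, in [0, 1]. The unweighted (Kolmogorov–Smirnov-style) variant was
chosen over significance-weighted alternatives because the reference sets
are themselves top-k lists; weighting would double-count rank information.
Significance comes from B (default 1000) uniformly resampled references of
the same size with the plus-one estimator p = (1 + #{perm ≥ obs})/(1 + B),
which is never zero and provably super-uniform under the null — the test
suite checks this by one-sided Kolmogorov–Smirnov at 500 replicates
(B = 199 per replicate; the estimator's validity does not depend on B).

## Numerical choices and degenerate inputs

- log10(p) is the authoritative significance field everywhere; the p column
  is derived on output (scientific notation synthesized from log10p beyond
  1e-300) and p = 0 on input is remapped and flagged.
- Identical z vectors short-circuit the overlap estimate to r = 1 exactly.
- Non-positive combined variances (possible only through degenerate R) fall
  back to the identity model for that variant with a warning.
- Variants contributed by a single study pass through every meta path with
  their original β, se, p and n bit-identical.
- Zero-signal replication reports carry rate = None rather than 0, keeping
  "no evidence" distinct from "all false".
- All simulation randomness flows from a single integer seed through fixed
  named substreams (variants, effects, z, artifacts), making every output
  byte-identical across runs and platforms.

## Problem sizes

The default test and acceptance runs use 10,000–20,000 variants for
moment-recovery and calibration checks (Monte-Carlo error on a correlation
at 10,000 nulls is ≈ 0.01, comfortably inside the ±0.05 bands), 200 random
instances of ≤ 200 variants for the clumping oracle, 10 corpora of 5 × 20,000
variants for the replication-ordering study, and 1,000 random vectors for
the BH-FDR oracle. These sizes make every property measurable at its stated
tolerance while keeping a full run to a few minutes on one core.

## Known limitations

- The overlap correction operates on the correlation of z-statistics; it
  corrects variance, not the modest downward bias in effect magnitudes that
  variance inflation induces — the same trade-off as genomic control.
- Effect-size scaling across studies reported in different units is exposed
  as a per-study affine transform in configuration, not inferred; studies
  must be brought to comparable units upstream.
- Coordinates are assumed GRCh37 and 1-based; there is no liftover.
- The LD panel is taken as given (variant map + pairwise r² files); the
  package does not compute r² from genotypes.
- Trans-ancestry combination is fixed-effects only; random-effects modeling
  of allelic heterogeneity is out of scope.
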