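# Methods

This note documents the statistical model behind `texpress`, the choices
made where the design was genuinely open, and what the synthetic-data
tests do and do not establish about real data.

## 1. Read assignment (EM)

Input is read–feature incidence only: each read carries the set of
features it aligns to, with no alignment scores.  The model is a
multinomial mixture: feature f emits reads with proportion
`p_f = a_f / N`, and a read's hit set is observed while its source is
latent.  EM alternates

- **E-step**: read weight to feature f ∝ `a_f + prior` over the read's
  hits (default `prior = 0`);
- **M-step**: `a_f` = summed read weights.

Initialization splits every read uniformly over its hits.  This is
deterministic, keeps total mass equal to the number of reads exactly at
every iteration, and breaks symmetric ties symmetrically (a read hitting
{A, B} with no other evidence ends at 0.5/0.5, not at an arbitrary
fixed point).  Iteration stops when no feature count changes by more
than `tol` (default 1e-6) or after `max_iter` (default 200).

*Numerical note.*  On boundary fixtures where a feature's mass decays to
zero, convergence is sublinear; "the fixed point" is then only defined
up to the stopping rule, which is why the test-suite oracle (an
independent read-level implementation) runs under the same rule.

Limitations: no mapping-quality weighting, no per-locus quantification
(counts are per TE name aggregated over genomic copies), and no
modeling of the upstream aligner's multimapper caps.

## 2. Normalization and differential expression

Size factors are plain median-of-ratios: per sample, the median over
all-positive features of count / geometric-mean.  A
`pseudo_reference=True` fallback computes geometric means over positive
entries only, for sparse matrices.  Exact algebra worth knowing:
multiplying one sample's counts by c scales factor *ratios* by exactly
c and all normalized counts by a single common scalar (`c^{1/m}` with m
samples), so every downstream fold-change and rank statistic is
invariant; the factors themselves are not individually equivariant —
no sample-symmetric normalization can be, given that identical columns
must map to unit factors.  Composition bias is inherited from the
scheme: if a visible fraction of features carries a real shift, the
medians absorb a small part of it (the recovery tests quantify this at
~0.1 log2 units when 1/8 of features change 4-fold).

The Wald test is a declared simplification of the standard GLM
machinery.  Per feature, on normalized counts restricted to the two
groups:

- dispersion: `alpha = max(1e-8, (pooled within-group variance − grand
  mean) / grand mean²)` — method of moments, no shrinkage;
- `log2FC = log2((m̄₁ + ½) / (m̄₀ + ½))`, pseudo-count 0.5 declared so
  tests are exact; all-zero features give log2FC = 0 and p = 1;
- SE by the delta method, propagating `Var(K) = mu + alpha mu²` with
  `mu` the fitted group mean scaled per sample by its size factor;
- p = two-sided normal tail of log2FC/SE; Benjamini–Hochberg across all
  tested features, genes and TEs jointly ("analyzed together" is a
  design requirement: one size-factor set, one table, one correction).

Default order is test-everything, then apply the strict
`base_mean > 10` screen before any class-level statistic; base_mean is
the mean of normalized counts over all samples (the normalized scale is
the convention of the emulating tool chain; a raw-scale screen would
only differ by depth).

*Calibration and known tails.*  At n = 20/group the null rejection rate
at nominal 0.05 is ~0.05–0.06 (the moments estimator's noise makes the
statistic mildly t-like).  Deep in the tail this matters: at BH
thresholds (~4.5 sigma with 10⁴ features) the t-like tails produce a
handful of spurious discoveries per run at desk sample sizes.  Tools
with dispersion shrinkage do not have this artifact; we deliberately do
not shrink.  Consequently the "broad shift with no individual
significance" regime is demonstrated as a recovery test with the
generator's known dispersion supplied to `wald_test` (dispersions are
an explicit input of that operation); the moments path's own behavior
is pinned by the calibration tests at conventional significance levels.

## 3. TE-class tests against the global null

The reference location is the mean log2FC of **all** filtered
transcripts — genes and TEs alike — because library-preparation and
normalization artifacts displace everything equally, and subtracting
the transcriptome-wide location cancels them.  This is stated as a
testable property: adding any constant to every log2FC leaves the
two-sample p unchanged to 1e-12.

Default mode `two_sample`: Mann–Whitney U of the class's log2FCs
against the full filtered log2FC vector (which contains the class; with
class/background ratios in realistic annotations this overlap is a
small conservative perturbation).  `reference="genes_only"` restricts
the reference.  The phrase "rank test versus a mean" is ambiguous
between a two-sample and a one-sample reading; `mode="one_sample"`
provides the literal one-sample Wilcoxon signed-rank against the mean
as a constant.  Exact U enumeration is used when the smaller sample has
≤ 25 values (assuming continuity; no tie correction in the exact
branch), tie-corrected normal approximation otherwise.  Shapiro–Wilk is
computed and reported for each class but never gates the rank test; for
classes above 5000 members it is evaluated on a fixed-seed subsample of
5000 (a standard implementation limit of the statistic).  Classes with
fewer than `min_class_size = 3` filtered members are flagged
untestable.  The `other` class (satellites, tRNAs, simple repeats) is
excluded from class-level testing by default and available behind a
flag.  No correction is applied across the four class-level p-values.

## 4. Correlations and matching

Age correlations are computed on normalized counts only, never raw.
`pearson_correlation` uses the two-sided t reference on n−2 df;
`partial_correlation` residualizes both variables on the covariates
plus intercept by least squares and uses n−2−k df, which reduces
exactly to Pearson at k = 0.  Categorical covariates (sex) expand to
indicator columns dropping the first level; rank-deficient covariate
sets are rejected naming the collinear columns.

Matching is configurable because only the outcome ("carefully sex- and
age-matched") is specified, not the algorithm.  `objective="pair"`
greedily pairs the two groups within each sex stratum by smallest
|age difference| (global smallest-first, sample-id lexicographic
tie-break — deterministic, and optimal on well-separated instances
though not in adversarial ones).  `objective="extremes"` picks the
n oldest and n youngest subjects under identical per-sex quotas,
for an old-vs-young contrast from a continuous age pool.

"Most increased" TEs are those with log2FC strictly greater than the
mean log2FC over all (filtered) TEs; strictness makes the all-equal and
single-TE cases empty by construction.  Set intersection over 2–6
contrasts assigns every TE in the union to exactly one membership
pattern; region counts are exhaustive and sum to the union size.

## 5. Synthetic data: what it emulates, what it does not

The generator draws NB counts (`variance = mu + alpha mu²`,
gamma–Poisson construction; `alpha = 0` is Poisson) with

- per-feature baselines ~ LogNormal(ln 100, 1) — a typical bulk
  count-abundance spread;
- per-sample size factors ~ Uniform(0.7, 1.4) — modest library-depth
  variation;
- gene log2FCs ~ N(0, 0.15): an "evenly distributed" background;
- TE log2FCs ~ N(delta_c, te_effect_sd) per class, default
  delta_c = 0.2 for all four classes with sd 0.1 — many small positive
  effects, the regime where class tests detect what per-TE tests
  cannot;
- ages uniform on 25–102 years (an adult brain-bank span), sex and a
  lognormal post-mortem interval (median ~10 h) optionally confounded
  with age through a Gaussian copula, so covariate correction has a
  real confound to remove;
- an optional TE-specific age slope in log2 units/year, centered on the
  age midpoint, applied independently of group so group-effect recovery
  stays unbiased.

Defaults are declared study conditions, not fits to any dataset.  All
randomness flows from a single integer seed through PCG64; fixed seed
means bit-identical output.  Test sample sizes are chosen for the
properties they probe: n = 10/group mirrors a matched old/young
comparison, n = 20–50/group the cohort-scale calibration and recovery
checks, and the broad-shift regime uses 500 TEs over a 10,000-gene
background with delta = 0.2.

Not emulated: read sequences, positions and splicing; per-copy TE
structure (one feature per TE name); outlier samples and batch
structure; count correlation between features.  Passing tests therefore
establish the statistical machinery's correctness and calibration under
the stated model, not robustness to artifacts outside it.

## 6. Pipeline determinism

`run_contrast` / `run_overlap_study` derive one substream seed per
stage from the root seed (SHA-256 of `seed:stage`), write every
artifact as TSV/JSON with 17-significant-digit floats, and record a
manifest of SHA-256 content hashes with no timestamps.  Two runs with
the same config and seed are bit-identical, which is also how the
acceptance suite audits determinism.
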