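# Methods

This note documents the statistical machinery, the synthetic-data design
and the numerical choices behind `fibromir`.

## Fibrotic score and stratification

The score averages the relative expression of COL1A1, FN1 and ACTA2, each
divided by its maximum over the cohort, giving FS ∈ (0, 1]. Properties
that follow directly and are enforced by tests: invariance to rescaling
any single marker across the whole cohort; strict monotonicity in each
marker of the focal sample; FS = 1 exactly when one sample attains every
cohort maximum. The reference cohort for the per-marker maxima is the
whole input panel by default; callers who want a DMD-only reference simply
pass a restricted panel.

Stratification assigns High to FS strictly greater than the threshold
(default 0.25) and Low otherwise, so a boundary score is Low. The
threshold is a dimensionless fraction of the cohort-maximum composite.

miRNA–score correlation is Pearson (not rank-based), computed on
log2(normalised count + 1) across all cohort samples, controls included.
Zero-variance miRNAs get r = NaN and are excluded from ranking. The
signature is the k = 25 highest-r miRNAs among those with r > 0.5; ties
at the k-th rank break lexicographically by miRNA identifier so the
selection is deterministic.

## Differential expression

Normalisation is median-of-ratios: factor_j is the median over miRNAs
(restricted to rows with a positive geometric mean) of count_ij divided by
the row geometric mean. Factors are defined only up to this pseudo-
reference, so invariance properties are stated on factor ratios.

Dispersion uses the NB2 parameterisation var = μ + αμ². Two estimators
are available:

* `estimate_dispersion` — per-miRNA method of moments,
  α_i = max(floor, (pooled within-group variance − mean)/mean²), with a
  floor of 1e-8; pooling is across groups with the sample (n−1)
  denominator.
* `dispersion_trend` (model default) — the raw moment estimates are
  regressed on the parametric trend α(μ) = a₀ + a₁/μ with a Huber robust
  linear model, and each miRNA receives its fitted value. With n ≈ 3–5
  replicates per group the per-miRNA estimate is noisy enough to make an
  exact test anticonservative (measured type-I ≈ 0.065 at nominal 0.05,
  5 vs 5); fit-based sharing restores calibration (measured 0.040–0.052
  across depths, dispersions and seeds). This mirrors the fit-only
  dispersion sharing recommended for few-replicate designs in count-based
  differential expression.

The test conditions on the total of the two group sums of normalised
counts (rounded half-to-even, since the enumeration needs integers).
A sum of n iid NB(μ, α) variables is exactly NB(nμ, α/n), so each group
sum is NB with mean n_g·μ₀ and dispersion α/n_g under the pooled-mean
null μ₀ = K/(n_A+n_B). The two-sided p-value sums, over all splits
(a, K−a), the joint probabilities not exceeding the observed split's
probability (with a 1e-7 relative tolerance so floating-point-equal
probabilities count as tied), divided by the total. K = 0 gives p = 1 by
convention. Probabilities are computed on the log scale and shifted by
the maximum before exponentiation for stability; the α → 0 limit is
handled as Poisson, where the conditional law is binomial.

log2 fold changes are log2((mean_B + ½)/(mean_A + ½)); the ½ pseudo-mean
is a conventional continuity correction that keeps all-zero rows at
log2FC = 0. Multiple testing uses Benjamini–Hochberg (via statsmodels).

## Clustering and archetypes

Distances are d = 1 − r (Pearson), in [0, 2]; linkage is complete
(inter-cluster distance = maximum pairwise distance), computed with scipy
and verified in tests against an exhaustive brute-force agglomeration for
n ≤ 6. miRNA profiles are Z-scored per row (sample sd, n−1; constant rows
dropped and reported) before miRNA clustering; samples are clustered on
their log2 profiles directly. Dendrogram "separation" of fibrosis strata
is quantified as the Rand index of cut(k = 2) labels against the planted
strata, since visual separation is not testable.

Archetype classification is rule-based rather than read off a dendrogram
cut, because the four progenitor profiles are defined by their
FAP/MP × TGFβ1 behaviour: with cell enrichment e = log2(mean FAP / mean
MP) (pseudo-count ½) and TGFβ1 response l measured in the enriched cell
type, the classes are C1 (e ≤ −e_min, l ≤ −l_min), C2 (e ≤ −e_min,
|l| < l_min), C3 (e ≥ e_min, l ≤ −l_min), C4 (e ≥ e_min, l ≥ l_min),
otherwise unclassified; defaults e_min = l_min = 1 log2 unit, with an
expression floor (default 5 normalised counts on the maximum condition
mean) below which nothing is classified. Every miRNA receives exactly one
class.

## Seed scanning

The seed is miRNA positions 2–8. Site classes on the UTR sense strand are
8mer (reverse complement of positions 2–8 followed by A), 7mer-m8 (the
same without the A), 7mer-A1 (reverse complement of 2–7 followed by A)
and 6mer (reverse complement of 2–7). Matching is exact Watson–Crick
only — no wobble pairs, no context scores. U and T are interchangeable on
input. Coordinates are 1-based inclusive, matching the convention in
which validated sites are printed (e.g. "position 1887–1893"); a BED
export converts to 0-based half-open explicitly. Overlapping candidate
sites at one locus are resolved greedily, strongest class first
(8mer > 7mer-m8 > 7mer-A1 > 6mer), then leftmost.

## Synthetic-data design

The generators emulate the *statistical structure* of a fibrosis
miRNome study, not its biology; none of the distributional laws below is
reported by any real dataset, and all are stand-ins chosen once for
plausibility.

**Cohort.** Default 3 controls + 8 dystrophic samples, 600 miRNAs,
library depth 1e5, NB dispersion 0.05. A latent fibrosis level f per
sample drives everything: controls draw f ~ U(0, 0.2); cases split into
a fixed-proportion Low subset (round(3/8·n) samples, f ~ U(0, 0.2)) and
a High remainder (f ~ U(0.4, 1)), so the canonical 8-case cohort is
exactly 3 Low / 5 High by construction. Counts are NB with
log2 mean = baseline + β·f·c, where c = +1 for the 25 planted fibromiRs,
−1 for the 8 planted myomiRs, 0 for background; β defaults to 2 log2
units per unit fibrosis. Baseline abundances are heavy-tailed
(lognormal, σ = 1.5), as in real small-RNA libraries.

Marker genes respond to f through a saturating, switch-like activation:
log Exp = γ·σ(κ(f − f₀)) + ε, with gain γ = 3, steepness κ = 20,
midpoint f₀ = 0.3 and lognormal noise sd 0.2. A Hill-type response is the
standard picture for fibrotic marker induction, and it makes the
0.25 score threshold fall reliably between the Low (f ≤ 0.2) and High
(f ≥ 0.4) latent bands regardless of where the cohort maximum lands — a
purely exponential response cannot achieve that under cohort-maximum
normalisation, because a cohort whose strongest sample is only mildly
fibrotic compresses all score gaps.

**2×2 design.** Four conditions (FAP/MP × ±TGFβ1), 3 replicates each,
dispersion 0.02, depth 1e5. Planted classes (15 miRNAs each over a
140-miRNA background) place ±enrichment_lfc/2 (default 4/2 = ±2 log2) on
the cell axis and a response_lfc (default 2 log2) TGFβ1 response in the
enriched cell type, exactly matching the archetype rule table so recovery
is a well-posed question.

**Ct tables.** Ct_target = Ct_ref + baseline ΔCt − true_log2_fold·
1(treated) + N(0, sd), reference Ct fixed at 20, baseline ΔCt 2. The
noiseless table inverts exactly to 2^true_log2_fold under ΔΔCt.

**UTRs.** Background bases are uniform A/C/G/T; planted windows carry the
exact site sequence for their class, and a rejection loop re-samples any
background position participating in an accidental or class-upgraded
match until a scan reports exactly the planted sites (bounded iterations,
error on failure). Planted sites must be non-overlapping and in bounds.

What these generators do **not** emulate: sequencing depth variation
tied to biology, miRNA–miRNA correlation structure, isomiR ambiguity,
batch effects, GC or length bias, and any real genomic sequence
composition. Passing recovery tests therefore demonstrates that the
machinery is correct under its stated model, not that the pipeline would
achieve the same recall on real biopsies.

## Problem sizes and determinism

Test and acceptance runs use the default desk-scale sizes above (600–5000
miRNAs, 10–24 samples, 50–100 replicates per Monte-Carlo estimate,
300–1000 random UTRs), chosen so the whole suite completes in well under
a minute per component. Every generator takes an explicit seed and builds
its own `numpy.random.Generator`; there is no global RNG state, and
identical parameters + seed give bit-identical outputs, which the tests
assert.

## Known limitations

* The exact test assumes a common dispersion per miRNA across groups and
  models group sums, not per-sample likelihoods; it is the classical
  small-sample exact approach, not a GLM with shrinkage.
* The dispersion trend is parametric (a₀ + a₁/μ); strongly bimodal
  mean–dispersion relationships would be better served by local
  regression.
* The comparative-CT module fixes PCR efficiency at 2 (100%); no
  standard-curve correction is implemented.
* The seed scanner deliberately ignores non-canonical (wobble, bulged,
  3′-compensatory) sites and thermodynamic context.
* qPCR "relative expression" can optionally be rescaled to a calibrator
  sample by dividing by that sample's 2^−ΔCt; the default reports
  2^−ΔCt directly.
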