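# Methods

## The count model

Per-peak open-fragment counts are modelled as negative binomial with mean μ
and dispersion α under the parameterisation **variance = μ + αμ²** (α → 0
recovers Poisson).  This convention is stated explicitly because "dispersion"
is used for both α and 1/α in the literature; everywhere in this package α
multiplies μ².

Sequencing depth enters through **median-of-ratios size factors**: for the
regions positive in every sample, each sample's factor is the median ratio
of its counts to the per-region geometric mean.  Factors are defined only up
to a common scale — multiplying one sample's counts by *c* multiplies its
factor *relative to every other sample* by exactly *c*.

**Dispersion** is estimated per region by method of moments on normalised
counts within replicate groups, `α̂ = (s² − m̄)/m̄²` pooled over groups with
weights equal to the group degrees of freedom, clipped at zero, then
averaged with a parametric mean–dispersion trend `a₀ + a₁/μ` (least squares
over regions) using weight `df / (df + prior_df)` on the per-region value
(`prior_df` = 10).  A floor of 1e-8 keeps the GLM weights finite.  With
2 × 3 replicates the per-region weight is 4/14 ≈ 0.29, i.e. estimates are
pulled strongly toward the trend — at these replicate numbers individual
moment estimates are far too noisy to stand alone.

**Fitting.**  The NB GLM (log link) is maximised by IRLS, tolerance 1e-8 on
the coefficient step, at most 100 iterations, batched across regions that
share a design matrix.  The quasi-likelihood score is evaluated on
size-factor-normalised counts rather than via offsets: for a group of
replicates the fitted group mean is then the plain average of normalised
counts, independent of α, which makes fold-changes *exactly* invariant under
per-sample depth rescaling (an offset formulation reweights samples by
depth, so a rescaled replicate would shift the estimate at the third
decimal).  The cost is a mildly misspecified Poisson term in the weights
when size factors sit far from 1; at the factor ranges of replicated ATAC
designs the effect on standard errors is a few percent.  Coefficients are
reported in log2 units; Wald z-tests use the normal reference, and
Benjamini–Hochberg adjustment is applied **within each contrast** (the four
contrasts correspond to independently run analyses).

No fold-change shrinkage is applied: classification thresholds raw log2
fold-changes at |log2FC| > 1, and shrinkage would bias calls near that
boundary.

**Calibration.**  On a null simulation (5000 regions, mean 200, α = 0.05,
n = 3 per group) the Wald test's p < 0.05 rate is ≈ 0.05 and the tail is
calibrated down to p ≈ 0.001, which is what lets BH control the FDR.
FDR-control checks use direction-balanced alternatives: ratio-based
normalisation assumes most regions are unchanged *on average*, and a
strongly one-sided alternative fraction biases every null fold-change
through the size factors — a property of median-of-ratios normalisation
generally, not of this engine.

**Contrasts.**  The four classification contrasts are computed as
stratified pairwise two-group tests (T_wt and T_mut within genotype, G_12
and G_72 within timepoint) rather than extracted from a single interaction
fit.  Both are defensible readings of a paired-test scheme; the stratified
form keeps each test's dispersion local to the samples it compares and
makes the four tests symmetric.  The full-factorial design (including the
interaction coefficient) remains available through `DesignSpec` and
`fit_nb_glm`.

## The ten-class truth table

Calls per contrast: `up` iff padj < α (strict) and log2FC > 1 (strict);
`down` symmetric; otherwise `ns`.  Boundary values (padj exactly α, |log2FC|
exactly 1) are deliberately ns — a region must clear the threshold, not
touch it.

The ordered predicates (first match wins; genotype contrasts are
mutant-over-wild-type, so `down` = higher in wild type):

| order | class | predicate | meaning |
|---|---|---|---|
| 1 | 6 | G_12 down ∧ G_72 down | constitutively wt-biased |
| 2 | 7 | G_12 up ∧ G_72 up | constitutively mut-biased |
| 3 | 4 | G_12 down ∧ T_wt down | wt-biased early, lost late |
| 4 | 5 | G_12 up ∧ T_mut down | mut-biased early, lost late |
| 5 | 2 | G_12 ns ∧ T_wt down ∧ G_72 up | lost in wild type only |
| 6 | 3 | G_12 ns ∧ T_mut down ∧ G_72 down | lost in mutant only |
| 7 | 9 | T_wt up ∧ G_72 down | late wt-biased gain |
| 8 | 10 | T_mut up ∧ G_72 up | late mut-biased gain |
| 9 | 1 | T_wt down ∧ T_mut down ∧ G_12 ns ∧ G_72 ns | uniform loss |
| 10 | 8 | T_wt up ∧ T_mut up ∧ G_12 ns ∧ G_72 ns | uniform gain |

Patterning-dependent predicates precede the uniform ones because they are
more specific.  Regions with no significant test are `nondynamic`; regions
with exactly one, or with a significant pattern matching no predicate, are
`ambiguous` — classes require *paired* evidence.  The table lives in a
single module constant (`classify.CLASS_PREDICATES`) so the mapping can be
revised without touching the engine, and an exhaustive enumeration test
asserts the mapping is total and single-valued on all 3⁴ = 81 patterns.

K-means over scaled condition profiles is provided for exploration only and
is made deterministic (seeded k-means++, single init, Lloyd iterations);
the predicate classifier is the reproducible deliverable.  The PCA
transform is log2(normalised count + 1) over non-nondynamic regions,
centred per region; other variance-stabilising transforms would be equally
defensible.

## The synthetic generator

The generator's defaults encode the study design it emulates: 2 genotypes ×
2 timepoints × 3 single-embryo replicates, a baseline of 200 expected open
fragments per peak per sample, dispersion α = 0.05, planted effects of
|log2FC| = 2, sub-nucleosomal fragments of 20–100 bp and mono-nucleosomal
fragments of 150–250 bp, dyad scatter sd 30 bp, and a marker SNP read at
depth 60 (within the observed 47–104 range) with 1% base error.

Per-class condition means are derived from a per-label offset table that
reproduces the contrast truth table exactly (an arithmetic identity checked
for all 12 labels).  One consequence of a 2×2 design is the **cycle
identity** `T_mut − T_wt = G_72 − G_12`; a pattern with exactly one nonzero
contrast is therefore unrealisable from condition means.  The planted
*ambiguous* class uses contrasts (−1, −0.4, −0.3, +0.3) × planted_lfc: at
the default planted_lfc = 2 only T_wt clears the |log2FC| > 1 call
threshold, so the expected outcome is a single significant test.

`open_frac` = 0.6 (the open share of the fragment-length mixture) is a free
parameter of the generator — the empirical library mixture is not published.
Motifs are planted one per peak, either within ±50 bp of the peak's dyad
("occluded", default fraction 0.5) or 110–180 bp into linker DNA.
Contaminant fragments (duplicates, MAPQ < 10, improper pairs) are opt-in
via `contaminant_frac` to exercise the filters.

What the generator does **not** emulate: mappability and sequence-dependent
Tn5 bias, peak-shape structure, overlapping peaks, spatially varying
dispersion, correlated replicates, and sub-peak accessibility gradients.
Passing tests therefore demonstrate the correctness and calibration of the
inference machinery under the stated statistical model, not robustness to
every artefact of real libraries.

## Nucleosome and motif analysis

Dyads are modelled from the midpoints of fragments longer than 100 bp:
midpoints are histogrammed at 1 bp, smoothed with a Gaussian kernel
(σ = 20 bp), and local maxima are accepted greedily by descending density
with a 147 bp exclusion zone (one nucleosome footprint).  Dyad support
counts midpoints within ±73 bp; dyads with support < 5 are dropped.  This
is a deliberate simplification of fragment-distribution nucleosome models;
smoothing and thresholds are exposed as parameters.  Two true nucleosomes
closer than the exclusion zone are merged — at 100 bp spacing one dyad is
reported, by construction.

PWM probabilities are `(count + 0.25) / (column sum + 1)`; scores are
summed log2-odds against a uniform background, normalised as
`(score − min) / (max − min)`, and a hit is a window with relative score
≥ 0.8 (the "80% match" convention; max-fraction normalisation would be the
alternative reading).  Both strands are scanned; a window matching on both
keeps the higher score, ties to plus.  Windows containing N are skipped.

The footprint boundary at 73 bp is inclusive; motif position is the motif
midpoint.  The permutation test on a difference in group means draws
"proportional" null groups (the observed sizes) from the pooled values;
exact enumeration over all C(n, |A|) partitions activates automatically
when that count is ≤ 1e5 (p = exceedance/total), otherwise the Monte-Carlo
add-one estimator `(1 + hits)/(1 + n_perm)` is used, which is never zero.
Default n_perm is 1e5; larger settings are a flag away.

## Genotyping

The observed allele-fraction modes (~0%, ~50%, ~100%) are mapped to calls
with guard bands: ≤ 0.15 hom_ref, 0.30–0.70 het, ≥ 0.85 hom_alt, minimum
depth 20, everything else `nocall`.  The bands were chosen so that binomial
noise at depth 47 (the lower end of the range markers are recovered at)
misclassifies < 1% of embryos — verifiable from the binomial tail — while
indeterminate fractions are never forced into a call.

## Annotation

The promoter window is [TSS − 500, TSS + 150) on the gene's strand — a
package convention, as "promoter region" has no universal numeric
definition.  Peaks are assigned by midpoint with precedence
promoter > exon > intron > intergenic.  CRMs inherit the peak with maximal
overlap (ties: larger peak, then leftmost); a CRM's "significant temporal
change" means its peak's T_wt outcome is not ns.  Term enrichment is
one-sided (greater) hypergeometric per term with ≥ 3 carriers in the
universe, BH-adjusted across tested terms — enrichment, not depletion, is
the question asked of these annotations.  Gene models are read from BED12.

## Pipeline and reproducibility

Configs are flat `key = value` text with sections; validation reports all
errors at once, a missing seed defaults to 0 with a warning.  Every
stochastic stage receives a child seed derived from the root seed through a
hash, so no stage's randomness depends on whether another stage ran.  The
run manifest records every output with a SHA-256 hash; identical config and
seed reproduce identical hashes.

## Problem sizes

The test suite and the acceptance script run the classifier study at 100
peaks per label (1200 regions), engine calibration at 5000 regions, dyad
recovery at 100 dyads × 200 fragments, displacement at 120 motifs,
occlusion at 400 motifs, permutation-null calibration at 1000 trials ×
n_perm 1e4, and genotyping at 3000 pileups per genotype — sizes at which
every Monte-Carlo band in the tests is comfortably wider than the
simulation error, while the full suite completes in about a minute.

## Known limitations

- Dispersion shrinkage is moment-plus-trend, not an empirical-Bayes
  posterior; no Cox–Reid adjustment, independent filtering or outlier
  replacement.  Numerical identity with reference count-model packages is
  not claimed (agreement is verified by cross-checking fold-changes against
  one on shared simulations).
- The Wald normal reference is slightly liberal for very low counts
  (baseMean ≲ 20 at n = 3); the study conditions sit well above that.
- Dyad calling reports point positions, not occupancy posteriors; closely
  spaced alternative nucleosome configurations are merged.
- Feature assignment uses peak midpoints; peaks straddling a feature
  boundary carry only their midpoint's label.
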