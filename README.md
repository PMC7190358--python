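# chromdyn

Chromatin accessibility dynamics from single-embryo ATAC-seq.

During early *Drosophila* embryogenesis — between zygotic genome activation
(nuclear cycle 14) and the onset of gastrulation — chromatin accessibility
changes both uniformly across the embryo and downstream of the maternal
patterning systems. `chromdyn` implements the analysis stack for dissecting
such dynamics from fragment-level ATAC data in a 2 genotype × 2 timepoint ×
replicates design:

- **Fragment processing** — filter properly paired, non-duplicate fragments
  with MAPQ ≥ 10; partition by mapped length at 100 bp into "open"
  (nucleosome-free) and nucleosome-associated classes; count open fragments
  over peaks; CPM coverage tracks; scaled per-condition accessibility
  profiles (each region's four condition means normalised to sum to 1).
- **Differential accessibility** — a negative-binomial GLM engine:
  median-of-ratios size factors, method-of-moments dispersion `α`
  (variance = μ + αμ²) shrunk toward a parametric mean–dispersion trend,
  IRLS fits, Wald contrasts, Benjamini–Hochberg adjustment.  The four
  classification contrasts are stratified pairwise tests: `T_wt`, `T_mut`
  (late vs early within genotype) and `G_12`, `G_72` (mutant vs wild type
  within timepoint).
- **Dynamics classification** — each region's four contrast outcomes
  (up/down/ns at padj < 0.01 and |log2FC| > 1) are matched against an
  ordered truth table of ten dynamic classes (uniform loss/gain,
  genotype-dependent early or late loss/gain, constitutive bias); regions
  significant in only one test are *ambiguous*, all-ns regions
  *nondynamic*.  PCA, seeded k-means exploration and control-region
  sampling included.
- **Embryo genotyping** — post-hoc zygotic genotype calls from marker-SNP
  allele fractions (~0% / ~50% / ~100% of base calls).
- **Nucleosome & motif analysis** — nucleosome dyads modelled from
  large-fragment midpoints (Gaussian-smoothed density, greedy maxima with a
  147 bp exclusion zone); PWM scanning at ≥ 80% of the maximal log-odds
  score; motif-to-dyad distances, the footprint fraction (motifs within
  73 bp of a dyad, inside the nucleosome wrap), paired displacement shifts,
  and a one-tailed permutation test on group means with automatic exact
  enumeration.
- **Annotation** — peak-set overlap bookkeeping, CRM (enhancer)
  accessibility scoring by best-overlapping peak, promoter/exon/intron/
  intergenic assignment, hypergeometric controlled-vocabulary term
  enrichment.
- **Synthetic data with planted truth** — every stage is exercised against
  a generator that plants the class structure (per-condition NB means
  consistent with each class's contrast pattern), a bimodal fragment-length
  mixture with dyad-centred large fragments, consensus motif instances
  (occluded or in linker DNA) and binomial SNP pileups.

## Worked example

```python
import chromdyn as cd

cfg = cd.SimulationConfig(n_peaks_per_class=20, n_chroms=2,
                          chrom_length=200_000, seed=0)
truth = cd.build_truth(cfg)
matrix = cd.simulate_count_matrix(truth)
contrasts = cd.run_four_contrasts(matrix)
labels, counts = cd.classify_all(contrasts)
```

Running `python examples/01_simulate_and_classify.py` (the same analysis)
prints:

```
regions per called class:
label
1             19
10            20
...
ambiguous     26
nondynamic    20

exact label recovery: 95.0% of 240 regions
PCA over dynamic regions: PC1 39%, PC2 36% of variance
```

240 regions were planted, 20 per label; 95% receive exactly their planted
class.  The residual errors are borderline fold-changes near the
|log2FC| > 1 threshold, which mostly migrate into the *ambiguous* bin —
the classifier demands **paired** significant tests before assigning a
class, so single-test evidence never fabricates a dynamic category.

The other scripts in `examples/` walk through genotyping
(`02`, ≥ 99.9% recovery at depths 47–104), the pioneer-factor displacement
signature (`03`, footprint fraction 1.00 → 0.00 with a 79.3 bp mean shift
against a planted 80 bp displacement), motif scanning (`04`), CRM scoring
and term enrichment (`05`) and the reproducible end-to-end pipeline (`06`).

A thin CLI mirrors the stages: `chromdyn simulate|count|genotype|test|
classify|nucmotif|run` (see `chromdyn --help`).

## Layout

```
src/chromdyn/      simulate, fragments, diffacc, classify, genotyping,
                   nucmotif, annotate, pipeline, cli, io, intervals
tests/             pytest suite (unit, property and end-to-end checks)
examples/          one narrative script per capability
docs/methods.md    models, parameters, numerical choices, limitations
```
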