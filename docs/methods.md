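# Methods

## Generative model of the synthetic cohort

The generator emulates a compartment-resolved DIA proteomics cohort at the
protein level.  For protein *p* and sample *s* (patient *i*, stage *t*,
compartment *c*) the log2 intensity is

```
x[p,s] = mu_p + beta_c + gamma(t, c, p) + u_i + eps,
```

with `mu_p ~ N(baseline_mean, baseline_sd²)` per-protein baselines,
`beta_c` a compartment shift (default 0), `gamma` the planted
stage × compartment effects, `u_i ~ N(0, patient_sd²)` a patient effect
shared by every tissue of one patient (so paired analyses see correlated
samples and patient effects cancel in balanced group means), and
`eps ~ N(0, (noise_sd · stage_scale)²)` residual noise.  Tumor stages get
inflated noise (`stage_scale` 1.4 for adenoma, 1.6 for carcinoma, 1.0 for
adjacent), which reproduces the qualitative pattern that within-group
Spearman correlations are highest in adjacent tissue.

Detection is missing-not-at-random: a cell is observed with probability
`1 / (1 + exp(-k (x - m0 + d_c)))`, with steepness `k = 1` per log2 unit,
midpoint `m0 = baseline_mean − 2`, and a compartment depth offset
`d_stroma = −2` (0 for epithelium).  With the defaults
(`baseline_mean = 20`, `baseline_sd = 2`, `patient_sd = 0.5`,
`noise_sd = 0.3`, 5,500 simulated proteins) this yields roughly 4,100
identified proteins per epithelium sample and 2,750 per stroma sample —
the depth regime of LCM stroma/epithelium DIA data.  Stroma-unique marker
proteins are censored to missing in every non-stroma sample.  The matrix
is exported on the linear scale (2^x) with explicit missing cells, because
the pipeline's first step is its own log transform.

The **default cohort** (22 patients, all six stage × compartment tissues)
plants the headline structure: one stromal tumor-response set receives the
*same* effect (±3 log2) in adenoma stroma and carcinoma stroma, while
epithelium effect sets are stage-specific and disjoint; a further
"stromal signature" set is shifted +2 in stroma at every stage (it
separates compartments but cancels in stroma stage contrasts).  Planted
set sizes scale linearly with `n_proteins` (reference sizes 250/120/250/
150/120 at 5,500).  Effect magnitudes sit at ±3 log2 — clearly beyond the
four-fold calling threshold — so that recovery failures indicate pipeline
defects rather than borderline effects; an effect of exactly ±2 would by
construction be called only about half the time under the strict
|log2FC| > 2 cut.

What the generator does **not** emulate: peptide-level quantification and
roll-up, shared/razor peptides, retention-time or batch effects,
correlated co-regulation beyond the planted blocks, and compositional
coupling between proteins.  Passing tests therefore demonstrate that the
statistical machinery recovers planted truth under realistic depth,
missingness and noise — not that any biological conclusion transfers to a
particular real cohort.

## Preprocessing

* Log base 2 throughout, so "four-fold" is exactly |log2FC| > 2.
* Normalization equalizes sample medians of observed values to the global
  median of sample medians; it is idempotent and leaves within-sample
  differences (hence missingness and ranks) unchanged.  Compartments are
  normalized separately by default (stroma and epithelium have different
  depth); cross-compartment contrasts use a jointly normalized table.
* The missing-frequency filter is strict (`missing fraction < threshold`)
  and applied within the analysis group, per compartment by default.
* Imputation is an EM loop: initialize missing cells at protein means,
  then iterate {row-center → rank-k SVD reconstruction → update missing
  cells} until the relative change of the imputed cells falls below `tol`.
  Only originally-missing cells are ever written; observed cells are
  returned bit-identical.  Default `n_components = 5`, `tol = 1e-6`.  On
  exactly low-rank matrices the loop converges to machine precision; on
  noisy full-rank data the relative change plateaus near 1e-5 — the
  orchestrated pipeline therefore runs with `tol = 1e-4`, and
  non-convergence sets a flag and warns rather than raising.
  Differential testing operates on observed values only (Welch handles
  unequal group sizes); imputed tables feed PCA and module clustering,
  which need complete matrices.

## Differential abundance

Per protein with at least `min_obs = 3` observed values in each group:
log2FC is the difference of group means, the test is Welch's two-sample t
(the effect direction and BH control carry the analysis; the exact test
statistic is a package choice), and q-values are Benjamini–Hochberg
step-up over the tested proteins.  BH was chosen over Storey's q-value
because no null-proportion machinery is involved anywhere downstream.
Proteins failing `min_obs` are reported as `untested`, never dropped.
Thresholds are strict for the group regimes ("greater than a four-fold
change": |log2FC| > 2 with q < 0.05; compartment contrasts |log2FC| > 1)
and inclusive for single-patient paired tissues (|log2 ratio| ≥ 1),
mirroring the wording difference between the two rules.

Diagonal comparability of two contrasts is quantified (the assessment is
otherwise only visual) by Lin's concordance correlation with
n-denominator moments plus the RMS perpendicular distance to the identity
line, over proteins with both ratios defined.

Module classification is a deliberately simplified stand-in for weighted
co-expression network analysis: distance 1 − Pearson between protein
profiles, average-linkage hierarchical clustering, static cut at k = 3
(configurable), eigenprotein = first principal component of the
standardized member profiles (sign-aligned with the module mean), module
label = trait with the largest |correlation| to the eigenprotein.  No
topological overlap, soft thresholding or dynamic tree cut.

## Rank concordance

Bins are contiguous groups of the descending-mean ranking; ties break by
protein ID and the remainder of n/k goes to the earliest (highest) bins,
so bin sizes differ by at most one and the assignment is deterministic
and invariant under any strictly increasing transform of the means.
Means use normalized log2 values over observed entries only (minimum 3
observations).  "Staying in the same bin" is exact-diagonal by default;
a ±1-bin tolerance mode exists because verbal descriptions of rank
similarity are loose.  No statistical test is attached — the table is
descriptive.

## Biomarker filter

The four criteria are audited independently and the panel is their
conjunction: (1) never observed in any epithelium sample of any stage;
(2) observed in strictly more than `min_patient_frac = 0.8` of patients
contributing stroma samples; (3) `up` status in the tumor-stroma vs
adjacent-stroma contrast of adenoma and/or carcinoma; (4) median-abundance
rank within the top `max_rank_frac = 0.8` of stroma proteins and at least
`min_peptides = 2` supporting peptides.  Two readings are deliberately
exposed as flags: the rank window can count from the top (default) or
exclude the complementary bottom quantile, and the peptide gate can be
inclusive (≥, default) or strict (>).  Note that on synthetic cohorts the
planted effect sets are disjoint from the stroma-unique set, so criteria
(1) and (3) cannot both hold and the default simulated panel is empty by
construction; the filter's correctness is demonstrated on an engineered
fixture in which each criterion is violated by exactly one candidate.

## Signatures

The single-sample enrichment score ranks observed proteins by descending
abundance and accumulates in-set increments proportional to rank^α
(α = 0.25, the top rank valued N) against uniform out-of-set decrements;
the score is the mean of the running sum over positions.  Dividing by N
makes samples with different identification depth comparable — without
it, deeper samples carry a systematically larger integrated deviation.
The score depends only on ranks, so it is invariant under any monotone
transform of abundances; a set occupying the top ranks is the maximum
over all placements.  A set covering every observed protein has no
out-of-set mass and scores 0 by convention.

Fraction deconvolution solves non-negative least squares
`min ‖S f − x‖, f ≥ 0` on linear-scale abundances (mixing is additive in
intensity), restricted to signature proteins observed in the sample and
requiring at least twice as many of them as cell types.  Each protein row
of S (and the matching entry of x) is scaled by the row's standard
deviation across cell types so no single abundant protein dominates the
fit; fractions are renormalized to sum to one (relative, not absolute,
abundances).  NNLS replaces the support-vector regression of hosted
deconvolution services because it is the standard identifiable-case
solver and fully testable; the recovery simulation (mean absolute
fraction error < 0.05 at 10% multiplicative noise, nine cell types) is
its validation.  The bundled stromal signature GMT and ligand-receptor
pair TSV are small editable placeholders — signatures are inputs, not
code.

## Pipeline and reproducibility

`run_pipeline` executes preprocess → QC → DEP (all contrasts) →
concordance → comparability → modules → biomarkers → scoring →
deconvolution → ligand-receptor screen, writing TSV tables, a log with
every resolved threshold, and a schema-versioned JSON summary.  All
randomness flows from the single root seed (stage-local generators derive
from it by fixed offsets), and identical config + seed reproduces the
summary byte for byte.  A stage failure aborts with the stage name in the
log; genuinely degenerate inputs (e.g. too few consensus DEPs for module
clustering) are recorded as skips instead.

## Problem sizes and numerical notes

The validation suite uses: exhaustive BH grids (step 0.05 up to length 4,
step 0.1 for lengths 5–6, ~23,000 vectors) plus 1,000 random vectors at
1e-12 agreement; 20 recovery cohorts of 3,000 proteins × 15 paired
samples per group; 20 default cohorts of 5,500 proteins × 132 samples for
the headline structure; 6,000-protein rankings for concordance
calibration; 200 mixtures of a 180-protein, 9-cell-type signature; and a
60 × 20 rank-1 matrix with 10% deletions for imputation.  These sizes
were chosen to match the scale of the emulated study while keeping the
full suite fast enough to run habitually.  Ties are broken
lexicographically everywhere a ranking is materialized; PCA component
signs are fixed by the largest-magnitude loading; Welch degrees of
freedom use the Welch–Satterthwaite approximation with zero-variance
groups handled as exact comparisons.

## Known limitations

Protein-level only (no peptide roll-up or identification FDR); the Welch
test ignores the patient pairing (patient effects cancel in means but
inflate variance estimates slightly, costing power, not validity);
module classification is a coarse stand-in for network analysis;
enrichment scores are not calibrated against a null distribution (group
comparisons use rank-sum tests instead); deconvolution assumes the
reference profiles span the mixture and reports relative fractions only.
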