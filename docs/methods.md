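# Methods

`ecglf` implements an unsupervised ECG feature-extraction and discovery
pipeline: a convolutional β-VAE learns a low-dimensional latent
representation of 8-lead median heartbeats, and the latent factors (LFs)
are carried through quantitative-trait association, rare-variant burden
testing and phenome-wide prediction comparison. Every stage is testable on
synthetic data with known ground truth, generated by the package itself.

## Median beats and preprocessing

A median beat is the per-sample median of R-peak-aligned heartbeat windows
from a resting 10-s ECG, one trace per lead. Eight leads are used — I, II
and V1–V6 — because lead III and the augmented limb leads are linear
combinations of I and II and add no information. Processing conventions:

* **Window**: 0.8 s at 500 Hz (400 samples). Longer beats are cropped
  symmetrically about the R peak; shorter ones are zero-padded on both
  ends, the extra zero of an odd deficit going at the end (arbitrary but
  fixed).
* **Alignment**: each record is circularly shifted by the lag maximising
  cross-correlation between its summed-absolute-lead trace and that of a
  reference beat; ties break toward the smallest absolute lag. Circular
  shifts preserve length; zero-padding at the edges would distort wave
  tails. The choice of alignment channel is a package convention — any
  single fixed channel works for clean signals.
* **Voltage filter**: a record is excluded when any sample is strictly
  below −8 mV or strictly above +8 mV (pacing spikes, gross noise).
  Samples at exactly ±8 mV are retained; the bounds are strict.
* **R-peak detection**: a derivative-gated threshold detector on lead II
  (fall-back: the largest-amplitude lead). This is adequate for clean and
  synthetic signals; clinical-grade vectorcardiographic median-beat
  construction is out of scope.
* **Split**: subjects (not records) are randomly assigned
  train/validation/test at 90/5/5% by largest-remainder rounding, so all
  records of one subject share a partition.

Running standardise → align → filter twice equals running it once
(idempotence), which the test suite asserts.

## The β-VAE

The encoder stacks stride-2 1-D convolutions with increasing filter counts
and decreasing kernel sizes toward the latent space (default
16→32→64→128 filters, kernels 15→9→5→3); the decoder mirrors it with
transposed convolutions. The latent space is capped at 30 dimensions; the
model typically leaves some collapsed, and a dimension is called *active*
when the across-subject variance of its posterior mean exceeds a threshold
(default 0.01).

The training objective is

```
L = SMAPE(x, x̂) + β · KL(q(z|x) ‖ N(0, I))
```

* **SMAPE** (symmetric mean absolute percentage error, in percent,
  bounded [0, 200]): `100 · mean |x−x̂| / ((|x|+|x̂|)/2 + ε)` with
  ε = 10⁻⁴ mV guarding 0/0 at zero-padded samples. The mean runs over
  samples, leads and batch.
* **KL**: `Σ_d −½(1 + logσ²_d − μ_d² − σ²_d)`, summed over latent
  dimensions and averaged over the batch.
* **β** trades reconstruction fidelity against disentanglement and is
  selected over the grid {0.1, 0.25, 0.5, 1, 3, 5, 10} by the mean
  validation reconstruction correlation, ties breaking toward the smaller
  β (a more regularised model must be strictly better to be preferred).
  The default is β = 0.25.

The network is implemented directly in NumPy (float32) with explicit
backpropagation and Adam (lr 10⁻³, no scheduler). All randomness —
initialisation, shuffling, reparameterisation noise — flows through one
seeded generator, so identical seeds give bit-identical trained weights.
Training uses reparameterised sampling; evaluation encodes with the
posterior mean only. Loss reductions, ε, layer sizes and the optimiser are
package conventions: they are not uniquely determined by the modelling
idea, and other choices would work.

**Reference benchmark recipe.** 200 training subjects, 50 held-out, 60
epochs, batch 32, β = 0.25, seed fixed. On synthetic beats this reaches a
mean held-out per-record Pearson reconstruction correlation ≥ 0.9 in a few
minutes on one CPU (typically ≈ 0.95–0.97); these problem sizes keep the
full test suite desk-scale while leaving the property with headroom. On
this small, comparatively homogeneous synthetic population all 30 latents
usually stay active; latent collapse to a smaller active subset emerges
with stronger regularisation or larger, more heterogeneous data.

## Interpretation

* **Latent traversal**: decode the population-mean latent vector while
  sweeping one dimension over −3…+3 across-subject SDs, holding the others
  at their mean. Grids for different LFs share the same baseline beat.
* **Stratified reconstruction**: decode per-group mean latent vectors with
  a shaded band from mean ± 0.5 SD per dimension.
* **Conventional parameters**: PR, QRS and QT are measured on the
  root-mean-square composite of the 8 leads. Supra-threshold segments are
  classified as P wave, QRS complex (the segment containing the global
  maximum) and T wave; PR = P onset→QRS onset, QRS = onset→offset,
  QT = QRS onset→T offset, and QTc uses Bazett (QT/√RR); the correction
  formula is a package convention. The activity threshold is the median
  composite amplitude plus 3 median absolute deviations (constants in
  `ecglf.interpret`): zero on noiseless compact-support beats — so
  fiducials are then exact to one sample — and adaptive on noisy or
  reconstructed beats. Undetectable waves yield missing values with a
  warning, never an exception.

## Genetic analysis

* **Normalisation**: rank-based inverse normal transform with Blom
  offsets, Φ⁻¹((rank − 3/8)/(n + ¼)), average ranks for ties, missing
  preserved. Output is invariant under strictly monotone transforms of the
  input.
* **Association**: per-variant least squares `trait ~ dosage + covariates`
  via Frisch–Waugh residualisation (exactly the joint OLS fit), two-sided
  t-test p-values, monomorphic variants reported missing, and the
  genomic-control λ = median(χ²)/0.4549 always reported. Mixed-model
  association and REML variance components are deliberately replaced by
  OLS + principal-component covariates and Haseman–Elston regression:
  exact at desk scale, no external solver, and λ keeps structure-driven
  inflation visible. This is a stand-in, not a claim of equivalence.
* **Thresholds**: per-trait Bonferroni of the genome-wide level (5×10⁻⁸
  divided by the number of traits: /20 for LFs → 2.5×10⁻⁹, /11 for
  conventional parameters → 4.5×10⁻⁹), gene-level 0.05/18,383 = 2.72×10⁻⁶,
  and Benjamini–Hochberg FDR (1% for GWAS novelty selection, 5% for burden
  tests) with all-or-none inclusion of tied p-values.
* **Loci**: significant variants within 500 kb single-linkage merge; the
  span gains 500 kb flanks each side, clipped at position 1; flanked spans
  with overlapping borders (e.g. across traits) merge again. Lead variant
  = smallest p. Without LD reference panels, conditionally independent
  signal counting is not attempted; loci derive from the distance rule
  only.
* **Replication**: discovery hits at FDR < 1% are validated when
  directionally concordant and p < 0.05 in the replication cohort;
  variants absent there are recorded untested.
* **Haseman–Elston**: for standardised y, E[y_i y_j] = h²·A_ij (i≠j) with
  A the GRM from standardised dosages; the OLS slope over off-diagonal
  pairs estimates h², symmetrised cross-trait products give the genetic
  covariance and r_g. Out-of-range estimates are flagged, never clamped.
  The naive OLS slope SE ignores pair dependence and is optimistic;
  adequate for simulation-scale checks only.
* **Burden**: qualifying variants are loss-of-function OR
  deleterious-by-all-five-predictors AND pass a frequency mask —
  *singleton* (exactly one alternate allele in the analysis sample, not an
  external frequency), af < 0.001 or af < 0.01, strict inequalities on the
  sample allele frequency. Per-gene burden is the qualifying
  alt-allele count per subject; a carrier indicator is emitted alongside
  because both conventions exist in the field. Burden association is the
  same covariate-adjusted least-squares fit, BH-corrected across the genes
  actually tested (subset analyses re-run the FDR on the subset).
* **Prioritisation**: per locus — (1) established Mendelian
  arrhythmia/cardiomyopathy genes win outright; (2) otherwise genes
  supported by >1 of PoPS/V2G/MAGMA, ties at equal method count resolved
  by a literature-support flag (all plausible genes kept); (3) failing
  that, the nearest gene. PoPS/V2G/MAGMA scores themselves are consumed as
  user-supplied boolean flags; computing them is out of scope.

## Phenome-wide comparison

Two least-squares prediction models per phenotype — all LFs, or the
conventional ECG parameters, each plus age, age² and sex — are fitted on
training subjects (one random record per subject, seeded) and evaluated on
held-out subjects by correlating predictions with the actual values:
Pearson for continuous traits, point-biserial for 0/1-coded binary traits
(algebraically the same computation). Binary phenotypes use a linear
probability fit: the biserial evaluation requires a continuous prediction,
which a linear model gives directly. Phenotypes with > 90% training
missingness, or binary phenotypes with < 100 training cases, are excluded
first. Significance is Bonferroni-corrected p < 0.05 within each model
family (the denominator convention is a package choice); phenotypes are
classified LF-only / ECG-only / both-LF-higher / both-ECG-higher / neither
by comparing correlation magnitudes (exact ties count toward LF), and
per-category feature importance is the category mean absolute coefficient
normalised to sum to 1 across features. A train/test leakage guard rejects
evaluation on any subject seen during fitting.

## Synthetic data

The generator provides ground truth the real study cannot: it does not
model any particular dataset's distributions.

* **Beats**: five wavelets (P, Q, R, S, T) are placed on the 0.8-s grid
  according to per-subject interval factors (PR, QRS, QT in ms), with the
  R peak fixed at 300 ms. Each wavelet is a *truncated* Gaussian bump that
  reaches exactly zero at its onset/offset: compact support makes wave
  boundaries well defined, so measured fiducial distances equal the
  configured intervals to within one sample on noiseless beats — a plain
  Gaussian has no defined onset at all. The T wave is skewed by an
  asymmetry factor. A 3-D dipole trajectory (fixed direction per wave,
  amplitude factors in mV) is projected to the 8 leads through a fixed
  full-rank Dower-style matrix, inducing realistic cross-lead correlation
  without any fitting. Additive iid Gaussian noise and, with configurable
  probability, an extreme-voltage artefact sample (|v| > 8 mV) complete a
  record. Factor distributions are loosely physiological (PR ≈ 165±18 ms,
  QRS ≈ 95±10 ms, QT ≈ 400±25 ms, RR ≈ 950±90 ms, truncated); the RR floor
  of 820 ms keeps consecutive beats' wave content disjoint within the
  0.8-s extraction window of the raw-signal generator.
* **Raw ECGs**: the subject's beat repeated at RR intervals with per-beat
  timing jitter over 10 s at 500 Hz.
* **Genotypes**: hard-call dosages from Hardy–Weinberg sampling at
  uniform-drawn allele frequencies on one synthetic chromosome (1-based
  positions, VCF convention); optional two-population structure by
  Balding–Nichols frequency perturbation at a given F_ST. A configurable
  tail of rare variants carries loss-of-function / deleterious flags and
  contiguous gene assignments for the burden masks. No linkage
  disequilibrium beyond population structure is modelled.
* **Phenotypes**: quantitative traits combine planted per-allele effects
  (or an infinitesimal all-variant contribution), in-sample standardised so
  the realised genetic variance fraction matches the target h², plus fixed
  covariate effects (age, age², sex, height, BMI) and Gaussian noise.
  Binary traits threshold an independent standard-normal liability at the
  configured prevalence, matching the biserial analysis downstream.

What passing tests show — and don't. The synthetic beats are smooth,
low-noise and unimodal per wave; real ECGs carry baseline wander,
morphological pathology, electrode artefacts and repeated measures, none
of which are modelled. Synthetic genotypes have no LD structure, so locus
aggregation exercises the distance rule, not fine-mapping behaviour.
Passing therefore demonstrates correctness of the algorithms and
recoverability of planted signal under the stated conditions, not clinical
or population-genetic performance.

## Numerical conventions and degenerate inputs

Strict inequalities follow the printed rules everywhere (±8 mV bounds,
frequency cutoffs, p < 0.05). Degenerate inputs prefer missing values plus
warnings over exceptions when the operation can proceed (zero-variance
correlation columns, undetectable waves, monomorphic variants, all-zero
burden columns) and raise informative errors when it cannot (all-tied INT
input, rank-deficient designs with the collinear columns named, flat
signals, non-finite training losses). Genomic coordinates are 1-based
inclusive throughout; locus clipping stops at position 1.

## Known limitations

* The NumPy VAE is desk-scale: minutes for hundreds of subjects, not
  suitable for million-record corpora.
* OLS association ignores relatedness; under strong structure λ will show
  the inflation rather than remove it.
* The HE standard error underestimates uncertainty (dependent pairs).
* Interval measurement is a research convenience, not clinical-grade.
* The synthetic phenome panel is small and fully synthetic; the
  2000-phenotype scale of real phenome scans is not reproduced.
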