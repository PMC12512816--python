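# ecglf

Unsupervised discovery of ECG structure and its genetic basis, at desk
scale. `ecglf` is aimed at researchers in cardiac electrophysiology and
statistical genetics who want a fully testable, self-contained
re-implementation of the latent-factor ECG pipeline: learn compact,
interpretable features from median heartbeats without labels, then treat
those features as quantitative traits in genetic and phenome-wide
analyses.

## What it does

**Representation learning.** A convolutional β-VAE encodes 8-lead median
beats (subjects × 8 × 400 samples, 0.8 s at 500 Hz; leads I, II, V1–V6)
into at most 30 latent factors z, trained to minimise

    L = SMAPE(x, x̂) + β · KL( q(z|x) ‖ N(0, I) )

where SMAPE is the symmetric mean absolute percentage error of the
reconstruction (bounded [0, 200]%) and β weights the Kullback–Leibler
pull toward the standard-normal prior, trading reconstruction fidelity
against disentanglement. β is selected over {0.1, 0.25, 0.5, 1, 3, 5, 10}
by validation reconstruction correlation (default 0.25). The VAE is
implemented directly in NumPy with explicit backpropagation — no deep
learning framework required — and is bit-reproducible under a fixed seed.

**Preprocessing.** Median-beat derivation from raw 10-s signals, crop/pad
to 0.8 s, cross-correlation alignment, exclusion of records with samples
outside ±8 mV, and subject-disjoint 90/5/5 splits.

**Genetics.** Rank-based inverse normal transform (Blom), per-variant
covariate-adjusted association with genomic-control λ, per-trait
Bonferroni thresholds (e.g. 5×10⁻⁸/20 = 2.5×10⁻⁹), Benjamini–Hochberg
FDR, 500-kb locus aggregation with 500-kb flanks, discovery/replication
filtering (directional concordance, p < 0.05), Haseman–Elston h²/r_g,
rare-variant burden collapsing under singleton / af<0.001 / af<0.01 masks
restricted to loss-of-function or deleterious-by-all-five variants, and a
per-locus gene prioritisation cascade (Mendelian genes → multi-method
support → literature → nearest gene).

**Phenome comparison.** Per phenotype, two regression models — latent
factors vs conventional ECG parameters, both with age, age², sex — are
fitted on a training split and scored by prediction–truth correlation
(Pearson / point-biserial) on held-out subjects, then classified by which
feature set wins.

**Synthetic ground truth.** A first-class simulator generates median
beats from known physiological factors (interval durations, wave
amplitudes, T-wave asymmetry) projected to 8 leads through a fixed dipole
matrix, plus genotypes (optionally with two-population structure),
covariates and phenotypes with planted SNP effects and target
heritability — so every downstream claim is testable against ground
truth. See `docs/methods.md` for the model and its limits.

## Worked example

```python
import numpy as np
from ecglf.simulate import SimConfig, simulate_median_beats, \
    simulate_genotypes, simulate_phenotypes
from ecglf.vae import BetaVAE, reconstruction_correlation
from ecglf.genetics import inverse_normal_transform, run_gwas, aggregate_loci

cfg = SimConfig(n_subjects=250, noise_sd=0.02, seed=1,
                n_variants=300, causal_map=[(42, "lf_like", 0.4)],
                h2_map={"lf_like": 0.3})
beats, factors = simulate_median_beats(cfg)
train, test = beats.subset(np.arange(200)), beats.subset(np.arange(200, 250))

model = BetaVAE(beta=0.25, epochs=60, seed=0).fit(train, X_val=test)
r, mean_r, sd_r = reconstruction_correlation(model, test)
print(f"held-out reconstruction r = {mean_r:.3f} +/- {sd_r:.3f}")
print(f"active latents: {len(model.active_latents_)} of {model.latent_dim}")

genotypes = simulate_genotypes(cfg.replace(n_subjects=2000))
pheno, covars = simulate_phenotypes(genotypes, None, cfg.replace(n_subjects=2000))
y = inverse_normal_transform(pheno["lf_like"])
result = run_gwas(genotypes, y, covars[["age", "sex", "height", "bmi"]])
print(f"lambda_GC = {result.lambda_gc:.3f}")

for lo in aggregate_loci(result.table[result.table["p"] < 1e-8]):
    print(f"locus {lo.chrom}:{lo.start}-{lo.end}  lead={lo.lead_variant}")
print(f"causal variant was {genotypes.variants.loc[42, 'variant_id']}")
```

Output (a few minutes on one CPU):

```
held-out reconstruction r = 0.965 +/- 0.009
active latents: 30 of 30
lambda_GC = 0.814
locus 1:30143644-31143644  lead=1:30643644
causal variant was 1:30643644
```

Reading it: the VAE reconstructs unseen synthetic beats almost perfectly
(r = 0.965); on this small homogeneous population all 30 latents stay
active. The association scan shows no inflation (λ ≈ 1 up to sampling
noise of the median on 300 variants), and the single genome-wide-
significant locus — the variant span ± 500 kb flanks — is led by exactly
the variant the simulation planted.

A `ecglf` command-line tool wraps the same stages
(`simulate`, `preprocess`, `train`, `encode`, `select-beta`, `gwas`,
`loci`, `burden`, `prioritise`, `phewas`); run `ecglf --help`.

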