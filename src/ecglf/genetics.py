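"""Desk-scale genetic analysis of latent factors and ECG traits.

Implements the statistical rules of the association pipeline: rank-based
inverse normal transform (Blom offsets), covariate-adjusted per-variant
least-squares association with genomic-control lambda, Bonferroni-per-trait
thresholds, Benjamini–Hochberg FDR, 500-kb locus aggregation with 500-kb
flanks, discovery/replication filtering (directional concordance at
p < 0.05), a Haseman–Elston regression stand-in for variance-component
heritability and genetic correlation, rare-variant burden collapsing under
frequency x deleteriousness masks, per-gene burden testing, and the
per-locus gene prioritisation rule cascade.

Mixed-model association and REML estimation are deliberately replaced by
OLS with principal-component covariates and Haseman–Elston regression:
both are exact at desk scale and require no external solver, and the
genomic-control lambda is always reported so residual structure-driven
inflation stays visible.
"""

from __future__ import annotations

import warnings
from collections import namedtuple
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ecglf.containers import AssocResult, GenotypeMatrix, Locus

__all__ = [
    "inverse_normal_transform",
    "run_gwas",
    "significance_threshold",
    "bh_fdr",
    "aggregate_loci",
    "replicate",
    "he_heritability",
    "HeritabilityEstimate",
    "burden_collapse",
    "burden_test",
    "prioritise_genes",
    "BURDEN_MASKS",
]

#: median of the 1-df chi-square distribution, the genomic-control null
CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, df=1))


def inverse_normal_transform(values) -> np.ndarray:
    """Rank-based inverse normal transform with Blom offsets.

    Maps value of rank r (average ranks for ties) among n non-missing
    observations to ``Phi^-1((r - 3/8) / (n + 1/4))``.  Missing values stay
    missing; the output preserves the input rank order and is invariant
    under strictly monotone transforms of the input.
    """
    x = np.asarray(values, dtype=float)
    out = np.full(x.shape, np.nan)
    mask = np.isfinite(x)
    n = int(mask.sum())
    if n < 2:
        raise ValueError("need at least 2 non-missing values")
    if np.unique(x[mask]).size == 1:
        raise ValueError("all values identical: ranks are degenerate")
    ranks = stats.rankdata(x[mask], method="average")
    out[mask] = stats.norm.ppf((ranks - 3.0 / 8.0) / (n + 0.25))
    return out


def _residualise(mat: np.ndarray, covariates: np.ndarray) -> np.ndarray:
    """Project out the column space of [1, covariates] from mat columns."""
    q, _ = np.linalg.qr(covariates)
    return mat - q @ (q.T @ mat)


def _covariate_design(covariates, n: int) -> tuple[np.ndarray, list[str]]:
    if covariates is None:
        return np.ones((n, 1)), ["intercept"]
    if isinstance(covariates, pd.DataFrame):
        names = list(covariates.columns)
        c = covariates.to_numpy(dtype=float)
    else:
        c = np.atleast_2d(np.asarray(covariates, dtype=float))
        if c.shape[0] != n:
            c = c.T
        names = [f"c{i}" for i in range(c.shape[1])]
    design = np.column_stack([np.ones(n), c])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate matrix is rank deficient")
    return design, ["intercept"] + names


def run_gwas(genotypes: GenotypeMatrix, trait, covariates=None,
             trait_name: str = "trait") -> AssocResult:
    """Per-variant least-squares association of a quantitative trait.

    Fits ``trait ~ dosage + covariates`` for every variant (via
    Frisch–Waugh residualisation, exactly equivalent to the joint OLS fit)
    and reports the dosage effect, its standard error and the two-sided
    p-value from the t distribution.  Monomorphic variants are reported
    missing.  The genomic-control lambda, median(chi2)/0.4549, indexes
    residual inflation.

    The trait is expected to be inverse-normal transformed; a warning is
    issued when its mean/SD are far from (0, 1).
    """
    y = np.asarray(trait, dtype=float)
    n = genotypes.n_subjects
    if y.shape[0] != n:
        raise ValueError("trait length must match number of subjects")
    design, _ = _covariate_design(covariates, n)
    k = design.shape[1]
    if n <= k + 2:
        raise ValueError(f"n={n} too small for {k} covariate columns")
    if abs(np.nanmean(y)) > 0.1 or abs(np.nanstd(y) - 1.0) > 0.1:
        warnings.warn("trait does not look inverse-normal transformed "
                      "(mean/SD far from 0/1); consider inverse_normal_transform")

    dos = genotypes.dosages.astype(float)
    mono = dos.std(axis=0) == 0

    yr = _residualise(y[:, None], design)[:, 0]
    gr = _residualise(dos, design)
    gss = (gr**2).sum(axis=0)
    gss_safe = np.where(gss > 0, gss, np.nan)
    gy = gr.T @ yr
    beta = gy / gss_safe
    df = n - k - 1
    sigma2 = ((yr @ yr) - beta * gy) / df
    se = np.sqrt(np.maximum(sigma2, 0) / gss_safe)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = beta / se
        p = np.maximum(2.0 * stats.t.sf(np.abs(tstat), df=df), 1e-300)
    beta[mono] = se[mono] = p[mono] = np.nan

    chi2 = tstat[~mono] ** 2
    lambda_gc = float(np.nanmedian(chi2) / CHI2_MEDIAN_1DF) if (~mono).any() else np.nan
    table = genotypes.variants[["chrom", "pos", "variant_id", "af"]].copy() \
        if "variant_id" in genotypes.variants else genotypes.variants[["chrom", "pos", "af"]].copy()
    table["beta"] = beta
    table["se"] = se
    table["p"] = p
    table["n"] = n
    return AssocResult(trait=trait_name, table=table, lambda_gc=lambda_gc)


Threshold = namedtuple("Threshold", ["threshold", "display"])


def significance_threshold(base_alpha: float, n_tests: int, sig_figs: int = 2) -> Threshold:
    """Bonferroni-style per-trait threshold base_alpha / n_tests.

    Returns both the raw value and a display string rounded to
    ``sig_figs`` significant figures (the precision thresholds are printed
    at, e.g. 5e-8/20 -> "2.5e-09").
    """
    if n_tests < 1:
        raise ValueError("n_tests must be at least 1")
    raw = base_alpha / n_tests
    return Threshold(raw, f"{raw:.{sig_figs - 1}e}")


def bh_fdr(pvalues, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: q-values and the significant set.

    Ties at equal p receive equal q-values, so inclusion at the threshold
    rank is all-or-none.  Missing p-values propagate as missing and are
    never significant.  Empty input gives empty output.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    ok = np.isfinite(p)
    if ((p[ok] <= 0) | (p[ok] > 1)).any():
        raise ValueError("p-values must lie in (0, 1]")
    qvals = np.full(p.shape, np.nan)
    m = int(ok.sum())
    if m:
        order = np.argsort(p[ok], kind="stable")
        ranked = p[ok][order] * m / (np.arange(m) + 1)
        qv = np.minimum.accumulate(ranked[::-1])[::-1]
        tmp = np.empty(m)
        tmp[order] = np.minimum(qv, 1.0)
        qvals[ok] = tmp
    significant = np.zeros(p.shape, dtype=bool)
    significant[ok] = qvals[ok] <= q
    return qvals, significant


def aggregate_loci(
    variants: pd.DataFrame,
    merge_dist: int = 500_000,
    flank: int = 500_000,
) -> list[Locus]:
    """Aggregate significant variants into loci.

    Variants on the same chromosome within ``merge_dist`` of each other are
    single-linkage clustered; each cluster spans
    [min pos - flank, max pos + flank], clipped at position 1.  Flanked
    spans with overlapping borders (e.g. across traits) are then merged.
    The lead variant of a locus is its smallest-p member when a ``p``
    column is present.
    """
    required = {"chrom", "pos"}
    if not required <= set(variants.columns):
        raise ValueError("variants need chrom and pos columns")
    if variants.empty:
        return []
    df = variants.copy()
    if "variant_id" not in df:
        df["variant_id"] = [f"{c}:{p}" for c, p in zip(df["chrom"], df["pos"])]
    clusters = []
    for chrom, grp in df.groupby("chrom", sort=False):
        grp = grp.sort_values("pos")
        pos = grp["pos"].to_numpy()
        breaks = np.flatnonzero(np.diff(pos) > merge_dist) + 1
        for part in np.split(np.arange(len(grp)), breaks):
            sub = grp.iloc[part]
            clusters.append(
                Locus(
                    chrom=str(chrom),
                    start=max(int(sub["pos"].min()) - flank, 1),
                    end=int(sub["pos"].max()) + flank,
                    member_variants=list(sub["variant_id"]),
                    lead_variant=str(
                        sub.loc[sub["p"].idxmin(), "variant_id"]
                        if "p" in sub and sub["p"].notna().any()
                        else sub["variant_id"].iloc[0]
                    ),
                    traits=sorted(set(sub["trait"])) if "trait" in sub else [],
                )
            )
    # combine loci with overlapping flanked borders
    merged: list[Locus] = []
    for locus in sorted(clusters, key=lambda lo: (lo.chrom, lo.start, lo.end)):
        if merged and merged[-1].overlaps(locus):
            prev = merged[-1]
            prev.end = max(prev.end, locus.end)
            prev.member_variants += locus.member_variants
            prev.traits = sorted(set(prev.traits) | set(locus.traits))
            # keep the lead with the smaller p when available
            if "p" in df:
                leads = df.set_index("variant_id")["p"]
                if leads.get(locus.lead_variant, np.inf) < leads.get(prev.lead_variant, np.inf):
                    prev.lead_variant = locus.lead_variant
        else:
            merged.append(locus)
    return merged


def replicate(
    discovery: AssocResult | pd.DataFrame,
    replication: AssocResult | pd.DataFrame,
    fdr: float = 0.01,
    p_rep: float = 0.05,
) -> pd.DataFrame:
    """Discovery/replication filter for candidate novel variants.

    Discovery variants passing BH-FDR < ``fdr`` are kept when they are
    directionally concordant and significant (p < ``p_rep``) in the
    replication cohort.  Variants absent from the replication set are
    recorded as untested.  Returns the discovery table with a ``status``
    column in {not_selected, untested, validated, not_validated}.
    """
    disc = discovery.table if isinstance(discovery, AssocResult) else discovery
    rep = replication.table if isinstance(replication, AssocResult) else replication
    disc = disc.copy()
    qvals, selected = bh_fdr(disc["p"].to_numpy(), q=fdr)
    disc["q"] = qvals
    rep_idx = rep.set_index("variant_id")
    status = []
    for sel, (_, row) in zip(selected, disc.iterrows()):
        if not sel:
            status.append("not_selected")
        elif row["variant_id"] not in rep_idx.index:
            status.append("untested")
        else:
            r = rep_idx.loc[row["variant_id"]]
            concordant = np.sign(row["beta"]) == np.sign(r["beta"])
            status.append("validated" if (r["p"] < p_rep and concordant) else "not_validated")
    disc["status"] = status
    return disc


# ---------------------------------------------------------------------------
# Haseman–Elston heritability / genetic correlation
# ---------------------------------------------------------------------------

@dataclass
class HeritabilityEstimate:
    """h2 (or rg for two traits) with a naive OLS standard error.

    Out-of-range estimates are returned raw with ``out_of_range`` set;
    nothing is clamped silently.
    """

    traits: tuple
    estimate: float
    se: float
    kind: str  # "h2" or "rg"
    out_of_range: bool
    h2_components: tuple | None = None


def _grm(dosages: np.ndarray) -> np.ndarray:
    sd = dosages.std(axis=0)
    ok = sd > 0
    z = (dosages[:, ok] - dosages[:, ok].mean(axis=0)) / sd[ok]
    return (z @ z.T) / ok.sum()


def _he_slope(products: np.ndarray, a: np.ndarray) -> tuple[float, float]:
    x = np.column_stack([np.ones_like(a), a])
    coef, *_ = np.linalg.lstsq(x, products, rcond=None)
    resid = products - x @ coef
    dof = max(products.size - 2, 1)
    sigma2 = (resid @ resid) / dof
    cov = sigma2 * np.linalg.inv(x.T @ x)
    return float(coef[1]), float(np.sqrt(cov[1, 1]))


def he_heritability(genotypes: GenotypeMatrix | np.ndarray, trait, trait2=None,
                    trait_names: tuple = ("trait1", "trait2")) -> HeritabilityEstimate:
    """Haseman–Elston regression of phenotype cross-products on the GRM.

    For standardised trait y, E[y_i y_j] = h2 * A_ij for i != j, where A is
    the genomic relationship matrix from standardised dosages; the OLS
    slope over off-diagonal pairs estimates h2.  With a second trait the
    symmetrised cross-trait products estimate the genetic covariance, and
    rg = cov_g / sqrt(h2_1 * h2_2).  The reported SE is the naive OLS
    slope SE (pairs are dependent, so it is optimistic; adequate for
    simulation-scale checks).
    """
    dos = genotypes.dosages if isinstance(genotypes, GenotypeMatrix) else np.asarray(genotypes)
    dos = dos.astype(float)
    n = dos.shape[0]
    if n < 100:
        warnings.warn("Haseman–Elston regression is unreliable below ~100 subjects")
    a = _grm(dos)
    iu = np.triu_indices(n, k=1)
    a_off = a[iu]

    def _std(v):
        v = np.asarray(v, dtype=float)
        return (v - v.mean()) / v.std()

    y1 = _std(trait)
    if trait2 is None:
        h2, se = _he_slope(y1[iu[0]] * y1[iu[1]], a_off)
        return HeritabilityEstimate((trait_names[0],), h2, se, "h2",
                                    out_of_range=not (0.0 <= h2 <= 1.0))
    y2 = _std(trait2)
    h2_1, _ = _he_slope(y1[iu[0]] * y1[iu[1]], a_off)
    h2_2, _ = _he_slope(y2[iu[0]] * y2[iu[1]], a_off)
    cross = 0.5 * (y1[iu[0]] * y2[iu[1]] + y1[iu[1]] * y2[iu[0]])
    cov_g, se = _he_slope(cross, a_off)
    denom = np.sqrt(max(h2_1, 1e-12) * max(h2_2, 1e-12))
    rg = cov_g / denom
    return HeritabilityEstimate(tuple(trait_names), rg, se / denom, "rg",
                                out_of_range=not (-1.0 <= rg <= 1.0),
                                h2_components=(h2_1, h2_2))


# ---------------------------------------------------------------------------
# rare-variant burden
# ---------------------------------------------------------------------------

#: canonical mask names with their frequency rules
BURDEN_MASKS = ("singleton", "af<0.001", "af<0.01")
_MASK_ALIASES = {"singleton": "singleton", "af001": "af<0.001", "af<0.001": "af<0.001",
                 "af01": "af<0.01", "af<0.01": "af<0.01"}


def burden_collapse(
    genotypes: GenotypeMatrix,
    mask: str,
    gene_map: dict | pd.Series | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse qualifying rare variants into per-gene per-subject burdens.

    Qualifying variants are loss-of-function OR deleterious-by-all-five
    predictors, AND pass the mask's frequency rule: ``singleton`` means
    exactly one alternate allele observed in the analysis sample, the af
    masks use strict sample allele-frequency cutoffs.  Returns the
    gene x subject allele-count burden matrix and the matching carrier
    indicator matrix; genes left empty by the mask are skipped with a
    warning.
    """
    mask_name = _MASK_ALIASES.get(mask)
    if mask_name is None:
        raise ValueError(f"unknown mask {mask!r}; choose from {BURDEN_MASKS}")
    var = genotypes.variants
    for col in ("is_lof", "deleterious_all5"):
        if col not in var.columns:
            raise ValueError(f"variant table lacks annotation column {col!r}")
    if gene_map is None:
        if "gene" not in var.columns:
            raise ValueError("no gene assignment: supply gene_map or a gene column")
        genes = var["gene"].to_numpy()
    else:
        gm = pd.Series(gene_map)
        genes = gm.reindex(range(genotypes.n_variants)).to_numpy()

    dos = genotypes.dosages.astype(float)
    alt_count = dos.sum(axis=0)
    af = alt_count / (2.0 * genotypes.n_subjects)
    if mask_name == "singleton":
        freq_ok = alt_count == 1
    else:
        cutoff = 0.001 if mask_name == "af<0.001" else 0.01
        freq_ok = af < cutoff
    qualifying = (var["is_lof"].to_numpy() | var["deleterious_all5"].to_numpy()) & freq_ok

    burden_rows, kept = [], []
    for gene in pd.unique(genes[~pd.isna(genes)]):
        cols = np.flatnonzero((genes == gene) & qualifying)
        if cols.size == 0:
            warnings.warn(f"gene {gene!r} has no qualifying variants under mask {mask_name}")
            continue
        burden_rows.append(dos[:, cols].sum(axis=1))
        kept.append(gene)
    if not kept:
        empty = pd.DataFrame(columns=genotypes.subject_ids)
        return empty, empty
    burden = pd.DataFrame(np.stack(burden_rows), index=kept, columns=genotypes.subject_ids)
    carriers = (burden > 0).astype(int)
    return burden, carriers


def burden_test(
    burden: pd.DataFrame,
    trait,
    covariates=None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Per-gene least-squares burden association with BH-FDR.

    ``burden`` is the gene x subject matrix from :func:`burden_collapse`.
    Fits ``trait ~ burden + covariates`` per gene; genes with an all-zero
    burden column are reported missing.  q-values use Benjamini–Hochberg
    across the tested set (subset analyses should re-run this function on
    the subset so the FDR denominator matches the number of genes tested).
    """
    y = np.asarray(trait, dtype=float)
    b = burden.to_numpy(dtype=float).T  # subjects x genes
    n = y.shape[0]
    if b.shape[0] != n:
        raise ValueError("trait length must match burden columns (subjects)")
    design, _ = _covariate_design(covariates, n)
    k = design.shape[1]
    if abs(np.nanmean(y)) > 0.1 or abs(np.nanstd(y) - 1.0) > 0.1:
        warnings.warn("trait does not look inverse-normal transformed")

    allzero = (b == 0).all(axis=0)
    yr = _residualise(y[:, None], design)[:, 0]
    br = _residualise(b, design)
    bss = (br**2).sum(axis=0)
    bss_safe = np.where(bss > 0, bss, np.nan)
    by = br.T @ yr
    beta = by / bss_safe
    df = n - k - 1
    sigma2 = ((yr @ yr) - beta * by) / df
    se = np.sqrt(np.maximum(sigma2, 0) / bss_safe)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = beta / se
        p = np.maximum(2.0 * stats.t.sf(np.abs(tstat), df=df), 1e-300)
    beta[allzero] = se[allzero] = p[allzero] = np.nan
    qvals, significant = bh_fdr(p, q=fdr)
    return pd.DataFrame(
        {
            "gene": burden.index,
            "n_carriers": (b > 0).sum(axis=0),
            "beta": beta,
            "se": se,
            "p": p,
            "q": qvals,
            "significant": significant,
        }
    )


# ---------------------------------------------------------------------------
# gene prioritisation
# ---------------------------------------------------------------------------

_FLAG_METHODS = ("pops_top3", "v2g_top3", "magma_sig")


def prioritise_genes(candidates: pd.DataFrame) -> pd.DataFrame:
    """Per-locus causal-gene prioritisation rule cascade.

    Expects one row per candidate gene with columns ``locus``, ``gene`` and
    boolean flags ``is_mendelian_arrhythmia_or_cm``, ``pops_top3``,
    ``v2g_top3``, ``magma_sig``, ``nearest``, ``literature_support``.

    Per locus: (1) every established Mendelian arrhythmia/cardiomyopathy
    gene is selected; (2) otherwise genes supported by more than one of
    PoPS/V2G/MAGMA — ties at equal method count resolved by literature
    support, keeping all literature-plausible genes; (3) with no literature
    evidence among the tied genes, or no multi-method gene at all, the
    nearest gene is selected.
    """
    required = {"locus", "gene", "is_mendelian_arrhythmia_or_cm", "nearest",
                "literature_support", *_FLAG_METHODS}
    missing = required - set(candidates.columns)
    if missing:
        raise ValueError(f"candidate table missing columns: {sorted(missing)}")
    out = []
    for locus, grp in candidates.groupby("locus", sort=False):
        if grp.empty:
            raise ValueError(f"locus {locus!r} has no candidate genes")
        if not grp["nearest"].any():
            raise ValueError(f"locus {locus!r} lacks a nearest-flagged gene")
        mendelian = grp[grp["is_mendelian_arrhythmia_or_cm"].astype(bool)]
        if len(mendelian):
            chosen, rule = list(mendelian["gene"]), "mendelian"
        else:
            counts = grp[list(_FLAG_METHODS)].astype(bool).sum(axis=1)
            multi = grp[counts > 1]
            if len(multi) == 1:
                chosen, rule = list(multi["gene"]), "multi_method"
            elif len(multi) > 1:
                top = multi[counts[multi.index] == counts[multi.index].max()]
                if len(top) == 1:
                    chosen, rule = list(top["gene"]), "multi_method"
                else:
                    lit = top[top["literature_support"].astype(bool)]
                    if len(lit):
                        chosen, rule = list(lit["gene"]), "literature"
                    else:
                        chosen, rule = list(grp.loc[grp["nearest"], "gene"]), "nearest"
            else:
                chosen, rule = list(grp.loc[grp["nearest"], "gene"]), "nearest"
        for gene in chosen:
            out.append({"locus": locus, "gene": gene, "rule": rule})
    return pd.DataFrame(out)
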