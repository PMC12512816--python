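"""Association machinery: INT, GWAS, thresholds, FDR, loci, replication,
Haseman–Elston heritability, burden collapsing/testing, prioritisation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ecglf.containers import GenotypeMatrix
from ecglf.genetics import (
    aggregate_loci,
    bh_fdr,
    burden_collapse,
    burden_test,
    he_heritability,
    inverse_normal_transform,
    prioritise_genes,
    replicate,
    run_gwas,
    significance_threshold,
)
from ecglf.simulate import SimConfig, simulate_genotypes, simulate_phenotypes


class TestInverseNormalTransform:
    def test_blom_offsets_exact_n3(self):
        out = inverse_normal_transform([5.0, 2.0, 9.0])
        expected = stats.norm.ppf((np.array([2, 1, 3]) - 3 / 8) / 3.25)
        np.testing.assert_allclose(out, expected)
        assert out[0] == 0.0  # middle value maps to the median of N(0,1)

    def test_mean_near_zero_by_symmetry(self):
        rng = np.random.default_rng(0)
        out = inverse_normal_transform(rng.exponential(size=101))
        assert abs(out.mean()) < 1e-6

    @settings(derandomize=True, max_examples=30, deadline=None)
    @given(st.lists(st.integers(-100, 100), min_size=3, max_size=50, unique=True))
    def test_invariant_under_monotone_transform(self, values):
        x = np.asarray(values, dtype=float)
        np.testing.assert_allclose(inverse_normal_transform(x),
                                   inverse_normal_transform(np.exp(x / 50.0)),
                                   atol=1e-12)

    def test_missing_preserved_and_ties_averaged(self):
        out = inverse_normal_transform([1.0, np.nan, 1.0, 4.0])
        assert np.isnan(out[1])
        assert out[0] == out[2] < out[3]

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            inverse_normal_transform([3.0, 3.0, 3.0])


@pytest.fixture(scope="module")
def null_gwas():
    cfg = SimConfig(n_subjects=2000, n_variants=1000, seed=30, h2_map={"t": 0.0})
    geno = simulate_genotypes(cfg)
    pheno, covars = simulate_phenotypes(geno, None, cfg)
    y = inverse_normal_transform(pheno["t"])
    result = run_gwas(geno, y, covars[["age", "sex", "height", "bmi"]])
    return result


class TestGwas:
    def test_null_pvalues_uniform(self, null_gwas):
        p = null_gwas.table["p"].dropna()
        ks = stats.kstest(p, "uniform").statistic
        assert ks < 1.63 / np.sqrt(len(p))  # 1% critical value

    def test_lambda_gc_near_one_without_structure(self, null_gwas):
        assert 0.85 < null_gwas.lambda_gc < 1.15

    def test_matches_statsmodels_ols(self, null_gwas):
        """The residualised per-variant fit equals the joint OLS fit."""
        import statsmodels.api as sm

        cfg = SimConfig(n_subjects=300, n_variants=5, seed=31, h2_map={"t": 0.2})
        geno = simulate_genotypes(cfg)
        pheno, covars = simulate_phenotypes(geno, None, cfg)
        y = inverse_normal_transform(pheno["t"])
        res = run_gwas(geno, y, covars[["age", "sex"]])
        for j in range(5):
            design = sm.add_constant(np.column_stack(
                [geno.dosages[:, j], covars[["age", "sex"]].to_numpy()]))
            fit = sm.OLS(y, design).fit()
            assert res.table.loc[j, "beta"] == pytest.approx(fit.params[1], rel=1e-8)
            assert res.table.loc[j, "se"] == pytest.approx(fit.bse[1], rel=1e-8)
            assert res.table.loc[j, "p"] == pytest.approx(fit.pvalues[1], rel=1e-6)

    def test_monomorphic_reported_missing(self):
        dosages = np.zeros((200, 2), dtype=int)
        rng = np.random.default_rng(1)
        dosages[:, 1] = rng.integers(0, 3, 200)
        variants = pd.DataFrame({"chrom": "1", "pos": [100, 200],
                                 "variant_id": ["v1", "v2"], "ref": "A", "alt": "G",
                                 "af": [0.0, 0.5]})
        geno = GenotypeMatrix(dosages, variants, np.arange(200).astype(str))
        y = inverse_normal_transform(rng.normal(size=200))
        res = run_gwas(geno, y)
        assert np.isnan(res.table.loc[0, "p"])
        assert np.isfinite(res.table.loc[1, "p"])

    def test_sample_size_guard(self):
        cfg = SimConfig(n_subjects=5, n_variants=3, seed=32)
        geno = simulate_genotypes(cfg)
        with pytest.raises(ValueError, match="too small"):
            run_gwas(geno, np.zeros(5), pd.DataFrame({"a": np.arange(5.0),
                                                      "b": np.arange(5.0) ** 2}))

    def test_untransformed_trait_warns(self):
        cfg = SimConfig(n_subjects=300, n_variants=3, seed=33)
        geno = simulate_genotypes(cfg)
        rng = np.random.default_rng(2)
        with pytest.warns(UserWarning, match="inverse-normal"):
            run_gwas(geno, rng.normal(50, 10, 300))


class TestSignificanceThreshold:
    def test_printed_thresholds(self):
        assert significance_threshold(5e-8, 20).threshold == 2.5e-9
        assert significance_threshold(5e-8, 20).display == "2.5e-09"
        assert significance_threshold(5e-8, 11).display == "4.5e-09"
        assert significance_threshold(0.05, 18383, sig_figs=3).display == "2.72e-06"

    def test_zero_tests_rejected(self):
        with pytest.raises(ValueError):
            significance_threshold(5e-8, 0)


def _bh_oracle(p, q):
    """Textbook step-up: largest k with p_(k) <= k q / m."""
    p = np.asarray(p)
    m = len(p)
    order = np.argsort(p)
    k_max = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_max = k
    sig = np.zeros(m, dtype=bool)
    sig[order[:k_max]] = True
    return sig


class TestBhFdr:
    def test_step_up_by_hand(self):
        q, sig = bh_fdr([0.01, 0.02, 0.03, 0.5], q=0.05)
        assert list(sig) == [True, True, True, False]

    def test_all_ones_none_significant(self):
        _, sig = bh_fdr([1.0, 1.0, 1.0])
        assert not sig.any()

    def test_single_p_at_threshold(self):
        _, sig = bh_fdr([0.04], q=0.05)
        assert sig[0]

    def test_empty_input(self):
        q, sig = bh_fdr([])
        assert q.size == 0 and sig.size == 0

    def test_tied_pvalues_all_or_none(self):
        q, sig = bh_fdr([0.03, 0.03, 0.9], q=0.05)
        assert sig[0] == sig[1]

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=40),
           st.sampled_from([0.01, 0.05, 0.1]))
    def test_matches_naive_step_up(self, pvals, q):
        _, sig = bh_fdr(pvals, q=q)
        np.testing.assert_array_equal(sig, _bh_oracle(pvals, q))


def _interval_union_oracle(positions, merge, flank):
    """Brute force: flanked per-variant intervals, chained by the merge rule."""
    loci = []
    for pos in sorted(positions):
        if loci and pos - loci[-1][-1] <= merge:
            loci[-1].append(pos)
        else:
            loci.append([pos])
    return [(max(lo[0] - flank, 1), lo[-1] + flank) for lo in loci]


class TestAggregateLoci:
    def test_two_close_variants_one_locus(self):
        df = pd.DataFrame({"chrom": "1", "pos": [1_000_000, 1_400_000]})
        loci = aggregate_loci(df)
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (500_000, 1_900_000)

    def test_flank_clipped_at_position_one(self):
        loci = aggregate_loci(pd.DataFrame({"chrom": "1", "pos": [600_000]}))
        assert (loci[0].start, loci[0].end) == (100_000, 1_100_000)
        loci = aggregate_loci(pd.DataFrame({"chrom": "1", "pos": [200_000]}))
        assert loci[0].start == 1

    def test_600kb_apart_merge_at_combine_step(self):
        """Variants 600 kb apart form two clusters whose 500-kb flanked
        spans overlap, so they merge when combining."""
        df = pd.DataFrame({"chrom": "1", "pos": [1_000_000, 1_600_000]})
        loci = aggregate_loci(df)
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end) == (500_000, 2_100_000)

    def test_distinct_chromosomes_never_merge(self):
        df = pd.DataFrame({"chrom": ["1", "2"], "pos": [1_000_000, 1_000_000]})
        assert len(aggregate_loci(df)) == 2

    def test_lead_variant_is_min_p(self):
        df = pd.DataFrame({"chrom": "1", "pos": [1_000_000, 1_100_000],
                           "variant_id": ["a", "b"], "p": [0.5, 1e-10]})
        assert aggregate_loci(df)[0].lead_variant == "b"

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.integers(1, 50_000_000), min_size=1, max_size=30, unique=True))
    def test_matches_interval_union_oracle(self, positions):
        df = pd.DataFrame({"chrom": "1", "pos": positions})
        loci = aggregate_loci(df)
        spans = [(lo.start, lo.end) for lo in loci]
        # the combine step additionally merges overlapping flanked spans
        expected = []
        for s, e in _interval_union_oracle(positions, 500_000, 500_000):
            if expected and s <= expected[-1][1]:
                expected[-1] = (expected[-1][0], max(expected[-1][1], e))
            else:
                expected.append((s, e))
        assert spans == expected
        # every variant inside exactly one locus
        for pos in positions:
            assert sum(s <= pos <= e for s, e in spans) == 1


class TestReplicate:
    def _tables(self):
        disc = pd.DataFrame({"variant_id": ["a", "b", "c", "d"],
                             "beta": [0.5, -0.4, 0.3, 0.2],
                             "p": [1e-6, 1e-6, 1e-6, 0.9]})
        rep = pd.DataFrame({"variant_id": ["a", "b", "c"],
                            "beta": [0.4, 0.4, 0.1],
                            "p": [0.04, 0.001, 0.06]})
        return disc, rep

    def test_status_assignment(self):
        disc, rep = self._tables()
        out = replicate(disc, rep)
        status = dict(zip(out["variant_id"], out["status"]))
        assert status["a"] == "validated"          # concordant, p < 0.05
        assert status["b"] == "not_validated"      # opposite signs
        assert status["c"] == "not_validated"      # p = 0.06
        assert status["d"] == "not_selected"

    def test_untested_when_absent_from_replication(self):
        disc, rep = self._tables()
        out = replicate(disc, rep.iloc[1:])
        assert out.loc[out["variant_id"] == "a", "status"].item() == "untested"

    def test_monotone_in_replication_threshold(self):
        disc, rep = self._tables()
        loose = set(replicate(disc, rep, p_rep=0.05)
                    .query("status == 'validated'")["variant_id"])
        tight = set(replicate(disc, rep, p_rep=0.01)
                    .query("status == 'validated'")["variant_id"])
        assert tight <= loose


class TestHeritability:
    def test_null_trait_near_zero(self):
        cfg = SimConfig(n_subjects=2000, n_variants=500, seed=40, h2_map={"t": 0.0})
        geno = simulate_genotypes(cfg)
        pheno, _ = simulate_phenotypes(geno, None, cfg, covariate_effects={
            "age": 0, "age2": 0, "sex": 0, "height": 0, "bmi": 0})
        est = he_heritability(geno, pheno["t"])
        assert abs(est.estimate) < 0.05

    def test_rg_with_itself_is_one(self):
        cfg = SimConfig(n_subjects=500, n_variants=200, seed=41, h2_map={"t": 0.4})
        geno = simulate_genotypes(cfg)
        pheno, _ = simulate_phenotypes(geno, None, cfg)
        est = he_heritability(geno, pheno["t"], pheno["t"])
        assert est.kind == "rg"
        assert est.estimate == pytest.approx(1.0, abs=1e-9)

    def test_out_of_range_flagged_not_clamped(self):
        rng = np.random.default_rng(3)
        dos = rng.integers(0, 3, size=(150, 50))
        est = he_heritability(dos, rng.normal(size=150))
        assert est.out_of_range == (not 0 <= est.estimate <= 1)


class TestBurdenCollapse:
    def _geno(self):
        # 4 subjects x 5 variants; last 4 variants are rare/annotated
        dosages = np.array([
            [2, 1, 0, 0, 1],
            [0, 0, 1, 0, 1],
            [1, 0, 0, 0, 0],
            [1, 0, 0, 1, 0],
        ])
        variants = pd.DataFrame({
            "chrom": "1", "pos": [100, 200, 300, 400, 500],
            "variant_id": [f"v{i}" for i in range(5)],
            "ref": "A", "alt": "G",
            "af": dosages.mean(axis=0) / 2,
            "is_lof": [False, True, True, True, False],
            "deleterious_all5": [False, False, False, False, True],
            "gene": ["g1", "g1", "g1", "g2", "g2"],
        })
        return GenotypeMatrix(dosages, variants, np.array(["s1", "s2", "s3", "s4"]))

    def test_singleton_mask_matches_loop_oracle(self):
        geno = self._geno()
        burden, carriers = burden_collapse(geno, "singleton")
        # oracle: per-subject loop over qualifying variants
        alt_counts = geno.dosages.sum(axis=0)
        for gene in burden.index:
            for si, subj in enumerate(geno.subject_ids):
                expected = sum(
                    geno.dosages[si, j]
                    for j in range(5)
                    if (geno.variants.loc[j, "gene"] == gene)
                    and (geno.variants.loc[j, "is_lof"]
                         or geno.variants.loc[j, "deleterious_all5"])
                    and alt_counts[j] == 1
                )
                assert burden.loc[gene, subj] == expected
                assert carriers.loc[gene, subj] == int(expected > 0)

    def test_singleton_lof_carrier_has_burden_one(self):
        geno = self._geno()
        burden, _ = burden_collapse(geno, "singleton")
        assert burden.loc["g1", "s2"] == 1.0  # v2: single alt allele, LoF

    def test_frequency_cutoff_strict(self):
        """A variant at af 0.005 qualifies under af<0.01 but not af<0.001."""
        rng = np.random.default_rng(4)
        n = 1000
        dosages = np.zeros((n, 1), dtype=int)
        dosages[rng.choice(n, 10, replace=False), 0] = 1  # af = 0.005
        variants = pd.DataFrame({"chrom": "1", "pos": [100], "variant_id": ["v"],
                                 "ref": "A", "alt": "G", "af": [0.005],
                                 "is_lof": [True], "deleterious_all5": [False],
                                 "gene": ["g"]})
        geno = GenotypeMatrix(dosages, variants, np.arange(n).astype(str))
        loose, _ = burden_collapse(geno, "af<0.01")
        assert loose.loc["g"].sum() == 10
        with pytest.warns(UserWarning, match="no qualifying"):
            tight, _ = burden_collapse(geno, "af<0.001")
        assert tight.empty

    def test_partially_deleterious_variant_never_qualifies(self):
        """Deleterious by 4 of 5 predictors (flag False) and not LoF is
        excluded from every mask."""
        geno = self._geno()
        var = geno.variants.copy()
        var.loc[4, "deleterious_all5"] = False  # now neither LoF nor del-all-5
        geno2 = GenotypeMatrix(geno.dosages, var, geno.subject_ids)
        with pytest.warns(UserWarning):
            burden, _ = burden_collapse(geno2, "af<0.01")
        assert "g2" not in burden.index or burden.loc["g2"].sum() == \
            geno.dosages[:, 3].sum()

    def test_unknown_mask_rejected(self):
        with pytest.raises(ValueError, match="mask"):
            burden_collapse(self._geno(), "af<0.5")


class TestBurdenTest:
    def test_planted_gene_effect_detected(self):
        """Carriers shifted by +0.8 SD put the planted gene at the smallest
        p-value and below FDR 5%."""
        cfg = SimConfig(n_subjects=4000, n_variants=400, seed=50)
        geno = simulate_genotypes(cfg, n_genes=20, rare_fraction=0.5, rare_af=2e-3)
        import warnings as _w
        with _w.catch_warnings():
            _w.simplefilter("ignore")
            burden, _ = burden_collapse(geno, "af<0.01")
        rng = np.random.default_rng(0)
        gene = burden.index[2]
        y = rng.normal(0, 1, 4000) + 0.8 * (burden.loc[gene].to_numpy() > 0)
        res = burden_test(burden, inverse_normal_transform(y))
        best = res.loc[res["p"].idxmin()]
        assert best["gene"] == gene and best["significant"]

    def test_all_zero_burden_missing(self):
        burden = pd.DataFrame([[0.0] * 200, [1.0] + [0.0] * 199],
                              index=["dead", "live"], columns=np.arange(200).astype(str))
        rng = np.random.default_rng(5)
        res = burden_test(burden, inverse_normal_transform(rng.normal(size=200)))
        assert np.isnan(res.set_index("gene").loc["dead", "p"])


class TestPrioritiseGenes:
    def _cands(self, rows):
        cols = ["locus", "gene", "is_mendelian_arrhythmia_or_cm", "pops_top3",
                "v2g_top3", "magma_sig", "nearest", "literature_support"]
        return pd.DataFrame(rows, columns=cols)

    def test_mendelian_gene_wins(self):
        cands = self._cands([
            ("L1", "SCN5A", True, False, False, False, False, False),
            ("L1", "OTHER", False, True, True, True, True, True),
        ])
        out = prioritise_genes(cands)
        assert list(out["gene"]) == ["SCN5A"]

    def test_multi_method_beats_single_method(self):
        cands = self._cands([
            ("L1", "A", False, True, True, False, False, False),
            ("L1", "B", False, False, True, False, True, False),
        ])
        out = prioritise_genes(cands)
        assert list(out["gene"]) == ["A"]

    def test_tie_resolved_by_literature(self):
        cands = self._cands([
            ("L1", "A", False, True, True, False, False, False),
            ("L1", "B", False, False, True, True, True, True),
        ])
        out = prioritise_genes(cands)
        assert list(out["gene"]) == ["B"]

    def test_tie_without_literature_falls_to_nearest(self):
        cands = self._cands([
            ("L1", "A", False, True, True, False, False, False),
            ("L1", "B", False, False, True, True, False, False),
            ("L1", "C", False, False, False, False, True, False),
        ])
        out = prioritise_genes(cands)
        assert list(out["gene"]) == ["C"]

    def test_no_flags_selects_nearest(self):
        cands = self._cands([
            ("L1", "A", False, False, False, False, False, False),
            ("L1", "B", False, False, False, False, True, False),
        ])
        out = prioritise_genes(cands)
        assert list(out["gene"]) == ["B"] and out["rule"].item() == "nearest"

    def test_multiple_literature_genes_all_selected(self):
        cands = self._cands([
            ("L1", "A", False, True, True, False, False, True),
            ("L1", "B", False, True, False, True, True, True),
        ])
        out = prioritise_genes(cands)
        assert set(out["gene"]) == {"A", "B"}

    def test_locus_without_nearest_rejected(self):
        cands = self._cands([("L1", "A", False, False, False, False, False, False)])
        with pytest.raises(ValueError, match="nearest"):
            prioritise_genes(cands)
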