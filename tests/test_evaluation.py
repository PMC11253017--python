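"""Cross-validation, correlation inference, and the two-tier significance rule."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from grainsel import (
    SNPEffectModel,
    corr_pvalue,
    cross_validate,
    fisher_ci,
    kfold_split,
    pearson_r,
    score_lines,
    significance_decision,
    simulate_panel,
    trait_correlation_matrix,
)

from conftest import make_config


class TestKFold:
    def test_study_design_fold_sizes(self):
        folds = kfold_split([f"l{i}" for i in range(149)], k=5, seed=1)
        assert sorted(folds.sizes().values()) == [29, 30, 30, 30, 30]

    def test_equal_folds(self):
        folds = kfold_split(list(range(10)), k=5, seed=0)
        assert set(folds.sizes().values()) == {2}

    def test_deterministic(self):
        a = kfold_split(list(range(50)), k=5, seed=42)
        b = kfold_split(list(range(50)), k=5, seed=42)
        assert np.array_equal(a.labels, b.labels)

    def test_k_exceeding_n_rejected(self):
        with pytest.raises(ValueError):
            kfold_split(list(range(4)), k=5, seed=0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(n=st.integers(5, 200), k=st.integers(2, 5), seed=st.integers(0, 99))
    def test_partition_properties(self, n, k, seed):
        if k > n:
            return
        folds = kfold_split(list(range(n)), k=k, seed=seed)
        sizes = list(folds.sizes().values())
        assert sum(sizes) == n
        assert max(sizes) - min(sizes) <= 1
        assert set(folds.labels) == set(range(1, k + 1))


def toy_model(snp_ids, alleles, others, coeffs, freqs):
    return SNPEffectModel(
        snp_ids=np.asarray(snp_ids, dtype=object),
        scored_allele=np.asarray(alleles, dtype=object),
        other_allele=np.asarray(others, dtype=object),
        coefficients=np.asarray(coeffs, dtype=float),
        frequencies=np.asarray(freqs, dtype=float),
        mu=0.0,
        n_train=10,
        sigma_g2=1.0,
        sigma_e2=1.0,
    )


class TestScoreLines:
    def test_two_snp_arithmetic(self, small_panel):
        panel = small_panel.subset(samples=[0], snps=[0, 1])
        panel.dosages[0] = [2.0, 1.0]
        model = toy_model(panel.snp_ids, panel.allele1, panel.allele2,
                          [0.5, -1.0], [0.3, 0.4])
        assert score_lines(model, panel)[0] == pytest.approx(0.0)

    def test_zero_coefficients_zero_scores(self, small_panel):
        model = toy_model(small_panel.snp_ids, small_panel.allele1,
                          small_panel.allele2, np.zeros(small_panel.n_snps),
                          np.full(small_panel.n_snps, 0.3))
        assert np.all(score_lines(model, small_panel) == 0.0)

    def test_allele_flip_handled(self, small_panel):
        panel = small_panel.subset(snps=[0, 1, 2])
        direct = toy_model(panel.snp_ids, panel.allele1, panel.allele2,
                           [1.0, 2.0, -0.5], [0.3, 0.3, 0.3])
        # same model expressed on the other allele: b' = -b, score shifts by 2*sum(b)
        flipped = toy_model(panel.snp_ids, panel.allele2, panel.allele1,
                            [-1.0, -2.0, 0.5], [0.7, 0.7, 0.7])
        s1 = score_lines(direct, panel)
        s2 = score_lines(flipped, panel)
        assert np.allclose(s1 - s2, 2 * (1.0 + 2.0 - 0.5))

    def test_missing_call_imputed_at_2p(self, small_panel):
        panel = small_panel.subset(samples=[0], snps=[0])
        panel.dosages[0, 0] = np.nan
        model = toy_model(panel.snp_ids, panel.allele1, panel.allele2, [1.0], [0.25])
        assert score_lines(model, panel)[0] == pytest.approx(0.5)

    def test_absent_snps_excluded_and_capped(self, small_panel):
        panel = small_panel.subset(snps=np.arange(10))
        ids = list(panel.snp_ids) + ["ghost1", "ghost2"]
        model = toy_model(ids, list(panel.allele1) + ["A", "A"],
                          list(panel.allele2) + ["G", "G"],
                          np.ones(12), np.full(12, 0.3))
        with pytest.warns(UserWarning, match="excluded"):
            score_lines(model, panel)
        mostly_ghost = toy_model(["g1", "g2", "g3"], "AAA", "GGG",
                                 np.ones(3), np.full(3, 0.3))
        with pytest.raises(ValueError, match="unusable"):
            score_lines(mostly_ghost, panel)


class TestCorrelationInference:
    def test_perfect_linear_relation(self):
        x = np.arange(10.0)
        assert pearson_r(x, 2 * x + 1) == pytest.approx(1.0)

    def test_orthogonal_pair(self):
        x = np.array([1.0, -1.0, 1.0, -1.0])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        assert pearson_r(x, y) == pytest.approx(0.0, abs=1e-12)

    def test_matches_sum_formula(self):
        rng = np.random.default_rng(3)
        x, y = rng.standard_normal((2, 30))
        n = 30
        num = n * (x * y).sum() - x.sum() * y.sum()
        den = np.sqrt(n * (x**2).sum() - x.sum() ** 2) * np.sqrt(
            n * (y**2).sum() - y.sum() ** 2
        )
        assert pearson_r(x, y) == pytest.approx(num / den, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            pearson_r(np.ones(5), np.arange(5.0))
        with pytest.raises(ValueError, match="length"):
            pearson_r(np.arange(4.0), np.arange(5.0))

    def test_fisher_ci_null_symmetry(self):
        lo, hi = fisher_ci(0.0, 30)
        half = np.tanh(1.959963984540054 / np.sqrt(27))
        assert lo == pytest.approx(-half, abs=1e-9)
        assert hi == pytest.approx(half, abs=1e-9)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(r=st.floats(-0.99, 0.99), n=st.integers(4, 500))
    def test_fisher_ci_contains_r(self, r, n):
        lo, hi = fisher_ci(r, n)
        assert -1 <= lo <= r <= hi <= 1

    def test_fisher_ci_degenerate_r(self):
        assert fisher_ci(1.0, 30) == (1.0, 1.0)

    def test_pvalue_null_and_monotonicity(self):
        assert corr_pvalue(0.0, 30) == pytest.approx(1.0)
        ps = [corr_pvalue(r, 30) for r in (0.1, 0.3, 0.5, 0.7, 0.9)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        assert corr_pvalue(-0.5, 30) == corr_pvalue(0.5, 30)

    def test_pvalue_matches_scipy_pearsonr(self):
        from scipy.stats import pearsonr

        rng = np.random.default_rng(8)
        x = rng.standard_normal(25)
        y = 0.4 * x + rng.standard_normal(25)
        res = pearsonr(x, y)
        assert corr_pvalue(pearson_r(x, y), 25) == pytest.approx(res.pvalue, rel=1e-9)

    def test_pvalue_degenerate_r(self):
        with pytest.warns(UserWarning):
            assert corr_pvalue(1.0, 30) == 0.0


class TestSignificanceRule:
    @pytest.mark.parametrize(
        "pvals,expected",
        [
            ((0.0005, 0.01, 0.02, 0.04, 0.03), True),
            ((0.0005, 0.06, 0.01, 0.01, 0.01), False),  # one >= nominal
            ((0.002, 0.002, 0.002, 0.002, 0.002), False),  # none < adjusted
        ],
    )
    def test_rule_cases(self, pvals, expected):
        assert significance_decision(pvals).significant is expected

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.lists(st.sampled_from([0.0005, 0.002, 0.01, 0.04, 0.06, 0.5]),
                    min_size=1, max_size=5))
    def test_matches_exhaustive_definition(self, pvals):
        v = significance_decision(pvals)
        assert v.significant == (min(pvals) < 0.001 and all(p < 0.05 for p in pvals))
        assert v.n_below_nominal == sum(p < 0.05 for p in pvals)
        assert v.n_below_adjusted == sum(p < 0.001 for p in pvals)


@pytest.fixture(scope="module")
def cv_dataset():
    cfg = make_config(n_lines=60, n_snps=150, n_traits=7, n_causal=30,
                      h2=0.6, seed=5)
    return simulate_panel(cfg)


class TestCrossValidate:
    def test_seven_traits_five_folds_is_35_models(self, cv_dataset):
        panel, phenos, _ = cv_dataset
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            report = cross_validate(panel, phenos, k=5, seed=2)
        assert len(report.folds) == 35
        assert set(report.folds["n_train"] + report.folds["n_test"]) == {60}
        assert ((report.folds["ci_low"] <= report.folds["r"])
                & (report.folds["r"] <= report.folds["ci_high"])).all()

    def test_deterministic_given_seed(self, cv_dataset):
        panel, phenos, _ = cv_dataset
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = cross_validate(panel, phenos, traits=["K"], k=4, seed=9)
            b = cross_validate(panel, phenos, traits=["K"], k=4, seed=9)
        assert a.folds.equals(b.folds)

    def test_no_leakage_from_test_phenotypes(self, cv_dataset):
        """Perturbing held-out phenotypes must not change the trained model."""
        panel, phenos, _ = cv_dataset
        from grainsel import PhenotypeTable
        from grainsel.evaluation import kfold_split

        folds = kfold_split(panel.sample_ids, k=4, seed=3)
        test_lines = set(panel.sample_ids[folds.fold_indices(1)])
        rec = phenos.records.copy()
        mask = rec["line_id"].isin(test_lines) & (rec["trait"] == "K")
        rec.loc[mask, "value"] += 1000.0
        perturbed = PhenotypeTable(records=rec)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, m1 = cross_validate(panel, phenos, traits=["K"], k=4, seed=3,
                                   return_models=True)
            _, m2 = cross_validate(panel, perturbed, traits=["K"], k=4, seed=3,
                                   return_models=True)
        np.testing.assert_array_equal(m1[("K", 1)].coefficients,
                                      m2[("K", 1)].coefficients)
        assert m1[("K", 1)].mu == m2[("K", 1)].mu

    def test_accuracy_increases_with_heritability(self):
        """Mean CV r under h2=0.8 beats h2=0.2 on matched panels."""
        def mean_r(h2, seed):
            cfg = make_config(n_lines=120, n_snps=240, n_traits=1, n_causal=30,
                              h2=h2, seed=seed)
            panel, phenos, _ = simulate_panel(cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                rep = cross_validate(panel, phenos, k=5, seed=seed)
            return rep.summary["mean_r"].iloc[0]

        high = [mean_r(0.8, s) for s in range(6)]
        low = [mean_r(0.2, s) for s in range(6)]
        assert np.mean(high) > np.mean(low)

    def test_accuracy_within_band_of_deterministic_formula(self):
        """Mean CV r sits in a generous band around the expectation
        r ~ sqrt(h2 n/(n + Me)) * sqrt(h2), Me from GRM eigenvalues."""
        from grainsel import PanelConfig, compute_grm

        obs, pred = [], []
        for seed in range(3):
            cfg = PanelConfig(n_lines=400, n_snps=800, n_chromosomes=4,
                              n_traits=1, n_causal=795, h2=0.5, ld_rho=0.6,
                              seed=seed)
            panel, phenos, _ = simulate_panel(cfg)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                grm = compute_grm(panel)
                lam = np.linalg.eigvalsh(grm.matrix)
                me = lam.sum() ** 2 / (lam**2).sum()
                n_train = 320
                pred.append(np.sqrt(0.5 * n_train / (n_train + me)) * np.sqrt(0.5))
                rep = cross_validate(panel, phenos, k=5, seed=seed)
            obs.append(rep.summary["mean_r"].iloc[0])
        assert 0.3 * np.mean(pred) <= np.mean(obs) <= 1.5 * np.mean(pred)

    def test_null_trait_accuracy_near_zero(self):
        cfg = make_config(n_lines=80, n_snps=160, n_traits=1, h2=0.0, seed=13)
        panel, phenos, _ = simulate_panel(cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            rep = cross_validate(panel, phenos, k=5, seed=13)
        assert abs(rep.summary["mean_r"].iloc[0]) < 0.45  # ~2 SE at n_test=16


class TestTraitCorrelations:
    def test_symmetric_unit_diagonal(self, cv_dataset):
        _, phenos, _ = cv_dataset
        corr = trait_correlation_matrix(phenos)
        assert np.allclose(corr.values, corr.values.T)
        assert np.allclose(np.diag(corr.values), 1.0)

    def test_independent_traits_weak_correlation(self):
        cfg = make_config(n_lines=149, n_snps=300, n_traits=2, n_causal=30,
                          pleiotropy_frac=0.0, h2=0.5, seed=4)
        panel, phenos, _ = simulate_panel(cfg)
        corr = trait_correlation_matrix(phenos, sample_ids=panel.sample_ids)
        assert abs(corr.iloc[0, 1]) < 0.2
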