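import numpy as np
import pandas as pd
import pytest
from scipy import stats

from crbnsplice.diffexpr import (
    bh_fdr,
    build_design,
    ebayes,
    fit_lm,
    log_cpm,
    run_de,
    voom_weights,
)
from crbnsplice.errors import ValidationError
from crbnsplice.io_formats import ExpressionMatrix
from crbnsplice.splice_classify import classify, TranscriptQuant
from crbnsplice.synthetic_data import (
    SimulationConfig,
    default_genes,
    make_regulon_db,
    simulate_cohorts,
)


def matrix(values, kind="log", genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples), kind)


def two_group_design(n_per_group):
    X = pd.DataFrame(
        {
            "intercept": 1.0,
            "group": [0.0] * n_per_group + [1.0] * n_per_group,
        },
        index=[f"s{j}" for j in range(2 * n_per_group)],
    )
    return X


class TestLogCpm:
    def test_formula(self):
        counts = matrix([[0], [999_999]], kind="counts")
        out = log_cpm(counts, prior_count=0.5)
        # libsize 999999 + 2*0.5 = 1e6; (0 + 0.5)/1e6 * 1e6 = 0.5
        assert out.data.iloc[0, 0] == pytest.approx(-1.0)

    def test_scale_invariance(self, rng):
        base = rng.integers(1, 1000, size=(50, 1)).astype(float)
        counts = matrix(np.hstack([base, 2 * base]), kind="counts")
        out = log_cpm(counts).values()
        np.testing.assert_allclose(out[:, 0], out[:, 1], rtol=0, atol=1e-3)

    def test_zero_prior_rejected(self):
        counts = matrix([[0], [5]], kind="counts")
        with pytest.raises(ValueError):
            log_cpm(counts, prior_count=0.0)

    def test_zero_library_size_names_sample(self):
        counts = matrix([[0, 1], [0, 2]], kind="counts")
        with pytest.raises(ValidationError, match="s0"):
            log_cpm(counts)

    def test_requires_counts(self):
        with pytest.raises(ValidationError):
            log_cpm(matrix([[1.0]], kind="log"))


class TestVoomWeights:
    def test_flat_trend_gives_near_constant_weights(self, rng):
        y = rng.normal(loc=rng.uniform(2, 10, size=(400, 1)), scale=1.0, size=(400, 30))
        design = two_group_design(15)
        w = voom_weights(matrix(y), design)
        assert w.max() / w.min() < 1.10

    def test_planted_decreasing_trend_is_monotone(self, rng):
        means = np.linspace(1.0, 16.0, 300)
        sd = means ** -0.5
        y = means[:, None] + rng.normal(size=(300, 40)) * sd[:, None]
        design = two_group_design(20)
        w = voom_weights(matrix(y), design)
        # weights grow with expression when sd falls with the mean
        gene_w = w.mean(axis=1)
        rho = stats.spearmanr(means, gene_w).statistic
        assert rho > 0.95

    def test_duplicated_gene_rows_get_identical_weights(self, rng):
        y = rng.normal(size=(20, 12))
        y = np.vstack([y, y[:1]])
        w = voom_weights(matrix(y), two_group_design(6))
        np.testing.assert_array_equal(w[0], w[-1])

    def test_too_few_genes_rejected(self, rng):
        with pytest.raises(ValidationError, match="10 genes"):
            voom_weights(matrix(rng.normal(size=(5, 12))), two_group_design(6))

    def test_more_design_columns_than_samples_rejected(self, rng):
        design = pd.DataFrame(
            np.eye(3), columns=["a", "b", "c"], index=["s0", "s1", "s2"]
        )
        y = matrix(rng.normal(size=(20, 3)))
        with pytest.raises(ValidationError):
            voom_weights(y, design)


class TestFitLm:
    def test_equal_group_means_give_zero_coefficient(self):
        y = np.tile([[1.0, 2.0, 1.0, 2.0]], (12, 1))
        fit = fit_lm(matrix(y), two_group_design(2))
        np.testing.assert_allclose(fit.coefficients[:, 1], 0.0, atol=1e-12)

    def test_coefficient_is_group_mean_difference(self, rng):
        y = rng.normal(size=(30, 16))
        fit = fit_lm(matrix(y), two_group_design(8))
        expected = y[:, 8:].mean(axis=1) - y[:, :8].mean(axis=1)
        np.testing.assert_allclose(fit.coefficients[:, 1], expected, atol=1e-10)

    def test_weight_scale_invariance(self, rng):
        y = rng.normal(size=(30, 16))
        w = rng.uniform(0.5, 2.0, size=y.shape)
        fit1 = fit_lm(matrix(y), two_group_design(8), w)
        fit2 = fit_lm(matrix(y), two_group_design(8), 2.0 * w)
        np.testing.assert_allclose(fit1.coefficients, fit2.coefficients, atol=1e-12)
        np.testing.assert_allclose(fit1.sigma2, fit2.sigma2, atol=1e-12)

    def test_rank_deficiency_lists_columns(self, rng):
        design = two_group_design(8)
        design["group_copy"] = design["group"]
        with pytest.raises(ValidationError, match="group"):
            fit_lm(matrix(rng.normal(size=(30, 16))), design)


class TestEbayes:
    def test_complete_pooling_limit(self, rng):
        y = rng.normal(size=(50, 20))
        fit = fit_lm(matrix(y), two_group_design(10))
        pooled = float(fit.sigma2.mean())
        table = ebayes(fit, prior_df=np.inf, prior_var=pooled)
        expected = fit.coefficients[:, 1] / (np.sqrt(pooled) * fit.stdev_unscaled[:, 1])
        np.testing.assert_allclose(table["t"].to_numpy(), expected, atol=1e-10)

    def test_no_moderation_limit_matches_ordinary_t(self, rng):
        y = rng.normal(size=(50, 20))
        fit = fit_lm(matrix(y), two_group_design(10))
        table = ebayes(fit, prior_df=0)
        t_ord = fit.coefficients[:, 1] / (
            np.sqrt(fit.sigma2) * fit.stdev_unscaled[:, 1]
        )
        np.testing.assert_allclose(table["t"].to_numpy(), t_ord, atol=1e-10)
        p_ord = 2 * stats.t.sf(np.abs(t_ord), df=fit.df_residual)
        np.testing.assert_allclose(table["p"].to_numpy(), p_ord, atol=1e-12)

    def test_null_gaussian_p_calibration(self, rng):
        y = rng.normal(size=(5000, 20))
        fit = fit_lm(matrix(y), two_group_design(10))
        table = ebayes(fit)
        frac = (table["p"] < 0.05).mean()
        assert 0.04 <= frac <= 0.06

    def test_gene_order_invariance(self, rng):
        y = rng.normal(size=(60, 16))
        m = matrix(y)
        perm = rng.permutation(60)
        m_perm = ExpressionMatrix(m.data.iloc[perm], "log")
        t1 = ebayes(fit_lm(m, two_group_design(8)))
        t2 = ebayes(fit_lm(m_perm, two_group_design(8)))
        pd.testing.assert_frame_equal(t1.loc[t2.index], t2)


class TestBhFdr:
    def test_worked_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_single_p(self):
        assert bh_fdr([0.5])[0] == 0.5

    def test_all_ones(self):
        np.testing.assert_array_equal(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    def test_monotone_along_sorted_p(self, rng):
        for _ in range(50):
            p = rng.uniform(size=rng.integers(2, 40))
            q = bh_fdr(p)
            order = np.argsort(p)
            assert np.all(np.diff(q[order]) >= -1e-15)
            assert np.all((q >= 0) & (q <= 1))


class TestEndToEnd:
    def test_logfc_slope_recovery(self):
        genes = default_genes(2000)
        db = make_regulon_db(genes, 1, 100, seed=42)
        config = SimulationConfig(
            n_cohorts=1,
            n_samples=200,
            n_genes=2000,
            prevalence_high=0.5,
            active_tfs={"TF001": 2.0},
            seed=7,
        )
        cohort = simulate_cohorts(config, db)[0]
        calls = classify(cohort.transcripts)
        de = run_de(cohort.counts, cohort.metadata, calls, ["batch"])
        truth = np.array([cohort.truth["log2fc"].get(g, 0.0) for g in de.index])
        slope = np.polyfit(truth, de["logFC"].to_numpy(), 1)[0]
        assert 0.9 <= slope <= 1.1

    def test_covariate_adjustment_removes_batch_signal(self, rng):
        # strong batch effect, no group effect: adjusted DE stays null
        config = SimulationConfig(
            n_cohorts=1,
            n_samples=60,
            n_genes=800,
            prevalence_high=0.3,
            batch_effect_log2=2.0,
            seed=13,
        )
        cohort = simulate_cohorts(config)[0]
        calls = classify(cohort.transcripts)
        de = run_de(cohort.counts, cohort.metadata, calls, ["batch"])
        assert (de["q"] < 0.05).sum() <= 5

    def test_design_requires_known_covariate(self):
        calls = classify([TranscriptQuant("s0", 1.0, 5.0, 0.9)])
        meta = pd.DataFrame(
            {"cohort": ["c"], "setting": ["NDMM"], "purity": [0.9]}, index=["s0"]
        )
        with pytest.raises(ValidationError, match="covariate"):
            build_design(meta, calls, ["nope"])
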