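"""Population model, error distributions, implied moments, reliability."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from modmedsem import popgen as pg


class TestPopulationSpec:
    def test_printed_parameterization(self):
        spec = pg.make_population_spec(pg.DesignCell(n=500, b3=0.2))
        assert spec.X.loadings.tolist() == [1.0, 0.65, 0.72]
        assert spec.M.loadings.tolist() == [1.0, 0.81, 0.53, 0.66]
        assert spec.Z.loadings.tolist() == [1.0, 0.83, 0.79]
        assert spec.Y.loadings.tolist() == [1.0, 0.68, 0.75, 0.83]
        for block in "XMZY":
            assert np.all(spec.block(block).intercepts == 0.5)
            assert np.all(spec.block(block).error_variances == 0.36)
        s = spec.structural
        assert (s.a, s.c, s.b1, s.b2, s.b3) == (0.75, 0.3, 0.56, 0.48, 0.2)
        assert s.var_X == s.var_Z == 1.0
        assert s.resid_var_M == s.resid_var_Y == 0.36

    def test_low_reliability_sets_indicator_error_variances(self):
        spec = pg.make_population_spec(
            pg.DesignCell(n=500, b3=0.2, reliability="low")
        )
        for block in "XMZY":
            assert np.all(spec.block(block).error_variances == 1.5)
        # structural residuals carry no reliability manipulation
        assert spec.structural.resid_var_M == 0.36
        assert spec.structural.resid_var_Y == 0.36

    def test_correlated_exogenous_latents(self):
        spec = pg.make_population_spec(pg.DesignCell(n=500, b3=0.2, cor_xz=0.3))
        assert spec.structural.cov_XZ == 0.3

    def test_nonnormal_types_apply_to_m_and_z_blocks_only(self):
        spec = pg.make_population_spec(
            pg.DesignCell(n=200, b3=0.2, distribution_type=5)
        )
        assert spec.M.error_distribution == "skewed_chisq1"
        assert spec.Z.error_distribution == "skewed_chisq1"
        assert spec.X.error_distribution == "normal"
        assert spec.Y.error_distribution == "normal"

    @pytest.mark.parametrize(
        "kwargs",
        [dict(n=123), dict(b3=0.7), dict(reliability="mid"),
         dict(distribution_type=9), dict(cor_xz=0.5)],
    )
    def test_cell_validation(self, kwargs):
        with pytest.raises(ValueError):
            pg.DesignCell(**kwargs)

    def test_spec_yaml_roundtrip(self, high_rel_spec, tmp_path):
        path = tmp_path / "spec.yaml"
        high_rel_spec.to_yaml(path)
        back = pg.PopulationSpec.from_yaml(path)
        assert np.allclose(back.M.loadings, high_rel_spec.M.loadings)
        assert back.structural == high_rel_spec.structural


class TestSampleError:
    def test_normal_variance(self):
        rng = np.random.default_rng(1)
        draws = pg.sample_error("normal", 0.36, 10**6, rng)
        assert draws.var() == pytest.approx(0.36, rel=0.01)
        assert draws.mean() == pytest.approx(0.0, abs=0.01)

    def test_uniform_centered_with_natural_variance(self):
        rng = np.random.default_rng(2)
        draws = pg.sample_error("uniform01", 0.36, 10**6, rng)
        assert draws.mean() == pytest.approx(0.0, abs=0.005)
        assert draws.var() == pytest.approx(1.0 / 12.0, rel=0.01)

    def test_chisq1_centered_skewness(self):
        # skewness of chi-square(1) is sqrt(8) ~ 2.83
        rng = np.random.default_rng(3)
        draws = pg.sample_error("skewed_chisq1", 0.36, 10**6, rng)
        assert draws.mean() == pytest.approx(0.0, abs=0.01)
        assert draws.var() == pytest.approx(2.0, rel=0.02)
        assert stats.skew(draws) == pytest.approx(np.sqrt(8.0), rel=0.05)

    @pytest.mark.parametrize("dist", ["symm_moderate_kurtosis", "symm_high_kurtosis"])
    def test_heavy_tail_types_hit_target_variance_and_are_symmetric(self, dist):
        rng = np.random.default_rng(4)
        draws = pg.sample_error(dist, 0.36, 10**6, rng)
        assert draws.var() == pytest.approx(0.36, rel=0.05)
        # heavy tails make moment-based skewness noisy; check the median too
        assert stats.skew(draws) == pytest.approx(0.0, abs=0.3)
        assert np.median(draws) == pytest.approx(0.0, abs=0.01)
        assert stats.kurtosis(draws) > 1.0  # leptokurtic

    def test_high_kurtosis_exceeds_moderate(self):
        rng = np.random.default_rng(5)
        k3 = stats.kurtosis(pg.sample_error("symm_moderate_kurtosis", 1.0, 10**6, rng))
        k4 = stats.kurtosis(pg.sample_error("symm_high_kurtosis", 1.0, 10**6, rng))
        assert k4 > k3 > 0

    def test_unknown_type_raises(self):
        with pytest.raises(ValueError):
            pg.sample_error("cauchy", 1.0, 10, np.random.default_rng(0))


class TestGenerateDataset:
    def test_sample_moments_match_population(self, high_rel_spec):
        rng = np.random.default_rng(6)
        ds = pg.generate_dataset(high_rel_spec, 100_000, rng)
        mean, cov = pg.population_moments(high_rel_spec)
        n = ds.n
        samp = ds.values.to_numpy()
        samp_mean = samp.mean(axis=0)
        samp_cov = np.cov(samp, rowvar=False)
        # every entry within 5 standard errors of its Monte-Carlo estimate
        se_mean = np.sqrt(np.diag(cov) / n)
        assert np.all(np.abs(samp_mean - mean) < 5 * se_mean)
        d = np.sqrt(np.diag(cov))
        se_cov = np.sqrt((np.outer(d, d) ** 2 + cov**2) / n)
        assert np.all(np.abs(samp_cov - cov) < 5 * se_cov)

    def test_var_m_and_independence_at_b3_zero(self):
        spec = pg.make_population_spec(pg.DesignCell(n=500, b3=0.0))
        ds = pg.generate_dataset(spec, 200_000, np.random.default_rng(7))
        m = ds.block("M").to_numpy() @ np.array([1, 0, 0, 0])  # m1 = 0.5 + M + err
        z1 = ds.values["z1"]
        # Var(M) = a^2 + 0.36 = 0.9225; Var(m1) adds error variance 0.36
        assert ds.values["m1"].var() == pytest.approx(0.9225 + 0.36, rel=0.02)
        assert ds.values["x1"].mean() == pytest.approx(0.5, abs=0.01)
        assert np.cov(m, z1)[0, 1] == pytest.approx(0.0, abs=0.015)

    def test_same_seed_bit_identical(self, high_rel_spec):
        a = pg.generate_dataset(high_rel_spec, 200, np.random.default_rng(8))
        b = pg.generate_dataset(high_rel_spec, 200, np.random.default_rng(8))
        assert a.values.equals(b.values)

    def test_csv_roundtrip(self, high_rel_spec, tmp_path):
        ds = pg.generate_dataset(high_rel_spec, 50, np.random.default_rng(9))
        path = tmp_path / "data.csv"
        ds.to_csv(path)
        back = pg.IndicatorDataset.from_csv(path)
        assert np.allclose(back.values, ds.values)


class TestPopulationMoments:
    def test_cross_block_entry_closed_form(self, high_rel_spec):
        _, cov = pg.population_moments(high_rel_spec)
        i, j = pg.COLUMNS.index("m1"), pg.COLUMNS.index("x1")
        # Cov(m1, x1) = lam_m1 * lam_x1 * a * Var(X) = 0.75
        assert cov[i, j] == pytest.approx(0.75, abs=1e-12)

    def test_latent_product_variance(self, high_rel_spec):
        _, lat_cov = pg.latent_moments(high_rel_spec.structural)
        # Var(MZ) = Var(M) Var(Z) + Cov(M,Z)^2 = 0.9225 under cor(X,Z)=0
        assert lat_cov[3, 3] == pytest.approx(0.9225, abs=1e-12)

    def test_symmetric_positive_definite(self, high_rel_spec):
        _, cov = pg.population_moments(high_rel_spec)
        assert np.allclose(cov, cov.T)
        assert np.all(np.linalg.eigvalsh(cov) > 0)

    def test_b3_zero_y_block_free_of_product_moments(self):
        s0 = pg.make_population_spec(pg.DesignCell(n=500, b3=0.0)).structural
        mean, lat_cov = pg.latent_moments(s0)
        assert lat_cov[3, 4] == 0.0  # Cov(MZ, Y) vanishes when b3 = 0
        assert mean[4] == 0.0

    def test_nonnormal_errors_rejected(self):
        spec = pg.make_population_spec(pg.DesignCell(n=200, b3=0.2, distribution_type=2))
        with pytest.raises(ValueError):
            pg.population_moments(spec)

    @given(
        a=st.floats(-1.5, 1.5), b3=st.floats(-0.6, 0.6),
        cov_xz=st.floats(-0.8, 0.8), resid=st.floats(0.05, 2.0),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_implied_covariance_always_positive_definite(self, a, b3, cov_xz, resid):
        s = pg.StructuralSpec(
            a=a, b1=0.5, b2=0.4, b3=b3, c=0.3,
            cov_XZ=cov_xz, resid_var_M=resid, resid_var_Y=resid,
        )
        _, lat_cov = pg.latent_moments(s)
        assert np.all(np.linalg.eigvalsh(lat_cov) > -1e-10)


class TestCronbachAlpha:
    # closed-form population alphas: (k/(k-1)) (1 - sum item var / var of sum)
    # X high: (3/2)(1 - 3.0209/6.6969) = 0.82337
    def test_x_block_closed_form(self, high_rel_spec):
        assert pg.population_alpha(high_rel_spec, "X") == pytest.approx(
            1.5 * (1 - 3.0209 / 6.6969), abs=1e-10
        )

    def test_m_block_closed_form(self, high_rel_spec):
        # Var(M) = 0.9225; item variances lam^2 * 0.9225 + 0.36
        lam = np.array([1.0, 0.81, 0.53, 0.66])
        item_vars = lam**2 * 0.9225 + 0.36
        total = lam.sum() ** 2 * 0.9225 + 4 * 0.36
        expected = (4 / 3) * (1 - item_vars.sum() / total)
        assert pg.population_alpha(high_rel_spec, "M") == pytest.approx(expected, abs=1e-10)
        assert expected == pytest.approx(0.837, abs=0.001)

    def test_identical_items_alpha_one(self):
        frame = np.tile(np.random.default_rng(0).normal(size=(100, 1)), (1, 14))
        ds = pg.IndicatorDataset(frame)
        assert pg.cronbach_alpha(ds, "X") == pytest.approx(1.0, abs=1e-10)

    def test_reliability_manipulation_monotone(self):
        rng = np.random.default_rng(10)
        hi = pg.generate_dataset(pg.make_population_spec(pg.DesignCell(n=500, b3=0.2)), 2000, rng)
        lo = pg.generate_dataset(
            pg.make_population_spec(pg.DesignCell(n=500, b3=0.2, reliability="low")), 2000, rng
        )
        for block in "XMZY":
            assert pg.cronbach_alpha(lo, block) < pg.cronbach_alpha(hi, block)

    def test_unknown_block_raises(self, dataset_n500):
        with pytest.raises(ValueError):
            pg.cronbach_alpha(dataset_n500, "Q")
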