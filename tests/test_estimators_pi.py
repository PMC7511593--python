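"""Product-indicator estimators: matching, constraints, CPI/UPI fits."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from modmedsem import popgen as pg
from modmedsem.estimators_pi import (
    ProductPairing,
    build_product_indicators,
    build_sem_model,
    cpi_constraint_fn,
    fit_cpi,
    fit_upi,
    match_indicators,
)
from modmedsem.sem_core import implied_moments


class TestMatching:
    def test_population_loadings_pairing(self):
        pairing = match_indicators([1.0, 0.81, 0.53, 0.66], [1.0, 0.83, 0.79])
        assert pairing.pairs == [("m1", "z1"), ("m2", "z2"), ("m4", "z3")]
        assert pairing.unmatched == ["m3"]

    def test_equal_loadings_tie_by_index(self):
        pairing = match_indicators([1.0, 1.0, 1.0, 1.0], [1.0, 1.0, 1.0])
        assert pairing.pairs == [("m1", "z1"), ("m2", "z2"), ("m3", "z3")]

    def test_single_indicator_factors(self):
        pairing = match_indicators([1.0], [1.0], m_names=("m1",), z_names=("z1",))
        assert pairing.pairs == [("m1", "z1")]

    def test_duplicate_indicator_rejected(self):
        with pytest.raises(ValueError):
            ProductPairing(pairs=[("m1", "z1"), ("m1", "z2")])

    @given(
        lm=st.lists(st.floats(0.1, 2.0), min_size=1, max_size=4),
        lz=st.lists(st.floats(0.1, 2.0), min_size=1, max_size=3),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_pair_count_and_uniqueness(self, lm, lz):
        m_names = tuple(f"m{i+1}" for i in range(len(lm)))
        z_names = tuple(f"z{i+1}" for i in range(len(lz)))
        pairing = match_indicators(lm, lz, m_names=m_names, z_names=z_names)
        assert len(pairing.pairs) == min(len(lm), len(lz))
        flat = [name for pair in pairing.pairs for name in pair]
        assert len(flat) == len(set(flat))


class TestProductIndicators:
    def test_raw_products(self):
        frame = pd.DataFrame(np.zeros((3, 14)), columns=list(pg.COLUMNS))
        frame["m1"] = 2.0
        frame["z1"] = 3.0
        pairing = ProductPairing(pairs=[("m1", "z1")])
        aug = build_product_indicators(pg.IndicatorDataset(frame), pairing, centering=False)
        assert np.allclose(aug["mz1"], 6.0)

    def test_centered_product_mean_is_sample_covariance(self, dataset_n500):
        pairing = ProductPairing(pairs=[("m1", "z1")])
        aug = build_product_indicators(dataset_n500, pairing, centering=True)
        cov = np.cov(dataset_n500.values["m1"], dataset_n500.values["z1"], ddof=0)[0, 1]
        assert aug["mz1"].mean() == pytest.approx(cov, abs=1e-12)

    def test_centered_products_near_zero_mean_when_uncorrelated(self):
        # cor(X,Z)=0 and b3=0 make Cov(M,Z)=0, so centered products average ~0
        spec = pg.make_population_spec(pg.DesignCell(n=1000, b3=0.0))
        ds = pg.generate_dataset(spec, 100_000, np.random.default_rng(17))
        pairing = match_indicators(spec.M.loadings, spec.Z.loadings)
        aug = build_product_indicators(ds, pairing)
        for k in range(1, 4):
            assert abs(aug[f"mz{k}"].mean()) < 0.02


class TestCpiConstraints:
    BASE = {
        "lam_m1": 1.0, "lam_z1": 1.0, "th_m1": 0.36, "th_z1": 0.36,
        "a": 0.75, "var_x": 1.0, "var_z": 1.0, "cov_xz": 0.0, "resid_m": 0.36,
    }

    def test_loading_product(self):
        out = cpi_constraint_fn(self.BASE, [("m1", "z1")])
        assert out["lam_mz1"] == pytest.approx(1.0)

    def test_error_variance_composition(self):
        # 1 * 0.9225 * 0.36 + 1 * 1 * 0.36 + 0.36^2 = 0.8217
        out = cpi_constraint_fn(self.BASE, [("m1", "z1")])
        assert out["th_mz1"] == pytest.approx(0.8217, abs=1e-10)

    def test_latent_product_mean_under_correlation(self):
        base = {**self.BASE, "cov_xz": 0.3}
        out = cpi_constraint_fn(base, [("m1", "z1")])
        assert out["mean_mz"] == pytest.approx(0.225)
        assert out["var_mz"] == pytest.approx(0.9225 * 1.0 + 0.225**2)

    def test_negative_variance_rejected(self):
        base = {**self.BASE, "th_m1": -0.1}
        with pytest.raises(ValueError):
            cpi_constraint_fn(base, [("m1", "z1")])


class TestModelStructure:
    def test_upi_frees_products_and_interaction_covariances(self):
        pairing = match_indicators([1.0, 0.81, 0.53, 0.66], [1.0, 0.83, 0.79])
        cpi = build_sem_model(pairing, constrained=True)
        upi = build_sem_model(pairing, constrained=False)
        freed = set(upi.param_names) - set(cpi.param_names)
        # 2 product loadings (one fixed for scale), 3 product error variances,
        # Var(MZ), and the two free MZ covariances
        assert freed == {
            "lam_mz2", "lam_mz3", "th_mz1", "th_mz2", "th_mz3",
            "var_mz", "cov_x_mz", "cov_z_mz",
        }

    def test_cpi_implied_constraints_hold_at_any_point(self, population_theta):
        # the constrained model's product parameters obey the composition
        # rules exactly, by construction, at the population point
        spec = pg.make_population_spec(pg.DesignCell(n=500, b3=0.2))
        pairing = match_indicators(spec.M.loadings, spec.Z.loadings)
        model = build_sem_model(pairing, constrained=True)
        theta = population_theta(spec, model.param_names)
        mm = model.constraint_fn(theta)
        # product loadings occupy the last 3 rows, latent MZ is column 3
        lam_mz = mm.lam[-3:, 3]
        expected = [1.0 * 1.0, 0.81 * 0.83, 0.66 * 0.79]
        assert np.allclose(lam_mz, expected)
        var_m = 0.75**2 + 0.36
        assert mm.psi[3, 3] == pytest.approx(var_m * 1.0)  # Eq-9 composition
        assert mm.alpha[3] == pytest.approx(0.0)  # a * cov_xz with cov 0
        th_mz1 = 1.0 * var_m * 0.36 + 1.0 * 1.0 * 0.36 + 0.36 * 0.36
        assert mm.theta[-3] == pytest.approx(th_mz1)

    def test_cpi_implied_moments_match_population_oracle(self, population_theta):
        # at the population values the 14x14 sub-block of the CPI-implied
        # covariance equals the generator's closed-form moments
        spec = pg.make_population_spec(pg.DesignCell(n=500, b3=0.2))
        pairing = match_indicators(spec.M.loadings, spec.Z.loadings)
        model = build_sem_model(pairing, constrained=True)
        theta = population_theta(spec, model.param_names)
        mu, sigma = implied_moments(model, theta)
        pmu, pcov = pg.population_moments(spec)
        assert np.max(np.abs(mu[:14] - pmu)) < 1e-10
        assert np.max(np.abs(sigma[:14, :14] - pcov)) < 1e-10


class TestFits:
    def test_cpi_and_upi_recover_population_paths(self):
        spec = pg.make_population_spec(pg.DesignCell(n=500, b3=0.2))
        ds = pg.generate_dataset(spec, 20_000, np.random.default_rng(18))
        for fn in (fit_cpi, fit_upi):
            fit, eff = fn(ds, compute_se=True)
            assert fit.converged and fit.proper_solution
            for name, truth in (("a", 0.75), ("b1", 0.56), ("b3", 0.2)):
                assert abs(fit.estimates[name] - truth) < 3 * fit.se[name], (
                    fn.__name__, name,
                )
            assert eff.index == pytest.approx(
                fit.estimates["a"] * fit.estimates["b3"]
            )

    def test_derived_effects_use_latent_moderator_sd(self, dataset_n500):
        fit, eff = fit_cpi(dataset_n500)
        assert eff.sd_moderator == pytest.approx(
            np.sqrt(fit.estimates["var_z"])
        )
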