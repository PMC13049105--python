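"""Hierarchical community x pH model: structure, sampling, decision rule."""

import numpy as np
import pandas as pd
import pytest

from ventflux.hierarchical import (
    COMMUNITY_LEVELS,
    PH_LEVELS,
    CommunityResponseModel,
    CommunityResponseResults,
    ModelError,
    ModelSpec,
    build_zeta,
    invert_zeta,
    meaningful_effect,
    retained_draws,
)


def simulate_gaussian(rng, beta=1.0, sigz=(0.4, 0.1), rho=0.3, noise=0.3,
                      tiles=6, times=(0, 7, 30, 120)):
    sigz = np.asarray(sigz)
    delta = rng.standard_normal((9, 2))
    zeta = build_zeta(delta, sigz, np.asarray(rho))
    rows = []
    for ci, comm in enumerate(COMMUNITY_LEVELS):
        for pi, ph in enumerate(PH_LEVELS):
            cell = ci * 3 + pi
            for _ in range(tiles):
                for t in times:
                    mu = beta + zeta[cell, 0] + zeta[cell, 1] * t
                    rows.append(dict(community=comm, ph_zone=ph, time_days=t,
                                     response=mu + noise * rng.standard_normal()))
    return pd.DataFrame(rows), zeta


class TestBookkeeping:
    def test_study_plan_retains_32000_draws(self):
        """Four chains of 10,000 iterations with 2,000 warm-up keep 32,000."""
        assert retained_draws(4, 10_000, 2_000) == 32_000

    def test_warmup_must_be_smaller(self):
        with pytest.raises(ModelError):
            retained_draws(4, 1000, 1000)

    def test_cell_index_layout(self):
        spec = ModelSpec("gaussian")
        assert spec.n_cells == 9
        assert spec.cell_index("calcifying", "ambient") == 0
        assert spec.cell_index("fleshy", "extreme_low") == 8
        with pytest.raises(ModelError):
            spec.cell_index("fleshy", "nope")


class TestZetaFactorisation:
    def test_zero_sigma_collapses_effects(self):
        delta = np.ones((9, 2))
        zeta = build_zeta(delta, np.array([0.0, 0.0]), np.array(0.0))
        assert np.all(zeta == 0.0)

    def test_identity_correlation_unit_sigma_gives_delta(self, rng):
        delta = rng.standard_normal((9, 2))
        zeta = build_zeta(delta, np.array([1.0, 1.0]), np.array(0.0))
        np.testing.assert_allclose(zeta, delta, atol=1e-15)

    def test_build_invert_roundtrip_exact(self, rng):
        delta = rng.standard_normal((9, 2))
        sigz = np.array([0.7, 0.2])
        rho = np.array(0.45)
        zeta = build_zeta(delta, sigz, rho)
        np.testing.assert_allclose(invert_zeta(zeta, sigz, rho), delta,
                                   atol=1e-12)


class TestMeaningfulEffect:
    def test_disjoint_point_masses(self):
        assert meaningful_effect(np.ones(100), np.full(100, 2.0)) is True

    def test_identical_draws_overlap(self):
        draws = np.random.default_rng(0).normal(size=200)
        assert meaningful_effect(draws, draws) is False

    def test_touching_endpoints_count_as_overlap(self):
        a = np.linspace(0.0, 1.0, 101)  # 75% interval [0.125, 0.875]
        b = a + 0.75                    # 75% interval [0.875, 1.625]
        assert meaningful_effect(a, b) is False
        assert meaningful_effect(np.full(50, 1.0), np.full(50, 1.0)) is False
        assert meaningful_effect(a, a + 10.0) is True


class TestModelValidation:
    def test_missing_columns_rejected(self):
        with pytest.raises(ModelError, match="missing"):
            CommunityResponseModel(pd.DataFrame({"response": [1.0]}))

    def test_weibull_requires_positive_response(self, rng):
        df, _ = simulate_gaussian(rng)
        df.loc[0, "response"] = -0.1
        with pytest.raises(ModelError, match="positive"):
            CommunityResponseModel(df, family="weibull")

    def test_unknown_family_rejected(self):
        with pytest.raises(ModelError):
            ModelSpec("lognormal")

    def test_seed_mandatory(self, rng):
        df, _ = simulate_gaussian(rng)
        with pytest.raises(ModelError, match="seed"):
            CommunityResponseModel(df).fit(chains=2, iterations=100, warmup=10)


class TestSampling:
    @pytest.fixture(scope="class")
    def fitted(self):
        rng = np.random.default_rng(7)
        df, zeta = simulate_gaussian(rng)
        model = CommunityResponseModel(df, family="gaussian")
        res = model.fit(chains=2, iterations=1200, warmup=300, seed=11)
        return df, zeta, model, res

    def test_retained_draw_bookkeeping(self, fitted):
        _, _, _, res = fitted
        assert res.n_retained == 2 * (1200 - 300)

    def test_seeded_reproducibility(self, fitted):
        df, _, _, res = fitted
        res2 = CommunityResponseModel(df, family="gaussian").fit(
            chains=2, iterations=1200, warmup=300, seed=11)
        np.testing.assert_array_equal(res.draws, res2.draws)

    def test_slopes_recovered_within_credible_intervals(self, fitted):
        _, zeta, _, res = fitted
        covered = 0
        for ci, comm in enumerate(COMMUNITY_LEVELS):
            for pi, ph in enumerate(PH_LEVELS):
                cell = ci * 3 + pi
                lo, hi = res.credible_interval(
                    res.cell_draws(comm, ph, "slope"), 0.95)
                covered += lo <= zeta[cell, 1] <= hi
        assert covered >= 7  # 9 cells, allow ordinary MC slack

    def test_factorisation_identity_holds_on_draws(self, fitted):
        _, _, _, res = fitted
        rebuilt = build_zeta(res.delta, res.sigma_zeta, res.rho)
        np.testing.assert_allclose(rebuilt, res.zeta, atol=1e-10)

    def test_summary_table_complete(self, fitted):
        _, _, _, res = fitted
        table = res.summary()
        assert "beta" in table.index
        assert {"ci75_low", "ci95_high", "r_hat"} <= set(table.columns)
        assert table["r_hat"].notna().all()

    def test_bayes_r2_in_unit_interval(self, fitted):
        _, _, _, res = fitted
        assert 0.0 <= res.bayes_r2() <= 1.0

    def test_fitted_quantity_effect_rule(self, fitted):
        _, zeta, _, res = fitted
        # the two cells with the most different true slopes must separate
        slopes = zeta[:, 1]
        hi_cell, lo_cell = int(np.argmax(slopes)), int(np.argmin(slopes))
        names = [(c, p) for c in COMMUNITY_LEVELS for p in PH_LEVELS]
        a = res.cell_draws(*names[hi_cell], "slope")
        b = res.cell_draws(*names[lo_cell], "slope")
        assert res.meaningful_effect(a, b, 0.75) is True


class TestWeibullFamily:
    def test_weibull_fit_recovers_location(self):
        import math

        rng = np.random.default_rng(3)
        k = 4.0
        rows = []
        for ci, comm in enumerate(COMMUNITY_LEVELS):
            for pi, ph in enumerate(PH_LEVELS):
                for _ in range(6):
                    for t in (0, 7, 30, 120):
                        mean = np.exp(0.2 - 0.004 * t)
                        lam = mean / math.gamma(1 + 1 / k)
                        rows.append(dict(community=comm, ph_zone=ph,
                                         time_days=t,
                                         response=lam * rng.weibull(k)))
        df = pd.DataFrame(rows)
        res = CommunityResponseModel(df, family="weibull").fit(
            chains=2, iterations=1200, warmup=300, seed=5)
        lo, hi = res.credible_interval(res.beta, 0.95)
        assert lo < 0.2 < hi or abs(res.beta.mean() - 0.2) < 0.25
        assert 0.0 <= res.bayes_r2() <= 1.0


class TestConvergence:
    def _fake_results(self, chain_offset=0.0):
        rng = np.random.default_rng(0)
        df, _ = simulate_gaussian(rng, tiles=1, times=(0, 1))
        model = CommunityResponseModel(df)
        draws = rng.standard_normal((2, 400, model.ndim)) * 0.1
        draws[1, :, :] += chain_offset
        draws[..., 19:21] = -1.0  # log sigma_zeta kept sane
        draws[..., 22] = 0.0
        return CommunityResponseResults(model=model, draws=draws, chains=2,
                                        iterations=500, warmup=100, seed=0)

    def test_well_mixed_chains_pass(self):
        passed, offending = self._fake_results(0.0).convergence_check()
        assert passed, offending

    def test_disjoint_chains_fail(self):
        passed, offending = self._fake_results(50.0).convergence_check()
        assert not passed and len(offending) > 0

    def test_threshold_monotone(self):
        res = self._fake_results(0.02)
        loose_pass, _ = res.convergence_check(threshold=1.5)
        strict_pass, strict_off = res.convergence_check(threshold=1.0001)
        assert loose_pass and not strict_pass and strict_off

    def test_single_chain_rhat_undefined(self):
        res = self._fake_results(0.0)
        res.chains = 1
        with pytest.raises(ModelError):
            res.rhat()


class TestBayesR2Limits:
    def _results_with(self, slopes_zero: bool, sigma: float):
        rng = np.random.default_rng(1)
        df, _ = simulate_gaussian(rng, tiles=2, times=(0, 10))
        model = CommunityResponseModel(df)
        draws = np.zeros((2, 50, model.ndim))
        draws[..., 0] = 1.0  # beta
        if not slopes_zero:
            draws[..., 2:20:2] = 0.05  # slope columns
        draws[..., 19:21] = -1.0
        draws[..., 22] = np.log(sigma)
        return CommunityResponseResults(model=model, draws=draws, chains=2,
                                        iterations=60, warmup=10, seed=0)

    def test_constant_fitted_values_give_zero(self):
        assert self._results_with(True, 1.0).bayes_r2() == pytest.approx(0.0)

    def test_vanishing_residual_variance_gives_one(self):
        assert self._results_with(False, 1e-8).bayes_r2() == pytest.approx(1.0, abs=1e-6)
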