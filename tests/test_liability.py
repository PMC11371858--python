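"""Covariance algebra, pattern probabilities and the log-likelihood."""

import math
from dataclasses import replace

import numpy as np
import pytest

from twinace.liability import (
    BivariateACEParams,
    decomposed_correlations,
    expected_covariance,
    implied_rp,
    loglik,
    os_cross_covariance,
    pattern_probability,
    predicted_threshold,
    predicted_prevalence,
)


class TestExpectedCovariance:
    def test_cross_twin_same_trait_arithmetic(self):
        p = BivariateACEParams(0, 0, 0.5, 0.3, 0.2, 0.4, 0.3, 0.3,
                               0.1, 0.1, 0.1)
        mz = expected_covariance(p, "MZ")
        dz = expected_covariance(p, "DZ_SS")
        assert mz[0, 2] == pytest.approx(0.8)
        assert dz[0, 2] == pytest.approx(0.55)
        assert np.all(np.diag(mz) == 1.0)

    def test_zero_cross_components_block_diagonal(self):
        p = BivariateACEParams(0, 0, 0.5, 0.3, 0.2, 0.4, 0.3, 0.3,
                               0.0, 0.0, 0.0)
        mz = expected_covariance(p, "MZ")
        assert mz[0, 1] == mz[0, 3] == mz[1, 2] == 0.0

    def test_cross_twin_cross_trait_closed_form(self, pooled_params):
        # cov_a + cov_c = 0.74*sqrt(.47*.28) + 0.47*sqrt(.34*.51)
        mz = expected_covariance(pooled_params, "MZ")
        expected = (0.74 * math.sqrt(0.47 * 0.28)
                    + 0.47 * math.sqrt(0.34 * 0.51))
        assert mz[0, 3] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.464, abs=5e-4)

    def test_mz_minus_dz_is_half_a_structure(self, pooled_params):
        p = pooled_params
        diff = (expected_covariance(p, "MZ")
                - expected_covariance(p, "DZ_SS"))
        a_block = np.array([[p.a_rsi, p.cov_a], [p.cov_a, p.a_ci]])
        assert np.allclose(diff[:2, 2:], 0.5 * a_block)
        assert np.allclose(diff[:2, :2], 0.0)

    def test_non_pd_covariance_names_eigenvalue(self):
        p = BivariateACEParams(0, 0, 0.9, 0.1, 0.0, 0.9, 0.1, 0.0,
                               0.0, 0.0, 0.99)
        with pytest.raises(ValueError, match="eigenvalue"):
            expected_covariance(p, "MZ")


class TestOSCrossCovariance:
    def test_equal_sexes_reduce_to_dz_block(self, pooled_params):
        p = pooled_params
        block = os_cross_covariance(p, p)
        dz = expected_covariance(p, "DZ_SS")
        assert np.allclose(block, dz[:2, 2:])

    def test_geometric_mean_bridging(self):
        pm = BivariateACEParams(0, 0, 0.4, 0.0, 0.6, 0.4, 0.0, 0.6, 0, 0, 0)
        pf = BivariateACEParams(0, 0, 0.9, 0.0, 0.1, 0.9, 0.0, 0.1, 0, 0, 0)
        block = os_cross_covariance(pm, pf)
        assert block[0, 0] == pytest.approx(0.5 * 0.6)  # 0.5*sqrt(.4*.9)

    def test_negative_component_falls_back_to_arithmetic(self, caplog):
        pm = BivariateACEParams(0, 0, -0.06, 0.5, 0.56, 0.3, 0.3, 0.4,
                                0, 0, 0)
        pf = BivariateACEParams(0, 0, 0.54, 0.2, 0.26, 0.3, 0.3, 0.4,
                                0, 0, 0)
        import twinace.liability as lb
        lb._BRIDGE_WARNED.clear()
        with caplog.at_level("WARNING"):
            block = os_cross_covariance(pm, pf)
        # 0.5 * arithmetic mean of (-0.06, 0.54) + sqrt(0.5*0.2)
        assert block[0, 0] == pytest.approx(
            0.5 * 0.24 + math.sqrt(0.1), abs=1e-12)
        assert any("arithmetic mean" in r.message for r in caplog.records)


class TestPatternProbability:
    def test_independent_traits_quarter_power(self, e_only_params):
        p = pattern_probability(e_only_params, "MZ", [1, 1, 1, 1])
        assert p == pytest.approx(0.0625, abs=1e-9)

    def test_sixteen_patterns_sum_to_one(self, pooled_params):
        total = sum(
            pattern_probability(pooled_params, zyg,
                                [(m >> j) & 1 for j in range(4)])
            for zyg in ("MZ",) for m in range(16))
        assert total == pytest.approx(1.0, abs=1e-6)

    def test_missing_dims_marginalize_exactly(self, pooled_params):
        # summing over a twin's patterns equals dropping that twin
        p_marg = pattern_probability(pooled_params, "MZ",
                                     [1, 0, None, None])
        p_sum = sum(pattern_probability(pooled_params, "MZ", [1, 0, a, b])
                    for a in (0, 1) for b in (0, 1))
        assert p_marg == pytest.approx(p_sum, abs=1e-8)

    def test_monotone_decreasing_in_threshold(self, pooled_params):
        probs = [pattern_probability(replace(pooled_params, tau_rsi=t),
                                     "MZ", [1, 1, 1, 1])
                 for t in (-1.0, -0.3, 0.2, 0.9, 1.7)]
        assert all(a > b for a, b in zip(probs, probs[1:]))

    def test_matches_monte_carlo_orthant_oracle(self, pooled_params):
        cov = expected_covariance(pooled_params, "MZ")
        rng = np.random.default_rng(314)
        hits = 0
        n = 10_000_000
        tau = np.array([pooled_params.tau_rsi, pooled_params.tau_ci] * 2)
        for _ in range(10):
            z = rng.multivariate_normal(np.zeros(4), cov, size=n // 10)
            hits += int(np.all(z > tau, axis=1).sum())
        mc = hits / n
        exact = pattern_probability(pooled_params, "MZ", [1, 1, 1, 1])
        assert exact == pytest.approx(mc, abs=4 * math.sqrt(mc / n) + 1e-4)

    def test_age_slope_shifts_threshold(self, pooled_params):
        p = replace(pooled_params, beta_rsi=0.02)
        young = pattern_probability(p, "MZ", [1, None, None, None], age=20,
                                    age_ref=30)
        old = pattern_probability(p, "MZ", [1, None, None, None], age=40,
                                  age_ref=30)
        assert old > young


class TestLoglik:
    def test_single_pair_closed_form(self, e_only_params):
        from twinace.data import TwinObs, TwinPairRecord
        rec = TwinPairRecord("p1", "MZ", "g", TwinObs("F", 30, 1, 1),
                             TwinObs("F", 30, 1, 1))
        ll = loglik({"g": e_only_params}, [rec])
        assert ll == pytest.approx(math.log(0.0625), abs=1e-9)

    def test_additivity_under_duplication(self, pooled_params, small_study):
        ll1 = loglik({"sim": pooled_params}, small_study)
        ll2 = loglik({"sim": pooled_params}, small_study + small_study)
        assert ll2 == pytest.approx(2 * ll1, rel=1e-12)

    def test_aggregated_equals_pairwise_sum(self, pooled_params):
        from twinace import simulate_pairs
        recs = simulate_pairs(pooled_params, n_mz=500, n_dz_ss=500,
                              seed=55, missing_rate=0.1, n_singletons=30)
        ll = loglik({"sim": pooled_params}, recs)
        brute = 0.0
        for r in recs:
            t2 = r.twin2
            pattern = [r.twin1.rsi, r.twin1.ci,
                       None if t2 is None else t2.rsi,
                       None if t2 is None else t2.ci]
            brute += math.log(pattern_probability(
                pooled_params, r.zygosity, pattern))
        assert ll == pytest.approx(brute, abs=1e-8)

    def test_invariant_to_twin_order_within_pair(self, pooled_params,
                                                 small_study):
        from twinace.data import TwinPairRecord
        swapped = [TwinPairRecord(r.pair_id, r.zygosity, r.group,
                                  r.twin2, r.twin1)
                   for r in small_study]
        assert loglik({"sim": pooled_params}, swapped) == pytest.approx(
            loglik({"sim": pooled_params}, small_study), abs=1e-8)

    def test_e_only_equals_univariate_probit_sum(self, e_only_params):
        from twinace import simulate_pairs
        from scipy.stats import norm
        p = replace(e_only_params, tau_rsi=0.3, tau_ci=-0.4)
        recs = simulate_pairs(p, n_mz=300, n_dz_ss=300, seed=8)
        ll = loglik({"sim": p}, recs)
        probit = 0.0
        for r in recs:
            for t in (r.twin1, r.twin2):
                for trait, tau in (("rsi", 0.3), ("ci", -0.4)):
                    y = getattr(t, trait)
                    pr = 1 - norm.cdf(tau)
                    probit += math.log(pr if y == 1 else 1 - pr)
        assert ll == pytest.approx(probit, rel=1e-9)

    def test_unknown_group_lists_pair_ids(self, pooled_params, small_study):
        with pytest.raises(ValueError, match="pair ids"):
            loglik({"other": pooled_params}, small_study)


class TestDerivedQuantities:
    def test_implied_rp_pooled_estimates(self, pooled_params):
        assert round(implied_rp(pooled_params), 2) == 0.56

    def test_rp_equals_r_under_homogeneity(self):
        p = BivariateACEParams.from_components(
            tau=(0, 0), a=(0.4, 0.4), c=(0.3, 0.3),
            r_a=0.6, r_c=0.6, r_e=0.6)
        assert implied_rp(p) == pytest.approx(0.6, abs=1e-12)

    def test_zero_cross_components_zero_rp(self, e_only_params):
        assert implied_rp(e_only_params) == 0.0

    def test_decomposed_simple_ratio(self):
        p = BivariateACEParams(0, 0, 0.5, 0.2, 0.3, 0.5, 0.2, 0.3,
                               0.25, 0.1, 0.1)
        assert decomposed_correlations(p)["rA"] == pytest.approx(0.5)

    def test_negative_component_gives_na(self):
        p = BivariateACEParams(0, 0, 0.5, 0.2, 0.3, -0.06, 0.7, 0.36,
                               0.1, 0.1, 0.1)
        assert math.isnan(decomposed_correlations(p)["rA"])

    def test_boundary_correlation_is_one(self):
        a1, a2 = 0.5, 0.3
        p = BivariateACEParams(0, 0, a1, 0.2, 0.3, a2, 0.4, 0.3,
                               math.sqrt(a1 * a2), 0.0, 0.0)
        assert decomposed_correlations(p)["rA"] == pytest.approx(1.0)

    def test_predicted_threshold_linear_in_age(self, pooled_params):
        p = replace(pooled_params, beta_rsi=0.02)
        base = predicted_threshold(p, "rsi", 30.0, age_ref=30.0)
        assert base == pytest.approx(p.tau_rsi)
        assert predicted_threshold(p, "rsi", 40.0, age_ref=30.0) == \
            pytest.approx(p.tau_rsi - 0.2)

    def test_threshold_roundtrip_against_age_stratum(self, pooled_params):
        # simulate with an age effect; empirical prevalence in an age
        # band matches the model-implied prevalence at that age
        from twinace import simulate_pairs
        from twinace.simulate import AgeDistribution
        p = replace(pooled_params, beta_rsi=0.03)
        recs = simulate_pairs(
            p, n_mz=20000, n_dz_ss=20000, seed=23,
            age_distribution=AgeDistribution("uniform", 20, 50),
            age_ref=35.0)
        hits = tot = 0
        for r in recs:
            if 24.0 <= r.twin1.age <= 26.0:
                for t in (r.twin1, r.twin2):
                    hits += t.rsi
                    tot += 1
        emp = hits / tot
        pred = predicted_prevalence(p, "rsi", age=25.0, age_ref=35.0)
        assert emp == pytest.approx(pred, abs=3 * math.sqrt(pred
                                                            * (1 - pred)
                                                            / tot))

    def test_serialization_roundtrip(self, pooled_params):
        d = pooled_params.to_dict()
        assert set(d) == {
            "tau_rsi", "tau_ci", "beta_rsi", "beta_ci", "a_rsi", "c_rsi",
            "e_rsi", "a_ci", "c_ci", "e_ci", "cov_a", "cov_c", "cov_e"}
        assert BivariateACEParams.from_dict(d) == pooled_params

    def test_validate_rejects_bad_unit_sum(self):
        p = BivariateACEParams(0, 0, 0.5, 0.3, 0.3, 0.4, 0.3, 0.3,
                               0.1, 0.1, 0.1)
        with pytest.raises(ValueError, match="A\\+C\\+E"):
            p.validate()
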