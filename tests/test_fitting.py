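"""Model specification, ML fitting, LRTs and profile intervals."""

import math

import numpy as np
import pytest

from twinace.fitting import (
    EqualityConstraint,
    ModelSpec,
    aic,
    count_free_parameters,
    equality_test_suite,
    fit,
    lrt,
    profile_ci,
    stratified_spec,
    unstratified_spec,
)
from twinace.simulate import simulate_pairs

FAST = dict(n_nodes=8, ftol=2e-9, gtol=1e-5)


class TestParameterCounting:
    def test_unstratified_counts_thirteen(self):
        assert count_free_parameters(unstratified_spec()) == 13

    def test_six_group_counts_seventy_eight(self):
        spec = stratified_spec(["NL", "FI", "MN"])
        assert count_free_parameters(spec) == 78

    def test_tying_a_derived_correlation_removes_redundancies(self):
        spec = stratified_spec(["NL", "FI", "MN"]).with_constraint(
            EqualityConstraint("rA", strata="all"))
        assert count_free_parameters(spec) == 73

    def test_fixing_age_slopes_removes_two_per_stratum(self):
        assert count_free_parameters(unstratified_spec(fix_betas=True)) == 11
        assert count_free_parameters(
            stratified_spec(["a", "b", "c"], fix_betas=True)) == 66

    def test_tying_all_parameters_collapses_to_thirteen(self):
        spec = stratified_spec(["NL", "FI"])
        for p in ("tau_rsi", "tau_ci", "beta_rsi", "beta_ci", "a_rsi",
                  "c_rsi", "a_ci", "c_ci", "cov_a", "cov_c", "cov_e"):
            spec = spec.with_constraint(EqualityConstraint(p, strata="all"))
        assert count_free_parameters(spec) == 13

    def test_constraint_on_absent_stratum_errors(self):
        spec = stratified_spec(["NL"]).with_constraint(
            EqualityConstraint("tau_rsi", strata=("XX|M",)))
        with pytest.raises(ValueError, match="absent"):
            count_free_parameters(spec)


class TestFit:
    def test_e_only_null_recovery(self, e_only_params):
        recs = simulate_pairs(e_only_params, n_mz=1500, n_dz_ss=1500,
                              seed=41)
        res = fit(recs, unstratified_spec(fix_betas=True), seed=1,
                  n_starts=2, **FAST)
        assert res.converged
        p = res.estimates["pooled"]
        # A-hat and C-hat near zero (3 x rough SE band)
        assert abs(p.a_rsi) < 0.25 and abs(p.c_rsi) < 0.2
        assert abs(p.cov_a + p.cov_c + p.cov_e) < 0.1

    def test_seed_insensitive_optimum(self, pooled_params):
        recs = simulate_pairs(pooled_params, n_mz=1500, n_dz_ss=1500,
                              seed=42)
        spec = unstratified_spec(fix_betas=True)
        r1 = fit(recs, spec, seed=1, n_starts=3, **FAST)
        r2 = fit(recs, spec, seed=99, n_starts=3, **FAST)
        assert r1.converged and r2.converged
        for name, v1 in r1.estimates["pooled"].to_dict().items():
            v2 = getattr(r2.estimates["pooled"], name)
            assert v1 == pytest.approx(v2, abs=2e-4), name

    def test_record_order_invariance(self, pooled_params, rng):
        recs = simulate_pairs(pooled_params, n_mz=600, n_dz_ss=600, seed=43)
        spec = unstratified_spec(fix_betas=True)
        r1 = fit(recs, spec, seed=1, n_starts=1, **FAST)
        shuffled = list(recs)
        rng.shuffle(shuffled)
        r2 = fit(shuffled, spec, seed=1, n_starts=1, **FAST)
        assert r1.minus2lnL == pytest.approx(r2.minus2lnL, abs=1e-8)

    def test_pooled_equals_fully_tied_stratified(self, pooled_params):
        recs = []
        for i, g in enumerate(("NL", "FI")):
            recs += simulate_pairs(pooled_params, n_mz=400, n_dz_ss=400,
                                   seed=50 + i, group=g)
        spec_u = unstratified_spec(fix_betas=True)
        spec_t = ModelSpec(grouping=("group",), strata=("FI", "NL"),
                           fixed={"beta_rsi": 0.0, "beta_ci": 0.0})
        for p in ("tau_rsi", "tau_ci", "a_rsi", "c_rsi", "a_ci", "c_ci",
                  "cov_a", "cov_c", "cov_e"):
            spec_t = spec_t.with_constraint(
                EqualityConstraint(p, strata="all"))
        tight = dict(n_nodes=8, ftol=1e-13, gtol=1e-7)
        ru = fit(recs, spec_u, seed=1, n_starts=1, **tight)
        rt = fit(recs, spec_t, seed=1, n_starts=1, **tight)
        assert ru.minus2lnL == pytest.approx(rt.minus2lnL, abs=1e-6)
        assert ru.n_free == rt.n_free == 11

    def test_aic_identity(self, pooled_params, small_study):
        res = fit(small_study, unstratified_spec(fix_betas=True),
                  seed=1, n_starts=1, **FAST)
        assert res.aic == pytest.approx(res.minus2lnL + 2 * res.n_free)
        assert aic(res) == res.aic

    def test_unresolvable_stratum_errors(self, small_study):
        spec = ModelSpec(grouping=("group",), strata=("othergroup",))
        with pytest.raises(ValueError, match="absent"):
            fit(small_study, spec, n_starts=1, **FAST)


class TestLRT:
    @pytest.fixture(scope="class")
    @staticmethod
    def nested_fits(pooled_params):
        recs = []
        for i, g in enumerate(("a", "b")):
            recs += simulate_pairs(pooled_params, n_mz=500, n_dz_ss=400,
                                   seed=60 + i, group=g)
        shared = {k: v for k, v in pooled_params.to_dict().items()
                  if k.startswith(("a_", "c_", "cov_"))}
        shared.update({"beta_rsi": 0.0, "beta_ci": 0.0})
        full_spec = ModelSpec(grouping=("group",), strata=("a", "b"),
                              fixed=shared)
        red_spec = full_spec.with_constraint(
            EqualityConstraint("tau_rsi", strata="all"))
        sv = {g: pooled_params.to_dict() for g in ("a", "b")}
        full = fit(recs, full_spec, n_starts=1, start_values=sv, **FAST)
        red = fit(recs, red_spec, n_starts=1, start_values=sv, **FAST)
        return full, red

    def test_chi2_df_and_p(self, nested_fits):
        full, red = nested_fits
        res = lrt(full, red)
        assert res["df"] == 1
        assert res["chi2"] >= 0.0
        assert 0.0 <= res["p"] <= 1.0

    def test_identical_fits_give_p_one(self, nested_fits):
        full, _ = nested_fits
        res = lrt(full, full.__class__(**{**full.__dict__,
                                          "n_free": full.n_free - 1}))
        assert res["chi2"] == 0.0 and res["p"] == pytest.approx(1.0)

    def test_reversed_nesting_errors(self, nested_fits):
        full, red = nested_fits
        with pytest.raises(ValueError, match="fewer free parameters"):
            lrt(red, full)

    def test_aic_difference_identity(self, nested_fits):
        full, red = nested_fits
        res = lrt(full, red)
        assert red.aic - full.aic == pytest.approx(
            res["chi2"] - 2 * res["df"], abs=1e-9)

    def test_power_grows_with_threshold_gap(self, pooled_params):
        # tau_rsi differs by 0.5 in one group: decisive rejection
        from dataclasses import replace
        shifted = replace(pooled_params,
                          tau_rsi=pooled_params.tau_rsi + 0.5)
        recs = []
        for g, par in (("a", pooled_params), ("b", pooled_params),
                       ("c", shifted)):
            recs += simulate_pairs(par, n_mz=1200, n_dz_ss=800,
                                   seed=abs(hash(g)) % 2**31, group=g)
        shared = {k: v for k, v in pooled_params.to_dict().items()
                  if k.startswith(("a_", "c_", "cov_"))}
        shared.update({"beta_rsi": 0.0, "beta_ci": 0.0})
        full_spec = ModelSpec(grouping=("group",),
                              strata=("a", "b", "c"), fixed=shared)
        red_spec = full_spec.with_constraint(
            EqualityConstraint("tau_rsi", strata="all"))
        sv = {g: pooled_params.to_dict() for g in ("a", "b", "c")}
        full = fit(recs, full_spec, n_starts=1, start_values=sv, **FAST)
        red = fit(recs, red_spec, n_starts=1, start_values=sv, **FAST)
        res = lrt(full, red)
        assert res["df"] == 2 and res["p"] < 1e-3


class TestEqualityTestSuite:
    @pytest.fixture(scope="class")
    @staticmethod
    def sexed_study(pooled_params):
        recs = []
        for i, g in enumerate(("NL", "FI")):
            recs += simulate_pairs(pooled_params, n_mz=500, n_dz_ss=350,
                                   n_dz_os=250, seed=70 + i, group=g)
        return recs

    def test_single_sex_data_errors(self, pooled_params):
        recs = simulate_pairs(pooled_params, n_mz=200, n_dz_ss=200,
                              seed=71, sex_ratio=0.0)
        spec = stratified_spec(["sim"], sexes=("M",), fix_betas=True)
        with pytest.raises(ValueError, match="stratum absent"):
            equality_test_suite(recs, spec, "tau_rsi",
                                "across_sex_within_country",
                                n_starts=1, **FAST)

    def test_sex_comparisons_one_per_group(self, sexed_study,
                                           pooled_params):
        spec = stratified_spec(["NL", "FI"], fix_betas=True)
        sv = {s: pooled_params.to_dict() for s in spec.strata}
        base = fit(sexed_study, spec, n_starts=1, start_values=sv, **FAST)
        table = equality_test_suite(
            sexed_study, spec, "tau_rsi", "across_sex_within_country",
            base_fit=base, n_starts=1, **FAST)
        assert len(table) == 2
        assert (table.df == 1).all()
        assert (table.error == "").all()
        # generating model is sex-homogeneous: no decisive rejections
        assert (table.p > 1e-4).all()

    def test_country_comparisons_df_two_with_three_groups(
            self, pooled_params):
        recs = []
        for i, g in enumerate(("a", "b", "c")):
            recs += simulate_pairs(pooled_params, n_mz=250, n_dz_ss=200,
                                   seed=80 + i, group=g)
        spec = stratified_spec(["a", "b", "c"], sexes=("M", "F"),
                               fix_betas=True)
        sv = {s: pooled_params.to_dict() for s in spec.strata}
        base = fit(recs, spec, n_starts=1, start_values=sv, **FAST)
        table = equality_test_suite(
            recs, spec, "tau_ci", "across_country_within_sex",
            base_fit=base, n_starts=1, **FAST)
        assert len(table) == 2  # one comparison per sex
        assert (table.df == 2).all()


class TestProfileCI:
    @pytest.fixture(scope="class")
    @staticmethod
    def fitted(pooled_params):
        recs = simulate_pairs(pooled_params, n_mz=1500, n_dz_ss=1500,
                              seed=90)
        spec = unstratified_spec(fix_betas=True)
        res = fit(recs, spec, seed=2, n_starts=2, **FAST)
        return recs, spec, res

    def test_interval_contains_point_estimate(self, fitted):
        recs, spec, res = fitted
        ci = profile_ci(recs, spec, res, "a_rsi", n_starts=1, **FAST)
        assert ci.lower_converged and ci.upper_converged
        assert ci.lower < res.estimates["pooled"].a_rsi < ci.upper

    def test_derived_target_profiles(self, fitted):
        recs, spec, res = fitted
        ci = profile_ci(recs, spec, res, "rP", n_starts=1, **FAST)
        from twinace.liability import implied_rp
        assert ci.contains(implied_rp(res.estimates["pooled"]))
        assert ci.upper - ci.lower < 0.2

    def test_univariate_probit_matches_wald(self):
        # RSI-only data, independence model: profile CI for tau should
        # match the closed-form Wald interval on the probit scale
        from twinace.data import TwinObs, TwinPairRecord
        from scipy.stats import norm
        rng = np.random.default_rng(4)
        n = 10000
        tau_true = 0.4
        y = (rng.standard_normal(n) > tau_true).astype(int)
        recs = [TwinPairRecord(f"p{i}", "MZ", "g",
                               TwinObs("F", 30.0, int(y[i]), None), None)
                for i in range(n)]
        spec = ModelSpec(
            grouping=(), strata=("pooled",),
            fixed={"beta_rsi": 0.0, "beta_ci": 0.0, "a_rsi": 0.0,
                   "c_rsi": 0.0, "a_ci": 0.0, "c_ci": 0.0, "cov_a": 0.0,
                   "cov_c": 0.0, "cov_e": 0.0, "tau_ci": 0.0})
        res = fit(recs, spec, n_starts=1, **FAST)
        assert res.n_free_internal == 1
        ci = profile_ci(recs, spec, res, "tau_rsi", n_starts=1, **FAST)
        p_hat = y.mean()
        tau_hat = norm.ppf(1 - p_hat)
        se = math.sqrt(p_hat * (1 - p_hat) / n) / norm.pdf(tau_hat)
        wald = (tau_hat - 1.959964 * se, tau_hat + 1.959964 * se)
        half_profile = (ci.upper - ci.lower) / 2
        half_wald = (wald[1] - wald[0]) / 2
        assert half_profile == pytest.approx(half_wald, rel=0.02)
        assert ci.lower == pytest.approx(wald[0], abs=0.02 * half_wald * 2)

    def test_unconverged_fit_rejected(self, fitted):
        recs, spec, res = fitted
        import dataclasses
        bad = dataclasses.replace(res, converged=False)
        with pytest.raises(ValueError, match="unconverged"):
            profile_ci(recs, spec, bad, "a_rsi")
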