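"""Model fitting, Wald/LRT tests, OLS comparators, heterogeneity."""

import math

import numpy as np
import pytest
from scipy import stats
from sklearn.base import clone

from dyadsem.inference import (
    FETAL_ONLY,
    FULL,
    MATERNAL_ONLY,
    NULL,
    FitResult,
    MaternalFetalSEM,
    ModelSpec,
    fit_model,
    heterogeneity_i2,
    linear_model_effects,
    lrt,
    summary_stats_to_group,
    two_df_test,
    wald_test,
)
from dyadsem.sem_core import BW, BWO, SNP, PathModelParams, summaries_from_data
from dyadsem.simulate import ScenarioConfig, simulate_dataset


@pytest.fixture(scope="module")
def recovery_fit(recovery_dataset):
    _, data = recovery_dataset
    groups = summaries_from_data(data)
    return fit_model(groups, FULL, seed=0)


class TestFitting:
    def test_parameter_recovery(self, recovery_dataset, recovery_fit):
        """Estimates land within 3 SEs of the generating values at n = 2e5."""
        config, _ = recovery_dataset
        fit = recovery_fit
        assert fit.converged
        assert abs(fit.estimates.f - config.f) < 3 * fit.se_f
        assert abs(fit.estimates.m - config.m) < 3 * fit.se_m
        assert abs(fit.estimates.rho - config.true_rho) < 0.01
        assert fit.estimates.phi == pytest.approx(1.0, abs=0.02)

    def test_null_data_estimates_centred_on_zero(self):
        data = simulate_dataset(ScenarioConfig(n_families=30_000, seed=101))
        fit = fit_model(summaries_from_data(data), FULL, seed=0)
        assert abs(fit.estimates.m) < 3 * fit.se_m + 1e-12
        assert abs(fit.estimates.f) < 3 * fit.se_f + 1e-12

    def test_fixed_paths_stay_zero(self, recovery_dataset):
        _, data = recovery_dataset
        groups = summaries_from_data(data)
        for spec, fixed in ((FETAL_ONLY, "m"), (MATERNAL_ONLY, "f"), (NULL, "m")):
            fit = fit_model(groups, spec, seed=0)
            assert getattr(fit.estimates, fixed) == 0.0
        null = fit_model(groups, NULL, seed=0)
        assert null.se_m is None and null.se_f is None

    def test_full_model_never_fits_worse_than_nested(self, recovery_dataset):
        _, data = recovery_dataset
        groups = summaries_from_data(data)
        full = fit_model(groups, FULL, seed=0)
        for spec in (FETAL_ONLY, MATERNAL_ONLY, NULL):
            reduced = fit_model(groups, spec, seed=0)
            assert full.neg2ll <= reduced.neg2ll + 1e-6

    def test_raw_and_summary_fits_agree(self):
        data = simulate_dataset(
            ScenarioConfig(n_families=15_000, v_fetal=0.0004, seed=31)
        )
        raw = fit_model(data, FULL, seed=0, method="raw")
        summ = fit_model(data, FULL, seed=0, method="cov")
        assert raw.estimates.m == pytest.approx(summ.estimates.m, abs=1e-4)
        assert raw.estimates.f == pytest.approx(summ.estimates.f, abs=1e-4)
        assert raw.estimates.rho == pytest.approx(summ.estimates.rho, abs=1e-4)

    def test_missing_design_fit_remains_unbiased(self):
        """FIML point estimates stay near truth under MCAR masking."""
        config = ScenarioConfig(
            n_families=60_000, v_fetal=0.0004, v_maternal=0.0002,
            missing_design="iii", seed=13,
        )
        data = simulate_dataset(config)
        fit = fit_model(summaries_from_data(data), FULL, seed=0)
        assert abs(fit.estimates.f - config.f) < 3 * fit.se_f
        assert abs(fit.estimates.m - config.m) < 3 * fit.se_m

    def test_design_iv_drops_rho(self):
        config = ScenarioConfig(n_families=20_000, missing_design="iv", seed=41)
        data = simulate_dataset(config)
        fit = fit_model(summaries_from_data(data), FULL, seed=0)
        assert "rho" not in fit.param_names
        assert fit.estimates.rho == 0.0

    def test_sklearn_protocol(self):
        est = MaternalFetalSEM(free_maternal=False, restarts=3)
        params = est.get_params()
        assert params["free_maternal"] is False
        cloned = clone(est)
        assert cloned.get_params() == params
        data = simulate_dataset(ScenarioConfig(n_families=5_000, seed=2))
        assert est.fit(data) is est
        assert hasattr(est, "f_") and hasattr(est, "neg2ll_")


class TestWaldAndLrt:
    def _fake_fit(self, m=0.0, f=0.0, se=0.01, neg2ll=0.0, spec=FULL):
        return FitResult(
            spec=spec,
            estimates=PathModelParams(m=m, f=f),
            se_m=se if spec.free_maternal else None,
            se_f=se if spec.free_fetal else None,
            neg2ll=neg2ll,
            converged=True,
            n_restarts_used=1,
            n_obs=1000,
        )

    def test_zero_estimate_gives_p_one(self):
        res = wald_test(self._fake_fit(m=0.0), "maternal")
        assert res.p_value == pytest.approx(1.0)
        assert res.statistic == 0.0

    def test_normal_quantile(self):
        res = wald_test(self._fake_fit(f=1.96e-2, se=1e-2), "fetal")
        assert res.p_value == pytest.approx(0.05, abs=1e-3)

    def test_wald_requires_free_path(self):
        with pytest.raises(ValueError):
            wald_test(self._fake_fit(spec=FETAL_ONLY), "maternal")

    def test_lrt_identical_fit_gives_p_one(self):
        full = self._fake_fit(neg2ll=100.0)
        reduced = self._fake_fit(neg2ll=100.0, spec=FETAL_ONLY)
        res = lrt(full, reduced)
        assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)
        assert res.name == "lrt_m" and res.df == 1

    def test_lrt_statistic_floored_at_zero(self):
        full = self._fake_fit(neg2ll=100.0)
        reduced = self._fake_fit(neg2ll=99.9, spec=FETAL_ONLY)
        assert lrt(full, reduced).statistic == 0.0

    def test_non_nested_specs_rejected(self):
        with pytest.raises(ValueError):
            lrt(self._fake_fit(spec=FETAL_ONLY),
                self._fake_fit(spec=MATERNAL_ONLY))
        with pytest.raises(ValueError):
            lrt(self._fake_fit(), self._fake_fit())

    def test_two_df_statistic(self):
        full = self._fake_fit(neg2ll=90.0)
        null = self._fake_fit(neg2ll=100.0, spec=NULL)
        res = two_df_test(full, null)
        assert res.df == 2 and res.name == "two_df"
        assert res.p_value == pytest.approx(stats.chi2.sf(10.0, 2))
        with pytest.raises(ValueError):
            two_df_test(full, self._fake_fit(neg2ll=100.0, spec=FETAL_ONLY))

    def test_p_monotone_in_statistic(self):
        ps = [
            wald_test(self._fake_fit(f=v, se=0.01), "fetal").p_value
            for v in (0.0, 0.01, 0.02, 0.03)
        ]
        assert all(a > b for a, b in zip(ps, ps[1:]))


class TestLinearComparators:
    def test_slope_is_fetal_plus_half_maternal(self):
        """OLS of own phenotype on dosage estimates f + m/2, not f."""
        config = ScenarioConfig(
            n_families=1_000_000, v_fetal=-0.0004, v_maternal=-0.000196, seed=55
        )
        assert config.f == pytest.approx(-0.020)
        assert config.m == pytest.approx(-0.014)
        data = simulate_dataset(config)
        lm = linear_model_effects(data)
        se = 1 / math.sqrt(config.n_families)
        assert lm["fetal"].beta == pytest.approx(-0.027, abs=3 * se)
        assert lm["maternal"].beta == pytest.approx(
            config.m + config.f / 2, abs=3 * se
        )

    def test_null_slopes_centred_on_zero(self):
        data = simulate_dataset(ScenarioConfig(n_families=50_000, seed=66))
        lm = linear_model_effects(data)
        for eff in lm.values():
            assert abs(eff.beta) < 3 * eff.se

    def test_available_case_subsets(self):
        data = simulate_dataset(
            ScenarioConfig(n_families=4_000, missing_design="iii", seed=7)
        )
        lm = linear_model_effects(data)
        assert lm["fetal"].n == 3_000  # both + own_only
        assert lm["maternal"].n == 3_000

    def test_constant_genotype_rejected(self):
        data = simulate_dataset(ScenarioConfig(n_families=100, seed=1))
        data[SNP] = 1.0
        with pytest.raises(ValueError):
            linear_model_effects(data)


class TestHeterogeneity:
    def test_identical_estimates(self):
        q, i2, p = heterogeneity_i2(0.03, 0.01, 0.03, 0.02)
        assert q == 0.0 and i2 == 0.0 and p == pytest.approx(1.0)

    def test_hand_computed_example(self):
        q, i2, p = heterogeneity_i2(0.05, 0.02, -0.01, 0.02)
        assert q == pytest.approx(4.5)
        assert i2 == pytest.approx(77.78, abs=0.01)
        assert p == pytest.approx(0.0339, abs=0.0005)

    def test_doubling_ses_quarters_q(self):
        q1, _, _ = heterogeneity_i2(0.05, 0.02, -0.01, 0.02)
        q2, _, _ = heterogeneity_i2(0.05, 0.04, -0.01, 0.04)
        assert q2 == pytest.approx(q1 / 4)

    def test_nonpositive_se_rejected(self):
        with pytest.raises(ValueError):
            heterogeneity_i2(0.1, 0.0, 0.2, 0.1)


class TestSummaryStatistics:
    def test_arithmetic(self):
        g = summary_stats_to_group(0.5, 0.02, 1.0, 1000, "fetal_arm")
        assert g.sample_cov[1, 1] == pytest.approx(0.5)
        assert g.sample_cov[0, 1] == pytest.approx(0.01)
        assert g.pattern.label == "own_only"
        assert summary_stats_to_group(0.5, 0.02, 1.0, 1000, "maternal_arm").pattern.label == "offspring_only"

    def test_impossible_correlation_rejected(self):
        with pytest.raises(ValueError):
            summary_stats_to_group(0.5, 10.0, 1.0, 1000, "fetal_arm")
        with pytest.raises(ValueError):
            summary_stats_to_group(1.5, 0.1, 1.0, 1000, "fetal_arm")

    @staticmethod
    def _to_raw_dosage(data, p=0.5):
        out = data.copy()
        scale = math.sqrt(2 * p * (1 - p))
        out[SNP] = out[SNP] * scale + 2 * p
        return out

    def test_round_trip_from_simulated_cohort(self):
        """GWAS-style summaries reproduce the cohort's direct summary group."""
        data = simulate_dataset(
            ScenarioConfig(n_families=100_000, v_fetal=0.0004,
                           missing_design="i", seed=88)
        )
        own = self._to_raw_dosage(data[data["pattern"] == "own_only"])
        direct = summaries_from_data(own)[0]
        x = own[SNP].to_numpy()
        y = own[BW].to_numpy()
        eaf = x.mean() / 2
        beta = np.cov(y, x, ddof=0)[0, 1] / x.var()
        rebuilt = summary_stats_to_group(eaf, beta, y.var(), len(own), "fetal_arm")
        assert rebuilt.sample_cov[1, 1] == pytest.approx(
            direct.sample_cov[1, 1], rel=0.02
        )
        assert rebuilt.sample_cov[0, 1] == pytest.approx(
            direct.sample_cov[0, 1], rel=0.05
        )
        assert rebuilt.sample_cov[0, 0] == pytest.approx(
            direct.sample_cov[0, 0], rel=0.01
        )

    def test_extra_summary_arm_tightens_maternal_se(self):
        """Joining a summary-only offspring-phenotype cohort shrinks SE(m)."""
        base = self._to_raw_dosage(
            simulate_dataset(
                ScenarioConfig(n_families=20_000, v_maternal=0.0002, seed=90)
            )
        )
        groups = summaries_from_data(base)
        fit_alone = fit_model(groups, FULL, seed=0)
        extra_raw = self._to_raw_dosage(
            simulate_dataset(
                ScenarioConfig(n_families=60_000, v_maternal=0.0002,
                               missing_design="ii", seed=91)
            )
        )
        off = extra_raw[extra_raw["pattern"] == "offspring_only"]
        x, y = off[SNP].to_numpy(), off[BWO].to_numpy()
        arm = summary_stats_to_group(
            x.mean() / 2, np.cov(y, x, ddof=0)[0, 1] / x.var(), y.var(),
            len(off), "maternal_arm",
        )
        fit_joint = fit_model(groups + [arm], FULL, seed=0)
        assert fit_joint.se_m < fit_alone.se_m
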