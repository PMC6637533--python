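"""Negative-binomial engine: closed forms, grid oracle, effect arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from nbsides.nb import (
    EffectEstimate,
    ExacerbationRateModel,
    RankDeficiencyError,
    TermLookupError,
    effect_from_fit,
    fit_nb_two_group,
    lr_test,
)


def nb2_loglik(y, mu, k):
    """Independent NB2 log-likelihood via scipy's parameterisation."""
    if k <= 0:
        return stats.poisson.logpmf(y, mu).sum()
    return stats.nbinom.logpmf(y, 1.0 / k, 1.0 / (1.0 + k * mu)).sum()


@pytest.fixture()
def twelve_rows():
    rng = np.random.default_rng(42)
    t = np.repeat([0, 1], 6)
    fu = rng.uniform(0.5, 1.0, 12).round(2)
    y = np.array([0, 1, 2, 0, 3, 1, 0, 0, 1, 0, 2, 0])
    return pd.DataFrame(
        {"treated": t, "exacerbation_count": y, "followup_years": fu}
    )


class TestFitNB:
    def test_poisson_closed_form_single_arm(self):
        df = pd.DataFrame(
            {"exacerbation_count": [2, 0, 1, 3, 1], "followup_years": [1.0] * 5}
        )
        fit = ExacerbationRateModel(df, []).fit(k=0)
        rate = np.exp(fit.params["Intercept"])
        assert rate == pytest.approx(7 / 5, rel=1e-8)

    def test_beats_grid_oracle(self, twelve_rows):
        """MLE loglik >= every point of a dense (b0, b1, k) lattice, and the
        lattice argmax sits within one grid step of the fitted optimum."""
        model = ExacerbationRateModel(twelve_rows, ["treated"])
        fit = model.fit()
        y = twelve_rows["exacerbation_count"].to_numpy()
        fu = twelve_rows["followup_years"].to_numpy()
        t = twelve_rows["treated"].to_numpy()
        b0s = np.linspace(-1.5, 1.5, 41)
        b1s = np.linspace(-2.0, 2.0, 41)
        ks = np.linspace(1e-6, 4.0, 41)
        best = (-np.inf, None)
        for b0 in b0s:
            for b1 in b1s:
                mu = fu * np.exp(b0 + b1 * t)
                for k in ks:
                    ll = nb2_loglik(y, mu, k)
                    if ll > best[0]:
                        best = (ll, (b0, b1, k))
        assert fit.llf >= best[0] - 1e-6
        b0g, b1g, kg = best[1]
        assert abs(fit.params["Intercept"] - b0g) <= 1.5 / 20 + 1e-9
        assert abs(fit.params["treated"] - b1g) <= 2.0 / 20 + 1e-9
        assert abs(fit.k - kg) <= 4.0 / 40 + 1e-9

    def test_all_zero_counts_flagged_not_crash(self):
        df = pd.DataFrame(
            {"treated": [0, 0, 1, 1], "exacerbation_count": [0] * 4,
             "followup_years": [1.0] * 4}
        )
        fit = ExacerbationRateModel(df, ["treated"]).fit()
        assert not fit.converged
        assert fit.se("treated") > 1e5

    def test_rank_deficiency_names_alias(self, twelve_rows):
        df = twelve_rows.copy()
        df["dup"] = df["treated"]
        with pytest.raises(RankDeficiencyError, match="dup"):
            ExacerbationRateModel(df, ["treated", "dup"])

    def test_arm_only_fit_reproduces_arm_means(self):
        """Score-equation identity: equal offsets + arm-only model => fitted
        means equal observed arm mean counts."""
        rng = np.random.default_rng(1)
        df = pd.DataFrame(
            {"treated": np.repeat([0, 1], 200),
             "exacerbation_count": rng.negative_binomial(1, 0.5, 400),
             "followup_years": np.ones(400)}
        )
        fit = ExacerbationRateModel(df, ["treated"]).fit()
        mean_c = df.loc[df["treated"] == 0, "exacerbation_count"].mean()
        mean_t = df.loc[df["treated"] == 1, "exacerbation_count"].mean()
        assert np.exp(fit.params["Intercept"]) == pytest.approx(mean_c, rel=1e-4)
        assert np.exp(fit.params["Intercept"] + fit.params["treated"]) == pytest.approx(
            mean_t, rel=1e-4
        )


class TestEffectEstimate:
    def test_printed_rate_ratio_maps_to_reduction(self):
        # the Table-3-style transformation: RR 0.56 (0.34, 0.94) -> 44% (6, 66)
        eff = EffectEstimate(rate_ratio=0.56, ci_low=0.34, ci_high=0.94,
                             p_value=0.028, n_treated=97, n_control=102)
        assert round(eff.reduction_pct) == 44
        lo, hi = eff.reduction_ci
        assert (round(lo), round(hi)) == (6, 66)

    def test_null_effect(self):
        eff = EffectEstimate.from_log_rr(0.0, 0.2, 10, 10)
        assert eff.rate_ratio == 1.0
        assert eff.reduction_pct == 0.0
        assert eff.p_value == pytest.approx(1.0)

    def test_halving_is_fifty_pct(self):
        eff = EffectEstimate.from_log_rr(np.log(0.5), 0.1, 10, 10)
        assert eff.reduction_pct == pytest.approx(50.0)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        log_rr=st.floats(-2, 2, allow_nan=False),
        se=st.floats(0.01, 2.0, allow_nan=False),
    )
    def test_ci_excludes_one_iff_p_below_005(self, log_rr, se):
        eff = EffectEstimate.from_log_rr(log_rr, se, 5, 5)
        excludes = eff.ci_low > 1.0 or eff.ci_high < 1.0
        assert excludes == (eff.p_value < 0.05)
        assert eff.ci_low <= eff.rate_ratio <= eff.ci_high
        lo, hi = eff.reduction_ci
        assert lo <= eff.reduction_pct <= hi

    def test_missing_term_lookup(self, twelve_rows):
        fit = ExacerbationRateModel(twelve_rows, ["treated"]).fit()
        with pytest.raises(TermLookupError):
            effect_from_fit(fit, "not_a_term")


class TestLRTest:
    def test_identical_fits_give_unit_p(self, twelve_rows):
        fit = ExacerbationRateModel(twelve_rows, ["treated"]).fit()
        stat, p = lr_test(fit, fit, df=1)
        assert stat == 0.0 and p == 1.0

    def test_nested_statistic_matches_grid_oracle(self, twelve_rows):
        """2*(llf_full - llf_reduced) against independently computed logliks."""
        full = ExacerbationRateModel(twelve_rows, ["treated"]).fit()
        reduced = ExacerbationRateModel(twelve_rows, []).fit()
        stat, p = lr_test(full, reduced, df=1)
        y = twelve_rows["exacerbation_count"].to_numpy()
        fu = twelve_rows["followup_years"].to_numpy()
        t = twelve_rows["treated"].to_numpy()
        ll_full = nb2_loglik(
            y, fu * np.exp(full.params["Intercept"] + full.params["treated"] * t),
            full.k,
        )
        ll_red = nb2_loglik(y, fu * np.exp(reduced.params["Intercept"]), reduced.k)
        assert stat == pytest.approx(2 * (ll_full - ll_red), abs=1e-6)
        assert 0 <= p <= 1

    def test_row_mismatch_rejected(self, twelve_rows):
        full = ExacerbationRateModel(twelve_rows, ["treated"]).fit()
        reduced = ExacerbationRateModel(twelve_rows.iloc[:10], []).fit()
        with pytest.raises(ValueError, match="different rows"):
            lr_test(full, reduced, df=1)


class TestFastTwoGroupFit:
    def test_matches_statsmodels_joint_mle(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        n = 600
        t = np.repeat([0, 1], n // 2)
        fu = rng.uniform(0.4, 1.0, n)
        mu = fu * np.exp(0.1 - 0.4 * t)
        y = rng.negative_binomial(1.0, 1.0 / (1.0 + mu))
        fast = fit_nb_two_group(y, t, fu)
        X = np.column_stack([np.ones(n), t])
        ref = sm.NegativeBinomial(y, X, offset=np.log(fu)).fit(disp=0)
        assert fast.beta == pytest.approx(ref.params[1], abs=2e-3)
        assert fast.se == pytest.approx(ref.bse[1], rel=2e-2)
        assert fast.k == pytest.approx(ref.params[2], rel=0.08)

    def test_degenerate_children_flagged(self):
        y = np.array([0, 0, 0, 0])
        t = np.array([0, 0, 1, 1])
        fu = np.ones(4)
        assert not fit_nb_two_group(y, t, fu).converged
        assert not fit_nb_two_group(np.array([1, 1, 1, 1]), np.ones(4), fu).converged

    def test_z_sign_convention(self):
        rng = np.random.default_rng(4)
        n = 2000
        t = np.repeat([0, 1], n // 2)
        y = rng.poisson(np.where(t == 1, 0.4, 0.8))
        f = fit_nb_two_group(y, t, np.ones(n))
        assert f.z_benefit > 0  # benefit = positive z
        assert f.reduction_pct == pytest.approx(50, abs=15)
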