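"""Univariable MR estimators and sensitivity analyses."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mrlink.exceptions import (DomainError, InsufficientInstrumentsError,
                               WeakInstrumentError)
from mrlink.mr import (cochran_q, divw, egger, ivw, leave_one_out, or_from_ci,
                       percent_excess_risk, q_pvalue, raps, steiger,
                       to_odds_ratio, wald_ratio)
from mrlink.simulate import Pleiotropy, TwoSampleSimConfig
from mrlink.sumstats import HarmonizedPair, InstrumentSet

from conftest import simulated_instruments


def pair(bx, sx, by, sy):
    return HarmonizedPair("rs", "1", 1, "A", "G", bx, sx, by, sy,
                          0.3, 0.3, 1e-10, 0.5)


def iset(bx, sx, by, sy):
    pairs = [pair(*t) for t in zip(bx, sx, by, sy)]
    return InstrumentSet(pairs, 1.0, 0.001, 10_000)


class TestWaldRatio:
    def test_closed_form(self):
        est = wald_ratio(pair(0.5, 0.01, 0.2, 0.1))
        assert est.beta == pytest.approx(0.4)
        assert est.se == pytest.approx(0.2)

    def test_null_outcome(self):
        est = wald_ratio(pair(0.5, 0.01, 0.0, 0.1))
        assert est.beta == 0.0 and est.pval == pytest.approx(1.0)

    def test_zero_exposure_effect_is_domain_error(self):
        with pytest.raises(DomainError):
            wald_ratio(pair(0.0, 0.01, 0.2, 0.1))

    @settings(deadline=None, derandomize=True)
    @given(bx=st.floats(0.05, 2), sx=st.floats(0.001, 0.5),
           by=st.floats(-2, 2), sy=st.floats(0.001, 0.5))
    def test_second_order_se_dominates_first(self, bx, sx, by, sy):
        p = pair(bx, sx, by, sy)
        assert wald_ratio(p, "second").se >= wald_ratio(p, "first").se


class TestIVW:
    def test_closed_form(self):
        est = ivw(iset([1, 1, 1, 1], [0.1] * 4, [0.1] * 4, [1] * 4),
                  mode="fixed")
        assert est.beta == pytest.approx(0.1)
        assert est.se == pytest.approx(0.5)

    def test_single_instrument_rejected_and_wald_is_the_limit(self):
        with pytest.raises(InsufficientInstrumentsError, match="wald_ratio"):
            ivw(iset([1.0], [0.1], [0.2], [0.3]))
        # the IVW formula with k=1 collapses to the Wald ratio
        w = wald_ratio(pair(1.0, 0.1, 0.2, 0.3))
        assert w.beta == pytest.approx((1.0 * 0.2 / 0.3 ** 2) / (1.0 / 0.3 ** 2))

    def test_matches_generic_weighted_regression_oracle(self, rng):
        import statsmodels.api as sm
        for _ in range(10):
            k = rng.integers(5, 30)
            bx = rng.normal(0, 0.2, k)
            by = 0.3 * bx + rng.normal(0, 0.05, k)
            sy = rng.uniform(0.02, 0.2, k)
            ours = ivw(iset(bx, np.zeros(k), by, sy), mode="fixed")
            fit = sm.WLS(by, bx, weights=1.0 / sy ** 2).fit()
            assert ours.beta == pytest.approx(fit.params[0], abs=1e-10)

    def test_random_effects_se_never_below_fixed(self, rng):
        for seed in range(20):
            s = simulated_instruments(theta=0.1, k=20, seed=seed)
            assert ivw(s, "random").se >= ivw(s, "fixed").se - 1e-15

    def test_recovers_true_effect(self):
        est = ivw(simulated_instruments(theta=0.2, k=50, seed=0))
        assert abs(est.beta - 0.2) < 3 * est.se


class TestEgger:
    def test_exact_line(self):
        bx = np.array([0.1, 0.2, 0.3, 0.4])
        by = 0.01 + 0.3 * bx
        slope, intercept = egger(iset(bx, np.zeros(4), by, np.full(4, 0.1)))
        assert slope.beta == pytest.approx(0.3)
        assert intercept.beta == pytest.approx(0.01)

    def test_requires_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            egger(iset([1, 1], [0, 0], [1, 1], [1, 1]))

    def test_matches_statsmodels_wls_oracle(self, rng):
        import statsmodels.api as sm
        for _ in range(20):
            k = int(rng.integers(8, 40))
            bx = np.abs(rng.normal(0.2, 0.1, k)) + 0.01
            by = 0.02 + 0.25 * bx + rng.normal(0, 0.3, k)
            sy = rng.uniform(0.02, 0.3, k)
            slope, intercept = egger(iset(bx, np.zeros(k), by, sy))
            X = sm.add_constant(bx)
            fit = sm.WLS(by, X, weights=1.0 / sy ** 2).fit()
            assert slope.beta == pytest.approx(fit.params[1], abs=1e-10)
            assert intercept.beta == pytest.approx(fit.params[0], abs=1e-10)
            if fit.scale > 1:  # floor inactive: SEs and t p-values coincide
                assert slope.se == pytest.approx(fit.bse[1], abs=1e-10)
                assert slope.pval == pytest.approx(fit.pvalues[1], abs=1e-10)

    def test_intercept_centred_at_zero_without_pleiotropy(self):
        intercepts = [egger(simulated_instruments(theta=0.2, k=50, seed=s))[1].beta
                      for s in range(100)]
        se_mean = np.std(intercepts) / np.sqrt(len(intercepts))
        assert abs(np.mean(intercepts)) < 4 * se_mean + 1e-4


class TestDivw:
    def test_zero_exposure_se_equals_fixed_ivw(self):
        s = iset([0.2, 0.3, 0.4], np.zeros(3), [0.05, 0.08, 0.1],
                 [0.1, 0.1, 0.1])
        assert divw(s).beta == pytest.approx(ivw(s, "fixed").beta)

    def test_closed_form(self):
        s = iset([1, 1], [0.1, 0.1], [0.5, 0.5], [1, 1])
        assert divw(s).beta == pytest.approx(0.5 / 0.99)

    def test_weak_instrument_error(self):
        s = iset([0.01, 0.01], [1.0, 1.0], [0.1, 0.1], [1, 1])
        with pytest.raises(WeakInstrumentError):
            divw(s)

    def test_less_biased_than_ivw_under_weak_instruments(self):
        ivws, divws = [], []
        for s in range(500):
            inst = simulated_instruments(theta=0.2, k=50, seed=s,
                                         gamma_sd=0.012)
            ivws.append(ivw(inst, "fixed").beta)
            divws.append(divw(inst, n_boot=50, seed=s).beta)
        assert abs(np.mean(divws) - 0.2) < abs(np.mean(ivws) - 0.2)


class TestRaps:
    def test_zero_exposure_se_matches_fixed_ivw(self):
        s = simulated_instruments(theta=0.15, k=30, seed=2)
        bx, sx, by, sy = s.arrays()
        z = iset(bx, np.zeros_like(sx), by, sy)
        assert raps(z).beta == pytest.approx(ivw(z, "fixed").beta, abs=1e-6)

    def test_exact_line(self):
        bx = np.array([0.1, 0.2, 0.3, 0.5])
        s = iset(bx, np.full(4, 0.01), 0.3 * bx, np.full(4, 0.1))
        assert raps(s).beta == pytest.approx(0.3, abs=1e-6)

    def test_mean_recovery(self):
        ests = [raps(simulated_instruments(theta=0.15, k=100, seed=s)).beta
                for s in range(200)]
        assert abs(np.mean(ests) - 0.15) < 0.01

    def test_overdispersion_variant_handles_pleiotropy(self):
        s = simulated_instruments(
            theta=0.2, k=80, seed=3,
            pleiotropy=Pleiotropy("balanced", sd=0.01))
        est = raps(s, overdispersion=True)
        assert abs(est.beta - 0.2) < 4 * est.se
        assert est.phi > 1.0  # picked up the extra variance


class TestCochranQ:
    def test_identical_ratios_give_zero(self):
        s = iset([0.1, 0.2, 0.4], np.zeros(3), [0.05, 0.1, 0.2],
                 [0.1, 0.1, 0.1])
        het = cochran_q(s)
        assert het.Q == pytest.approx(0.0, abs=1e-20)
        assert het.pval == pytest.approx(1.0)

    def test_published_chi_square_tails(self):
        # low-heterogeneity sensitivity statistics reported for the
        # GDM->CTS instrument sets
        assert round(q_pvalue(17.02, 18), 2) == 0.52
        assert round(q_pvalue(30.74, 25), 1) == 0.2

    def test_df_is_k_minus_one(self):
        s = simulated_instruments(k=12, seed=0)
        assert cochran_q(s).df == 11

    def test_invariant_to_relabeling(self, rng):
        s = simulated_instruments(k=20, seed=4)
        bx, sx, by, sy = s.arrays()
        perm = rng.permutation(20)
        q1 = cochran_q(iset(bx, sx, by, sy)).Q
        q2 = cochran_q(iset(bx[perm], sx[perm], by[perm], sy[perm])).Q
        assert q1 == pytest.approx(q2)


class TestLeaveOneOut:
    def test_cardinality(self):
        table = leave_one_out(simulated_instruments(k=3, seed=1))
        assert len(table) == 3

    def test_homogeneous_panel_unflagged(self):
        table = leave_one_out(simulated_instruments(theta=0.2, k=50, seed=6))
        assert not table["flagged"].any()

    def test_planted_outlier_flagged(self):
        s = simulated_instruments(theta=0.05, k=20, seed=8)
        out_pair = s.pairs[0]
        out_pair.beta_y = 10 * out_pair.beta_x * 0.05 + 0.5
        table = leave_one_out(s)
        assert table.loc[table["snp_id"] == out_pair.snp_id, "flagged"].item()


class TestSteiger:
    def test_separation(self):
        s = simulated_instruments(theta=0.1, k=50, seed=0)
        res = steiger(s, 100_000, 100_000)
        assert res.direction_ok and res.pval < 1e-6

    def test_antisymmetry(self):
        s = simulated_instruments(theta=0.1, k=50, seed=0)
        bx, sx, by, sy = s.arrays()
        fwd = steiger(iset(bx, sx, by, sy), 1e5, 1e5)
        rev = steiger(iset(by, sy, bx, sx), 1e5, 1e5)
        assert fwd.direction_ok != rev.direction_ok
        assert fwd.r2_exposure == pytest.approx(rev.r2_outcome)

    def test_forward_chain_supported_in_most_reps(self):
        ok = sum(steiger(simulated_instruments(theta=0.2, k=50, seed=s),
                         1e5, 1e5).direction_ok for s in range(200))
        assert ok / 200 >= 0.95

    def test_small_samples_rejected(self):
        with pytest.raises(DomainError):
            steiger(simulated_instruments(k=5, seed=0), 3, 100)


class TestOddsRatioArithmetic:
    def test_published_point_estimates(self):
        # indirect log-odds 0.1004 -> OR 1.106; replicated protein CI
        assert round(to_odds_ratio(0.1004, 0.0363)[0], 3) == 1.106
        assert round(or_from_ci(1.1226, 1.5057), 4) == 1.3001
        assert round(percent_excess_risk(1.1586), 1) == 15.9

    def test_null_effect_symmetric_ci(self):
        orr, lo, hi = to_odds_ratio(0.0, 0.1)
        assert orr == 1.0
        assert lo * hi == pytest.approx(1.0)

    @settings(deadline=None, derandomize=True)
    @given(beta=st.floats(-2, 2), se=st.floats(0.001, 1.0))
    def test_ci_brackets_point_and_round_trips(self, beta, se):
        orr, lo, hi = to_odds_ratio(beta, se)
        assert lo < orr < hi
        assert or_from_ci(lo, hi) == pytest.approx(orr, rel=1e-9)
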