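"""Causal estimators: hand-arithmetic fixtures, equivalences, invariances."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from hba1c_mr import (
    AssocResult,
    grs_ratio_estimate,
    ivw,
    ivw_regression,
    leave_one_out,
    linear_assoc,
    mr_egger,
    wald_ratios,
    weighted_median,
)
from hba1c_mr.mr import WeightedMedianEstimator
from helpers import cohort_summary_stats, recovery_config, tsls_beta
from hba1c_mr import simulate_cohort


def assoc(beta, se, n=1000):
    return AssocResult(beta=beta, se=se, stat=beta / se, p=0.05, n=n,
                       r2=0.01, f_stat=(beta / se) ** 2)


def make_ss(bx, by, sx=None, sy=None):
    bx = np.asarray(bx, dtype=float)
    by = np.asarray(by, dtype=float)
    return pd.DataFrame(
        {
            "rsid": [f"rs{j}" for j in range(len(bx))],
            "bx": bx,
            "sx": np.full(len(bx), 0.01) if sx is None else np.asarray(sx, float),
            "by": by,
            "sy": np.full(len(bx), 0.05) if sy is None else np.asarray(sy, float),
        }
    )


def ss_from_ratios(ratios, ses, bx=1.0):
    """Summary stats whose first-order Wald ratios/SEs equal the given values."""
    ratios = np.asarray(ratios, dtype=float)
    ses = np.asarray(ses, dtype=float)
    return make_ss(np.full(len(ratios), bx), ratios * bx, sy=ses * bx)


class TestGrsRatio:
    def test_simple_ratio(self):
        res = grs_ratio_estimate(assoc(0.5, 0.1), assoc(0.25, 0.05))
        assert res.beta == pytest.approx(0.5)

    def test_delta_method_hand_value(self):
        res = grs_ratio_estimate(assoc(0.5, 0.1), assoc(0.2, 0.05))
        assert res.beta == pytest.approx(0.4)
        assert res.se == pytest.approx(np.sqrt(0.05**2 / 0.25 + 0.04 * 0.01 / 0.0625))
        assert res.se == pytest.approx(0.1280625, abs=1e-6)
        assert res.ci95 == pytest.approx((res.beta - 1.96 * res.se,
                                          res.beta + 1.96 * res.se))

    def test_exact_instrument_limit(self):
        res = grs_ratio_estimate(assoc(1.0, 1e-30), assoc(0.2, 0.05))
        assert res.beta == pytest.approx(0.2)
        assert res.se == pytest.approx(0.05)

    def test_weak_instrument_rejected(self):
        with pytest.raises(ValueError, match="weak-instrument"):
            grs_ratio_estimate(assoc(1e-14, 0.1), assoc(0.2, 0.05))


class TestWaldRatios:
    def test_single_snp(self):
        res = wald_ratios(make_ss([0.2], [0.1]))
        assert res[0].beta == pytest.approx(0.5)

    def test_allele_flip_invariance(self):
        a = wald_ratios(make_ss([0.2], [0.1]))[0]
        b = wald_ratios(make_ss([-0.2], [-0.1]))[0]
        assert a.beta == pytest.approx(b.beta)
        assert a.se == pytest.approx(b.se)

    def test_zero_bx_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero gene-exposure"):
            res = wald_ratios(make_ss([0.0, 0.2], [0.1, 0.1]))
        assert len(res) == 1

    def test_single_snp_ratio_equals_two_stage_least_squares(self):
        """On individual data with one genetic instrument, the ratio of the
        two regressions must agree with the 2SLS oracle."""
        g, df, _ = simulate_cohort(recovery_config(seed=42, n=10_000))
        z = g.dosages[:, 0].astype(float)
        ex = linear_assoc(df["hba1c"], z)
        out = linear_assoc(df["tc"], z)
        ratio = grs_ratio_estimate(ex, out).beta
        oracle = tsls_beta(df["tc"], df["hba1c"], z)
        assert ratio == pytest.approx(oracle, rel=1e-8)


class TestIvw:
    def test_two_ratio_hand_value(self):
        ss = ss_from_ratios([0.2, 0.5], [0.1, 0.2])
        res = ivw(ss)
        assert res.beta == pytest.approx(0.26)
        assert res.se == pytest.approx(1 / np.sqrt(125), abs=1e-6)

    def test_single_snp_equals_wald_ratio(self):
        ss = make_ss([0.3], [0.12])
        assert ivw(ss).beta == wald_ratios(ss)[0].beta
        assert ivw(ss).se == wald_ratios(ss)[0].se

    def test_homogeneous_ratios_have_zero_q(self):
        ss = ss_from_ratios([0.4, 0.4, 0.4], [0.1, 0.2, 0.3])
        res = ivw(ss)
        assert res.extras["Q"] == pytest.approx(0.0, abs=1e-20)
        assert res.extras["Q_df"] == 2

    @given(st.integers(0, 2**31 - 1))
    def test_ratio_form_equals_regression_form(self, seed):
        rng = np.random.default_rng(seed)
        J = 8
        ss = make_ss(rng.normal(0.1, 0.03, J), rng.normal(0.05, 0.02, J),
                     sx=rng.uniform(0.005, 0.02, J), sy=rng.uniform(0.01, 0.05, J))
        a = ivw(ss)
        b = ivw_regression(ss)
        assert a.beta == pytest.approx(b.beta, rel=1e-10)
        assert a.se == pytest.approx(b.se, rel=1e-10)

    def test_random_effects_inflates_se_under_heterogeneity(self):
        ss = ss_from_ratios([0.1, 0.9, -0.4, 0.5], [0.05] * 4)
        fe = ivw(ss)
        re = ivw(ss, random_effects=True)
        assert re.se > fe.se
        assert re.beta == pytest.approx(fe.beta)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            ivw(make_ss([], []))


class TestWeightedMedian:
    def test_equal_weight_triple(self):
        ss = ss_from_ratios([0.1, 0.2, 0.9], [0.1, 0.1, 0.1])
        assert weighted_median(ss, n_boot=100, seed=0).beta == pytest.approx(0.2)

    def test_majority_weight_snp_wins(self):
        # middle SNP carries 50% of the weight -> cumulative midpoint hits 0.5
        ses = np.array([0.1 / np.sqrt(0.25), 0.1 / np.sqrt(0.5), 0.1 / np.sqrt(0.25)])
        ss = ss_from_ratios([0.1, 0.4, 0.9], ses)
        assert weighted_median(ss, n_boot=100, seed=0).beta == pytest.approx(0.4)

    def test_input_order_invariance(self):
        ss = ss_from_ratios([0.5, 0.1, 0.9, 0.3], [0.1, 0.2, 0.15, 0.12])
        shuffled = ss.sample(frac=1, random_state=3).reset_index(drop=True)
        a = weighted_median(ss, n_boot=100, seed=1)
        b = weighted_median(shuffled, n_boot=100, seed=1)
        assert a.beta == pytest.approx(b.beta)

    def test_seeded_bootstrap_reproducible(self):
        ss = ss_from_ratios([0.1, 0.3, 0.8], [0.1, 0.1, 0.2])
        a = weighted_median(ss, n_boot=200, seed=5)
        b = weighted_median(ss, n_boot=200, seed=5)
        assert a.se == b.se

    def test_preconditions(self):
        with pytest.raises(ValueError):
            weighted_median(ss_from_ratios([0.1, 0.2], [0.1, 0.1]))
        with pytest.raises(ValueError, match="n_boot"):
            weighted_median(ss_from_ratios([0.1, 0.2, 0.3], [0.1] * 3), n_boot=10)


class TestMrEgger:
    def test_exact_affine_relation(self):
        bx = np.array([0.05, 0.1, 0.2, 0.15])
        ss = make_ss(bx, 0.05 + 0.4 * bx, sy=[0.03, 0.05, 0.02, 0.04])
        slope, intercept = mr_egger(ss)
        assert slope.beta == pytest.approx(0.4, abs=1e-10)
        assert intercept.beta == pytest.approx(0.05, abs=1e-10)

    def test_no_pleiotropy_null_intercept(self):
        bx = np.array([0.05, 0.1, 0.2])
        slope, intercept = mr_egger(make_ss(bx, 0.4 * bx))
        assert intercept.beta == pytest.approx(0.0, abs=1e-12)

    def test_orientation_invariance(self):
        bx = np.array([0.05, 0.1, 0.2, 0.15])
        by = 0.02 + 0.4 * bx
        flipped = make_ss(bx * [1, -1, 1, -1], by * [1, -1, 1, -1])
        slope, intercept = mr_egger(make_ss(bx, by))
        slope_f, intercept_f = mr_egger(flipped)
        assert slope.beta == pytest.approx(slope_f.beta)
        assert intercept.beta == pytest.approx(intercept_f.beta)

    def test_zero_intercept_form_reproduces_regression_ivw(self):
        bx = np.array([0.05, 0.1, 0.2, 0.15])
        ss = make_ss(bx, 0.4 * bx, sy=[0.03, 0.05, 0.02, 0.04])
        constrained, _ = mr_egger(ss, fit_intercept=False)
        reference = ivw_regression(ss)
        assert constrained.beta == pytest.approx(reference.beta, rel=1e-12)
        # exact fit -> residual factor floored at 1 -> identical SEs too
        assert constrained.se == pytest.approx(reference.se, rel=1e-12)

    def test_degenerate_bx_rejected(self):
        with pytest.raises(ValueError, match="spread"):
            mr_egger(make_ss([0.1, 0.1, 0.1], [0.04, 0.04, 0.04]))


class TestLeaveOneOut:
    def test_two_snp_case(self):
        ss = ss_from_ratios([0.2, 0.6], [0.1, 0.1])
        loo = leave_one_out(ss).set_index("rsid")
        assert loo.loc["rs0", "beta"] == pytest.approx(0.6)
        assert loo.loc["rs1", "beta"] == pytest.approx(0.2)

    def test_homogeneous_ratios_match_full_ivw(self):
        ss = ss_from_ratios([0.4] * 5, [0.1, 0.2, 0.1, 0.3, 0.2])
        full = ivw(ss).beta
        loo = leave_one_out(ss)
        np.testing.assert_allclose(loo["beta"], full)

    def test_outlier_removal_moves_toward_median(self):
        ratios = [0.29, 0.30, 0.31, 0.30, 0.90]
        ss = ss_from_ratios(ratios, [0.05] * 5)
        med = np.median(ratios)
        full = ivw(ss).beta
        loo = leave_one_out(ss).set_index("rsid")
        assert abs(loo.loc["rs4", "beta"] - med) < abs(full - med)

    def test_minimum_size(self):
        with pytest.raises(ValueError):
            leave_one_out(ss_from_ratios([0.1], [0.1]))


class TestSignFlipInvariance:
    @given(st.integers(0, 2**31 - 1))
    def test_joint_flip_of_any_subset_preserves_estimates(self, seed):
        rng = np.random.default_rng(seed)
        J = 7
        ss = make_ss(rng.uniform(0.05, 0.2, J), rng.normal(0.05, 0.03, J),
                     sx=rng.uniform(0.005, 0.02, J), sy=rng.uniform(0.02, 0.05, J))
        flip = rng.random(J) < 0.5
        sign = np.where(flip, -1.0, 1.0)
        flipped = ss.assign(bx=ss["bx"] * sign, by=ss["by"] * sign)
        assert ivw(ss).beta == pytest.approx(ivw(flipped).beta, rel=1e-12)
        theta, w = ss["by"] / ss["bx"], (ss["bx"] / ss["sy"]) ** 2
        point = WeightedMedianEstimator._point
        assert point(theta.to_numpy(), w.to_numpy()) == pytest.approx(
            point((flipped["by"] / flipped["bx"]).to_numpy(),
                  ((flipped["bx"] / flipped["sy"]) ** 2).to_numpy())
        )
        assert mr_egger(ss)[0].beta == pytest.approx(mr_egger(flipped)[0].beta, rel=1e-12)
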