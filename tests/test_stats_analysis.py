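import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from beliefsim.stats_analysis import (
    bh_adjust,
    bootstrap_mediation,
    directional_error_filter,
    joint_regression_coef_diff,
    model_agnostic_indices,
    permutation_corr,
)


class TestDirectionalErrorFilter:
    def test_monotone_correct_run(self, make_traj):
        feedback = np.array([1, 0] * 10)
        reports = [0.5]
        for x in feedback:
            reports.append(reports[-1] + (0.02 if x else -0.02))
        n, excluded = directional_error_filter(make_traj(reports, feedback))
        assert (n, excluded) == (0, False)

    def test_exactly_nine_errors_excluded(self, make_traj):
        feedback = np.ones(20, dtype=int)
        reports = np.full(21, 0.5)
        # nine strict decreases after positive feedback, rest unchanged
        for t in range(1, 10):
            reports[t] = reports[t - 1] - 0.01
        reports[10:] = reports[9]
        n, excluded = directional_error_filter(make_traj(reports, feedback))
        assert (n, excluded) == (9, True)

    def test_unchanged_report_is_no_error(self, make_traj):
        feedback = np.array([1, 0] * 10)
        reports = np.full(21, 0.5)
        n, excluded = directional_error_filter(make_traj(reports, feedback))
        assert (n, excluded) == (0, False)

    def test_eight_errors_not_excluded(self, make_traj):
        feedback = np.ones(20, dtype=int)
        reports = np.full(21, 0.5)
        for t in range(1, 9):
            reports[t] = reports[t - 1] - 0.01
        reports[9:] = reports[8]
        n, excluded = directional_error_filter(make_traj(reports, feedback))
        assert (n, excluded) == (8, False)


class TestModelAgnosticIndices:
    def test_constant_reports(self, make_traj):
        traj = make_traj(np.full(21, 0.42), np.ones(20))
        start, end, change = model_agnostic_indices(traj)
        assert (start, end, change) == (0.42, 0.42, 0.0)

    def test_arithmetic(self, make_traj):
        reports = np.linspace(0.4, 0.7, 21)
        start, end, change = model_agnostic_indices(make_traj(reports, np.ones(20)))
        assert start == pytest.approx(0.4)
        assert end == pytest.approx(0.7)
        assert change == pytest.approx(0.3)

    def test_feedback_order_split_on_synthetic_cohort(self):
        # RW updating weights recent feedback most; the positive-first
        # sequence has only 4 positives in its last ten trials, so its
        # simulated belief change is lower: E[mu_20] = (1-eta)^20 mu_0
        # + eta*b*sum (1-eta)^(20-t) X_t favours late feedback
        from beliefsim.models import Referent
        from beliefsim.synthetic_data import CohortConfig, sample_cohort

        cohort = sample_cohort(CohortConfig(n_participants=120, seed=21))
        changes = {"positive_first": [], "negative_first": []}
        for t in cohort.trajectories:
            if t.referent is Referent.SELF:
                changes[t.feedback_order.value].append(model_agnostic_indices(t)[2])
        assert np.mean(changes["negative_first"]) > np.mean(changes["positive_first"])


class TestPermutationCorr:
    def test_exact_enumeration_identity_line(self):
        x = np.array([1.0, 2, 3, 4, 5])
        res = permutation_corr(x, x, enumerate_small=True)
        # only identity and reversal reach |r| = 1 among 120 permutations
        assert res.exact
        assert res.p_uncorrected == pytest.approx(2 / 120)
        assert res.r == pytest.approx(1.0)

    def test_add_one_bound(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=30), rng.normal(size=30)
        y = x + 0.01 * y  # extremely strong correlation
        res = permutation_corr(x, y, n_perm=1000, seed=1)
        assert res.p_uncorrected >= 1 / 1001
        assert res.p_uncorrected == pytest.approx(1 / 1001)

    def test_default_n_perm(self):
        rng = np.random.default_rng(2)
        res = permutation_corr(rng.normal(size=20), rng.normal(size=20))
        assert res.n_perm == 10_000

    def test_deterministic_by_seed(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(size=25), rng.normal(size=25)
        a = permutation_corr(x, y, n_perm=500, seed=7)
        b = permutation_corr(x, y, n_perm=500, seed=7)
        assert a.p_uncorrected == b.p_uncorrected

    def test_constant_input_error(self):
        with pytest.raises(ValueError):
            permutation_corr(np.ones(10), np.arange(10.0))

    def test_r_matches_scipy(self):
        from scipy.stats import pearsonr

        rng = np.random.default_rng(4)
        x, y = rng.normal(size=40), rng.normal(size=40)
        res = permutation_corr(x, y, n_perm=100, seed=0)
        assert res.r == pytest.approx(pearsonr(x, y).statistic)

    def test_agrees_with_exact_on_small_sample(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=6), rng.normal(size=6)
        exact = permutation_corr(x, y, enumerate_small=True)
        sampled = permutation_corr(x, y, n_perm=20_000, seed=6)
        assert sampled.p_uncorrected == pytest.approx(exact.p_uncorrected, abs=0.02)


class TestBHAdjust:
    def test_single_p_identity(self):
        np.testing.assert_allclose(bh_adjust([0.04]), [0.04])

    def test_hand_stepup(self):
        np.testing.assert_allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_twelve_test_family_example(self):
        # two smallest of twelve at 0.007/0.008, the rest large:
        # both adjust to 12*0.008/2 = 0.048
        p = [0.007, 0.008] + [0.28 + 0.05 * i for i in range(10)]
        adj = bh_adjust(p)
        assert adj[0] == pytest.approx(0.048)
        assert adj[1] == pytest.approx(0.048)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])

    @given(
        ps=st.lists(st.floats(0.0, 1.0), min_size=1, max_size=30)
    )
    @settings(max_examples=50)
    def test_properties(self, ps):
        adj = bh_adjust(ps)
        p = np.asarray(ps)
        assert (adj >= p - 1e-12).all()  # never decreases
        assert (adj <= 1.0).all()
        order = np.argsort(p, kind="stable")
        assert (np.diff(adj[order]) >= -1e-12).all()  # monotone in order stats


class TestJointRegression:
    def test_planted_linear_truth(self):
        rng = np.random.default_rng(0)
        mu0 = rng.uniform(0.2, 0.8, size=80)
        b = rng.uniform(0.5, 1.5, size=80)
        F = pd.DataFrame(
            {
                "general": rng.normal(size=80),
                "anxiety_specific": rng.normal(size=80),
                "depression_specific": 2.0 * mu0,
            }
        )
        out = joint_regression_coef_diff(F, mu0, b, n_perm=200, seed=1)
        dep = out["regressions"]["depression_specific"]["coef"]
        assert dep["mu0"] == pytest.approx(2.0, abs=1e-8)
        assert dep["b"] == pytest.approx(0.0, abs=1e-8)

    def test_null_calibration(self):
        # shuffled factors: difference p's roughly uniform over seeds
        rng = np.random.default_rng(2)
        n = 60
        mu0 = rng.uniform(0.2, 0.8, size=n)
        b = 0.5 * mu0 + rng.normal(scale=0.2, size=n)
        ps = []
        for seed in range(20):
            rs = np.random.default_rng(100 + seed)
            F = pd.DataFrame(rs.normal(size=(n, 3)),
                             columns=["general", "anxiety_specific", "depression_specific"])
            out = joint_regression_coef_diff(F, mu0, b, n_perm=200, seed=seed)
            ps.append(
                out["coefficient_differences"][
                    "mu0:anxiety_specific-depression_specific"
                ]["p"]
            )
        ps = np.array(ps)
        assert ps.min() < 0.5 < ps.max()
        assert np.mean(ps < 0.05) <= 0.25

    def test_interaction_lrt_reported(self):
        rng = np.random.default_rng(3)
        n = 50
        mu0 = rng.uniform(0, 1, n)
        b = rng.uniform(0, 2, n)
        F = pd.DataFrame(rng.normal(size=(n, 3)), columns=list("abc"))
        out = joint_regression_coef_diff(
            F, mu0, b, n_perm=50, seed=0, include_interaction=True
        )
        for entry in out["regressions"].values():
            assert 0.0 <= entry["interaction_lrt_p"] <= 1.0

    def test_rank_deficient_design(self):
        rng = np.random.default_rng(4)
        mu0 = rng.uniform(size=30)
        F = pd.DataFrame(rng.normal(size=(30, 1)), columns=["f"])
        with pytest.raises(np.linalg.LinAlgError):
            joint_regression_coef_diff(F, mu0, 2.0 * mu0, n_perm=10, seed=0)


class TestBootstrapMediation:
    def test_null_mediation(self):
        rng = np.random.default_rng(0)
        n = 200
        x = rng.normal(size=n)
        m = rng.normal(size=n)  # independent of x
        y = 0.8 * x + rng.normal(scale=0.3, size=n)
        res = bootstrap_mediation(x, m, y, n_boot=500, seed=1)
        assert abs(res.acme) < 0.05
        assert res.acme_p > 0.1

    def test_full_mediation(self):
        # y depends on x only through m; tiny noise on m keeps the
        # (x, m) design full-rank
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        m = 0.7 * x + 1e-6 * rng.normal(size=100)
        y = 1.3 * m
        res = bootstrap_mediation(x, m, y, n_boot=200, seed=2)
        assert res.acme == pytest.approx(res.total_effect, abs=1e-6)
        assert res.direct_effect == pytest.approx(0.0, abs=1e-6)

    def test_decomposition_identity(self):
        rng = np.random.default_rng(2)
        n = 150
        x = rng.normal(size=n)
        m = 0.5 * x + rng.normal(scale=0.5, size=n)
        y = 0.3 * x + 0.6 * m + rng.normal(scale=0.5, size=n)
        res = bootstrap_mediation(x, m, y, n_boot=200, seed=3)
        assert res.total_effect == pytest.approx(res.acme + res.direct_effect, abs=1e-8)

    def test_partial_correlation_analogue(self):
        # partialing out a mediator uncorrelated with both leaves r unchanged
        from scipy.stats import pearsonr
        import statsmodels.api as sm

        rng = np.random.default_rng(3)
        n = 300
        x = rng.normal(size=n)
        y = -0.4 * x + rng.normal(scale=0.8, size=n)
        m = rng.normal(size=n)
        r_raw = pearsonr(x, y).statistic
        rx = sm.OLS(x, sm.add_constant(m)).fit().resid
        ry = sm.OLS(y, sm.add_constant(m)).fit().resid
        r_partial = pearsonr(rx, ry).statistic
        assert r_partial == pytest.approx(r_raw, abs=0.05)


class TestTypeICalibrationSmall:
    def test_rejection_rate_near_alpha(self):
        # smaller version of the acceptance calibration check
        rng = np.random.default_rng(7)
        rejections = 0
        reps = 200
        for i in range(reps):
            x, y = rng.normal(size=(2, 30))
            res = permutation_corr(x, y, n_perm=199, seed=i)
            rejections += res.p_uncorrected <= 0.05
        rate = rejections / reps
        assert 0.01 <= rate <= 0.10
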