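"""MR estimator suite: closed-form cases, independent matrix/quadrature
oracles, robustness and invariance properties."""

import numpy as np
import pytest
from scipy import stats

from mirqtl.mr import (MRInput, bidirectional_mr, cochran_q, enrichment_test, ivw, ivw_correlated, mr_bma, mr_egger,
                       mr_presso, mvmr, two_step_mediation, wald_ratio,
                       weighted_median)


def _valid_input(rng, J=10, theta=0.3, se_by=0.02, se_bx=0.01):
    bx_true = rng.uniform(0.1, 0.3, J) * rng.choice([-1, 1], J)
    bx = bx_true + rng.normal(0, se_bx, J)
    by = bx_true * theta + rng.normal(0, se_by, J)
    return MRInput(bx, se_bx, by, se_by)


class TestWaldRatio:
    def test_arithmetic(self):
        assert wald_ratio(0.1, 0.2, 0.05) == (2.0, 0.5)
        assert wald_ratio(0.1, 0.0, 0.05)[0] == 0.0
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.2, 0.05)

    def test_se_matches_parametric_bootstrap(self, rng):
        bx, by, se_by = 0.2, 0.06, 0.02
        _, se = wald_ratio(bx, by, se_by)
        draws = rng.normal(by, se_by, 100_000) / bx
        assert se == pytest.approx(draws.std(ddof=1), rel=0.05)


class TestIVW:
    def test_equal_ratios_give_exact_theta_and_zero_q(self):
        inp = MRInput([0.1, 0.2, 0.3], 0.01, [0.05, 0.10, 0.15], 0.02)
        res = ivw(inp)
        assert res.theta == pytest.approx(0.5)
        assert res.Q == pytest.approx(0.0, abs=1e-20)
        assert res.se == pytest.approx(ivw(inp, model="FE").se)

    def test_single_instrument_directs_to_wald_ratio(self):
        with pytest.raises(ValueError, match="wald_ratio"):
            ivw(MRInput([0.1], 0.01, [0.05], 0.02))

    def test_calibration_over_replicates(self):
        rng = np.random.default_rng(77)
        est, covered = [], 0
        for _ in range(1000):
            inp = _valid_input(rng)
            res = ivw(inp)
            est.append(res.theta)
            lo, hi = res.ci()
            covered += lo <= 0.3 <= hi
        assert abs(np.mean(est) - 0.3) < 0.01
        assert 0.92 <= covered / 1000 <= 0.97


class TestIVWCorrelated:
    def test_identity_correlation_reduces_to_fe(self, rng):
        inp = _valid_input(rng)
        inp.corr = np.eye(inp.J)
        a = ivw_correlated(inp)
        b = ivw(inp, model="FE")
        assert a.theta == pytest.approx(b.theta, abs=1e-10)
        assert a.se == pytest.approx(b.se, abs=1e-10)

    def test_duplicated_instrument_collapses(self, rng):
        bx, by, se = 0.2, 0.06, 0.02
        inp = MRInput([bx, bx], 0.01, [by, by], se,
                      corr=np.array([[1.0, 0.999], [0.999, 1.0]]))
        single = by / bx
        assert ivw_correlated(inp).theta == pytest.approx(single, abs=1e-3)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_direct_gls_oracle(self, seed):
        rng = np.random.default_rng(seed)
        J = 8
        inp = _valid_input(rng, J=J)
        A = rng.normal(size=(J, J))
        C = A @ A.T + J * np.eye(J)
        d = np.sqrt(np.diag(C))
        inp.corr = C / np.outer(d, d)
        res = ivw_correlated(inp)
        omega = np.outer(inp.se_by, inp.se_by) * inp.corr
        oi = np.linalg.inv(omega)
        theta = (inp.bx @ oi @ inp.by) / (inp.bx @ oi @ inp.bx)
        se = 1 / np.sqrt(inp.bx @ oi @ inp.bx)
        assert res.theta == pytest.approx(theta, abs=1e-8)
        assert res.se == pytest.approx(se, abs=1e-8)


class TestEgger:
    def test_too_few_instruments_raise(self):
        with pytest.raises(ValueError):
            mr_egger(MRInput([0.1, 0.2], 0.01, [0.05, 0.1], 0.02))

    def test_constant_outcome_shift_moves_intercept_only(self):
        bx = np.array([0.1, 0.15, 0.2, 0.25, 0.3])
        by = 0.4 * bx
        base = mr_egger(MRInput(bx, 0.01, by, 0.02))
        shifted = mr_egger(MRInput(bx, 0.01, by + 0.05, 0.02))
        assert shifted.theta == pytest.approx(base.theta, abs=1e-10)
        assert shifted.egger_intercept == pytest.approx(
            base.egger_intercept + 0.05, abs=1e-10)

    def test_intercept_null_calibrated(self):
        rng = np.random.default_rng(5)
        cover = 0
        n_rep = 500
        for _ in range(n_rep):
            res = mr_egger(_valid_input(rng, J=12))
            cover += res.p_intercept > 0.05
        assert cover / n_rep > 0.90  # nominal 95%, MRE scaling conservative


class TestWeightedMedian:
    def test_odd_j_equal_weights_is_middle_ratio(self):
        inp = MRInput([0.1, 0.1, 0.1], 0.01, [0.01, 0.02, 0.05], 0.01)
        res = weighted_median(inp, n_boot=0)
        assert res.theta == pytest.approx(0.2)

    def test_fixed_seed_reproducible_se(self, rng):
        inp = _valid_input(rng)
        a = weighted_median(inp, n_boot=500, seed=3)
        b = weighted_median(inp, n_boot=500, seed=3)
        assert a.se == b.se

    def test_beats_ivw_under_directional_pleiotropy(self):
        rng = np.random.default_rng(11)
        bias_ivw, bias_wm = [], []
        for _ in range(500):
            J = 10
            bx_true = rng.uniform(0.1, 0.3, J)
            bx = bx_true + rng.normal(0, 0.01, J)
            by = bx_true * 0.3 + rng.normal(0, 0.02, J)
            by[:4] += 0.08  # 40% invalid with directional pleiotropy
            inp = MRInput(bx, 0.01, by, 0.02)
            bias_ivw.append(ivw(inp).theta - 0.3)
            bias_wm.append(weighted_median(inp, n_boot=0).theta - 0.3)
        assert abs(np.mean(bias_wm)) < abs(np.mean(bias_ivw))


class TestCochranQ:
    def test_hand_formula_on_three_instruments(self):
        inp = MRInput([0.1, 0.2, 0.4], 0.01, [0.03, 0.09, 0.1], 0.02)
        r = inp.by / inp.bx
        w = (inp.bx / inp.se_by) ** 2
        theta = np.sum(w * r) / np.sum(w)
        expected = np.sum(w * (r - theta) ** 2)
        Q, p = cochran_q(inp)
        assert Q == pytest.approx(expected, abs=1e-12)
        assert p == pytest.approx(stats.chi2.sf(expected, 2), abs=1e-12)

    def test_null_distribution_is_chi2(self):
        rng = np.random.default_rng(8)
        qs = []
        for _ in range(2000):
            J = 6
            bx = rng.uniform(0.2, 0.4, J)  # tight bx: ratio normality holds
            by = bx * 0.3 + rng.normal(0, 0.02, J)
            qs.append(cochran_q(MRInput(bx, 1e-6, by, 0.02))[0])
        ks = stats.kstest(qs, stats.chi2(5).cdf)
        assert ks.pvalue > 0.01


class TestPresso:
    def test_clean_data_global_p_rarely_small(self):
        rng = np.random.default_rng(21)
        small = 0
        for rep in range(200):
            gp, out, _ = mr_presso(_valid_input(rng), n_sim=1000, seed=rep)
            small += gp < 0.05
        assert small / 200 <= 0.10

    def test_injected_outlier_flagged(self):
        rng = np.random.default_rng(22)
        flagged = 0
        for rep in range(100):
            inp = _valid_input(rng)
            inp.by[3] += 10 * inp.se_by[3]
            _, out, corrected = mr_presso(inp, n_sim=1000, seed=rep)
            flagged += inp.ids[3] in out
        assert flagged / 100 >= 0.90

    def test_fixed_seed_deterministic(self, rng):
        inp = _valid_input(rng)
        assert mr_presso(inp, 1000, seed=5)[0] == mr_presso(inp, 1000, seed=5)[0]

    def test_too_few_instruments_raise(self):
        with pytest.raises(ValueError):
            mr_presso(MRInput([0.1] * 3, 0.01, [0.05] * 3, 0.02), 1000, 0)


class TestMVMR:
    def test_null_second_exposure_recovered(self):
        rng = np.random.default_rng(31)
        est2, covered = [], 0
        for _ in range(500):
            J = 12
            BX = rng.normal(0, 0.2, (J, 2))
            by = BX[:, 0] * 0.4 + rng.normal(0, 0.02, J)
            res = mvmr(BX, 0.01, by, np.full(J, 0.02))
            t2 = res[res["exposure"] == "X2"].iloc[0]
            est2.append(t2["theta"])
            covered += abs(t2["theta"]) <= 1.96 * t2["se"]
        assert abs(np.mean(est2)) < 0.02
        assert covered / 500 > 0.90

    def test_duplicated_exposure_column_raises(self, rng):
        BX = rng.normal(size=(10, 2))
        BX[:, 1] = BX[:, 0]
        with pytest.raises(ValueError, match="collinear"):
            mvmr(BX, 0.01, rng.normal(size=10), np.full(10, 0.02))

    def test_orthogonal_design_matches_univariable_ivw(self):
        rng = np.random.default_rng(32)
        J = 40
        BX = np.zeros((J, 2))
        BX[:20, 0] = rng.uniform(0.1, 0.3, 20)
        BX[20:, 1] = rng.uniform(0.1, 0.3, 20)
        by = BX[:, 0] * 0.4 + BX[:, 1] * (-0.2) + rng.normal(0, 0.01, J)
        res = mvmr(BX, 0.01, by, np.full(J, 0.01))
        u1 = ivw(MRInput(BX[:20, 0], 0.01, by[:20], 0.01), model="FE")
        assert res["theta"].iloc[0] == pytest.approx(u1.theta, abs=0.01)


class TestBMA:
    def test_true_exposure_gets_top_inclusion(self):
        rng = np.random.default_rng(41)
        wins = 0
        for _ in range(100)  :
            J = 30
            BX = rng.normal(0, 0.2, (J, 3))
            by = BX[:, 0] * 0.5 + rng.normal(0, 0.02, J)
            res = mr_bma(BX, 0.01, by, np.full(J, 0.02))
            wins += res["inclusion_probability"].idxmax() == 0
        assert wins >= 95

    def test_vanishing_inclusion_prior_selects_null_model(self, rng):
        BX = rng.normal(0, 0.2, (15, 2))
        by = rng.normal(0, 0.02, 15)
        res = mr_bma(BX, 0.01, by, np.full(15, 0.02), prior_incl=1e-9)
        assert res["inclusion_probability"].max() < 1e-3

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_multivariate_normal_oracle_at_k4(self, seed):
        rng = np.random.default_rng(seed)
        J, K = 20, 4
        BX = rng.normal(0, 0.2, (J, K))
        by = BX[:, 1] * 0.3 + rng.normal(0, 0.02, J)
        se_by = np.full(J, 0.02)
        prior_incl, prior_var = 0.1, 0.25
        res = mr_bma(BX, 0.01, by, se_by, prior_incl, prior_var)
        # oracle: score every model through the full covariance mvn logpdf
        ytil = by / se_by
        Xtil = BX / se_by[:, None]
        logps = []
        for s in range(2 ** K):
            members = [k for k in range(K) if s >> k & 1]
            Xs = Xtil[:, members]
            cov = Xs @ (prior_var * np.eye(len(members))) @ Xs.T + np.eye(J)
            lp = (len(members) * np.log(prior_incl)
                  + (K - len(members)) * np.log(1 - prior_incl)
                  + stats.multivariate_normal.logpdf(ytil, np.zeros(J), cov))
            logps.append(lp)
        post = np.exp(logps - np.logaddexp.reduce(logps))
        incl_oracle = np.zeros(K)
        for s in range(2 ** K):
            for k in range(K):
                if s >> k & 1:
                    incl_oracle[k] += post[s]
        np.testing.assert_allclose(res["inclusion_probability"], incl_oracle,
                                   atol=1e-6)

    def test_k_too_large_raises(self, rng):
        with pytest.raises(ValueError, match="screen"):
            mr_bma(rng.normal(size=(30, 13)), 0.01, rng.normal(size=30),
                   np.full(30, 0.02))


class TestMediation:
    def test_arithmetic_cases(self):
        res = two_step_mediation(1.0, 0.1, 0.5, 0.05, 0.4, 0.05)
        assert res.proportion_mediated == pytest.approx(0.20)
        res0 = two_step_mediation(1.0, 0.1, 0.0, 0.05, 0.4, 0.05)
        assert res0.proportion_mediated == 0.0
        with pytest.raises(ZeroDivisionError):
            two_step_mediation(0.0, 0.1, 0.5, 0.05, 0.4, 0.05)

    def test_delta_ci_matches_bootstrap_at_small_se(self):
        d = two_step_mediation(1.0, 0.01, 0.7, 0.01, 0.7, 0.01,
                               ci_method="delta")
        b = two_step_mediation(1.0, 0.01, 0.7, 0.01, 0.7, 0.01,
                               ci_method="bootstrap", n_boot=200_000, seed=1)
        assert d.ci_lower == pytest.approx(b.ci_lower, abs=0.002)
        assert d.ci_upper == pytest.approx(b.ci_upper, abs=0.002)


class TestBidirectional:
    def test_forward_only_effect_detected_and_reverse_null(self):
        rng = np.random.default_rng(51)
        fwd_sig, rev_sig = 0, 0
        for _ in range(200):
            fwd = _valid_input(rng, theta=0.3)
            rev = _valid_input(rng, theta=0.0)
            rev.ids = [f"rev{j}" for j in range(rev.J)]
            res = bidirectional_mr(fwd, rev)
            fwd_sig += res["forward"].pval < 0.05
            rev_sig += res["reverse"].pval < 0.05
        assert fwd_sig / 200 > 0.95
        assert rev_sig / 200 <= 0.07

    def test_identical_inputs_give_symmetric_outputs(self, rng):
        inp = _valid_input(rng)
        with pytest.warns(UserWarning, match="shared"):
            res = bidirectional_mr(inp, inp)
        assert res["forward"].theta == res["reverse"].theta
        assert set(res["shared_instruments"]) == set(inp.ids)


class TestEnrichment:
    def test_disjoint_sets_give_p_near_one(self):
        universe = {f"g{i}" for i in range(1000)}
        res = enrichment_test({"g1", "g2", "g3"}, {"g10", "g11", "g12"},
                              universe)
        assert res.pval > 0.95 and res.overlap == 0

    def test_identical_sets_match_enumeration_oracle(self):
        universe = {f"g{i}" for i in range(40)}
        target = {f"g{i}" for i in range(4)}
        res = enrichment_test(target, target, universe)
        # oracle: exhaustive hypergeometric tail P(overlap >= 4)
        from math import comb

        p_oracle = comb(4, 4) * comb(36, 0) / comb(40, 4)
        assert res.pval == pytest.approx(p_oracle, rel=1e-9)

    def test_subset_violation_raises(self):
        with pytest.raises(ValueError):
            enrichment_test({"x"}, {"y"}, {"y"})


class TestInvariances:
    def test_outcome_scale_equivariance(self, rng):
        inp = _valid_input(rng)
        c = 3.7
        scaled = MRInput(inp.bx, inp.se_bx, c * inp.by, c * inp.se_by)
        for fn in (lambda d: ivw(d), lambda d: mr_egger(d),
                   lambda d: weighted_median(d, n_boot=0)):
            a, b = fn(inp), fn(scaled)
            assert b.theta == pytest.approx(c * a.theta, rel=1e-9)
            if np.isfinite(a.se):
                assert b.se == pytest.approx(c * a.se, rel=1e-9)

    def test_instrument_order_invariance(self, rng):
        inp = _valid_input(rng)
        perm = rng.permutation(inp.J)
        shuffled = MRInput(inp.bx[perm], inp.se_bx[perm], inp.by[perm],
                           inp.se_by[perm])
        assert ivw(shuffled).theta == pytest.approx(ivw(inp).theta, abs=1e-12)
        assert mr_egger(shuffled).theta == pytest.approx(
            mr_egger(inp).theta, abs=1e-12)

    def test_estimators_agree_with_valid_instruments(self):
        rng = np.random.default_rng(61)
        diffs = []
        for _ in range(100)  :
            inp = _valid_input(rng, J=15)
            t = [ivw(inp).theta, mr_egger(inp).theta,
                 weighted_median(inp, n_boot=0).theta]
            diffs.append(max(t) - min(t))
        assert np.median(diffs) < 0.1
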