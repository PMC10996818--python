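"""Rating transforms, two-part mixed models, ICC/R-squared, Mann-Whitney U."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import neurosync as ns
from neurosync.emotions import LATENT_LOGISTIC_VAR, _fit_logistic_glmm
from neurosync.synth import RatingsGenSpec


class TestTransform:
    def test_negative_emotion_extremes(self):
        out = ns.transform_ratings(np.array([100.0, 0.0, 50.0]), "anger")
        assert out["transformed"][0] == 0.0 and out["extreme"][0]
        assert out["transformed"][1] == pytest.approx(np.log(101), abs=1e-12)
        assert not out["extreme"][1]

    def test_joy_extreme_at_zero(self):
        out = ns.transform_ratings(np.array([0.0, 100.0]), "joy")
        assert out["transformed"][0] == 0.0 and out["extreme"][0]
        assert out["transformed"][1] == pytest.approx(np.log(101))

    def test_fear_passthrough(self):
        vals = np.array([0.0, 42.5, 100.0])
        out = ns.transform_ratings(vals, "fear")
        np.testing.assert_array_equal(out["transformed"], vals)
        assert not out["extreme"].any()

    def test_out_of_range_rejected(self):
        with pytest.raises(ns.InvalidSpecError):
            ns.transform_ratings(np.array([101.0]), "anger")

    @settings(deadline=None, derandomize=True)
    @given(
        st.lists(st.floats(min_value=0, max_value=100), min_size=1, max_size=30),
        st.sampled_from(["anger", "disgust", "sadness", "joy", "fear"]),
    )
    def test_bijection_round_trip(self, raws, emotion):
        raw = np.array(raws)
        t = ns.transform_ratings(raw, emotion)["transformed"].to_numpy()
        back = ns.inverse_transform(t, emotion)
        np.testing.assert_allclose(back, raw, atol=1e-12, rtol=1e-12)


class TestVariancePartition:
    def test_icc_gaussian_worked_examples(self):
        assert round(ns.icc_gaussian(0.28, 0.35), 3) == 0.444
        assert round(ns.icc_gaussian(492.76, 333.88), 3) == 0.596
        assert ns.icc_gaussian(0.0, 1.0) == 0.0

    def test_icc_logistic_worked_examples(self):
        assert round(ns.icc_logistic(4.27), 3) == 0.565
        assert round(ns.icc_logistic(3.70), 3) == 0.529
        assert ns.icc_logistic(0.0) == 0.0

    def test_r2_identity_with_icc(self):
        # conditional = marginal + (1 - marginal) * ICC, algebraically
        for vf, tau, s2 in [(0.01, 0.3, 0.4), (1.5, 0.2, 2.0), (0.0, 0.5, 0.5)]:
            m, c = ns.r2_nakagawa(vf, tau, s2)
            icc = ns.icc_gaussian(tau, s2)
            assert c == pytest.approx(m + (1 - m) * icc, abs=1e-12)

    def test_r2_worked_example(self):
        # marginal 0.010 with tau00=0.28, sigma2=0.35 implies var_fixed
        vf = 0.010 / 0.990 * (0.28 + 0.35)
        m, c = ns.r2_nakagawa(vf, 0.28, 0.35)
        assert round(m, 3) == 0.010 and round(c, 3) == 0.450

    def test_zero_variance_rejected(self):
        with pytest.raises(ns.InvalidSpecError):
            ns.r2_nakagawa(0.0, 0.0, 0.0)
        with pytest.raises(ns.InvalidSpecError):
            ns.icc_gaussian(0.1, 0.0)


class TestLogisticGLMM:
    def test_recovers_known_coefficients(self):
        rng = np.random.default_rng(0)
        n_sub, n_obs = 150, 12
        beta = np.array([0.8, -0.6, 0.4, -1.0])
        sd_u = 1.0
        rows = []
        for i in range(n_sub):
            u = sd_u * rng.standard_normal()
            g = i % 2
            for t in (0, 1):
                for _ in range(n_obs // 2):
                    eta = beta[0] + beta[1] * t + beta[2] * g + beta[3] * t * g + u
                    y = rng.random() < 1 / (1 + np.exp(-eta))
                    rows.append((i, t, g, float(y)))
        df = pd.DataFrame(rows, columns=["subject", "time", "group", "y"])
        X = np.column_stack(
            [np.ones(len(df)), df["time"], df["group"], df["time"] * df["group"]]
        )
        fit = _fit_logistic_glmm(X, df["y"].to_numpy(), df["subject"].to_numpy())
        np.testing.assert_allclose(fit["coef"], beta, atol=0.35)
        assert abs(fit["sd_u"] - sd_u) < 0.35
        assert fit["converged"]


class TestTwoPartFit:
    def test_or_equals_exp_of_coefficient(self):
        df = ns.simulate_ratings(RatingsGenSpec(n_subjects=40, seed=2))
        fit = ns.fit_two_part_zig(df, emotion="anger")
        np.testing.assert_allclose(
            fit.logistic.odds_ratio, np.exp(fit.logistic.coef), rtol=1e-12
        )
        assert fit.logistic.sigma2 == LATENT_LOGISTIC_VAR

    def test_no_extremes_equals_plain_lmm(self):
        # without extreme rows the two-part model degenerates to one LMM
        spec = RatingsGenSpec(n_subjects=30, logit_coefs=(50.0, 0, 0, 0), seed=3)
        df = ns.simulate_ratings(spec)
        assert (df["value"] == 100).sum() == 0
        fit = ns.fit_two_part_zig(df, emotion="anger")
        assert fit.logistic_skipped and fit.logistic is None
        import statsmodels.api as sm

        t = ns.transform_ratings(df["value"].to_numpy(), "anger")["transformed"]
        X = np.column_stack(
            [np.ones(len(df)), df["session"], df["group"],
             df["session"] * df["group"]]
        )
        direct = sm.MixedLM(t.to_numpy(), X, groups=df["subject"].to_numpy()).fit(
            reml=False
        )
        np.testing.assert_allclose(fit.gaussian.coef, direct.fe_params, atol=1e-6)

    def test_constant_group_rank_deficient(self):
        df = ns.simulate_ratings(RatingsGenSpec(n_subjects=20, seed=4))
        df["group"] = 0
        with pytest.raises(ns.InvalidSpecError, match="rank deficient"):
            ns.fit_two_part_zig(df, emotion="anger")

    def test_fear_rejected_by_two_part(self):
        df = ns.simulate_ratings(RatingsGenSpec(n_subjects=20, seed=5))
        df["emotion"] = "fear"
        with pytest.raises(ns.InvalidSpecError):
            ns.fit_two_part_zig(df, emotion="fear")


class TestGaussianLMM:
    def test_near_exact_recovery_with_tiny_noise(self):
        rng = np.random.default_rng(0)
        beta = np.array([50.0, 2.0, -3.0, 4.0])
        rows = []
        for i in range(24):
            g = i % 2
            for t in (0, 1):
                for _ in range(4):
                    y = beta[0] + beta[1] * t + beta[2] * g + beta[3] * t * g
                    rows.append((f"s{i}", t, g, "fear", y + 1e-7 * rng.standard_normal()))
        df = pd.DataFrame(rows, columns=["subject", "session", "group", "emotion", "value"])
        fit = ns.fit_gaussian_lmm(df, emotion="fear")
        np.testing.assert_allclose(fit.coef, beta, atol=1e-6)

    def test_single_observation_per_subject_flagged(self):
        rng = np.random.default_rng(1)
        n = 40
        df = pd.DataFrame(
            {
                "subject": [f"s{i}" for i in range(n)],
                "session": [i % 2 for i in range(n)],
                "group": [i // (n // 2) for i in range(n)],
                "emotion": "fear",
                "value": rng.uniform(0, 100, n),
            }
        )
        fit = ns.fit_gaussian_lmm(df, emotion="fear")
        assert any("identifiable" in note for note in fit.notes)

    def test_icc_consistent_with_variance_components(self):
        df = ns.simulate_ratings(RatingsGenSpec(n_subjects=40, seed=6))
        df["emotion"] = "fear"  # treat raw values as untransformed outcome
        fit = ns.fit_gaussian_lmm(df, emotion="fear")
        assert fit.icc == pytest.approx(
            fit.tau00 / (fit.tau00 + fit.sigma2), abs=1e-12
        )


class TestMannWhitney:
    def test_complete_separation(self):
        u, _ = ns.mann_whitney_u([1.0, 2.0], [3.0, 4.0])
        assert u == 0.0

    def test_identical_samples_symmetric_u(self):
        a = [1.0, 5.0, 9.0]
        u, _ = ns.mann_whitney_u(a, list(a))
        assert u == len(a) * len(a) / 2

    def test_exact_enumeration_small_samples(self):
        # 20 equally likely rank assignments; only the two most extreme
        # orderings are as separated: p = 2/20 = 0.1
        _, p = ns.mann_whitney_u([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ns.InvalidSpecError):
            ns.mann_whitney_u([], [1.0])
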