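import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from softgait import (StatisticsError, ChangeRatios, effect_size_r,
                      normality_gate, regress_upward_accel,
                      spearman_change_correlation, summarize_cohort,
                      wilcoxon_signed_rank)

from conftest import make_metric_frame


def exact_signflip_p(diffs):
    """Independent oracle: full enumeration of sign assignments over the
    average ranks of |d|, two-sided."""
    ranks = sps.rankdata(np.abs(diffs))
    w_obs = ranks[diffs > 0].sum()
    ws = [np.dot(signs, ranks)
          for signs in itertools.product((0.0, 1.0), repeat=len(ranks))]
    n_le = sum(w <= w_obs for w in ws)
    n_ge = sum(w >= w_obs for w in ws)
    return min(1.0, 2.0 * min(n_le, n_ge) / len(ws))


class TestNormalityGate:
    def test_heavy_skew_routed_nonparametric(self):
        hits = 0
        for seed in range(10):
            x = np.random.default_rng(seed).lognormal(0.0, 1.5, 500)
            route, p = normality_gate(x)
            hits += route == "non_normal"
        assert hits == 10

    def test_gaussian_nominal_level(self):
        routes = []
        for seed in range(30):
            x = np.random.default_rng(seed).normal(0.0, 1.0, 500)
            routes.append(normality_gate(x)[0])
        assert routes.count("normal") >= 26  # ~95% under the null

    def test_degenerate_inputs(self):
        with pytest.raises(StatisticsError):
            normality_gate([1.0, 2.0])
        with pytest.raises(StatisticsError):
            normality_gate([3.0] * 20)


class TestWilcoxon:
    def test_all_zero_differences_rejected(self):
        x = np.arange(8.0)
        with pytest.raises(StatisticsError, match="zero"):
            wilcoxon_signed_rank(x, x)

    def test_exact_matches_signflip_oracle(self):
        rng = np.random.default_rng(12)
        for n in range(5, 11):
            for _ in range(25):
                pre = rng.normal(10, 2, n)
                post = pre + rng.normal(0.3, 1.0, n)
                res = wilcoxon_signed_rank(pre, post, method="exact")
                assert res.p_value == pytest.approx(exact_signflip_p(post - pre))

    def test_exact_handles_tied_magnitudes(self):
        pre = np.array([10.0, 10, 10, 10, 10, 10])
        post = pre + np.array([1.0, 1.0, -1.0, 2.0, 2.0, 3.0])
        res = wilcoxon_signed_rank(pre, post, method="exact")
        assert res.p_value == pytest.approx(exact_signflip_p(post - pre))

    def test_approx_agrees_with_reference_implementation(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            pre = rng.normal(10, 2, 40)
            post = pre + rng.normal(0.5, 1.0, 40)
            res = wilcoxon_signed_rank(pre, post)
            ref = sps.wilcoxon(post, pre, correction=False, method="approx")
            assert res.p_value == pytest.approx(ref.pvalue, rel=1e-10)

    def test_signed_z_direction(self):
        pre = np.arange(1.0, 21.0)
        up = wilcoxon_signed_rank(pre, pre + 1.0)
        down = wilcoxon_signed_rank(pre, pre - 1.0)
        assert up.z_score > 0 > down.z_score
        assert up.p_value < 0.001

    def test_effect_size_attached(self):
        rng = np.random.default_rng(9)
        pre = rng.normal(10, 2, 30)
        res = wilcoxon_signed_rank(pre, pre + rng.normal(0.5, 1, 30))
        assert res.effect_size_r == pytest.approx(abs(res.z_score) / np.sqrt(res.n))
        assert 0 <= res.effect_size_r <= 1

    def test_zero_differences_dropped(self):
        pre = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        post = pre + np.array([0.0, 0, 1, -2, 3, 1, 2, -1])
        res = wilcoxon_signed_rank(pre, post)
        assert res.n == 8 and res.n_used == 6


class TestEffectSize:
    @pytest.mark.parametrize("z, n, expected", [
        (4.685, 223, 0.31),   # step length row
        (6.036, 223, 0.40),   # step counts row
        (2.820, 223, 0.19),   # upward acceleration row
        (0.127, 223, 0.01),   # walking speed row
        (0.0, 50, 0.0),
    ])
    def test_reported_values(self, z, n, expected):
        assert round(effect_size_r(z, n), 2) == expected

    def test_invalid_n(self):
        with pytest.raises(StatisticsError):
            effect_size_r(1.0, 0)


class TestSpearman:
    def test_monotone_extremes(self):
        x = np.linspace(0.9, 1.1, 10)
        up = ChangeRatios(step_length_ratio=x, upward_accel=x ** 3)
        down = ChangeRatios(step_length_ratio=x, upward_accel=x[::-1])
        assert spearman_change_correlation(up)[0] == pytest.approx(1.0)
        assert spearman_change_correlation(down)[0] == pytest.approx(-1.0)

    def test_small_example_matches_rank_formula(self):
        x = np.array([0.95, 1.02, 0.99, 1.10, 0.91, 1.05])
        y = np.array([0.97, 1.08, 0.96, 1.04, 0.90, 1.01])
        rho, _ = spearman_change_correlation(
            ChangeRatios(step_length_ratio=x, upward_accel=y))
        d = sps.rankdata(x) - sps.rankdata(y)
        n = len(x)
        assert rho == pytest.approx(1 - 6 * np.sum(d ** 2) / (n * (n ** 2 - 1)))

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0.8, 1.2, 30)
        y = rng.uniform(0.8, 1.2, 30)
        base = spearman_change_correlation(
            ChangeRatios(step_length_ratio=x, upward_accel=y))[0]
        warped = spearman_change_correlation(
            ChangeRatios(step_length_ratio=np.exp(x), upward_accel=y ** 5))[0]
        assert warped == pytest.approx(base)

    def test_degenerate_inputs(self):
        with pytest.raises(StatisticsError):
            spearman_change_correlation(ChangeRatios(
                step_length_ratio=np.full(10, 1.0),
                upward_accel=np.linspace(0.9, 1.1, 10)))
        with pytest.raises(StatisticsError):
            spearman_change_correlation(ChangeRatios(
                step_length_ratio=np.array([1.0, 1.1]),
                upward_accel=np.array([1.0, 1.1])))


class TestRegression:
    COEFS = {"const": -0.077, "step_length_ratio_norm": 36.141,
             "steps_per_min_norm": 0.082, "speed_m_s": 1.842}

    def _frame_from_model(self, rng, n=60, noise=0.0):
        frame = make_metric_frame(rng, n)
        y = (self.COEFS["const"]
             + self.COEFS["step_length_ratio_norm"] * frame["step_length_ratio_norm"]
             + self.COEFS["steps_per_min_norm"] * frame["steps_per_min_norm"]
             + self.COEFS["speed_m_s"] * frame["speed_m_s"])
        frame["upward_accel_norm"] = y + noise * rng.normal(size=n)
        return frame

    def test_noiseless_recovery(self):
        frame = self._frame_from_model(np.random.default_rng(8))
        res = regress_upward_accel(frame)
        for name, value in self.COEFS.items():
            assert res.params[name] == pytest.approx(value, abs=1e-8)

    def test_orthogonal_predictors_unit_vif(self):
        from scipy.linalg import hadamard
        h = np.tile(hadamard(4)[:, 1:], (4, 1)).astype(float)  # 16 x 3, orthogonal
        frame = pd.DataFrame({
            "participant_id": [f"P{i}" for i in range(16)],
            "label": "pre",
            "step_length_ratio_norm": 0.33 + 0.05 * h[:, 0],
            "steps_per_min_norm": 90 + 8 * h[:, 1],
            "speed_m_s": 1.35 + 0.2 * h[:, 2],
        })
        frame["upward_accel_norm"] = np.random.default_rng(0).normal(10, 1, 16)
        res = regress_upward_accel(frame)
        assert np.allclose(res.vif, 1.0, atol=1e-10)

    def test_duplicated_predictor_rank_deficient(self):
        frame = self._frame_from_model(np.random.default_rng(1))
        frame["speed_m_s"] = frame["step_length_ratio_norm"]
        with pytest.raises(StatisticsError, match="rank"):
            regress_upward_accel(frame)

    def test_standardized_beta_identity(self):
        rng = np.random.default_rng(4)
        frame = self._frame_from_model(rng, noise=0.5)
        res = regress_upward_accel(frame)
        y_sd = frame["upward_accel_norm"].std(ddof=1)
        for p in res.beta.index:
            expected = res.params[p] * frame[p].std(ddof=1) / y_sd
            assert res.beta[p] == pytest.approx(expected)
        assert np.all(res.vif >= 1.0)

    def test_too_few_rows(self):
        with pytest.raises(StatisticsError, match=">= 10"):
            regress_upward_accel(self._frame_from_model(np.random.default_rng(2), n=6))


class TestSummarizeCohort:
    def test_table_shape_and_columns(self, small_cohort):
        table = summarize_cohort(small_cohort)
        assert list(table.columns) == ["measurement", "pre", "post", "p_value",
                                       "z_score", "effect_size_r", "n"]
        assert len(table) == 4
        assert (table["n"] == 60).all()
        # ratios rendered to 3 decimals, speeds to 2
        assert table.loc[0, "pre"].count(".") >= 2
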