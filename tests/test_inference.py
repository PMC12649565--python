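"""Statistical endpoints: delta pairing, gated tests, mixed models, power."""

import numpy as np
import pandas as pd
import pytest

from hrvpipe.inference import (
    categorical_compare,
    cohens_d_from_summary,
    delta,
    fisher_from_counts,
    fit_mixed_model,
    group_compare,
    power_two_sample,
    sample_size_two_sample,
)


def _entropy_table(rows):
    return pd.DataFrame(rows, columns=["subject", "visit", "position",
                                       "sampen", "entropy_rate"])


class TestDelta:
    def test_identical_visits_zero_delta(self):
        rows = [(f"s{i}", v, "begin", 1.5, 2.0)
                for i in range(5) for v in ("first", "last")]
        d = delta(_entropy_table(rows), "begin")
        assert (d["sampen"] == 0.0).all()
        assert (d["entropy_rate"] == 0.0).all()

    def test_pairing_rule_excludes_incomplete(self):
        rows = [("s1", "first", "begin", 1.0, 1.0),
                ("s1", "last", "begin", 2.0, 2.0),
                ("s2", "first", "begin", 1.0, 1.0)]  # s2 has no last visit
        d = delta(_entropy_table(rows), "begin")
        assert list(d.index) == ["s1"]
        assert d.loc["s1", "sampen"] == 1.0

    def test_position_specific_accounting(self):
        # 10 subjects; 8 have valid last-begin, 6 valid last-end
        rows = []
        for i in range(10):
            rows += [(f"s{i}", "first", "begin", 1.0, 1.0),
                     (f"s{i}", "first", "end", 1.0, 1.0)]
            if i < 8:
                rows.append((f"s{i}", "last", "begin", 2.0, 2.0))
            if i < 6:
                rows.append((f"s{i}", "last", "end", 2.0, 2.0))
        table = _entropy_table(rows)
        assert len(delta(table, "begin")) == 8
        assert len(delta(table, "end")) == 6


class TestGroupCompare:
    def test_null_effect_d_zero(self, rng):
        vals = np.concatenate([np.array([1.0, 2.0, 3.0, 4.0])] * 2)
        groups = ["intervention"] * 4 + ["control"] * 4
        res = group_compare(vals, np.array(groups))
        assert res.effect_d == pytest.approx(0.0)

    def test_one_sided_p_below_two_sided_in_correct_direction(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            gi = r.normal(1.0, 1.0, 12)
            gc = r.normal(0.0, 1.0, 8)
            vals = np.concatenate([gi, gc])
            groups = np.array(["intervention"] * 12 + ["control"] * 8)
            one = group_compare(vals, groups, sided="one")
            two = group_compare(vals, groups, sided="two")
            assert one.p_value < two.p_value

    def test_cohens_d_hand_formula(self, rng):
        gi = rng.normal(2.0, 1.0, 10)
        gc = rng.normal(0.0, 1.5, 14)
        vals = np.concatenate([gi, gc])
        groups = np.array(["intervention"] * 10 + ["control"] * 14)
        res = group_compare(vals, groups)
        pooled = np.sqrt((9 * np.var(gi, ddof=1) + 13 * np.var(gc, ddof=1)) / 22)
        assert res.effect_d == pytest.approx((gi.mean() - gc.mean()) / pooled,
                                             abs=1e-12)

    def test_nonnormal_data_routes_to_mann_whitney(self, rng):
        gi = np.exp(rng.normal(0, 2.5, 30))  # heavily skewed
        gc = np.exp(rng.normal(0, 2.5, 30))
        vals = np.concatenate([gi, gc])
        groups = np.array(["intervention"] * 30 + ["control"] * 30)
        res = group_compare(vals, groups)
        assert res.test_name == "mann-whitney-u"
        assert res.effect_r is not None and 0 <= res.effect_r <= 1

    def test_zero_variance_undefined(self):
        vals = np.full(10, 3.0)
        groups = np.array(["intervention"] * 5 + ["control"] * 5)
        res = group_compare(vals, groups)
        assert res.test_name == "undefined"


class TestCategoricalCompare:
    def test_fisher_yoga_practice_counts(self):
        # control 8/14 vs intervention 14/14, one-sided
        res = fisher_from_counts(8, 14, 14, 14, alternative="less")
        assert res.p_value == pytest.approx(0.008, abs=5e-4)

    def test_fisher_activity_counts(self):
        # control 7/14 vs intervention 12/12, one-sided
        res = fisher_from_counts(7, 14, 12, 12, alternative="less")
        assert res.p_value == pytest.approx(0.005, abs=5e-4)

    def test_saturated_table_p_one(self):
        res = fisher_from_counts(10, 10, 12, 12, alternative="less")
        assert res.p_value == 1.0

    def test_one_sided_never_exceeds_two_sided(self, rng):
        for _ in range(20):
            t = rng.integers(0, 10, size=(2, 2)) + 1
            two = categorical_compare(t, "two-sided").p_value
            one = min(categorical_compare(t, "less").p_value,
                      categorical_compare(t, "greater").p_value)
            assert one <= two + 1e-12

    def test_rxc_routes_to_chi_squared(self):
        t = np.array([[10, 5, 3], [4, 8, 9]])
        res = categorical_compare(t)
        assert res.test_name == "chi-squared"

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError):
            categorical_compare(np.array([[0, 0], [3, 4]]))


class TestMixedModel:
    def test_noiseless_exact_recovery(self):
        rows = []
        for i in range(8):
            g = 1.0 if i < 4 else 0.0
            for t, tp in ((0.0, "first_begin"), (1.0, "last_end")):
                y = 1.0 + 2.0 * g + 3.0 * t + 4.0 * g * t
                rows.append({"subject": f"s{i}", "timepoint": tp,
                             "group": "intervention" if g else "control",
                             "unified_hrv_index": y})
        res = fit_mixed_model(pd.DataFrame(rows))
        fe = res.fixed_effects["estimate"]
        assert fe["intercept"] == pytest.approx(1.0, abs=1e-6)
        assert fe["group"] == pytest.approx(2.0, abs=1e-6)
        assert fe["time"] == pytest.approx(3.0, abs=1e-6)
        assert fe["group_x_time"] == pytest.approx(4.0, abs=1e-6)

    def test_random_intercept_absorbs_subject_offsets(self, rng):
        rows = []
        for i in range(20):
            off = rng.normal(0, 5.0)
            g = i < 10
            for t, tp in ((0, "first_begin"), (1, "last_end")):
                rows.append({"subject": f"s{i}", "timepoint": tp,
                             "group": "intervention" if g else "control",
                             "unified_hrv_index": off + 0.5 * t
                             + rng.normal(0, 0.5)})
        res = fit_mixed_model(pd.DataFrame(rows))
        assert res.random_intercept_var > res.residual_var

    def test_covariate_sensitivity_mode(self, rng):
        rows = []
        for i in range(16):
            g = i < 8
            age = rng.uniform(25, 42)
            for t, tp in ((0, "first_begin"), (1, "last_end")):
                rows.append({"subject": f"s{i}", "timepoint": tp,
                             "group": "intervention" if g else "control",
                             "age": age,
                             "unified_hrv_index": 0.1 * age + rng.normal()})
        res = fit_mixed_model(pd.DataFrame(rows), covariates=("age",))
        assert "age" in res.fixed_effects.index


class TestPowerAndSampleSize:
    def test_published_power_value(self):
        assert power_two_sample(14, 0.83, 0.05) == pytest.approx(0.56, abs=0.01)

    def test_null_effect_power_equals_alpha(self):
        assert power_two_sample(20, 0.0, 0.05) == pytest.approx(0.05, abs=1e-6)

    def test_monotone_in_n(self):
        powers = [power_two_sample(n, 0.5, 0.05) for n in range(5, 101)]
        assert all(b >= a for a, b in zip(powers, powers[1:]))

    def test_published_sample_size(self):
        assert sample_size_two_sample(0.83, 0.025, 0.80,
                                      "normal_approx") == 28

    def test_effect_size_from_summary(self):
        d = cohens_d_from_summary(5.0, 6.0)
        assert round(d, 2) == 0.83

    def test_inverse_square_scaling(self):
        n1 = sample_size_two_sample(0.4, 0.05, 0.8, "normal_approx")
        n2 = sample_size_two_sample(0.8, 0.05, 0.8, "normal_approx")
        assert n1 / n2 == pytest.approx(4.0, rel=0.1)

    def test_power_sample_size_mutually_consistent(self):
        for d, alpha, target in [(0.83, 0.025, 0.8), (0.5, 0.05, 0.9)]:
            n = sample_size_two_sample(d, alpha, target, "noncentral_t")
            assert power_two_sample(n, d, alpha) >= target
            assert power_two_sample(n - 1, d, alpha) < target

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            power_two_sample(14, 0.83, 1.5)
        with pytest.raises(ValueError):
            sample_size_two_sample(0.0, 0.05, 0.8)
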