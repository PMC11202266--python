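"""GSI/CF arithmetic, maturity grouping, cohort filters, hormone statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from testispec import (InputError, RunConfig, assign_maturity_group,
                       compute_cf, compute_gsi, correlate_with_index,
                       filter_cohort, group_difference_test, group_fold,
                       has_observation, stage_above)

positive = st.floats(min_value=1e-3, max_value=1e6, allow_nan=False)


class TestIndices:
    @pytest.mark.parametrize("gonad, body, expected", [
        (0.0, 1000.0, 0.0),
        (0.5, 1000.0, 0.05),
        (2.3, 1000.0, 0.23),   # lands exactly on the pubertal threshold
    ])
    def test_gsi_arithmetic(self, gonad, body, expected):
        assert compute_gsi(gonad, body) == pytest.approx(expected)

    def test_gsi_rejects_nonpositive_body(self):
        with pytest.raises(InputError):
            compute_gsi(1.0, 0.0)

    @pytest.mark.parametrize("weight, length, expected", [
        (1017.0, 41.3, 1.44),  # cohort means reproduce the reported CF
        (100.0, 10.0, 10.0),
        (1000.0, 100.0, 0.1),
    ])
    def test_cf_arithmetic(self, weight, length, expected):
        assert round(compute_cf(weight, length), 2) == pytest.approx(expected)

    @given(gonad=positive, body=positive, k=st.floats(1e-2, 1e2))
    @settings(max_examples=50, derandomize=True)
    def test_gsi_scale_invariance(self, gonad, body, k):
        assert compute_gsi(k * gonad, k * body) == pytest.approx(
            compute_gsi(gonad, body), rel=1e-9)

    @given(weight=positive, length=st.floats(1.0, 200.0),
           k=st.floats(0.1, 10.0))
    @settings(max_examples=50, derandomize=True)
    def test_cf_allometric_invariance(self, weight, length, k):
        # W -> k^3 W together with L -> k L leaves CF unchanged
        assert compute_cf(k**3 * weight, k * length) == pytest.approx(
            compute_cf(weight, length), rel=1e-9)


class TestMaturityGrouping:
    @pytest.mark.parametrize("gsi, label", [
        (0.05, "immature"),
        (0.079, "immature"),
        (0.08, "indeterminate"),   # immature bound is strict
        (0.15, "indeterminate"),
        (0.23, "pubertal"),        # pubertal bound is inclusive
        (0.6, "pubertal"),
    ])
    def test_boundaries(self, gsi, label):
        assert assign_maturity_group(gsi) == label

    def test_negative_gsi_rejected(self):
        with pytest.raises(InputError):
            assign_maturity_group(-0.01)

    @given(gsi=st.floats(0.0, 10.0, allow_nan=False))
    @settings(max_examples=100, derandomize=True)
    def test_partition_is_total_and_disjoint(self, gsi):
        label = assign_maturity_group(gsi)
        expected = ("immature" if gsi < 0.08
                    else "pubertal" if gsi >= 0.23 else "indeterminate")
        assert label == expected


class TestCohortFilters:
    def test_advanced_stage_selects_six(self, cohort_records):
        subset, n = filter_cohort(cohort_records, stage_above("SPA"))
        assert n == 6
        assert {r.fish_id for r in subset} == {"184", "190", "213", "245",
                                               "211", "202"}

    def test_oocyte_flag_selects_three(self, cohort_records):
        subset, n = filter_cohort(cohort_records, has_observation("oocytes"))
        assert n == 3
        assert {r.fish_id for r in subset} == {"198", "255", "221"}

    def test_empty_cohort(self):
        subset, n = filter_cohort([], stage_above("SPA"))
        assert subset == [] and n == 0

    def test_unknown_stage_label(self, cohort_records):
        with pytest.raises(InputError):
            filter_cohort(cohort_records, stage_above("SPX"))

    def test_maturity_group_sizes(self, cohort_records):
        groups = [assign_maturity_group(r.gsi) for r in cohort_records]
        assert groups.count("immature") == 14
        assert groups.count("pubertal") == 6


def _panel(values: dict[str, list[float]], fish=None) -> pd.DataFrame:
    fish = fish or [f"F{i}" for i in range(len(next(iter(values.values()))))]
    rows = [{"fish_id": f, "analyte": a, "concentration": v}
            for a, vals in values.items() for f, v in zip(fish, vals)]
    return pd.DataFrame(rows)


class TestHormoneStats:
    def test_perfect_linearity(self):
        gsi = pd.Series([0.01, 0.05, 0.1, 0.3, 0.5],
                        index=[f"F{i}" for i in range(5)])
        panel = _panel({"a": (2 * gsi).tolist(),
                        "b": (10 - gsi).tolist()},
                       fish=list(gsi.index))
        r, _, _ = correlate_with_index(panel, gsi)
        assert r["a"] == pytest.approx(1.0)
        assert r["b"] == pytest.approx(-1.0)

    def test_constant_analyte_is_undefined_not_error(self):
        gsi = pd.Series([0.01, 0.05, 0.3], index=["F0", "F1", "F2"])
        panel = _panel({"flat": [5.0, 5.0, 5.0]}, fish=list(gsi.index))
        r, _, _ = correlate_with_index(panel, gsi)
        assert np.isnan(r["flat"])

    @given(scale=st.floats(0.1, 50.0), shift=st.floats(0.0, 5.0))
    @settings(max_examples=30, derandomize=True)
    def test_affine_invariance(self, scale, shift):
        rng = np.random.default_rng(3)
        gsi = pd.Series(rng.uniform(0.01, 0.6, 12),
                        index=[f"F{i}" for i in range(12)])
        conc = rng.uniform(1, 20, 12)
        base = _panel({"a": conc.tolist()}, fish=list(gsi.index))
        trans = _panel({"a": (scale * conc + shift).tolist()},
                       fish=list(gsi.index))
        r1, _, _ = correlate_with_index(base, gsi)
        r2, _, _ = correlate_with_index(trans, gsi)
        assert r1["a"] == pytest.approx(r2["a"], abs=1e-9)

    def test_group_fold_arithmetic(self):
        fish = [f"F{i}" for i in range(4)]
        panel = _panel({"a": [2.0, 2.0, 15.0, 15.0],
                        "same": [3.0, 3.0, 3.0, 3.0]}, fish=fish)
        groups = pd.Series(["immature", "immature", "pubertal", "pubertal"],
                           index=fish)
        fold = group_fold(panel, groups)
        assert fold["a"] == pytest.approx(7.5)
        assert fold["same"] == pytest.approx(1.0)

    def test_group_fold_zero_immature_mean_undefined(self):
        fish = [f"F{i}" for i in range(4)]
        panel = _panel({"a": [0.0, 0.0, 5.0, 5.0]}, fish=fish)
        groups = pd.Series(["immature", "immature", "pubertal", "pubertal"],
                           index=fish)
        assert np.isnan(group_fold(panel, groups)["a"])

    def test_indeterminate_fish_excluded_from_fold(self):
        fish = [f"F{i}" for i in range(5)]
        panel = _panel({"a": [2.0, 2.0, 999.0, 15.0, 15.0]}, fish=fish)
        groups = pd.Series(["immature", "immature", "indeterminate",
                            "pubertal", "pubertal"], index=fish)
        assert group_fold(panel, groups)["a"] == pytest.approx(7.5)

    def test_identical_constant_groups_p_one(self):
        fish = [f"F{i}" for i in range(4)]
        panel = _panel({"a": [3.0, 3.0, 3.0, 3.0]}, fish=fish)
        groups = pd.Series(["immature", "immature", "pubertal", "pubertal"],
                           index=fish)
        assert group_difference_test(panel, groups)["a"] == 1.0

    def test_power_on_widely_separated_groups(self):
        rng = np.random.default_rng(11)
        imm = rng.normal(0.0, 1.0, 14)
        pub = rng.normal(10.0, 1.0, 6)    # 10 pooled SDs apart
        fish = [f"F{i}" for i in range(20)]
        panel = _panel({"a": np.concatenate([imm - imm.min() + 1,
                                             pub - imm.min() + 1]).tolist()},
                       fish=fish)
        groups = pd.Series(["immature"] * 14 + ["pubertal"] * 6, index=fish)
        assert group_difference_test(panel, groups)["a"] < 1e-3

    def test_small_group_undefined(self):
        fish = [f"F{i}" for i in range(3)]
        panel = _panel({"a": [1.0, 2.0, 5.0]}, fish=fish)
        groups = pd.Series(["immature", "immature", "pubertal"], index=fish)
        assert np.isnan(group_difference_test(panel, groups)["a"])
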