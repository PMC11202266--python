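"""Differential specific activity: log2-ER, per-gene test, classification,
centering, specificity summary, candidate screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from testispec import (ExpressionMatrix, InputError, RunConfig,
                       candidate_screen, center_to_sample_average, classify,
                       differential_activity, log2_expression_ratio,
                       per_gene_test, signed_fold, summarize_by_specificity)
from testispec.activity import HSA, LSA, NS, adjust_bh


def _matrix(values, genes=None, samples=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"G{i}" for i in range(values.shape[0])]
    samples = samples or [f"S{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))


def _groups(n_imm, n_pub, samples=None):
    samples = samples or [f"S{i}" for i in range(n_imm + n_pub)]
    return pd.Series(["immature"] * n_imm + ["pubertal"] * n_pub,
                     index=samples)


class TestLog2ExpressionRatio:
    def test_flat_gene_is_zero(self):
        m = _matrix([[5, 5, 5, 5]])
        assert log2_expression_ratio(m, _groups(2, 2))["G0"] == pytest.approx(0.0)

    def test_exact_doubling_is_one(self):
        m = _matrix([[4, 8, 8, 16]])
        assert log2_expression_ratio(m, _groups(2, 2))["G0"] == pytest.approx(1.0)

    def test_matches_brute_force(self, small_matrix, two_groups):
        er = log2_expression_ratio(small_matrix, two_groups)
        vals = small_matrix.values
        pub = [s for s in small_matrix.sample_ids if two_groups[s] == "pubertal"]
        imm = [s for s in small_matrix.sample_ids if two_groups[s] == "immature"]
        for g in small_matrix.gene_ids:
            expected = (np.mean([np.log2(vals.loc[g, s]) for s in pub])
                        - np.mean([np.log2(vals.loc[g, s]) for s in imm]))
            assert er[g] == pytest.approx(expected, abs=1e-12)

    def test_missing_group_is_error(self, small_matrix):
        labels = pd.Series("immature", index=small_matrix.sample_ids)
        with pytest.raises(InputError):
            log2_expression_ratio(small_matrix, labels)


class TestPerGeneTest:
    def test_identical_constant_groups_p_one(self):
        m = _matrix([[3, 3, 3, 3, 3]])
        assert per_gene_test(m, _groups(3, 2))["G0"] == 1.0

    def test_matches_per_gene_scipy_oracle(self):
        rng = np.random.default_rng(5)
        m = _matrix(np.exp2(rng.normal(6, 1, (10, 20))))
        groups = _groups(14, 6)
        p = per_gene_test(m, groups)
        log2 = m.log2
        for g in m.gene_ids:
            a = log2.loc[g, [s for s in m.sample_ids if groups[s] == "pubertal"]]
            b = log2.loc[g, [s for s in m.sample_ids if groups[s] == "immature"]]
            expected = stats.ttest_ind(a, b, equal_var=False).pvalue
            assert p[g] == pytest.approx(expected, rel=1e-10)

    def test_planted_shift_power(self):
        rng = np.random.default_rng(9)
        base = rng.normal(8, 1, (100, 1))
        noise = rng.normal(0, 0.5, (100, 20))
        shift = np.zeros((100, 20))
        shift[:, 14:] = 1.0          # 2 pooled SDs on the log2 scale
        m = _matrix(np.exp2(base + noise + shift))
        p = per_gene_test(m, _groups(14, 6))
        assert np.median(p) < 0.05


class TestClassification:
    @pytest.mark.parametrize("er, p, label", [
        (0.8, 0.01, NS),       # cutoff is strict
        (1.0, 0.049, HSA),
        (-3.0, 0.001, LSA),
        (1.0, 0.05, NS),       # alpha is strict
        (-0.79, 0.001, NS),
    ])
    def test_criteria(self, er, p, label):
        res = classify(pd.Series({"g": er}), pd.Series({"g": p}))
        assert res.loc["g", "class"] == label

    def test_antisymmetry_under_group_swap(self, small_matrix, two_groups):
        res = differential_activity(small_matrix, two_groups)
        swapped = two_groups.map({"immature": "pubertal",
                                  "pubertal": "immature"})
        res_swapped = differential_activity(small_matrix, swapped)
        np.testing.assert_allclose(res_swapped["log2_er"], -res["log2_er"],
                                   atol=1e-12)
        np.testing.assert_allclose(res_swapped["p_value"], res["p_value"],
                                   rtol=1e-9)
        mapped = res_swapped["class"].map({HSA: LSA, LSA: HSA, NS: NS})
        assert (mapped == res["class"]).all()

    def test_sign_of_fold_matches_er(self, small_matrix, two_groups):
        res = differential_activity(small_matrix, two_groups)
        nonzero = res[res["log2_er"].abs() > 0]
        assert (np.sign(nonzero["fold"]) == np.sign(nonzero["log2_er"])).all()

    def test_bh_adjustment_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(2)
        p = pd.Series(rng.uniform(0, 1, 200))
        adj = adjust_bh(p)
        expected = multipletests(p.to_numpy(), method="fdr_bh")[1]
        np.testing.assert_allclose(adj.to_numpy(), expected, rtol=1e-12)


class TestSignedFold:
    @pytest.mark.parametrize("er, fold", [(0.0, 1.0), (1.0, 2.0), (-1.0, -2.0)])
    def test_reference_points(self, er, fold):
        assert signed_fold(er) == pytest.approx(fold)

    def test_table_formatting_example(self):
        assert round(signed_fold(-3.036), 1) == -8.2

    @given(er=st.floats(-20, 20, allow_nan=False))
    @settings(max_examples=100, derandomize=True)
    def test_symmetry(self, er):
        # the map is antisymmetric away from 0 (0 itself prints as fold 1)
        if er != 0:
            assert signed_fold(-er) == pytest.approx(-signed_fold(er),
                                                     rel=1e-12)
        assert abs(signed_fold(er)) >= 1.0


class TestCentering:
    def test_constant_gene_becomes_zero(self):
        df = pd.DataFrame([[3.0, 3.0, 3.0]], index=["g"])
        assert (center_to_sample_average(df) == 0).all().all()

    def test_two_sample_example(self):
        df = pd.DataFrame([[1.0, 3.0]], index=["g"])
        assert center_to_sample_average(df).loc["g"].tolist() == [-1.0, 1.0]

    def test_row_means_vanish(self, small_matrix):
        centered = center_to_sample_average(small_matrix.log2)
        assert centered.mean(axis=1).abs().max() < 1e-12


class TestSpecificitySummary:
    def test_published_count_arithmetic(self):
        from testispec import SpecificitySummary
        s = SpecificitySummary.from_counts(hsa=(3524, 584), lsa=(4268, 214))
        assert s.percent(HSA) == 16.6
        assert s.percent(LSA) == 5.0
        assert s.total_differential == 7792
        assert s.total_specific == 798
        assert s.total_percent == 10.2
        assert s.specificity_ratio == 3.3

    def test_all_ns_gives_zero_rows(self):
        res = pd.DataFrame({"class": [NS, NS]}, index=["a", "b"])
        flags = pd.Series([True, False], index=["a", "b"])
        s = summarize_by_specificity(res, flags)
        assert s.counts[HSA] == 0 and s.counts[LSA] == 0
        assert s.total_differential == 0

    def test_half_specific(self):
        res = pd.DataFrame({"class": [HSA] * 10}, index=[f"g{i}" for i in range(10)])
        flags = pd.Series([True] * 5 + [False] * 5, index=res.index)
        assert summarize_by_specificity(res, flags).percent(HSA) == 50.0

    def test_unflagged_gene_is_error(self):
        res = pd.DataFrame({"class": [HSA]}, index=["a"])
        with pytest.raises(InputError, match="a"):
            summarize_by_specificity(res, pd.Series(dtype=bool))


class TestCandidateScreen:
    def _base(self):
        # baseline flat at 64, includes elevated 4x (2 log2) where planted
        genes = [f"g{i}" for i in range(5)]
        samples = [f"S{i}" for i in range(8)]
        values = np.full((5, 8), 64.0)
        return genes, samples, values

    def test_exclusion_rule(self):
        genes, samples, values = self._base()
        values[0, 4:6] = 256.0       # include samples
        values[0, 6] = 256.0         # ... but also elevated in the exclude
        m = _matrix(values, genes, samples)
        picked = candidate_screen(m, include_samples=samples[4:6],
                                  exclude_samples=[samples[6]],
                                  baseline_samples=samples[:4])
        assert "g0" not in picked

    def test_selection_rule(self):
        genes, samples, values = self._base()
        values[1, 4:6] = 256.0       # 2 log2 above baseline = 2x cutoff
        m = _matrix(values, genes, samples)
        picked = candidate_screen(m, include_samples=samples[4:6],
                                  exclude_samples=[samples[6]],
                                  baseline_samples=samples[:4])
        assert picked == ["g1"]

    def test_planted_truth_recovery(self):
        rng = np.random.default_rng(21)
        n = 200
        samples = [f"S{i}" for i in range(10)]
        log2 = rng.normal(8, 0.1, (n, 10))
        planted = rng.choice(n, 20, replace=False)
        log2[planted][:, :]  # no-op guard for readability
        log2[np.ix_(planted, range(6, 9))] += 2.0   # includes
        m = _matrix(np.exp2(log2), [f"g{i}" for i in range(n)], samples)
        picked = candidate_screen(m, include_samples=samples[6:9],
                                  exclude_samples=[samples[9]],
                                  baseline_samples=samples[:6])
        assert sorted(picked) == sorted(f"g{i}" for i in planted)

    def test_overlapping_sets_rejected(self):
        genes, samples, values = self._base()
        m = _matrix(values, genes, samples)
        with pytest.raises(InputError):
            candidate_screen(m, include_samples=samples[:2],
                             exclude_samples=samples[1:3],
                             baseline_samples=samples[4:])
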