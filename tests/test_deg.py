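"""Fold change, the per-probe test, the joint criterion, collapse, and corrections."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from npscreen.deg import (
    DEGCriteria,
    adjust_pvalues,
    call_degs,
    collapse_probes,
    fold_change,
    passes_criteria,
    probe_test,
)
from npscreen.simulate import SimulationDesign, generate_expression


def welch_p_oracle(a, b):
    """Welch's test written out from the formula, independent of scipy."""
    a, b = np.asarray(a, float), np.asarray(b, float)
    na, nb = len(a), len(b)
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    return 2 * sps.t.sf(abs(t), df)


class TestFoldChange:
    def test_identical_group_means_give_unity(self):
        assert fold_change([2.0, 4.0], [3.0, 3.0]) == 1.0

    def test_hand_arithmetic(self):
        assert fold_change([2.6, 2.6], [2.0, 2.0]) == pytest.approx(1.3)
        assert fold_change([1.0], [2.0]) == 0.5

    @given(
        st.lists(st.floats(0.1, 1e4), min_size=1, max_size=6),
        st.lists(st.floats(0.1, 1e4), min_size=1, max_size=6),
    )
    @settings(max_examples=50, derandomize=True)
    def test_reciprocal_property(self, ko, wt):
        assert fold_change(ko, wt) * fold_change(wt, ko) == pytest.approx(1.0)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            fold_change([], [1.0])
        with pytest.raises(ValueError):
            fold_change([1.0], [-1.0, 3.0])


class TestProbeTest:
    def test_identical_groups_give_p_one(self):
        assert probe_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0]) == pytest.approx(1.0)
        assert probe_test([5.0, 5.0], [5.0, 5.0]) == 1.0

    def test_matches_reference_welch_formula(self):
        a, b = [1.0, 2.0, 3.0], [1.1, 2.1, 2.9]
        assert probe_test(a, b) == pytest.approx(welch_p_oracle(a, b), abs=1e-10)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_reference_formula_on_random_groups(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.normal(size=4), rng.normal(loc=0.5, size=6)
        assert probe_test(a, b) == pytest.approx(welch_p_oracle(a, b), abs=1e-10)

    def test_clear_separation_gives_tiny_p(self):
        assert probe_test([0, 0, 0, 0], [10, 10, 10, 10.001]) < 1e-6

    def test_single_value_group_rejected(self):
        with pytest.raises(ValueError, match=">= 2 values"):
            probe_test([1.0], [1.0, 2.0])

    def test_student_option_matches_pooled_variance_test(self):
        a, b = [1.0, 2.0, 3.0], [2.0, 2.5, 4.0]
        expected = sps.ttest_ind(a, b, equal_var=True).pvalue
        assert probe_test(a, b, equal_var=True) == pytest.approx(expected, abs=1e-12)


class TestJointCriterion:
    CRITERIA = DEGCriteria()

    @pytest.mark.parametrize(
        "p, fc, expected",
        [
            (0.04, 1.4, True),    # passes both
            (0.04, 1.0, False),   # fold change at identity
            (0.04, 0.70, True),   # down-regulation: 1/0.70 ~ 1.43 > 1.3
            (0.06, 2.0, False),   # p too large
            (0.05, 1.4, False),   # boundary p is strict
            (0.04, 1.3, False),   # boundary FC is strict
            (0.04, 1 / 1.3, False),
        ],
    )
    def test_symmetric_strict_thresholds(self, p, fc, expected):
        assert passes_criteria(p, fc, self.CRITERIA) is expected

    def test_invalid_criteria_rejected(self):
        with pytest.raises(ValueError):
            DEGCriteria(alpha=0.0)
        with pytest.raises(ValueError):
            DEGCriteria(fc_threshold=1.0)


class TestCallDegs:
    def make_matrix(self, seed=0):
        design = SimulationDesign(n_genes=10, arrays_per_group=3, seed=seed)
        return generate_expression(design), design

    def test_agrees_with_per_probe_loop_oracle(self):
        matrix, _ = self.make_matrix()
        condition = ("cortex", 18)
        table = call_degs(matrix, condition).set_index("probe")
        ko_cols = matrix.arrays_for("KO", *condition)
        wt_cols = matrix.arrays_for("WT", *condition)
        for probe in matrix.probes:
            ko = matrix.values.loc[probe, ko_cols].to_numpy()
            wt = matrix.values.loc[probe, wt_cols].to_numpy()
            assert table.loc[probe, "p_value"] == pytest.approx(
                probe_test(np.log2(ko), np.log2(wt)), abs=1e-12
            )
            assert table.loc[probe, "fold_change"] == pytest.approx(
                fold_change(ko, wt), abs=1e-12
            )
            assert table.loc[probe, "significant"] == passes_criteria(
                table.loc[probe, "p_value"], table.loc[probe, "fold_change"], DEGCriteria()
            )

    def test_invariant_to_array_column_order(self):
        matrix, _ = self.make_matrix(seed=3)
        shuffled = matrix.values[list(reversed(matrix.values.columns))]
        from npscreen.io import ExpressionMatrix

        reordered = ExpressionMatrix(values=shuffled, samples=matrix.samples)
        a = call_degs(matrix, ("hippocampus", 7))
        b = call_degs(reordered, ("hippocampus", 7))
        pd.testing.assert_frame_equal(a, b)

    def test_absent_condition_rejected(self):
        matrix, _ = self.make_matrix()
        with pytest.raises(ValueError, match="thalamus"):
            call_degs(matrix, ("thalamus", 7))


class TestCollapseProbes:
    def make_table(self, rows):
        df = pd.DataFrame(rows, columns=["probe", "p_value", "fold_change", "significant"])
        df["direction"] = np.where(df["fold_change"] > 1, "up", "down")
        return df[["probe", "p_value", "fold_change", "direction", "significant"]]

    def test_single_probe_genes_mirror_probe_records(self):
        table = self.make_table([("p1", 0.01, 1.5, True), ("p2", 0.4, 0.9, False)])
        out = collapse_probes(table, {"p1": "A", "p2": "B"})
        assert list(out["gene"]) == ["A", "B"]
        assert list(out["significant"]) == [True, False]

    def test_min_p_probe_is_representative_and_any_probe_significance(self):
        table = self.make_table([("p1", 0.01, 1.5, True), ("p2", 0.2, 1.1, False)])
        out = collapse_probes(table, {"p1": "A", "p2": "A"})
        assert len(out) == 1
        row = out.iloc[0]
        assert row["probe"] == "p1" and row["fold_change"] == 1.5 and row["significant"]

    def test_tie_on_p_breaks_to_smallest_probe_id(self):
        table = self.make_table([("p9", 0.05, 2.0, False), ("p2", 0.05, 0.5, False)])
        out = collapse_probes(table, {"p9": "A", "p2": "A"})
        assert out.iloc[0]["probe"] == "p2"

    def test_all_nonsignificant_gene_still_present(self):
        table = self.make_table([("p1", 0.9, 1.01, False)])
        out = collapse_probes(table, {"p1": "A"})
        assert not out.iloc[0]["significant"]

    def test_unmapped_probe_raises_listing_offenders(self):
        table = self.make_table([("p1", 0.01, 1.5, True)])
        with pytest.raises(ValueError, match="p1"):
            collapse_probes(table, {"other": "A"})


def bh_oracle(p):
    """Brute-force step-up adjustment, independent of statsmodels."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    adjusted = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running_min = min(running_min, p[i] * m / rank_from_top)
        adjusted[i] = running_min
    return np.minimum(adjusted, 1.0)


class TestAdjustPvalues:
    def test_single_p_unchanged_by_both_methods(self):
        for method in ("bonferroni", "bh"):
            assert adjust_pvalues([0.03], method) == pytest.approx([0.03])

    def test_bonferroni_hand_arithmetic(self):
        assert list(adjust_pvalues([0.01, 0.02], "bonferroni")) == pytest.approx([0.02, 0.04])
        assert list(adjust_pvalues([0.9, 0.8], "bonferroni")) == pytest.approx([1.0, 1.0])

    def test_bh_matches_step_up_oracle(self):
        p = [0.01, 0.04, 0.03]
        assert list(adjust_pvalues(p, "bh")) == pytest.approx(list(bh_oracle(p)))

    @pytest.mark.parametrize("seed", range(5))
    def test_bh_matches_oracle_on_random_vectors(self, seed):
        p = np.random.default_rng(seed).uniform(size=40)
        assert list(adjust_pvalues(p, "bh")) == pytest.approx(list(bh_oracle(p)))

    def test_adjusted_never_below_raw_and_at_most_one(self):
        p = np.random.default_rng(1).uniform(size=30)
        for method in ("bonferroni", "bh"):
            adj = adjust_pvalues(p, method)
            assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        p = rng.uniform(size=25)
        perm = rng.permutation(25)
        for method in ("bonferroni", "bh"):
            direct = adjust_pvalues(p, method)
            shuffled = adjust_pvalues(p[perm], method)
            unshuffled = np.empty_like(shuffled)
            unshuffled[perm] = shuffled
            assert list(unshuffled) == pytest.approx(list(direct))

    def test_empty_list_gives_empty_result(self):
        assert len(adjust_pvalues([], "bh")) == 0
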