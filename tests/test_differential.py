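"""Fold changes, Welch tests (with a hand-computed oracle), the combined
VIP/FC/p screen, Venn regions and top-k ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from vola.differential import (Thresholds, log2_fold_change, pairwise_test,
                               screen, top_k_by_fc, venn_counts)
from vola.tables import CONCENTRATION, FeatureTable, StageDesign, ValidationError


def _setup(g1, g2):
    g1, g2 = np.atleast_2d(g1), np.atleast_2d(g2)
    n1, n2 = g1.shape[1], g2.shape[1]
    samples = [f"a{i}" for i in range(n1)] + [f"b{i}" for i in range(n2)]
    design = StageDesign(pd.DataFrame(
        {"time_point": ["T0"] * n1 + ["T1"] * n2,
         "stage": ["G1"] * n1 + ["G4"] * n2,
         "replicate_index": list(range(1, n1 + 1)) + list(range(1, n2 + 1))},
        index=pd.Index(samples, name="sample_id")))
    vals = np.hstack([g1, g2])
    ct = FeatureTable(pd.DataFrame(
        vals, index=[f"c{i}" for i in range(vals.shape[0])], columns=samples),
        CONCENTRATION)
    return ct, design


class TestLog2FoldChange:
    def test_equal_means_zero(self):
        ct, design = _setup([[1.0, 3.0]], [[2.0, 2.0]])
        assert log2_fold_change(ct, design, ("G1", "G4"))["c0"] == pytest.approx(0.0)

    def test_ratio_four_gives_two(self):
        ct, design = _setup([[1.0, 1.0]], [[4.0, 4.0]])
        assert log2_fold_change(ct, design, ("G1", "G4"))["c0"] == pytest.approx(2.0)

    @settings(max_examples=50, derandomize=True)
    @given(st.lists(st.floats(0.01, 1e3), min_size=2, max_size=5),
           st.lists(st.floats(0.01, 1e3), min_size=2, max_size=5))
    def test_direction_swap_flips_sign(self, a, b):
        ct, design = _setup([a], [b])
        fwd = log2_fold_change(ct, design, ("G1", "G4"))["c0"]
        rev = log2_fold_change(ct, design, ("G4", "G1"))["c0"]
        assert fwd == pytest.approx(-rev, rel=1e-12, abs=1e-12)

    def test_empty_stage_raises(self):
        ct, design = _setup([[1.0, 1.0]], [[2.0, 2.0]])
        with pytest.raises(ValidationError):
            log2_fold_change(ct, design, ("G1", "G9"))


class TestPairwiseTest:
    def test_identical_groups_p_one(self):
        ct, design = _setup([[1.0, 2.0, 3.0]], [[1.0, 2.0, 3.0]])
        assert pairwise_test(ct, design, ("G1", "G4"))["c0"] == pytest.approx(1.0)

    def test_extreme_separation_hand_oracle(self):
        """Welch statistic recomputed from its definition on log values."""
        a = np.array([1.0, 1.0, 1.0, 1.000001])
        b = np.array([100.0, 100.0, 100.0, 100.0001])
        ct, design = _setup([a], [b])
        p = pairwise_test(ct, design, ("G1", "G4"))["c0"]
        la, lb = np.log(a), np.log(b)
        va, vb = la.var(ddof=1) / 4, lb.var(ddof=1) / 4
        tstat = (la.mean() - lb.mean()) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va ** 2 / 3 + vb ** 2 / 3)
        p_oracle = 2 * stats.t.sf(abs(tstat), df)
        assert p == pytest.approx(p_oracle, rel=1e-9)
        assert p < 1e-6

    def test_welch_equals_student_when_balanced_equal_variance(self, rng):
        a = rng.lognormal(size=(3, 5))
        b = a * 2.0   # equal log-variances, equal n
        ct, design = _setup(a, b)
        pw = pairwise_test(ct, design, ("G1", "G4"), method="welch")
        ps = pairwise_test(ct, design, ("G1", "G4"), method="student")
        assert np.allclose(pw, ps)

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_zero_variance_unequal_means(self):
        ct, design = _setup([[1.0, 1.0]], [[2.0, 2.0]])
        assert pairwise_test(ct, design, ("G1", "G4"))["c0"] == 0.0

    def test_single_replicate_rejected(self):
        ct, design = _setup([[1.0, 2.0]], [[3.0, 4.0]])
        design.table.drop(index="b1", inplace=True)
        with pytest.raises(ValidationError):
            pairwise_test(ct, design, ("G1", "G4"))


class TestScreen:
    def _frame(self, vip, fc, p):
        idx = pd.Index([f"c{i}" for i in range(len(vip))])
        return (pd.Series(vip, idx), pd.Series(fc, idx), pd.Series(p, idx))

    @pytest.mark.parametrize("vip,fc,p,call", [
        (1.5, 2.0, 0.001, "up"),
        (0.9, 3.0, 1e-5, "not_significant"),
        (2.0, -1.5, 0.005, "down"),
        (1.0, 1.0, 0.0099, "up"),          # inclusive VIP and FC boundaries
        (1.0, 1.0, 0.01, "not_significant"),  # strict p boundary
        (1.2, 0.99, 0.001, "not_significant"),
    ])
    def test_call_boundaries(self, vip, fc, p, call):
        res = screen(*self._frame([vip], [fc], [p]))
        assert res["call"]["c0"] == call

    @settings(max_examples=100, derandomize=True)
    @given(st.floats(0, 3), st.floats(-4, 4), st.floats(0.0001, 1))
    def test_partition_exclusive_and_exhaustive(self, vip, fc, p):
        res = screen(*self._frame([vip], [fc], [p]))
        call = res["call"]["c0"]
        sig = vip >= 1 and abs(fc) >= 1 and p < 0.01
        assert (call != "not_significant") == sig
        if sig:
            assert call == ("up" if fc > 0 else "down")

    def test_bh_q_values_monotone_in_p(self, rng):
        p = pd.Series(rng.uniform(size=30), [f"c{i}" for i in range(30)])
        res = screen(pd.Series(1.5, p.index), pd.Series(2.0, p.index), p)
        order = p.sort_values().index
        assert (res["q"][order].cummax() == res["q"][order]).all()


class TestVennCounts:
    def test_three_set_enumeration(self):
        counts = venn_counts({"A": {"a", "b"}, "B": {"b", "c"}, "C": {"b"}})
        assert counts[("A", "B", "C")] == 1
        assert counts[("A",)] == 1
        assert counts[("B",)] == 1
        assert counts[("C",)] == 0
        assert sum(counts.values()) == 3  # union size

    def test_disjoint_sets(self):
        counts = venn_counts({"A": {1}, "B": {2}, "C": {3}})
        assert all(v == 0 for k, v in counts.items() if len(k) > 1)

    def test_identical_sets_all_mass_in_center(self):
        s = {"x", "y"}
        counts = venn_counts({"A": set(s), "B": set(s), "C": set(s)})
        assert counts[("A", "B", "C")] == 2
        assert sum(v for k, v in counts.items() if len(k) < 3) == 0

    def test_wrong_arity(self):
        with pytest.raises(ValueError):
            venn_counts({"A": set()})


class TestTopK:
    def _res(self, fcs, ps=None, calls=None):
        idx = pd.Index([f"c{i}" for i in range(len(fcs))])
        ps = ps or [0.001] * len(fcs)
        calls = calls or ["up"] * len(fcs)
        return pd.DataFrame({"vip": 1.5, "log2fc": fcs, "p": ps,
                             "q": ps, "call": calls}, index=idx)

    def test_k_larger_than_set_returns_all(self):
        out = top_k_by_fc({"cmp": self._res([2.0, 3.0])}, k=20)
        assert len(out) == 2

    def test_ties_broken_by_p_then_id(self):
        df = self._res([2.0, 2.0, 2.0], ps=[0.005, 0.001, 0.005])
        out = top_k_by_fc({"cmp": df}, k=3)
        assert list(out["compound_id"]) == ["c1", "c0", "c2"]

    def test_not_significant_excluded_and_common_flagged(self):
        a = self._res([5.0, 2.0], calls=["up", "not_significant"])
        b = self._res([4.0, 3.0], calls=["up", "down"])
        out = top_k_by_fc({"A": a, "B": b}, k=2)
        assert "c1" not in set(out.loc[out["comparison"] == "A", "compound_id"])
        flagged = out.loc[out["in_all_comparisons"], "compound_id"]
        assert set(flagged) == {"c0"}

    def test_ranked_descending_by_absolute_fc(self):
        df = self._res([1.5, -4.0, 2.5])
        out = top_k_by_fc({"cmp": df}, k=3)
        assert list(out["compound_id"]) == ["c1", "c2", "c0"]
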