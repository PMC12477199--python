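"""Semi-quantification arithmetic and ANOVA/Tukey compact letter displays."""

import itertools

import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from vola.quantify import (ClassTotalsResult, class_totals,
                           compact_letter_display, semi_quantify)
from vola.tables import (CONCENTRATION, AnnotationTable, FeatureTable,
                         InternalStandardParams, StageDesign, ValidationError)


def _ft(areas, samples=None, kind="peak_area"):
    arr = np.atleast_2d(np.asarray(areas, float))
    samples = samples or [f"s{i}" for i in range(arr.shape[1])]
    return FeatureTable(pd.DataFrame(
        arr, index=[f"c{i}" for i in range(arr.shape[0])], columns=samples), kind)


def _isp(areas_by_sample):
    return InternalStandardParams(is_peak_area=pd.Series(areas_by_sample))


class TestSemiQuantify:
    def test_printed_constants_map_equal_areas_to_0_2(self):
        """With a 10 uL x 10 ug/mL spike into 0.5 g, I_i = I_s gives 0.2 ug/g."""
        ft = _ft([[5.0e5]], samples=["s0"])
        ct = semi_quantify(ft, _isp({"s0": 5.0e5}))
        assert ct.values.iat[0, 0] == pytest.approx(0.2, abs=1e-15)
        assert ct.value_kind == CONCENTRATION

    def test_zero_area_gives_zero_concentration(self):
        ct = semi_quantify(_ft([[0.0]], samples=["s0"]), _isp({"s0": 1e6}))
        assert ct.values.iat[0, 0] == 0.0

    def test_linearity_in_analyte_area(self):
        ct = semi_quantify(_ft([[1e5], [2e5]], samples=["s0"]), _isp({"s0": 1e6}))
        assert ct.values.iat[1, 0] == pytest.approx(2 * ct.values.iat[0, 0])

    def test_per_sample_internal_standard(self):
        # same analyte area, doubled IS area → halved concentration
        ct = semi_quantify(_ft([[1e5, 1e5]]), _isp({"s0": 1e6, "s1": 2e6}))
        assert ct.values.iat[0, 0] == pytest.approx(2 * ct.values.iat[0, 1])

    def test_nonpositive_is_area_rejected(self):
        with pytest.raises(ValidationError, match="s0"):
            semi_quantify(_ft([[1e5]], samples=["s0"]), _isp({"s0": 0.0}))

    def test_commutes_with_compound_subsetting(self, default_ds):
        ft, isp = default_ds.features, default_ds.is_params
        sub = ft.subset(compounds=ft.compound_ids[:10])
        full_then_sub = semi_quantify(ft, isp).subset(compounds=ft.compound_ids[:10])
        sub_then_quant = semi_quantify(sub, isp)
        pd.testing.assert_frame_equal(full_then_sub.values, sub_then_quant.values)

    def test_nonpositive_spike_params_rejected(self):
        with pytest.raises(ValidationError, match="v_s"):
            InternalStandardParams(v_s=0.0)


def _design(groups):
    rows, idx = [], []
    for t, n in groups.items():
        for r in range(1, n + 1):
            idx.append(f"{t}_r{r}")
            rows.append((t, t, r))
    return StageDesign(pd.DataFrame(
        rows, columns=["time_point", "stage", "replicate_index"],
        index=pd.Index(idx, name="sample_id")))


def _single_class_setup(values_by_tp):
    """One single-compound class with given per-time-point replicate values."""
    design = _design({t: len(v) for t, v in values_by_tp.items()})
    vals = list(itertools.chain.from_iterable(values_by_tp.values()))
    ct = FeatureTable(pd.DataFrame([vals], index=["c0"],
                                   columns=design.sample_ids), CONCENTRATION)
    ann = AnnotationTable(pd.DataFrame(
        {"compound_class": ["ketones"], "aroma_descriptors": [frozenset()],
         "odor_threshold": [np.nan], "pathway_ids": [frozenset()]},
        index=pd.Index(["c0"], name="compound_id")))
    return ct, ann, design


class TestClassTotals:
    def test_identical_groups_share_letter_a(self):
        ct, ann, design = _single_class_setup(
            {"T0": [1.0, 1.0, 1.0], "T1": [1.0, 1.0, 1.0]})
        res = class_totals(ct, ann, design)
        assert set(res.summary["letter"]) == {"a"}

    def test_clearly_separated_groups_get_distinct_letters(self):
        ct, ann, design = _single_class_setup(
            {"T0": [1.0, 1.0 + 1e-6, 1.0 - 1e-6],
             "T1": [10.0, 10.0 + 1e-6, 10.0 - 1e-6]})
        res = class_totals(ct, ann, design)
        letters = dict(zip(res.summary["time_point"], res.summary["letter"]))
        # larger mean carries 'a' by convention
        assert letters == {"T0": "b", "T1": "a"}

    def test_close_pair_shares_letter_far_group_differs(self, rng):
        """Means 0, 0.01, 10 with SD 0.5 and n=6: only the far group splits."""
        vals = {t: list(m + 0.5 * rng.standard_normal(6))
                for t, m in (("T0", 0.0), ("T1", 0.01), ("T2", 10.0))}
        # shift to keep concentrations non-negative
        shift = -min(min(v) for v in vals.values()) + 0.01
        vals = {t: [x + shift for x in v] for t, v in vals.items()}
        ct, ann, design = _single_class_setup(vals)
        res = class_totals(ct, ann, design)
        letters = dict(zip(res.summary["time_point"], res.summary["letter"]))
        assert letters["T0"] == letters["T1"]
        assert letters["T2"] != letters["T0"]

    def test_single_replicate_time_point_rejected(self):
        with pytest.raises(ValidationError):
            ct, ann, design = _single_class_setup({"T0": [1.0, 2.0], "T1": [3.0]})
            class_totals(ct, ann, design)

    def test_per_sample_sums(self, default_ds, default_ct):
        res = class_totals(default_ct, default_ds.annotations, default_ds.design)
        s0 = default_ds.design.biological_samples()[0]
        classes = default_ds.annotations.table["compound_class"]
        expected = default_ct.values[s0].groupby(classes).sum()
        pd.testing.assert_series_equal(res.per_sample.loc[s0], expected,
                                       check_names=False)

    def test_letters_match_tukey_p_matrix_on_random_instances(self, rng):
        """Groups share a letter iff their Tukey-adjusted p ≥ alpha.

        Cross-checked against the statsmodels Tukey HSD implementation.
        """
        for _ in range(10):
            k = int(rng.integers(3, 6))
            means = rng.uniform(0, 6, size=k)
            vals = {f"T{i}": list(np.abs(means[i] + rng.standard_normal(5)))
                    for i in range(k)}
            ct, ann, design = _single_class_setup(vals)
            res = class_totals(ct, ann, design)
            letters = dict(zip(res.summary["time_point"], res.summary["letter"]))

            flat = [(t, x) for t, v in vals.items() for x in v]
            tk = pairwise_tukeyhsd(np.array([x for _, x in flat]),
                                   np.array([t for t, _ in flat]), alpha=0.05)
            groups = list(tk.groupsunique)
            for (i, j), p in zip(itertools.combinations(range(len(groups)), 2),
                                 tk.pvalues):
                share = bool(set(letters[groups[i]]) & set(letters[groups[j]]))
                assert share == (p >= 0.05), (letters, groups[i], groups[j], p)


class TestCompactLetterDisplay:
    def test_no_significant_pairs_single_letter(self):
        means = pd.Series({"a_grp": 3.0, "b_grp": 2.0, "c_grp": 1.0})
        assert set(compact_letter_display(means, set()).values()) == {"a"}

    def test_chain_structure(self):
        # A≠C significant, A~B and B~C not: A=a, B=ab, C=b
        means = pd.Series({"A": 3.0, "B": 2.0, "C": 1.0})
        letters = compact_letter_display(means, {frozenset({"A", "C"})})
        assert letters["A"] == "a"
        assert letters["C"] == "b"
        assert set(letters["B"]) == {"a", "b"}

    def test_all_pairs_distinct(self):
        means = pd.Series({"A": 3.0, "B": 2.0, "C": 1.0})
        sig = {frozenset(p) for p in itertools.combinations("ABC", 2)}
        letters = compact_letter_display(means, sig)
        assert sorted(letters.values()) == ["a", "b", "c"]
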