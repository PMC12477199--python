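"""Internal-standard semi-quantification and per-class time-course statistics.

Semi-quantification converts each analyte's peak area to a concentration
by ratio to the spiked deuterated internal standard:

    X_i = (V_s * C_s / M) * (I_i / I_s) * 1e-3   [ug/g]

with V_s the spike volume (uL), C_s the spike concentration (ug/mL), M the
sample mass (g), and I_i / I_s the analyte / internal-standard peak areas.
The 1e-3 converts the uL * ug/mL spike amount to ug, so with the study's
constants (10 uL, 10 ug/mL, 0.5 g) an analyte matching the standard's peak
area maps to 0.2 ug/g.

Class totals summarize the concentration of each chemical class per sample,
then test for change across time points with one-way ANOVA and Tukey's HSD,
summarized as a compact letter display (groups sharing a letter are not
significantly different at alpha).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .tables import (
    CONCENTRATION,
    PEAK_AREA,
    QC_STAGE,
    AnnotationTable,
    FeatureTable,
    InternalStandardParams,
    StageDesign,
    ValidationError,
)

__all__ = ["semi_quantify", "class_totals", "compact_letter_display",
           "ClassTotalsResult"]


def semi_quantify(ft: FeatureTable, isp: InternalStandardParams) -> FeatureTable:
    """Convert peak areas to semi-quantified concentrations (ug/g).

    Each sample's analyte areas are divided by that sample's internal
    standard area.  Raises if the table already holds concentrations or if
    any sample's internal-standard area is missing or non-positive.
    """
    if ft.value_kind != PEAK_AREA:
        raise ValidationError("semi_quantify expects a peak-area table")
    is_area = isp.is_peak_area.reindex(ft.sample_ids)
    bad = is_area[~(is_area > 0)]
    if len(bad):
        raise ValidationError(
            f"internal-standard peak area missing or non-positive for samples "
            f"{sorted(bad.index)}")
    factor = isp.v_s * isp.c_s / isp.sample_mass * 1e-3
    conc = ft.values * (factor / is_area)
    return FeatureTable(conc, CONCENTRATION)


def _absorb(columns: list[set]) -> list[set]:
    """Drop letter columns that duplicate or are contained in another."""
    out = []
    for i, c in enumerate(columns):
        dominated = any(
            c < o or (c == o and j < i)
            for j, o in enumerate(columns) if j != i)
        if not dominated:
            out.append(c)
    return out


def compact_letter_display(means: pd.Series,
                           sig_pairs: set[frozenset]) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    ``means`` maps group name to mean (used only to order letters so that
    'a' attaches to the largest mean); ``sig_pairs`` holds frozensets of
    group-name pairs that differ significantly.  Two groups share a letter
    iff they are not in ``sig_pairs``.
    """
    groups = list(means.sort_values(ascending=False).index)
    columns: list[set] = [set(groups)]
    for pair in sig_pairs:
        a, b = tuple(pair)
        for col in list(columns):
            if a in col and b in col:
                columns.remove(col)
                columns.extend(c for c in (col - {a}, col - {b}) if c)
        columns = _absorb(columns)
    # letter order: columns sorted by their best (largest-mean) member
    rank = {g: i for i, g in enumerate(groups)}
    columns.sort(key=lambda col: min(rank[g] for g in col))
    letters = {g: "" for g in groups}
    for i, col in enumerate(columns):
        ch = chr(ord("a") + i)
        for g in groups:
            if g in col:
                letters[g] += ch
    return letters


@dataclass
class ClassTotalsResult:
    """Per-class concentration totals and their time-course statistics."""

    per_sample: pd.DataFrame   # sample x class summed concentration
    summary: pd.DataFrame      # (class, time_point) -> mean, sd, n, letter
    anova_p: pd.Series         # class -> one-way ANOVA p across time points
    alpha: float = 0.05


def _tukey_sig_pairs(groups: dict[str, np.ndarray], alpha: float) -> set[frozenset]:
    names = list(groups)
    arrays = [np.asarray(groups[g], float) for g in names]
    pooled_var = np.concatenate([a - a.mean() for a in arrays]).var(ddof=0)
    if pooled_var == 0.0:
        # degenerate zero within-group variance: groups differ iff means do
        return {frozenset((a, b)) for i, a in enumerate(names)
                for b in names[i + 1:]
                if not np.isclose(arrays[i].mean(), groups[b].mean())}
    res = stats.tukey_hsd(*arrays)
    out = set()
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            if res.pvalue[i, j] < alpha:
                out.add(frozenset((names[i], names[j])))
    return out


def class_totals(ct: FeatureTable, ann: AnnotationTable, design: StageDesign,
                 alpha: float = 0.05) -> ClassTotalsResult:
    """Sum concentrations per chemical class and sample, then test for
    differences across time points (one-way ANOVA + Tukey HSD letters).

    QC samples are excluded from the statistics.  Requires >= 2 replicates
    at every time point.
    """
    if ct.value_kind != CONCENTRATION:
        raise ValidationError("class_totals expects concentrations")
    bio = design.biological_samples()
    classes = ann.table["compound_class"]
    vals = ct.values.loc[:, bio]
    per_sample = vals.groupby(classes.reindex(vals.index)).sum().T
    per_sample.index.name = "sample_id"

    tp = design.table.loc[bio, "time_point"]
    counts = tp.value_counts()
    thin = counts[counts < 2]
    if len(thin):
        raise ValidationError(
            f"time points with a single replicate: {sorted(thin.index)}")
    tp_order = list(dict.fromkeys(design.table.loc[bio, "time_point"]))

    rows = []
    anova_p = {}
    for cls in per_sample.columns:
        groups = {t: per_sample.loc[tp == t, cls].to_numpy() for t in tp_order}
        arrays = list(groups.values())
        if np.ptp(np.concatenate(arrays)) == 0:
            p = 1.0
        else:
            with np.errstate(invalid="ignore", divide="ignore"):
                p = float(stats.f_oneway(*arrays).pvalue)
            if not np.isfinite(p):
                p = 1.0
        anova_p[cls] = p
        means = pd.Series({t: g.mean() for t, g in groups.items()})
        sig = _tukey_sig_pairs(groups, alpha)
        letters = compact_letter_display(means, sig)
        for t in tp_order:
            rows.append((cls, t, means[t], groups[t].std(ddof=1),
                         len(groups[t]), letters[t]))
    summary = pd.DataFrame(rows, columns=["compound_class", "time_point",
                                          "mean", "sd", "n", "letter"])
    return ClassTotalsResult(per_sample=per_sample, summary=summary,
                             anova_p=pd.Series(anova_p), alpha=alpha)
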