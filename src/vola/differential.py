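"""Differential-volatile screening between aging stages.

A compound is called differential for a stage contrast when it passes the
combined criterion VIP >= 1, |log2FC| >= 1 and p < 0.01 (Welch t-test on
log concentrations by default; no multiple-testing correction in the
primary call, BH q-values reported alongside).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import CONCENTRATION, FeatureTable, StageDesign, ValidationError

__all__ = ["Thresholds", "log2_fold_change", "pairwise_test", "screen",
           "venn_counts", "top_k_by_fc"]


@dataclass(frozen=True)
class Thresholds:
    """Differential call thresholds: VIP and |log2FC| inclusive, p strict."""

    vip: float = 1.0
    log2fc: float = 1.0
    p: float = 0.01


def _stage_values(ct: FeatureTable, design: StageDesign, stage: str) -> pd.DataFrame:
    samples = design.samples_of_stage(stage)
    if not samples:
        raise ValidationError(f"stage {stage!r} has no samples")
    return ct.values[samples]


def log2_fold_change(ct: FeatureTable, design: StageDesign,
                     comparison: tuple[str, str]) -> pd.Series:
    """log2 of the ratio of stage-mean concentrations (b over a).

    Missing values must be filled upstream (half-minimum fill keeps the
    ratio finite and positive).
    """
    a, b = comparison
    mean_a = _stage_values(ct, design, a).mean(axis=1)
    mean_b = _stage_values(ct, design, b).mean(axis=1)
    if (mean_a <= 0).any() or (mean_b <= 0).any() or mean_a.isna().any() or mean_b.isna().any():
        raise ValidationError("non-positive or missing stage means; apply the "
                              "half-minimum fill before computing fold changes")
    out = np.log2(mean_b / mean_a)
    out.name = f"log2fc_{a}_vs_{b}"
    return out


def pairwise_test(ct: FeatureTable, design: StageDesign,
                  comparison: tuple[str, str], method: str = "welch") -> pd.Series:
    """Per-compound two-sided test between two stages on log concentrations.

    ``method``: 'welch' (default), 'student', or 'mannwhitney'.  Degenerate
    zero-variance groups: p = 1 when the means coincide, else p -> 0.
    """
    a, b = comparison
    va = _stage_values(ct, design, a)
    vb = _stage_values(ct, design, b)
    if va.shape[1] < 2 or vb.shape[1] < 2:
        raise ValidationError("each stage needs >= 2 replicates for testing")
    la, lb = np.log(va.to_numpy(float)), np.log(vb.to_numpy(float))
    if method in ("welch", "student"):
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.ttest_ind(la, lb, axis=1,
                                  equal_var=(method == "student"))
        p = np.asarray(res.pvalue, dtype=float)
    elif method == "mannwhitney":
        res = stats.mannwhitneyu(la, lb, axis=1, alternative="two-sided")
        p = np.asarray(res.pvalue, dtype=float)
    else:
        raise ValueError(f"unknown test {method!r}")
    # zero variance in both groups: identical means → no evidence (p = 1),
    # different means → arbitrarily strong evidence (p = 0)
    degen = (la.var(axis=1) == 0) & (lb.var(axis=1) == 0)
    if degen.any():
        eq = np.isclose(la.mean(axis=1), lb.mean(axis=1))
        p = np.where(degen, np.where(eq, 1.0, 0.0), p)
    return pd.Series(p, index=ct.values.index, name=f"p_{a}_vs_{b}")


def screen(vip: pd.Series, log2fc: pd.Series, p: pd.Series,
           thresholds: Thresholds = Thresholds()) -> pd.DataFrame:
    """Combine VIP, fold change and p-value into up/down/not_significant calls.

    Returns a per-compound frame with the three statistics, BH-adjusted
    q-values and the call.
    """
    idx = vip.index
    if not (idx.equals(log2fc.index) and idx.equals(p.index)):
        raise ValidationError("vip, log2fc and p must share the compound index")
    q = pd.Series(multipletests(p.to_numpy(), method="fdr_bh")[1], index=idx)
    sig = (vip >= thresholds.vip) & (p < thresholds.p)
    call = pd.Series("not_significant", index=idx, dtype=object)
    call[sig & (log2fc >= thresholds.log2fc)] = "up"
    call[sig & (log2fc <= -thresholds.log2fc)] = "down"
    return pd.DataFrame({"vip": vip, "log2fc": log2fc, "p": p, "q": q,
                         "call": call})


def venn_counts(sets: dict[str, set]) -> dict[tuple[str, ...], int]:
    """Exclusive region counts for 2 or 3 named sets.

    Keys are tuples of the set names present in a region; e.g. for sets
    A,B,C the key ("A","B") counts members of A and B but not C.
    """
    names = list(sets)
    if not 2 <= len(names) <= 3:
        raise ValueError("venn_counts supports 2 or 3 sets")
    out: dict[tuple[str, ...], int] = {}
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            inside = set.intersection(*(sets[n] for n in combo))
            outside = set.union(set(), *(sets[n] for n in names if n not in combo))
            out[combo] = len(inside - outside)
    return out


def top_k_by_fc(results: dict[str, pd.DataFrame], k: int = 20) -> pd.DataFrame:
    """Top-k differential compounds per comparison, ranked by |log2FC|.

    Only significant compounds (call != not_significant) are ranked; ties
    break by smaller p, then compound id.  The output pools all
    comparisons' top lists, deduplicated, and flags compounds common to
    every comparison's top-k.
    """
    tops: dict[str, list[str]] = {}
    rows = []
    for name, df in results.items():
        sig = df[df["call"] != "not_significant"].copy()
        sig["absfc"] = sig["log2fc"].abs()
        sig = sig.reset_index(names="compound_id").sort_values(
            ["absfc", "p", "compound_id"], ascending=[False, True, True],
            kind="mergesort")
        tops[name] = list(sig["compound_id"][:k])
        for rank, cid in enumerate(tops[name], start=1):
            rows.append((name, rank, cid, df.at[cid, "log2fc"],
                         df.at[cid, "p"], df.at[cid, "call"]))
    common = set.intersection(*(set(v) for v in tops.values())) if tops else set()
    out = pd.DataFrame(rows, columns=["comparison", "rank", "compound_id",
                                      "log2fc", "p", "call"])
    out["in_all_comparisons"] = out["compound_id"].isin(common)
    return out
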