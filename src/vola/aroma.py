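"""Relative odor activity values (rOAV), aroma radar profiles and the
key-aroma-compound screen.

rOAV_i = X_i / T_i: stage-mean concentration over odor threshold, both in
ug/g.  rOAV >= 1 marks a likely aroma contributor, >= 10 a pronounced one.
Radar profiles average rOAV over the compounds sharing an aroma category
and UV-standardize each category across stages, so the chart shows each
note's relative trajectory over aging.  The key-compound screen keeps
compounds whose trend subclass is monotone (up or down) and whose rOAV
exceeds 1 (strict) at the first or last aging stage.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .tables import AnnotationTable, FeatureTable, StageDesign
from .trends import ClusterAssignment, stage_mean_profiles

logger = logging.getLogger(__name__)

__all__ = ["RADAR_CATEGORIES", "compute_roav", "radar_profile",
           "screen_key_compounds"]

#: The ten aroma attributes of the radar chart; the first five intensify
#: with aging in the emulated study, the last five fade.
RADAR_CATEGORIES = ("fruity", "floral", "honey", "woody", "sweet",
                    "coffee", "roasted", "hay", "burnt", "spicy")


def compute_roav(ct: FeatureTable, ann: AnnotationTable,
                 design: StageDesign) -> pd.DataFrame:
    """Long-form rOAV table: one row per compound per stage.

    Columns: stage, concentration (stage mean, ug/g), odor_threshold,
    roav, key_contributor (rOAV >= 1), pronounced (rOAV >= 10).  Compounds
    without a threshold are carried with missing rOAV (and excluded from
    category averages downstream).
    """
    stage_means = stage_mean_profiles(ct, design)
    thr = ann.thresholds().reindex(stage_means.index)
    n_missing = int(thr.isna().sum())
    if n_missing:
        logger.info("compute_roav: %d compounds lack an odor threshold; "
                    "their rOAV is missing", n_missing)
    long = stage_means.stack().rename("concentration").reset_index()
    long.columns = ["compound_id", "stage", "concentration"]
    long["odor_threshold"] = long["compound_id"].map(thr)
    long["roav"] = long["concentration"] / long["odor_threshold"]
    long["key_contributor"] = long["roav"] >= 1.0
    long["pronounced"] = long["roav"] >= 10.0
    return long


def radar_profile(roav: pd.DataFrame, ann: AnnotationTable,
                  categories: tuple[str, ...] = RADAR_CATEGORIES) -> pd.DataFrame:
    """Category x stage aroma scores, raw and UV-standardized.

    A compound contributes to every category matching one of its
    descriptors; the raw score is the mean rOAV of contributing compounds
    per stage; each category is then standardized to mean 0, SD 1 across
    stages.  Categories without any threshold-bearing member are dropped
    with a warning.
    """
    stages = list(dict.fromkeys(roav["stage"]))
    scored = roav.dropna(subset=["roav"])
    rows = []
    for cat in categories:
        members = [c for c in ann.compound_ids if cat in ann.descriptors(c)]
        sub = scored[scored["compound_id"].isin(members)]
        if sub.empty:
            logger.warning("radar_profile: category %r has no scored members; "
                           "dropped", cat)
            continue
        raw = sub.groupby("stage", sort=False)["roav"].mean().reindex(stages)
        sd = raw.std(ddof=1)
        std = (raw - raw.mean()) / sd if sd > 0 else raw * np.nan
        for s in stages:
            rows.append((cat, s, raw[s], std[s]))
    return pd.DataFrame(rows, columns=["category", "stage", "raw_score",
                                       "uv_score"])


def screen_key_compounds(roav: pd.DataFrame, clusters: ClusterAssignment,
                         ann: AnnotationTable,
                         first_stage: str = "G1",
                         last_stage: str = "G4") -> pd.DataFrame:
    """Select key aroma-active compounds.

    Keeps compounds whose trend subclass is monotone up or down and whose
    rOAV is strictly above 1 at the first or last aging stage.  Returns
    one row per key compound: direction, rOAV at both terminal stages,
    subclass and descriptors.
    """
    trend = clusters.compound_trend()
    wide = roav.pivot(index="compound_id", columns="stage", values="roav")
    rows = []
    for cid, direction in trend.items():
        if direction not in ("up", "down") or cid not in wide.index:
            continue
        r1 = wide.at[cid, first_stage] if first_stage in wide.columns else np.nan
        r4 = wide.at[cid, last_stage] if last_stage in wide.columns else np.nan
        if (np.isfinite(r1) and r1 > 1.0) or (np.isfinite(r4) and r4 > 1.0):
            desc = ";".join(sorted(ann.descriptors(cid))) \
                if cid in ann.table.index else ""
            sub = clusters.labels.get(cid, pd.NA)
            rows.append((cid, direction, r1, r4, sub, desc))
    out = pd.DataFrame(rows, columns=["compound_id", "direction",
                                      f"roav_{first_stage}",
                                      f"roav_{last_stage}",
                                      "subclass", "descriptors"])
    return out.sort_values(["direction", "compound_id"], ignore_index=True)
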