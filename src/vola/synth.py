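"""Synthetic volatile feature-table generator with planted ground truth.

Emulates the structure of a long-term cigar-aging volatilomics study:
six sampling time points (S0..S5) with six biological replicates each,
pooled QC injections, four aging stages G1 (S0-S1), G2 (S2), G3 (S3),
G4 (S4-S5), a compound-class mix dominated by terpenoids / esters /
heterocyclics / ketones, planted monotone-up, monotone-down, transient
and flat abundance trajectories under multiplicative log-normal noise,
odor thresholds spanning several orders of magnitude, and a
compound -> pathway map with one pathway enriched among up-trending
compounds.

Every draw comes from a single seeded generator, so a fixed seed yields
bit-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .tables import (
    PEAK_AREA,
    QC_STAGE,
    AnnotationTable,
    FeatureTable,
    InternalStandardParams,
    StageDesign,
)

__all__ = ["SynthConfig", "GroundTruth", "SyntheticDataset",
           "generate_dataset", "plant_key_aroma"]

TRENDS = ("up", "down", "transient", "flat")

#: Descriptor pools: up-trending compounds carry the aroma notes the study
#: found to intensify with aging, down-trending the ones that fade; flat and
#: transient compounds get neutral notes outside the ten radar attributes.
UP_DESCRIPTORS = ("fruity", "floral", "honey", "woody", "sweet")
DOWN_DESCRIPTORS = ("coffee", "roasted", "hay", "burnt", "spicy")
NEUTRAL_DESCRIPTORS = ("green", "earthy", "nutty")

#: Typical per-class base concentration scale (ug/g); order-of-magnitude
#: realism only, spread further by a log-uniform factor per compound.
CLASS_SCALE = {
    "terpenoids": 1.5,
    "esters": 0.8,
    "heterocyclics": 0.6,
    "ketones": 0.5,
    "aldehydes": 0.3,
    "others": 0.2,
}


class ConfigError(ValueError):
    """Degenerate or inconsistent synthetic-data configuration."""


@dataclass(frozen=True)
class SynthConfig:
    """Study-design parameters for the generator.

    ``effect_log2fc`` is the planted G4-vs-G1 log2 fold change of trending
    compounds; ``noise_cv`` the multiplicative log-normal coefficient of
    variation of biological replicates.  Defaults mirror the emulated
    study: 6 time points x 6 replicates, ~200 detected compounds at desk
    scale, strong planted separation.
    """

    n_compounds: int = 200
    class_mix: Mapping[str, float] = field(default_factory=lambda: {
        "terpenoids": 0.21, "esters": 0.18, "heterocyclics": 0.12,
        "ketones": 0.10, "aldehydes": 0.08, "others": 0.31})
    n_timepoints: int = 6
    replicates_per_timepoint: int = 6
    n_qc: int = 4
    trend_mix: Mapping[str, float] = field(default_factory=lambda: {
        "up": 0.15, "down": 0.10, "transient": 0.10, "flat": 0.65})
    effect_log2fc: float = 2.0
    noise_cv: float = 0.1
    qc_noise_cv: float = 0.02
    threshold_log10_range: tuple[float, float] = (-4.0, 1.0)
    threshold_coverage: float = 0.8
    n_pathways: int = 8
    enriched_pathway_fraction_up: float = 0.8
    background_pathway_prob: float = 0.15
    n_key_up: int = 14
    n_key_down: int = 7
    is_mean_area: float = 1.0e6
    is_cv: float = 0.02
    seed: int = 17

    def __post_init__(self) -> None:
        if self.n_compounds < 10:
            raise ConfigError("n_compounds must be >= 10")
        for name, mix in (("class_mix", self.class_mix),
                          ("trend_mix", self.trend_mix)):
            total = float(sum(mix.values()))
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{name} proportions sum to {total}, not 1")
        if self.effect_log2fc <= 0 or self.noise_cv <= 0:
            raise ConfigError("effect_log2fc and noise_cv must be positive")
        counts = _largest_remainder(self.trend_mix, self.n_compounds, TRENDS)
        n_up, n_down = counts["up"], counts["down"]
        if self.enriched_pathway_fraction_up > 0 and n_up == 0:
            raise ConfigError("enrichment among up-compounds requested but "
                              "trend_mix plants no up-trending compounds")
        if self.n_key_up > n_up or self.n_key_down > n_down:
            raise ConfigError(
                f"cannot plant {self.n_key_up} up / {self.n_key_down} down key "
                f"compounds: only {n_up} up and {n_down} down trending")


@dataclass
class GroundTruth:
    """What the generator planted, for downstream recovery checks."""

    trend: pd.Series                      # compound -> up/down/transient/flat
    base_abundance: pd.Series             # compound -> true base conc (ug/g)
    expected_stage_conc: pd.DataFrame     # compound x stage, noiseless means
    enriched_pathway: str
    key_up: list[str]
    key_down: list[str]

    @property
    def key_compounds(self) -> list[str]:
        return self.key_up + self.key_down

    def compounds_with_trend(self, trend: str) -> list[str]:
        return list(self.trend.index[self.trend == trend])


@dataclass
class SyntheticDataset:
    features: FeatureTable                # peak areas
    annotations: AnnotationTable
    design: StageDesign
    truth: GroundTruth
    is_params: InternalStandardParams


def _largest_remainder(mix: Mapping[str, float], n: int,
                       order: tuple[str, ...]) -> dict[str, int]:
    """Integer counts summing exactly to n, proportional to mix."""
    keys = [k for k in order if k in mix] + [k for k in mix if k not in order]
    raw = np.array([mix.get(k, 0.0) * n for k in keys])
    base = np.floor(raw).astype(int)
    rem = n - base.sum()
    frac_order = np.argsort(-(raw - base), kind="stable")
    for i in frac_order[:rem]:
        base[i] += 1
    return dict(zip(keys, base.astype(int)))


def _stage_of_timepoint(n_timepoints: int) -> list[str]:
    """Map time points to the four aging stages.

    For the canonical 6-point design: S0,S1 -> G1; S2 -> G2; S3 -> G3;
    S4,S5 -> G4.  Other counts split the time axis into four contiguous
    quartile blocks.
    """
    if n_timepoints == 6:
        return ["G1", "G1", "G2", "G3", "G4", "G4"]
    edges = np.linspace(0, n_timepoints, 5)
    return [f"G{int(np.searchsorted(edges[1:], t, side='right')) + 1}"
            for t in range(n_timepoints)]


def _trend_multipliers(trend: str, effect_log2fc: float) -> np.ndarray:
    """Per-stage abundance multipliers over the 4 stages (G1..G4).

    Monotone trends are geometric so that log2(G4/G1) equals the planted
    effect exactly; transient compounds spike at G2 and return to baseline.
    """
    r = 2.0 ** (effect_log2fc / 3.0)
    if trend == "up":
        return r ** np.arange(4)
    if trend == "down":
        return r ** -np.arange(4)
    if trend == "transient":
        return np.array([1.0, 2.0 ** effect_log2fc, 1.0, 1.0])
    return np.ones(4)


def plant_key_aroma(ann: AnnotationTable, truth: GroundTruth,
                    n_key_up: int, n_key_down: int,
                    rng: np.random.Generator) -> tuple[AnnotationTable, list[str], list[str]]:
    """Assign odor thresholds so a chosen subset of trending compounds are
    key aroma contributors.

    Planted key compounds get a threshold one tenth of their (noiseless)
    stage-mean concentration at the stage where they are most abundant
    (G4 for up-trending, G1 for down-trending), i.e. rOAV = 10 there.
    Every other monotone-trending compound gets a threshold ten times its
    G1/G4 maximum, pinning its rOAV below 1 at both terminal stages.
    """
    table = ann.table.copy()
    up_ids = truth.compounds_with_trend("up")
    down_ids = truth.compounds_with_trend("down")
    key_up = [str(c) for c in rng.choice(up_ids, size=n_key_up,
                                         replace=False)] if n_key_up else []
    key_down = [str(c) for c in rng.choice(down_ids, size=n_key_down,
                                           replace=False)] if n_key_down else []

    exp = truth.expected_stage_conc
    for cid in up_ids:
        peak = exp.at[cid, "G4"] if cid in key_up else None
        if peak is not None:
            table.at[cid, "odor_threshold"] = peak / 10.0
        else:
            table.at[cid, "odor_threshold"] = 10.0 * max(exp.at[cid, "G1"],
                                                         exp.at[cid, "G4"])
    for cid in down_ids:
        if cid in key_down:
            table.at[cid, "odor_threshold"] = exp.at[cid, "G1"] / 10.0
        else:
            table.at[cid, "odor_threshold"] = 10.0 * max(exp.at[cid, "G1"],
                                                         exp.at[cid, "G4"])
    return AnnotationTable(table), key_up, key_down


def generate_dataset(cfg: SynthConfig) -> SyntheticDataset:
    """Generate a full synthetic study: peak areas, annotations, design,
    internal-standard bookkeeping and ground truth.

    Sample values are ``base x stage-multiplier x exp(N(0, sigma))`` with
    ``sigma = sqrt(log(1 + noise_cv^2))``, so expected stage-mean ratios
    reproduce the planted log2 fold change exactly.  QC samples are the
    per-compound mean of all biological samples under much smaller noise,
    emulating pooled quality-control injections.
    """
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_compounds
    compound_ids = [f"VOC{i:04d}" for i in range(1, n + 1)]

    # classes and trends, counts forced by the configured proportions
    class_counts = _largest_remainder(cfg.class_mix, n, tuple(CLASS_SCALE))
    classes = np.repeat(list(class_counts), list(class_counts.values()))
    rng.shuffle(classes)
    trend_counts = _largest_remainder(cfg.trend_mix, n, TRENDS)
    trends = np.repeat(list(trend_counts), list(trend_counts.values()))
    rng.shuffle(trends)

    trend_s = pd.Series(trends, index=compound_ids, name="trend")
    class_s = pd.Series(classes, index=compound_ids, name="compound_class")

    # base abundance: per-class scale spread log-uniformly over 3 decades
    scale = class_s.map(lambda c: CLASS_SCALE.get(c, 0.2)).to_numpy(float)
    base = scale * 10.0 ** rng.uniform(-1.5, 1.5, size=n)
    base_s = pd.Series(base, index=compound_ids, name="base_abundance")

    # design
    stage_of_tp = _stage_of_timepoint(cfg.n_timepoints)
    rows = []
    for t in range(cfg.n_timepoints):
        for r in range(1, cfg.replicates_per_timepoint + 1):
            rows.append((f"S{t}_r{r}", f"S{t}", stage_of_tp[t], r))
    for q in range(1, cfg.n_qc + 1):
        rows.append((f"QC_{q}", QC_STAGE, QC_STAGE, q))
    design_df = pd.DataFrame(rows, columns=["sample_id", "time_point", "stage",
                                            "replicate_index"]).set_index("sample_id")
    design = StageDesign(design_df)

    bio_samples = design.biological_samples()
    stage_idx = {"G1": 0, "G2": 1, "G3": 2, "G4": 3}
    mult = np.stack([_trend_multipliers(t, cfg.effect_log2fc) for t in trends])
    sample_stage = design_df.loc[bio_samples, "stage"].map(stage_idx).to_numpy()

    sigma = float(np.sqrt(np.log1p(cfg.noise_cv ** 2)))
    noise = rng.normal(0.0, sigma, size=(n, len(bio_samples)))
    conc_bio = base[:, None] * mult[:, sample_stage] * np.exp(noise)

    # QC: pooled mean of all biological samples + tight analytical noise
    sigma_qc = float(np.sqrt(np.log1p(cfg.qc_noise_cv ** 2)))
    qc_base = conc_bio.mean(axis=1)
    conc_qc = qc_base[:, None] * np.exp(
        rng.normal(0.0, sigma_qc, size=(n, cfg.n_qc)))

    conc = np.concatenate([conc_bio, conc_qc], axis=1)
    all_samples = bio_samples + design.qc_samples()

    # internal standard: per-sample peak area with small analytical CV;
    # invert the semi-quantification formula to get analyte peak areas
    isp_const = InternalStandardParams()
    factor = isp_const.v_s * isp_const.c_s / isp_const.sample_mass * 1e-3
    sigma_is = float(np.sqrt(np.log1p(cfg.is_cv ** 2)))
    is_area = cfg.is_mean_area * np.exp(
        rng.normal(0.0, sigma_is, size=len(all_samples)))
    is_series = pd.Series(is_area, index=all_samples, name="is_peak_area")
    areas = conc / factor * is_area[None, :]

    features = FeatureTable(
        pd.DataFrame(areas, index=compound_ids, columns=all_samples), PEAK_AREA)
    isp = InternalStandardParams(is_peak_area=is_series)

    # noiseless expected stage-mean concentrations, for planting thresholds
    expected = pd.DataFrame(
        base[:, None] * mult, index=compound_ids, columns=["G1", "G2", "G3", "G4"])

    # descriptors tied to trend direction (aging intensifies the up-pool
    # notes and fades the down-pool notes in the emulated study)
    pools = {"up": UP_DESCRIPTORS, "down": DOWN_DESCRIPTORS,
             "transient": NEUTRAL_DESCRIPTORS, "flat": NEUTRAL_DESCRIPTORS}
    descriptors = []
    for t in trends:
        pool = pools[t]
        k = int(rng.integers(1, 3))
        descriptors.append(frozenset(
            str(d) for d in rng.choice(pool, size=min(k, len(pool)),
                                       replace=False)))

    # thresholds: log-uniform over several decades, partially missing;
    # overwritten for trending compounds by plant_key_aroma below
    lo, hi = cfg.threshold_log10_range
    thr = 10.0 ** rng.uniform(lo, hi, size=n)
    has_thr = rng.random(n) < cfg.threshold_coverage
    thr = np.where(has_thr, thr, np.nan)

    # pathways: one planted pathway concentrated in up-trending compounds,
    # the rest are uniform background membership
    pathway_ids = [f"PW{i:02d}" for i in range(1, cfg.n_pathways + 1)]
    enriched_pw = pathway_ids[0]
    up_ids = list(trend_s.index[trend_s == "up"])
    n_enr = int(round(cfg.enriched_pathway_fraction_up * len(up_ids)))
    enriched_members = set(rng.choice(up_ids, size=n_enr, replace=False)) if n_enr else set()
    pw_sets: list[set[str]] = [set() for _ in range(n)]
    for i, cid in enumerate(compound_ids):
        if cid in enriched_members:
            pw_sets[i].add(enriched_pw)
        for pw in pathway_ids[1:]:
            if rng.random() < cfg.background_pathway_prob:
                pw_sets[i].add(pw)

    ann_df = pd.DataFrame({
        "compound_class": class_s,
        "aroma_descriptors": descriptors,
        "odor_threshold": thr,
        "pathway_ids": [frozenset(s) for s in pw_sets],
    }, index=pd.Index(compound_ids, name="compound_id"))
    ann = AnnotationTable(ann_df)

    truth = GroundTruth(trend=trend_s, base_abundance=base_s,
                        expected_stage_conc=expected,
                        enriched_pathway=enriched_pw, key_up=[], key_down=[])
    ann, key_up, key_down = plant_key_aroma(ann, truth, cfg.n_key_up,
                                            cfg.n_key_down, rng)
    truth = replace_keys(truth, key_up, key_down)
    return SyntheticDataset(features=features, annotations=ann, design=design,
                            truth=truth, is_params=isp)


def replace_keys(truth: GroundTruth, key_up: list[str],
                 key_down: list[str]) -> GroundTruth:
    return GroundTruth(trend=truth.trend, base_abundance=truth.base_abundance,
                       expected_stage_conc=truth.expected_stage_conc,
                       enriched_pathway=truth.enriched_pathway,
                       key_up=sorted(key_up), key_down=sorted(key_down))
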