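"""End-to-end orchestration of the volatilomics analysis.

Runs semi-quantification, PCA stage overview, per-contrast OPLS-DA with
the VIP/fold-change/p differential screen, trend clustering of the
differential union, pathway enrichment and the rOAV aroma analysis from
one configuration, writing result CSVs and a JSON run manifest.  One
global seed fans out deterministically to per-stage seeds so each stage
can be re-run in isolation.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aroma import RADAR_CATEGORIES, compute_roav, radar_profile, screen_key_compounds
from .chemometrics import opls_da, pca, permutation_test
from .differential import (Thresholds, log2_fold_change, pairwise_test, screen,
                           top_k_by_fc, venn_counts)
from .enrichment import msea, shared_pathways
from .quantify import class_totals, semi_quantify
from .synth import SynthConfig, generate_dataset
from .tables import (FeatureTable, align, fill_missing_half_min,
                     read_annotations, read_design, read_feature_table)
from .trends import kmeans_cluster, stage_mean_profiles, uv_scale_profiles

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_all"]

_STAGE_NAMES = ("synth", "quantify", "pca", "opls", "differential",
                "cluster", "enrichment", "aroma")


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage child seed below 2**31."""
    idx = _STAGE_NAMES.index(stage)
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0] % (2 ** 31))


@dataclass
class RunConfig:
    """Everything a full run needs; synthetic by default.

    Provide either ``synth`` (a generator configuration) or the three
    input paths.  ``comparisons`` are (reference, contrast) stage pairs.
    """

    outdir: str | Path = "results"
    seed: int = 17
    synth: SynthConfig | None = None
    features_path: str | Path | None = None
    annotations_path: str | Path | None = None
    design_path: str | Path | None = None
    comparisons: tuple = (("G1", "G2"), ("G1", "G3"), ("G1", "G4"))
    thresholds: Thresholds = field(default_factory=Thresholds)
    n_ortho: int = 1
    cv_folds: int = 7
    n_perm: int = 200
    run_permutation: bool = False
    k_clusters: int = 8
    kmeans_n_init: int = 50
    top_k: int = 20
    enrichment_alpha: float = 0.05
    radar_categories: tuple = RADAR_CATEGORIES

    def __post_init__(self) -> None:
        if self.synth is None and not (self.features_path and
                                       self.annotations_path and
                                       self.design_path):
            raise ValueError("RunConfig needs either a synth config or all "
                             "three input table paths")


def run_all(cfg: RunConfig) -> dict:
    """Execute every analysis stage; returns the results bundle.

    The bundle maps stage names to in-memory results; all tables are also
    written as CSV under ``cfg.outdir`` together with ``manifest.json``
    recording parameters, seed and the filter-count chain.
    """
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "package_version": __version__,
                      "counts": {}, "parameters": {
                          "comparisons": [list(c) for c in cfg.comparisons],
                          "thresholds": vars(cfg.thresholds),
                          "n_ortho": cfg.n_ortho, "cv_folds": cfg.cv_folds,
                          "k_clusters": cfg.k_clusters, "top_k": cfg.top_k,
                          "enrichment_alpha": cfg.enrichment_alpha}}
    results: dict = {}

    # --- inputs -----------------------------------------------------------
    if cfg.synth is not None:
        # the global run seed fans out; the synth config's own seed field is
        # overridden so one RunConfig seed fixes the whole run
        synth_cfg = SynthConfig(**{**vars(cfg.synth),
                                   "seed": stage_seed(cfg.seed, "synth")})
        ds = generate_dataset(synth_cfg)
        ft, ann, design, isp = ds.features, ds.annotations, ds.design, ds.is_params
        results["truth"] = ds.truth
        manifest["parameters"]["synth"] = {
            k: (list(v) if isinstance(v, tuple) else
                dict(v) if hasattr(v, "keys") else v)
            for k, v in vars(synth_cfg).items()}
    else:
        ft = read_feature_table(cfg.features_path)
        ann = read_annotations(cfg.annotations_path)
        design = read_design(cfg.design_path)
        isp = None
    bundle = align(ft, ann, design)
    ft, ann, design = bundle.features, bundle.annotations, bundle.design
    manifest["counts"]["detected_compounds"] = len(ft.compound_ids)
    manifest["counts"]["samples"] = len(ft.sample_ids)

    # --- quantify ---------------------------------------------------------
    if ft.value_kind == "peak_area":
        if isp is None:
            raise ValueError("peak-area input requires internal-standard "
                             "parameters for semi-quantification")
        ct = semi_quantify(ft, isp)
    else:
        ct = ft
    ct = fill_missing_half_min(ct)
    totals = class_totals(ct, ann, design)
    results["concentrations"] = ct
    results["class_totals"] = totals
    ct.values.to_csv(out / "concentrations.csv", index_label="compound_id")
    totals.summary.to_csv(out / "class_totals.csv", index=False)

    # --- PCA stage overview ----------------------------------------------
    X_all = np.log10(ct.values.to_numpy(float)).T   # samples x compounds
    pca_res = pca(X_all, scaling="uv")
    results["pca"] = pca_res
    scores = pd.DataFrame(pca_res.scores[:, :2], index=ct.sample_ids,
                          columns=["PC1", "PC2"])
    scores["stage"] = design.table["stage"]
    scores.to_csv(out / "pca_scores.csv", index_label="sample_id")
    manifest["pca_explained_variance_pc1_pc2"] = [
        round(float(r), 4) for r in pca_res.explained_variance_ratio[:2]]

    # --- OPLS-DA + differential screen per comparison ---------------------
    diff_results: dict[str, pd.DataFrame] = {}
    models: dict[str, dict] = {}
    opls_seed = stage_seed(cfg.seed, "opls")
    for i, (a, b) in enumerate(cfg.comparisons):
        name = f"{a}_vs_{b}"
        samples = design.samples_of_stage(a) + design.samples_of_stage(b)
        X = np.log10(ct.values[samples].to_numpy(float)).T
        y = design.table.loc[samples, "stage"].to_numpy()
        model = opls_da(X, y, n_ortho=cfg.n_ortho, cv_folds=cfg.cv_folds,
                        seed=opls_seed + i)
        vip = pd.Series(model.vip, index=ct.compound_ids, name="vip")
        fc = log2_fold_change(ct, design, (a, b))
        p = pairwise_test(ct, design, (a, b))
        diff = screen(vip, fc, p, cfg.thresholds)
        diff_results[name] = diff
        models[name] = {"r2y": model.r2y, "q2": model.q2,
                        "cv_folds": model.cv_folds, "n_ortho": model.n_ortho}
        if cfg.run_permutation:
            perm = permutation_test(X, y, n_ortho=cfg.n_ortho,
                                    cv_folds=cfg.cv_folds, n_perm=cfg.n_perm,
                                    seed=opls_seed + 100 + i)
            models[name]["permutation_p_q2"] = perm.p_q2
            models[name]["permutation_p_r2y"] = perm.p_r2y
        diff.to_csv(out / f"differential_{name}.csv", index_label="compound_id")
        manifest["counts"][f"up_{name}"] = int((diff["call"] == "up").sum())
        manifest["counts"][f"down_{name}"] = int((diff["call"] == "down").sum())
    results["differential"] = diff_results
    results["opls_models"] = models
    with open(out / "opls_models.json", "w") as fh:
        json.dump(models, fh, indent=2)

    diff_sets = {name: set(df.index[df["call"] != "not_significant"])
                 for name, df in diff_results.items()}
    union = sorted(set().union(*diff_sets.values()))
    manifest["counts"]["differential_union"] = len(union)
    if len(diff_sets) >= 2:
        venn = venn_counts(diff_sets)
        pd.Series({"+".join(k): v for k, v in venn.items()}, name="count") \
            .to_csv(out / "venn_regions.csv", index_label="region")
        results["venn"] = venn
    topk = top_k_by_fc(diff_results, k=cfg.top_k)
    topk.to_csv(out / "top_fold_changes.csv", index=False)
    results["top_k"] = topk

    # --- trend clustering of the differential union -----------------------
    profiles = stage_mean_profiles(ct, design).loc[union]
    scaled, flat = uv_scale_profiles(profiles)
    k = min(cfg.k_clusters, len(scaled))
    clusters = kmeans_cluster(scaled, k=k, n_init=cfg.kmeans_n_init,
                              seed=stage_seed(cfg.seed, "cluster"),
                              flat_compounds=flat)
    results["clusters"] = clusters
    assign = pd.DataFrame({"subclass": clusters.labels,
                           "trend": clusters.labels.map(clusters.trend)})
    assign.to_csv(out / "cluster_assignments.csv", index_label="compound_id")
    clusters.centroids.to_csv(out / "cluster_centroids.csv",
                              index_label="subclass")

    # --- pathway enrichment ------------------------------------------------
    background = set(ct.compound_ids)
    pw_map = ann.pathway_map()
    enr = {name: msea(dset, background, pw_map, alpha=cfg.enrichment_alpha)
           for name, dset in diff_sets.items() if dset}
    results["enrichment"] = enr
    for name, df in enr.items():
        df.to_csv(out / f"enrichment_{name}.csv", index=False)
    if len(enr) >= 2:
        shared = shared_pathways(enr, alpha=cfg.enrichment_alpha)
        results["shared_pathways"] = shared
        manifest["counts"]["shared_enriched_pathways"] = len(shared)

    # --- aroma -------------------------------------------------------------
    roav = compute_roav(ct, ann, design)
    radar = radar_profile(roav, ann, cfg.radar_categories)
    keys = screen_key_compounds(roav, clusters, ann)
    results["roav"], results["radar"], results["key_compounds"] = roav, radar, keys
    roav.to_csv(out / "roav.csv", index=False)
    radar.to_csv(out / "radar_profile.csv", index=False)
    keys.to_csv(out / "key_compounds.csv", index=False)
    manifest["counts"]["key_compounds"] = len(keys)
    manifest["counts"]["key_up"] = int((keys["direction"] == "up").sum())
    manifest["counts"]["key_down"] = int((keys["direction"] == "down").sum())

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    results["manifest"] = manifest
    logger.info("run_all: wrote results to %s", out)
    return results
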