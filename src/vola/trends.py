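"""K-means trend clustering of stage profiles.

Differential compounds are summarized as stage-mean profiles (G1..G4),
unit-variance scaled per compound, clustered with K-means (Lloyd,
k-means++ seeding, best of many restarts), and each cluster centroid is
classified as monotone up, monotone down or other.  Constant profiles
have no UV scale and are routed to a dedicated flat bucket instead of
being clustered.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .tables import AnnotationTable, FeatureTable, StageDesign

__all__ = ["stage_mean_profiles", "uv_scale_profiles", "kmeans_cluster",
           "classify_trend", "attribute_tally", "ClusterAssignment"]


def stage_mean_profiles(ct: FeatureTable, design: StageDesign,
                        stages: Iterable[str] | None = None) -> pd.DataFrame:
    """Compound x stage matrix of stage-mean concentrations (QC excluded)."""
    stages = list(stages) if stages is not None else design.stages
    cols = {s: ct.values[design.samples_of_stage(s)].mean(axis=1) for s in stages}
    return pd.DataFrame(cols)


def uv_scale_profiles(stage_means: pd.DataFrame) -> tuple[pd.DataFrame, pd.Index]:
    """Per-compound UV scaling of stage profiles (mean 0, SD 1, n-1).

    Returns the scaled matrix and the index of constant ("flat") profiles,
    which are excluded from the scaled output rather than raising.
    """
    if stage_means.shape[1] < 2:
        raise ValueError("need >= 2 stages to scale profiles")
    sd = stage_means.std(axis=1, ddof=1)
    flat = stage_means.index[sd == 0]
    keep = stage_means.loc[sd > 0]
    scaled = keep.sub(keep.mean(axis=1), axis=0).div(sd[sd > 0], axis=0)
    return scaled, flat


def classify_trend(centroid: np.ndarray, min_rise: float = 0.1,
                   step_tol: float = 1e-9) -> str:
    """Label a per-stage centroid as 'up', 'down' or 'other'.

    'up' means non-decreasing stage-to-stage (within ``step_tol``) with a
    total rise above ``min_rise`` in scaled units; 'down' is symmetric.
    """
    c = np.asarray(centroid, dtype=float)
    if len(c) < 2:
        raise ValueError("need >= 2 stages")
    d = np.diff(c)
    total = c[-1] - c[0]
    if np.all(d >= -step_tol) and total > min_rise:
        return "up"
    if np.all(d <= step_tol) and total < -min_rise:
        return "down"
    return "other"


@dataclass
class ClusterAssignment:
    """K-means result over UV-scaled stage profiles."""

    labels: pd.Series          # compound -> subclass index (1..k)
    centroids: pd.DataFrame    # subclass x stage
    sizes: pd.Series           # subclass -> member count
    trend: pd.Series           # subclass -> up/down/other
    wcss: float
    flat_compounds: pd.Index   # constant profiles kept out of clustering

    def compound_trend(self) -> pd.Series:
        """Per-compound trend via its subclass centroid; flats are 'other'."""
        t = self.labels.map(self.trend)
        if len(self.flat_compounds):
            t = pd.concat([t, pd.Series("other", index=self.flat_compounds)])
        return t

    def compounds_in_trend(self, trend: str) -> list[str]:
        t = self.compound_trend()
        return list(t.index[t == trend])


def kmeans_cluster(scaled: pd.DataFrame, k: int = 8, n_init: int = 50,
                   seed: int | None = 0, min_rise: float = 0.1,
                   flat_compounds: pd.Index | None = None) -> ClusterAssignment:
    """Cluster UV-scaled stage profiles with K-means.

    Lloyd's algorithm with k-means++ seeding, best of ``n_init`` restarts
    by within-cluster sum of squares (WCSS); deterministic under a fixed
    seed.  Subclass indices are renumbered 1..k by decreasing size.
    """
    if k > len(scaled):
        raise ValueError(f"k={k} exceeds the {len(scaled)} profiles available")
    km = KMeans(n_clusters=k, n_init=n_init, algorithm="lloyd",
                random_state=None if seed is None else int(seed) % (2 ** 31))
    raw = km.fit_predict(scaled.to_numpy(float))
    order = pd.Series(raw).value_counts().index
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([remap[r] for r in raw], index=scaled.index,
                       name="subclass")
    centroids = pd.DataFrame(km.cluster_centers_, columns=scaled.columns)
    centroids.index = [remap[i] for i in range(k)]
    centroids = centroids.sort_index()
    sizes = labels.value_counts().sort_index()
    if centroids.shape[1] >= 2:
        trend = pd.Series({i: classify_trend(centroids.loc[i].to_numpy(), min_rise)
                           for i in centroids.index}, name="trend")
    else:   # a single stage column has no direction
        trend = pd.Series("other", index=centroids.index, name="trend")
    return ClusterAssignment(
        labels=labels, centroids=centroids, sizes=sizes, trend=trend,
        wcss=float(km.inertia_),
        flat_compounds=flat_compounds if flat_compounds is not None else pd.Index([]))


def attribute_tally(compound_ids: Iterable[str], ann: AnnotationTable) -> Counter:
    """Count sensory descriptors over a compound set.

    A compound with d descriptors contributes one count to each of the d
    attributes; compounds without descriptors contribute nothing.
    """
    tally: Counter = Counter()
    for cid in compound_ids:
        for d in ann.descriptors(cid):
            tally[d] += 1
    return tally
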