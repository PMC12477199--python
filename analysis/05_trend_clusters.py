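"""K-means trend clustering of the differential union and sensory-attribute
tallies of the up- and down-trending subclasses."""

import pandas as pd
from _common import RESULTS, SEED, load_study
from vola.trends import (attribute_tally, kmeans_cluster, stage_mean_profiles,
                         uv_scale_profiles)

ds, ct = load_study()

union = sorted(set().union(*(
    set(pd.read_csv(RESULTS / f"differential_G1_vs_{g}.csv",
                    index_col=0).query("call != 'not_significant'").index)
    for g in ("G2", "G3", "G4"))))

profiles = stage_mean_profiles(ct, ds.design).loc[union]
scaled, flat = uv_scale_profiles(profiles)
clusters = kmeans_cluster(scaled, k=8, n_init=50, seed=SEED,
                          flat_compounds=flat)

assign = pd.DataFrame({"subclass": clusters.labels,
                       "trend": clusters.labels.map(clusters.trend)})
assign.to_csv(RESULTS / "cluster_assignments.csv", index_label="compound_id")
clusters.centroids.to_csv(RESULTS / "cluster_centroids.csv",
                          index_label="subclass")

print(f"clustered {len(scaled)} differential compounds into 8 subclasses "
      f"(+{len(flat)} flat profiles kept aside):")
for i in clusters.centroids.index:
    c = clusters.centroids.loc[i]
    print(f"  subclass {i}: n={clusters.sizes[i]:3d} trend={clusters.trend[i]:>5s} "
          f"centroid " + " ".join(f"{v:+.2f}" for v in c))

for direction in ("up", "down"):
    members = clusters.compounds_in_trend(direction)
    tally = attribute_tally(members, ds.annotations)
    pd.Series(tally, name="count").sort_values(ascending=False) \
        .to_csv(RESULTS / f"attribute_tally_{direction}.csv",
                index_label="descriptor")
    print(f"{direction}-trending subclasses ({len(members)} compounds), "
          f"descriptor counts: {dict(tally.most_common())}")
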