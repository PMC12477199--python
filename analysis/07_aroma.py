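"""rOAV aroma analysis: stage-level radar profiles over the ten aroma
attributes and the key-aroma-compound screen (monotone trend subclass and
rOAV > 1 at G1 or G4)."""

import pandas as pd
from _common import RESULTS, SEED, load_study
from vola.aroma import compute_roav, radar_profile, screen_key_compounds
from vola.trends import kmeans_cluster, stage_mean_profiles, uv_scale_profiles

ds, ct = load_study()

union = sorted(set().union(*(
    set(pd.read_csv(RESULTS / f"differential_G1_vs_{g}.csv",
                    index_col=0).query("call != 'not_significant'").index)
    for g in ("G2", "G3", "G4"))))
scaled, flat = uv_scale_profiles(stage_mean_profiles(ct, ds.design).loc[union])
clusters = kmeans_cluster(scaled, k=8, n_init=50, seed=SEED,
                          flat_compounds=flat)

roav = compute_roav(ct, ds.annotations, ds.design)
roav.to_csv(RESULTS / "roav.csv", index=False)
radar = radar_profile(roav, ds.annotations)
radar.to_csv(RESULTS / "radar_profile.csv", index=False)

print("UV-standardized aroma scores G1 -> G4:")
for cat, g in radar.groupby("category", sort=False):
    arrow = "rises" if g["uv_score"].iloc[-1] > g["uv_score"].iloc[0] else "fades"
    print(f"  {cat:>8s}: " + " ".join(f"{v:+.2f}" for v in g["uv_score"])
          + f"  ({arrow} with aging)")

keys = screen_key_compounds(roav, clusters, ds.annotations)
keys.to_csv(RESULTS / "key_compounds.csv", index=False)
n_up = (keys["direction"] == "up").sum()
n_down = (keys["direction"] == "down").sum()
planted = set(ds.truth.key_compounds)
recovered = len(planted & set(keys["compound_id"]))
print(f"key aroma compounds: {len(keys)} ({n_up} up, {n_down} down); "
      f"{recovered}/{len(planted)} planted key compounds recovered")
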