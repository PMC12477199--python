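"""Generate the synthetic aging study and write its input tables.

Emulates a 6-time-point x 6-replicate volatile profiling design with
pooled QC injections: ~200 compounds dominated by terpenoids, esters,
heterocyclics and ketones, planted monotone/transient/flat trajectories
(G4-vs-G1 log2FC = 2 for trending compounds), odor thresholds spanning
five decades, and one pathway concentrated in up-trending compounds.
"""

import json
from pathlib import Path

from vola.synth import SynthConfig, generate_dataset
from vola.tables import write_annotations, write_design, write_feature_table

OUT = Path(__file__).resolve().parents[1] / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)

cfg = SynthConfig(seed=17)
ds = generate_dataset(cfg)

write_feature_table(ds.features, OUT / "peak_areas.csv")
write_annotations(ds.annotations, OUT / "annotations.csv")
write_design(ds.design, OUT / "design.csv")
ds.is_params.is_peak_area.to_csv(OUT / "internal_standard_areas.csv",
                                 index_label="sample_id")
with open(OUT / "ground_truth.json", "w") as fh:
    json.dump({"trend": ds.truth.trend.to_dict(),
               "enriched_pathway": ds.truth.enriched_pathway,
               "key_up": ds.truth.key_up, "key_down": ds.truth.key_down},
              fh, indent=2)

tc = ds.truth.trend.value_counts().to_dict()
print(f"wrote {ds.features.values.shape[0]} compounds x "
      f"{ds.features.values.shape[1]} samples to {OUT}")
print(f"planted trends: {tc}; key compounds: {len(ds.truth.key_up)} up + "
      f"{len(ds.truth.key_down)} down; enriched pathway: "
      f"{ds.truth.enriched_pathway}")
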