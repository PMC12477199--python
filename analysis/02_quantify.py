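"""Semi-quantify peak areas against the internal standard and summarize
per-class concentration totals across aging time points (one-way ANOVA +
Tukey letters)."""

from _common import RESULTS, load_study
from vola.quantify import class_totals

ds, ct = load_study()
res = class_totals(ct, ds.annotations, ds.design)

RESULTS.mkdir(exist_ok=True)
ct.values.to_csv(RESULTS / "concentrations.csv", index_label="compound_id")
res.summary.to_csv(RESULTS / "class_totals.csv", index=False)

print(f"quantified {ct.values.shape[0]} compounds; class totals by time point:")
for cls, p in res.anova_p.sort_values().items():
    sub = res.summary[res.summary["compound_class"] == cls]
    trail = " ".join(f"{t}:{m:.1f}{l}" for t, m, l in
                     zip(sub["time_point"], sub["mean"], sub["letter"]))
    print(f"  {cls:>13s}  ANOVA p={p:.2e}  {trail}")
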