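"""Hypergeometric pathway enrichment of the differential sets, per contrast
and intersected across contrasts."""

import pandas as pd
from _common import RESULTS, load_study
from vola.enrichment import msea, shared_pathways

ds, ct = load_study()
background = set(ct.compound_ids)
pw_map = ds.annotations.pathway_map()

results = {}
for g in ("G2", "G3", "G4"):
    name = f"G1_vs_{g}"
    diff = set(pd.read_csv(RESULTS / f"differential_{name}.csv", index_col=0)
               .query("call != 'not_significant'").index)
    res = msea(diff, background, pw_map, alpha=0.05)
    res.to_csv(RESULTS / f"enrichment_{name}.csv", index=False)
    results[name] = res
    sig = res[res["significant"]]
    top = sig.iloc[0] if len(sig) else None
    print(f"{name}: {len(diff)} differential, {len(sig)} enriched pathway(s)"
          + (f"; best {top['pathway_id']} (k={top['k']}/{top['K']}, "
             f"p={top['p']:.2e})" if top is not None else ""))

shared = shared_pathways(results, alpha=0.05)
print(f"shared across all contrasts: {sorted(shared) or 'none'} "
      f"(planted: {ds.truth.enriched_pathway}, carried by up-trending "
      f"compounds, hence enriched where those are differential)")
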