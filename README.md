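# vola — untargeted volatilomics of cigar aging

`vola` re-implements, as a tested analysis pipeline, the statistics behind an
untargeted HS-SPME-GC-MS study of how a cigar's volatile profile evolves over
long-term aging. It is aimed at flavor chemists and metabolomics analysts who
have a compound × sample peak-area (or concentration) table, per-compound
annotations (chemical class, aroma descriptors, odor thresholds, pathway
memberships) and a sample design (time points, aging stages, pooled QC
injections), and want the full chain from semi-quantification to key
aroma-active compounds.

## What it computes

- **Internal-standard semi-quantification.** With a deuterated standard
  (3-hexanone-2,2,4,4-d₄) spiked at volume *Vₛ* (μL) and concentration *Cₛ*
  (μg/mL) into *M* g of sample, each analyte concentration is
  *Xᵢ = (Vₛ·Cₛ/M)·(Iᵢ/Iₛ)·10⁻³* μg/g, ratioing the analyte peak area *Iᵢ*
  to the standard's *Iₛ* in the same injection.
- **Per-class time courses.** Class-summed concentrations tested across time
  points with one-way ANOVA and Tukey's HSD, reported as compact letter
  displays (groups sharing a letter do not differ at α = 0.05).
- **PCA** (from-scratch SVD on UV-scaled data) to visualize stage structure
  and QC tightness.
- **OPLS-DA** (from-scratch NIPALS/OSC, one predictive + *n* orthogonal
  components) per stage contrast, with R²Y, stratified 7-fold
  cross-validated Q², predictive-component VIP (normalized so
  mean(VIP²) = 1), and 200-label-permutation validation.
- **Differential screen:** VIP ≥ 1, |log₂FC| ≥ 1 (stage-mean ratio) and
  Welch-test p < 0.01 on log concentrations; Venn regions and pooled
  top-20 |log₂FC| lists.
- **Trend clustering:** K-means (k = 8) on UV-scaled stage profiles of the
  differential union; centroids classified monotone-up / monotone-down /
  other; sensory-descriptor tallies per direction.
- **Pathway enrichment:** hypergeometric over-representation (MSEA) of each
  differential set against the compound→pathway map, intersected across
  contrasts.
- **Aroma analysis:** relative odor activity values rOAV = X/T (threshold
  *T* in μg/g; rOAV ≥ 1 = key contributor, ≥ 10 = pronounced), UV-standardized
  radar profiles over ten aroma attributes, and the key-compound screen
  (monotone trend subclass **and** rOAV > 1 at the first or last stage).

Because the original study's deposited data and identification library are
not needed here, every stage is exercised on a synthetic feature-table
generator (`vola.synth`) that plants known trends, effect sizes, thresholds,
an enriched pathway and a 14-up/7-down key-aroma set, so recovery can be
verified against ground truth.

## Worked example

The numbered drivers under `analysis/` run the whole study on the default
synthetic configuration (seed 17) and write tables under `results/`:

```sh
python analysis/01_simulate.py
python analysis/04_differential_screen.py
python analysis/07_aroma.py   # needs 04's outputs
```

`04_differential_screen.py` prints:

```
G1_vs_G2: R2Y=0.9998 Q2=0.9840 -> 20 up, 0 down
G1_vs_G3: R2Y=0.9998 Q2=0.9632 -> 30 up, 20 down
G1_vs_G4: R2Y=0.9995 Q2=0.9801 -> 30 up, 20 down
G1_vs_G4 permutation test (n=200): p(Q2)=0.0050, mean permuted Q2=-0.193 ...
differential union: 70 compounds; in all three contrasts: 0
```

Each line is one stage contrast: the OPLS-DA explains essentially all label
variance (R²Y) and predicts it under cross-validation (Q²), and the screen
calls the planted monotone compounds — at G2 only the transient spike has
|log₂FC| ≥ 1, so just 20 calls; by G3/G4 all 30 up- and 20 down-trending
compounds are called. The permutation p of 1/201 means no permuted model
approached the observed Q². `07_aroma.py` then prints the radar trajectory
of each aroma note (fruity/floral/honey/woody/sweet rise, coffee/roasted/
hay/burnt/spicy fade) and ends with:

```
key aroma compounds: 21 (14 up, 7 down); 21/21 planted key compounds recovered
```

The same flow is available as one call: `vola.pipeline.run_all(RunConfig(...))`.

## Layout

- `src/vola/` — the library: `tables` (I/O + domain types), `synth`
  (generator), `quantify`, `chemometrics` (PCA/OPLS-DA), `differential`,
  `trends`, `enrichment`, `aroma`, `pipeline`.
- `analysis/` — numbered narrative drivers.
- `tests/` — unit, property and end-to-end suites with independent
  brute-force oracles (`tests/oracles.py`).
- `docs/methods.md` — models, assumptions, parameter defaults and
  limitations.
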