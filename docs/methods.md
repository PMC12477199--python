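# Methods

This note documents the models, conventions and parameter defaults behind
`vola`, and what the synthetic benchmark does and does not establish.

## Data model and missing values

The pipeline consumes a compound × sample abundance matrix, a per-compound
annotation table and a sample design mapping samples to time points and
aging stages (pooled QC injections carry the reserved stage `QC`).
Unobserved abundances are *missing*, never zero: a missing peak is below
detection, not absent. Before any log transform the half-minimum fill
replaces each compound's missing cells with half its smallest positive
observed value — the common metabolomics convention, chosen because it keeps
log₂ fold changes finite without inventing signal above the detection floor.
The fill is applied exactly once, and its cell count is logged.

Alignment intersects the compound and sample universes of the three tables,
logging counts dropped from each side; it is idempotent, and an empty
intersection is a hard error rather than a silent empty analysis.

## Semi-quantification

Concentrations are computed literally as
*Xᵢ = (Vₛ·Cₛ/M)·(Iᵢ/Iₛ)·10⁻³* with defaults Vₛ = 10 μL, Cₛ = 10 μg/mL,
M = 0.5 g. Unit chain: Vₛ·Cₛ is μL·μg/mL; the 10⁻³ converts that spike
amount to μg, so Xᵢ lands in μg/g and an analyte whose peak area matches
the internal standard's maps to 0.2 μg/g. Each sample uses its own
internal-standard area, so injection-to-injection response drift cancels.
This is semi-quantification: it assumes equal response factors across
analytes and is interpreted as relative, not absolute, concentration.

## Per-class ANOVA and compact letters

Class totals are per-sample sums of member-compound concentrations,
compared across time points with classic one-way ANOVA (equal-variance)
followed by Tukey's HSD at α = 0.05 (`scipy.stats.tukey_hsd`; the suite
cross-checks letters against the statsmodels implementation). Letters are
assigned by insert-and-absorb: start from one column holding all groups,
split a column for every significantly different pair it contains, absorb
columns that became subsets, then letter columns in order of their
largest-mean member, giving a contiguous alphabet from "a". Two groups
share a letter iff their adjusted p ≥ α. Zero within-group variance is
handled directly (pairs differ iff their means differ) since the
studentized range is undefined there.

## PCA

SVD of the column-centered, optionally column-scaled (UV or Pareto) sample ×
compound matrix. Explained-variance ratios are squared singular values over
their total. Sign convention: the largest-magnitude loading per component
is positive, making score plots reproducible across LAPACK builds. Constant
columns under UV scaling raise an error pointing at the scaling policy
rather than silently producing NaNs.

## OPLS-DA, VIP, Q², permutations

For a binary contrast with labels encoded −1/+1 and X UV-scaled (sample SD,
n−1), the predictive weight vector is w ∝ Xᵀy (the NIPALS PLS1 direction).
Per orthogonal component the X-loading of the current predictive score is
split into its part along w and its remainder; the remainder (normalized)
defines an orthogonal score/loading pair that is deflated from X. Because
each orthogonal score is y-orthogonal by construction, w needs no
recomputation after deflation, and the predictive score from the filtered
matrix is uncorrelated with every orthogonal score (asserted at 1e-8).
Defaults: exactly one predictive and one orthogonal component — the
standard choice for a two-class model; the component count is a parameter,
not a fitted quantity, since there is no universal selection rule.

- **R²Y** = 1 − SS(residual)/SS(y) on training labels.
- **Q²** uses stratified k-fold cross-validation (default 7 folds, the
  SIMCA convention; folds shuffled under the model seed, per-fold
  re-scaling and refitting, prediction of held-out labels). If a class has
  fewer members than folds the fold count drops to the smaller class size;
  classes under 3 samples are refused.
- **VIP** is predictive-component VIP; with one predictive component it is
  √p·|wⱼ| for p variables, so mean(VIP²) = 1 identically. (A total-VIP
  including orthogonal components would mix discriminatory and structured
  noise directions, so the predictive-only form is the default.)
- **Permutation validation** refits the full model (including Q²) under
  uniform label permutations (default 200) and reports add-one empirical
  p-values, floor 1/(n_perm+1), for both R²Y and Q²; the verdict statistic
  is Q².

## Differential screen

Per stage contrast: log₂FC = log₂ of the ratio of stage-mean
concentrations; the test is a two-sided Welch t on log concentrations
(flags switch to Student or Mann-Whitney) — Welch because per-compound
variance heterogeneity between stages is the rule in volatile data, log
because the noise is multiplicative. Call boundaries: VIP ≥ 1 and
|log₂FC| ≥ 1 inclusive, p < 0.01 strict. No multiple-testing correction is
applied to the primary call, matching the stated screening criterion;
BH q-values are reported alongside for transparency. Both-groups-constant
degenerate cases get p = 1 (equal means) or p = 0 (different means). Top-k
ranking uses |log₂FC| descending with ties broken by smaller p then
compound id, so results are stable across runs.

## Trend clustering

The union of differential compounds over all contrasts is summarized as
stage-mean profiles (G1..G4), UV-scaled per compound; constant profiles go
to a dedicated flat bucket instead of breaking the scaling. K-means
(scikit-learn: Lloyd, k-means++, best of 50 restarts by WCSS, seeded)
clusters the scaled profiles with k = 8 by default; k is a flag and no
automatic selection is attempted. A centroid is "up" when stage-to-stage
non-decreasing with total rise > 0.1 scaled units (symmetric for "down");
the 0.1 tolerance keeps noise-level wiggles out of the monotone classes and
is configurable. The suite verifies the clusterer's WCSS against an
exhaustive partition oracle on small instances.

## Enrichment

Over-representation of a differential set against pathway annotations:
upper hypergeometric tail P(X ≥ k) for k overlap out of n differential, K
pathway members in a background of N. The background is all detected,
annotated compounds (not a reference database universe) — the defensible
choice when detection itself restricts the universe; a flag switches it.
Headline significance is raw p < 0.05, BH alongside. The tail is validated
against exhaustive draw enumeration for all N ≤ 12.

## rOAV and the key-compound screen

rOAV = stage-mean concentration / odor threshold, both μg/g; stage
aggregation is the mean over the stage's samples. Compounds without
thresholds carry missing rOAV and are excluded from category averages
(excluding, not zeroing, avoids biasing categories toward zero wherever
threshold databases are sparse). Flags use rOAV ≥ 1 (key contributor) and
≥ 10 (pronounced); the key-compound screen uses strict rOAV > 1 at the
first or last stage — both boundary conventions are deliberate and
documented where they apply. Radar categories are a closed, ordered list of
ten attributes; a compound contributes to every category matching one of
its descriptors (dropping multi-descriptor compounds would discard
information), and each category is UV-standardized across stages, so the
radar shows relative trajectories, not absolute intensity.

## Synthetic data generator

The generator emulates the study design so every stage is testable against
planted truth: 6 time points × 6 replicates plus 4 pooled QC injections;
stages G1 = {S0,S1}, G2 = {S2}, G3 = {S3}, G4 = {S4,S5}; 200 compounds
split terpenoids 0.21 / esters 0.18 / heterocyclics 0.12 / ketones 0.10 /
aldehydes 0.08 / others 0.31 (the class ranking of the emulated study);
trends up 0.15 / down 0.10 / transient 0.10 / flat 0.65. Abundances are
base × stage-multiplier × exp(N(0, σ)) with σ = √log(1+CV²) — strictly
positive, CV-parameterized, the standard model for MS intensities. Monotone
trends are geometric across the four stages so the expected stage-mean
log₂(G4/G1) equals the planted effect (default 2.0) exactly; transients
spike at G2. Replicate noise CV defaults to 0.1 ("low noise", the strong
planted separation configuration); QC noise 0.02; internal-standard areas
are simulated per sample at 2% CV so quantification is exercised
non-trivially. Base concentrations are per-class scales spread log-uniformly
over three decades, putting class totals in the tens-of-μg/g range.
Thresholds are log-uniform over 10⁻⁴..10¹ μg/g with 80% coverage;
`plant_key_aroma` then pins 14 up- and 7 down-trending compounds at
rOAV = 10 at their peak terminal stage and every other monotone compound a
decade below rOAV 1, so the planted key set is exactly recoverable. One
pathway concentrates 80% of up-trending compounds; seven background
pathways have 15% uniform membership. Descriptors follow trend direction
(up-pool: fruity/floral/honey/woody/sweet; down-pool: coffee/roasted/hay/
burnt/spicy; neutral notes otherwise), mirroring the sensory shift the
pipeline is meant to detect.

What the generator does **not** emulate: chromatographic drift, co-elution,
identification error, censoring at the detection limit, or correlated
compound families. Passing recovery tests therefore demonstrates the
statistical machinery is correct and calibrated under the planted model,
not that real cigar data would yield these recovery rates.

## Problem sizes and determinism

The bundled analyses and tests run at desk scale — 200 compounds, 40
samples, 50-run Monte-Carlo loops, 200 permutations — sizes chosen so the
full suite completes in well under a minute per heavy test while leaving
the Monte-Carlo tolerances meaningful. All randomness flows from explicit
seeds; the pipeline fans one global seed out to per-stage child seeds
(`numpy.random.SeedSequence`) so any stage can be re-run in isolation and a
rerun with the same configuration is bit-identical.

## Known limitations

- OPLS-DA is two-class only; multi-stage structure is handled as pairwise
  contrasts against G1.
- The p < 0.01 screen is uncorrected by design fidelity; users screening
  thousands of compounds should consult the reported q-values.
- Semi-quantified concentrations inherit the equal-response-factor
  assumption; rOAVs built on them are order-of-magnitude statements.
- The compact-letter display is not unique when the significance relation
  is intransitive; insert-and-absorb yields one minimal, deterministic
  labelling.
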