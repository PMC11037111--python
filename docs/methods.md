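# Methods

`milscore` re-creates, at desk scale, a weakly-supervised pipeline for
scoring histological disease activity in inflammatory bowel disease (IBD)
biopsies: H&E images are segmented, tiled into overlapping patches,
stain-normalised and quality-filtered; patch embeddings are aggregated by
attention-based multiple instance learning (MIL) into per-biopsy severity
predictions for GHAS (Crohn's disease) and Geboes (ulcerative colitis)
subgrades; and model output is compared against readers with standard
agreement statistics.  Because clinical trial slides of this kind are not
publicly available, the package ships a synthetic-biopsy generator with
planted, mask-level ground truth, and every claim the test suite makes is
a claim about recovery of that planted truth.

## Scoring model

Both instruments are held as integer severity maps, 0–3 per subgrade:

* **GHAS** — `EPDAM` (epithelial damage), `PolysEP` (neutrophils in
  epithelium), `PolysLP` (neutrophils in lamina propria), `MonosLP`
  (mononuclear cells in lamina propria), `ULCER`; scored per compartment
  (ileum or colon).  `ULCER` is modelled 0–3 with presence defined as
  severity > 0, the most conservative reading of a "presence of ulcers"
  item.
* **Geboes** — grades `G0`–`G5` with the published sublevels (e.g.
  2B.0–2B.3) encoded as integers 0–3 per grade, so that all grades share
  one arithmetic and one binarisation rule.

Presence-of-pathology binarisation maps each of four shared features to
one subgrade (`EPDAM`/`G5`, `PolysEP`/`G3`, `PolysLP`/`G2B`,
`MonosLP`/`G1`) and declares pathology present when that severity exceeds
zero.  The simplified Geboes scale merges the two highest levels of every
grade (3 → 2 by default); the exact published merge table is not public,
so the map is config-overridable per grade, constrained to be
order-preserving and non-increasing — which makes it idempotent.
Histological-improvement definitions vary between trials, so they are
pluggable named predicates; the shipped default `neutrophil_resolution`
requires G2B = G3 = G4 = G5 = 0 at follow-up (neutrophil clearance with no
crypt destruction or erosion/ulceration).

## Synthetic biopsies

The generator is the package's ground-truth instrument, not a photorealism
exercise.  Each biopsy is a blob-shaped tissue region (elliptical bump plus
smoothed noise, roughly 30–55 % of a 1024-px square frame) on a white
slide, carrying crypt-like low-frequency colour texture and fine nuclear
speckle.  An epithelial band (the outer ~`size`/24 of the tissue by
distance transform) and the lamina-propria interior partition the tissue
for feature placement.  Per subgrade:

* neutrophil subgrades plant dark-purple disks of radius 2–4 px —
  30 × severity at 1024 px, area-scaled otherwise — confined to a single
  inflammatory *focus* (disk of radius `size`/7), since IBD neutrophil
  infiltration is focal rather than uniform; clustering is also what makes
  attention localization a well-posed recovery target;
* mononuclear/chronic-inflammation subgrades threshold a smooth density
  field to a blobby region covering 7 % × severity of the candidate area;
* damage/ulcer subgrades paint pale disrupted regions at the epithelial
  border and crater-shaped erosions.

Severity nesting: for a fixed seed, severity *s* plants a prefix of the
candidate set used at *s* + 1 (dots) or a superset threshold of one fixed
field (regions), so planted area is non-decreasing — and dot counts
strictly increasing — in severity.  Stain batch effects are per-channel
multiplicative factors in optical density (`I' = 255 (I/255)^f`, f drawn
from 1 ± 0.2 by default), which leaves white background invariant.
Artefacts (blank-out, blur σ = 8, white shear streaks at 75 % duty, dark
folds at 25 % luminance) are painted last over their own mask, *inside*
the tissue interior — an artefact flush with the tissue boundary would be
indistinguishable from slide background at patch level, and central-lab
artefacts (shearing, folds) are tissue phenomena.

Datasets allocate class counts by largest-remainder quota rather than
i.i.d. sampling, so a requested 90:10 imbalance is hit exactly up to
rounding.  What the generator does **not** model: real crypt architecture,
cell morphology, z-axis focus, multi-biopsy slides, scanner noise.
Passing tests therefore demonstrate that the pipeline machinery recovers
planted signal under controlled staining and artefact variation — not
clinical performance.

## Preprocessing

Segmentation thresholds HSV saturation with Otsu's criterion (absolute
floor fallback for unimodal images), closes small gaps, and fills **all**
enclosed holes by default.  Hole filling is load-bearing: blank and streak
artefacts planted inside tissue stay part of the tissue mask, so QC can
read "near-white inside tissue" as an anomaly rather than background.

Tiling is raster-order, 0-based, half-open windows of 224 px at stride
112 (50 % overlap), values chosen from common MIL practice and exposed in
config.  The pipeline tiles with `min_tissue=0` and delegates all
filtering to QC, so kept + rejected always equals the full grid and every
rejection carries exactly one reason (first failing check in the fixed
order background → low_tissue → blur → artefact):

* *background*: near-white fraction (all channels ≥ 220) > 0.75;
* *low_tissue*: mask tissue fraction < 0.3;
* *blur*: the patch is divided into a 14 × 14 cell grid; cells at least
  half tissue with Laplacian variance < 25 are "flat", and a flat-cell
  fraction ≥ 0.45 rejects.  Cell-wise scoring catches half-blurred patches
  whose sharp half would dominate a whole-patch variance (clean synthetic
  tissue scores ≈ 1000, blurred regions ≈ 0, so the threshold sits three
  orders of magnitude below clean texture);
* *artefact*: near-white-inside-tissue fraction > 0.25 (blank, streaks),
  very-dark fraction > 0.12 (folds), or a combined anomalous-area score
  (white-in-tissue + dark + flat-cell area) ≥ 0.28, which catches mixed
  partial artefacts none of which dominates alone.  On clean synthetic
  patches the combined score is ≤ 0.01, so the margin is ~30-fold.

Stain normalization is Reinhard-style colour transfer in CIELAB computed
on non-background pixels only (background is left untouched), with a
Macenko-style stain-vector method available as a config alternative.
Normalising a patch to a reference built from itself is an identity up to
one grey level, and the operation is idempotent at the same tolerance.

## Patch embedding

The backbone is a four-block convolutional network evaluated in NumPy
(im2col + matmul) with fixed, seeded He-initialised weights — a
random-features extractor in the extreme-learning-machine tradition.  This
is a deliberate design: the package targets single-CPU determinism and
testability, so the convolutional filters are never trained and all task
adaptation lives in the MIL head.  Two choices matter for recovering
small rare objects (neutrophil-sized dots occupy ~0.1 % of a patch):
3×3 stride-1 convolutions with interleaved 2×2 max pooling rather than
strided convolution, and a global readout that concatenates the spatial
*mean* of half the final channels with the spatial *max* of the other half
(d = 128 by default).  Max pooling propagates peak responses that average
pooling washes out; on synthetic patches this raises instance-level
separability of dot-bearing patches from ~0.78 to ~0.94.  Patches are
resized to 112 px before embedding.  A deeper `resnet_like` variant with
identity skips is config-selectable.

## MIL aggregation and training

Three aggregators over a bag `H = (h_1 … h_N)` of patch embeddings:

* **SA-AbMILP** (primary): optional pairwise self-attention
  `h'_k = h_k + g · softmax(HHᵀ/√d) H` with the residual gain g learnable
  and initialised at 0 (identity at start; an RBF kernel is the config
  alternative), followed by gated attention pooling
  `e_k = w · (tanh(V h'_k) ⊙ σ(U h'_k))`, `a = softmax(e)`,
  `z = Σ a_k h'_k`, and a linear class head.  Attention weights are
  non-negative and sum to 1 by construction, giving permutation
  invariance, m-fold replication invariance, and per-patch relevance for
  heatmaps.
* **RNN**: instances ranked by an auxiliary relevance scorer (multinomial
  logistic regression on instances inheriting their bag label; relevance
  = 1 − P(lowest severity)); the top-S = 32 in rank order feed a tanh
  recurrent unit (hidden 64) whose final state is classified.  Ranking is
  used because raster order is meaningless after QC removal.  A plain tanh
  unit replaces a gated recurrent unit: it is what the package can
  differentiate by hand cleanly, and the aggregator exists as a
  comparison baseline, not the primary model.
* **FV + RF**: improved Fisher vectors (gradients w.r.t. means and
  diagonal variances of a K = 8 diagonal GMM fitted on training
  instances; signed-sqrt power and L2 normalisation; length 2·K·d) under a
  500-tree random forest.

The neural heads train with hand-derived gradients (verified against
finite differences to ~1e-10 in the test suite) and Adam (lr 5e-3),
per-bag updates in seeded shuffled order, under the focal loss
`FL = −α_c (1 − p_t)^γ log p_t` with γ = 2 and inverse-frequency class
weights by default — the standard counter to severity-class imbalance;
γ = 0 with uniform weights recovers cross-entropy exactly.  Early stopping
monitors validation accuracy (loss as tie-break) with patience 20 over at
most 120 epochs.

Splitting is stratified 80/20 into working/testing sets with 5 inner
folds over the working set, grouped at the patient level (a patient's
stratum is their maximum severity) so repeated biopsies from one patient
can never leak across the split.  Folds assign patients round-robin within
each stratum, which bounds per-fold class-proportion drift.  The final
model is the fold ensemble (averaged probabilities) by default — fold
models exist anyway and averaging is variance-reducing and deterministic —
with a whole-working-set refit (trained for the mean best-epoch count) as
the config alternative.  Prediction breaks probability ties toward the
lower severity, the conservative direction for a screening instrument.

## Agreement statistics

All statistics are closed-form implementations cross-checked in tests
against independent direct-formula recomputation (and against
scikit-learn/statsmodels): unweighted Cohen's κ (linear weighting
optional), Fleiss' κ generalised to varying rater counts, modal panel
scores with ties broken upward, the pooled two-proportion Z-test, odds
ratios with Woolf log-intervals (Haldane–Anscombe +0.5 on zero cells,
flagged) and Fisher's exact association p-value, and Wilson score
intervals for accuracies.  Kappas with degenerate chance terms return a
NaN sentinel rather than a silent 0 or 1, so report tables can print
"n/a".

## Heatmaps

Attention weights are classed by *rank* tercile — top third red, middle
yellow, bottom green — rather than by weight value, so heavily skewed
attention distributions still produce three classes; the all-ties
degenerate case maps to yellow.  Overlapping windows are blended by the
per-pixel mean of covering patch weights before the pixel is coloured
against the tercile boundaries.  Rejected patches stay uncoloured.

## Validation experiments and problem sizes

`milscore.validation` packages the experiments that the acceptance script
and the heavy tests share.  The headline end-to-end study uses 200
biopsies at 1024 px (binary PolysEP 0 vs 2, balanced, 160 working / 40
testing), 128-d embeddings and the SA-AbMILP aggregator; the imbalance
diagnostic uses 120 biopsies at 512 px with a 9:1 skew and compares
minority-class recall of FV+RF (no reweighting) against SA-AbMILP (focal
+ inverse-frequency weights) on the same embeddings and split; QC rates
are measured on 512-px biopsies (≥ 500 clean patches and every patch with
≥ 50 % planted-artefact overlap); stain-normalization benefit on 100
jittered copies of one biopsy.  These sizes were chosen as the smallest
that make the statistics stable on a single CPU.

## Numerical choices and degenerate inputs

All randomness descends from one integer seed through named
`SeedSequence` child streams, so images are byte-identical across calls
and training runs are exactly repeatable.  Softmaxes are
max-subtracted; p_t is clipped at 1e-12 inside the focal loss; attention
normalisation tolerates 1e-6; embedding standardisation floors zero
variances at 1; the GMM uses reg_covar 1e-4; Fisher vectors guard the
zero-norm bag.  Degenerate inputs follow explicit conventions rather than
exceptions where a convention exists: pooled proportions of 0 or 1 give
z = 0, p = 1 flagged degenerate; all-white patches return unchanged with
a warning flag; single-member severity classes go to the working set with
a warning; folds whose training side is single-class are skipped with a
warning.

## Known limitations

* The backbone is untrained; tasks whose signal random convolutional
  features cannot expose (subtle textural pathology) would need the
  trained-backbone extension.
* The synthetic generator's visual model is a stand-in; no claim of
  histological fidelity is made, and thresholds calibrated on it (QC,
  blur) would need re-calibration on scanner data.
* Geboes simplified-scale merge table and trial improvement definitions
  are placeholders behind config, as the published sources do not specify
  them.
* Fleiss' κ with varying rater counts uses the pairwise-agreement
  generalisation; with a constant rater count it reduces to the standard
  form (tested).
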