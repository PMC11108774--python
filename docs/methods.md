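# Methods

## Problem and model family

`cytorigin` classifies serous-effusion cytology cases — a smear frame tiled
into 224 × 224 patches ("bag" of "instances") plus three clinical covariates
(age *a*, sex *s*, specimen sampling site *t* ∈ {hydrothorax, ascites}) —
into five categories: digestive, female reproductive, respiratory,
blood/lymphatic, and benign. Only the case carries a label; no patch-level
annotation exists, so all classifiers are weakly supervised
multiple-instance learners over per-patch feature vectors.

Four heads share that contract:

* **AbMIL** — instance transform `h_i = ReLU(W₂ ReLU(W₁x_i + b₁) + b₂)`,
  gated attention `a_i ∝ exp[tanh(V h_i) ⊙ sigmoid(U h_i)]` normalized over
  the bag, pooled bag feature `Z = Hᵀ A`, and `p = softmax(W₃ Z + b₃)`.
  The gated trunk output is a vector per instance; the plain head reduces it
  with an unweighted sum (equivalently a fixed all-ones branch vector),
  while the multi-branch variant learns the branch vectors.
* **AbMIL–MB** — a shared gated trunk splits into one attention branch
  `W_{a,i} ∈ R^{1×384}` and one linear classifier `W_{c,i} ∈ R^{1×512}` per
  class; each branch's attention normalizes to 1 over the bag and yields a
  class-specific pooled representation.
* **TransMIL** — token sequence `{h_class, h_1..h_k, h_sex, h_age,
  h_origin}` (k + 4 tokens of width 384) through 3 transformer encoder
  layers (multi-head scaled-dot attention with `d_k = 64`, hence 6 heads at
  width 384; position-wise FFN with ReLU; LayerNorm before and after the
  FFN; residual connections on both sublayers); a linear classifier reads
  the class token.
* **TransMIL-CMA** — separate image (`{h_class, h_1..h_k}` + positions) and
  clinical (`{h_sex, h_age, h_origin}`) streams pass through two stacked
  multimodal attention blocks — each stream updated by its self-term plus a
  cross-term using the other stream's keys/values, then LayerNorm → MLP →
  residual — are concatenated through one standard self-attention block,
  average-pooled, and classified by a two-layer MLP.

Clinical fusion is additive for the AbMIL variants
(`X = X_image + X_age + X_sex + X_location`, learned d-vector embedding
tables; ages bucketed into 5-year bins over 18–90) and token-based for the
transformer variants. The cancer-positive probability is
`P_cancer = 1 − P_benign`.

Reference training settings: Adam, constant lr 2·10⁻⁴, weight decay 10⁻⁵,
batch size 1 (one bag per step), 100 epochs, checkpoint chosen as the
lowest-validation-loss epoch from epoch 60 onward (earliest on ties). The
ensemble averages the probability vectors of its members; the reference
configuration is 4 architectures × 3 feature inputs = 12 models.

## Self-supervised feature extractor

Per-patch features come from momentum contrast (MoCo): a query encoder
trained against a slowly updated key encoder
(`θ_k ← m·θ_k + (1−m)·θ_q`, reference `m = 0.999`) and a FIFO queue of
negative keys (reference size 65,536) via the InfoNCE loss at temperature
τ = 0.07. Optimization is SGD (initial lr 0.015, weight decay 10⁻⁴, batch
128, 200 epochs) under cosine decay
`lr_i = lr₀ · 0.5 · (1 + cos(π·i/n))`. The backbone is a four-stage
residual CNN (50-layer-equivalent at reference scale) followed by a
two-layer MLP projection head used only during pretraining; exported
features are the pre-projection backbone output, the standard MoCo
evaluation choice. Keys are L2-normalized before enqueueing; the queue is
initialized with unit random vectors and then burned in with one
gradient-free key-encoder pass so the loss is defined and meaningful from
the first step.

Desk-scale adaptations, all exposed in `EncoderConfig`/`MoCoTrainConfig`
with the reference values as defaults:

* **No batch normalization.** Training runs one image at a time on CPU, so
  batch statistics do not exist. An optional per-channel spatial
  normalization (`normalize_blocks`) is available but off by default: global
  average pooling must retain each image's chromatic profile, which spatial
  normalization would cancel.
* **Projection centering.** Without batch normalization the projections of
  a small random network are nearly collinear (a shared mean component
  dominates), which makes positives and negatives indistinguishable and the
  loss uninformative. A running mean of raw key projections is subtracted
  before L2 normalization on both branches — the same mechanism as teacher
  centering in self-distillation methods.
* **Momentum at toy scale.** `m = 0.999` assumes tens of thousands of
  steps; a five-epoch toy run takes ~35 steps, over which the key encoder
  would stay at its random initialization. Toy configurations use `m = 0.8`.
* **Progress monitoring.** The training loss's own target (keys, queue,
  center) drifts by construction, and once the encoder clusters same-class
  near-duplicates the achievable loss rises again. The log therefore also
  records an evaluation loss against a frozen set of view pairs and a frozen
  negative queue; that quantity is the monotone progress measure the tests
  assert on.

Channel normalization statistics (R/G/B mean and SD) are computed from the
training corpus at `train_moco` time and stored with the encoder.

## Data plumbing

Images are tiled into non-overlapping 224 × 224 patches, row-major from the
top-left corner; partial edge tiles are dropped so a 2,797 × 1,757 frame
yields 12 × 7 = 84 patches. Patch QC removes blank patches (grayscale
intensity variance below 10 on the 8-bit scale) and unfocused patches
(Laplacian variance below 5); both thresholds are config-exposed and the
operation is idempotent. The taxonomy maps organs to fine subgroups (cavity
digestive, secretory digestive, female genital including breast, respiratory
tract, blood/lymphatic) and on to the five categories; subgroups that rarely
metastasize to the serous cavities (urinary, head and neck, nervous system,
bone/soft tissue, melanoma, mesothelioma, thymoma) raise a dedicated
excluded-subgroup error, distinct from unknown labels. Each image combined
with its clinical record is one case; a patient with several frames
contributes several cases. Magnification (×200/×400) is metadata only — no
rescaling is attempted.

## Evaluation statistics

* Micro-averaged one-versus-rest AUROC: the five one-hot label columns and
  five probability columns are flattened into one binary ranking problem;
  the point estimate is the Mann–Whitney rank statistic (ties ½) and the CI
  uses DeLong's structural-component variance (cross-checked against R
  pROC in the tests). Per-category OvR AUROCs are emitted alongside.
* Top-n accuracy (n = 1, 2, 3) with ties broken by the fixed category order
  (digestive, female reproductive, respiratory, blood/lymphatic, benign).
* Proportion CIs are exact Clopper–Pearson (beta quantiles). Multi-class
  metrics use argmax assignment; the binary cancer task thresholds
  `P_cancer` at 0.5 by default (the full ROC is available).
* Diagnostic score η per case: 0 for benign↔malignant confusion, 1 for
  malignant with wrong origin, 2 for fully correct; the mean carries a
  normal-approximation CI.
* Fleiss' κ = (p_o − p_e)/(1 − p_e) with the Landis–Koch qualitative bins
  (contiguous at 0.2/0.4/0.6/0.8; the published rendering of the fair bin's
  lower edge as 0.21 is treated as a printing artifact) and a two-sided
  z-test using the Fleiss (1971) large-sample null variance.
* Real-world accuracy bounds for cohorts containing uncertainty cases
  (no ground truth): lower = acc·n_known/(n_known+n_uncertain),
  upper = (acc·n_known + n_uncertain)/(n_known+n_uncertain). Published
  figures for such bounds do not exactly equal this formula applied to the
  rounded published accuracies, because the underlying correct-case counts
  are not printed; the formula is implemented as defined.
* Permutation tests: paired samples use sign-flips of per-case differences,
  unpaired samples label shuffling; two-sided, 10,000 replicates by
  default, add-one estimator so p ≥ 1/(reps+1).
* Perturbation importance: age resampled uniformly on [18, 90], sex and
  site flipped; Δ^c = (τ − τ^c)/τ on top-1 accuracy.

## Survival analysis

Kaplan–Meier curves with the median as the earliest time with S(t) ≤ 0.5
(not reached when no crossing) and median CIs read from the log-log curve
CI. Log-rank tests are the standard 1-df chi-square. Cox regression
maximizes the partial likelihood through lifelines with Efron tie handling —
the design originally called for Breslow as default, but lifelines
implements Efron only; the synthetic cohorts have continuous, tie-free
times, where the two coincide, and a scikit-survival (Breslow) route exists
for cross-checks. Stepwise selection is bidirectional by AIC with the
concordance exposure forced to remain (it is the reported effect); the full
no-selection model is always emitted alongside. Karnofsky functional-score
comparisons use two-sided two-sample t-tests with Bonferroni correction
across the two timepoints.

## Synthetic data: what it emulates and what it does not

The generators make every pipeline stage testable offline:

* **Tiles** — procedural textures (blob size, clustering, chromatic profile
  differ by class) standing in for papillary/wreath-like/compact cell
  clusters. They are *not* photorealistic cytology; passing tests show the
  pretraining and tiling machinery works, not that real smears would be
  classified correctly.
* **Feature bags** — positive bags mix witness vectors (background + a
  class-specific mean shift, Bernoulli(w) per instance with at least one
  forced) into N(0, I) background; benign bags are background-only.
  Defaults: 200 cases, d = 64, 8–24 patches per bag, witness rate 0.6,
  shift 2.5, balanced classes (so every category is learnable at desk
  scale), stratified 60/20/20 split. Covariates follow class-conditional
  distributions echoing the site–origin association of effusion cytology
  (digestive → ascites 0.8, respiratory → hydrothorax 0.85, female
  reproductive skewed female); a site-only configuration (no feature
  signal, site association 0.95/0.05, uninformative sex/age) plants the
  truth that the perturbation experiment must recover (Δ^site dominant).
* **Rater matrices** — each case has a latent label reported with
  probability ρ, otherwise a draw from the marginal; ρ tunes κ
  monotonically.
* **Survival cohorts** — exponential event times (λ_ref = ln2/median,
  λ_alt = HR·λ_ref) with uniform censoring whose upper bound is calibrated
  by root-finding so P(censored) equals the requested rate.
* **Synthetic CUP stand-in** (`synthetic_cup_cohort`) — the deposited
  391-patient treatment-concordance table is restricted-access, so a
  stand-in fixes the reported marginal composition exactly (276/115
  concordant/discordant, 102 + 61 deaths, 310 treated with PR/SD/PD
  75/91/48 and 14/29/53) and draws times from exponentials with the
  reported group medians (27 and 17 months) under uniform staggered
  admission; the per-group follow-up horizon is calibrated so the model's
  natural death probability equals the reported death fraction, which makes
  conditioning on the exact death counts unbiased (both horizons land near
  40 months, consistent with the ~3.4-year enrollment window). Count-derived
  statistics are therefore reproduced exactly and the KM medians by
  construction; the multivariate hazard ratio depends on the real cohort's
  covariate structure, which no stand-in can supply — the analysis reports
  whatever the stand-in yields (≈ the marginal hazard ratio 17/27 ≈ 0.63
  up to sampling noise).

All generators are pure functions of (config, seed).

## Numerical substrate

The networks run on a small reverse-mode autodiff engine
(`cytorigin._autodiff`) written for this package: float64 numpy arrays,
broadcasting arithmetic with gradient unbroadcasting, batched matrix
products, im2col convolution and max pooling, topological-order
backpropagation, SGD (momentum + L2) and Adam. Gradient correctness is
enforced by finite-difference tests at 10⁻⁴ relative tolerance (absolute
near zero, where normalization layers legitimately produce exactly-zero
gradients). Everything is deterministic given a `numpy.random.Generator`
seed; no threading or GPU nondeterminism exists.

## Desk-scale problem sizes

Defaults in tests and the acceptance script: MIL experiments use 200 bags
at d = 64 with width-48 transformers (d_k = 8, 6 heads) and 12–30 epochs
(checkpoint window scaled to half the epochs); MoCo toys use 200 tiles at
96 px, 64-px crops, queue 256, 5 epochs; survival calibration uses 200
null replicates at n = 80 and recovery at n = 2,000. These sizes are the
package's own desk-scale choices; every reference-scale value remains the
config default where it does not conflict with single-CPU determinism.

## Known limitations

* The synthetic bags are Gaussian in feature space; real per-patch MoCo
  features are heavy-tailed and correlated within a smear.
* The stand-in CUP cohort cannot reproduce covariate-adjusted hazard
  ratios from the real table, only marginal structure.
* The attention heatmap for transformer variants uses last-layer
  class-token attention averaged over heads — a standard but not unique
  choice, recorded in the overlay metadata.
* No whole-slide (pyramidal) inputs, stain normalization, or scanner
  calibration; magnification is metadata only.
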