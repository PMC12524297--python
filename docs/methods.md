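# Methods

## Problem and model

`hazchemnet` classifies small molecules as hazardous (1) or non-hazardous
(0) from their SMILES strings. The pipeline has three stages.

**Featurization.** Each molecule is canonicalized with RDKit and encoded as
a 512-bit Morgan (circular) fingerprint of bond radius 2 concatenated with
four global physicochemical descriptors in fixed order — molecular weight
MolWt (g/mol), Crippen logP (unitless lipophilicity), and the hydrogen-bond
donor and acceptor counts NumHDonors / NumHAcceptors — giving
x = [f_Morgan, d] ∈ ℝ⁵¹⁶. All 516 features (bits included) are z-scored
with population statistics, x′ᵢ = (xᵢ − μᵢ)/σᵢ, fitted on the training
split only and applied unchanged everywhere else; zero-variance columns
(fingerprint bits never set in training) keep σ = 1 so they map to a
constant 0 rather than NaN.

**Attention autoencoder.** Encoder h₁ = ReLU(W₁x′ + b₁),
z = ReLU(W₂h₁ + b₂). Attention over the latent code: u = tanh(W_a z + b_a),
α = softmax(u), z′ = α ⊙ z, with the softmax taken over all latent
dimensions (max-subtraction for overflow safety). The decoder maps z′
through a mirror-image ReLU layer back to ℝ⁵¹⁶ and the stack minimizes the
mean-squared reconstruction error, averaged over samples and dimensions.
The decoder consumes the attention-weighted code z′, not the raw z, so
attention participates in the reconstruction objective.

**Mixture of experts.** Each of M experts is a small feed-forward network
on z′ ending in a sigmoid, y_m ∈ [0, 1]; a linear gating network scores the
same z′ and g = softmax over the M scores. The prediction
y = Σ_m g_m·y_m is a convex combination of expert probabilities, trained
with binary cross-entropy. A molecule is called hazardous when
y ≥ 0.5; ties at the threshold go to the hazardous class, deliberately
favouring recall over precision — in a screening setting a missed hazard is
the expensive error.

All network code — forward passes, analytic gradients, and the Adam
optimizer — is implemented directly in NumPy. The analytic gradients of
both loss functions (including backprop through the attention softmax and
the gating network) are verified against central finite differences in the
test suite to ~1e-8 absolute agreement.

## Training schedule

Training is staged: (1) the autoencoder is trained on reconstruction MSE
(default 120 epochs, where its loss curve plateaus); (2) the encoder and
attention are frozen and the MoE is trained on z′ with BCE (default 100
epochs). An optional third stage (`joint_finetune`, off by default)
backpropagates the classification loss end to end through the attention
and encoder. The decoder is untouched during fine-tuning.

Fine-tuning matters when the class signal is invisible to reconstruction.
After z-scoring, every column has unit variance, so a signal carried by a
single column (e.g. one descriptor) gives the MSE objective no reason to
preserve that column through the bottleneck; only a supervised gradient
reaching the encoder can select it. The planted-signal ablation experiment
therefore runs with fine-tuning enabled.

Defaults (all config-exposed, YAML-overridable; unknown keys are errors):
hidden_dim 256, latent_dim 64, expert_hidden 32, M = 4 experts, Adam with
learning rate 1e-3, batch size 64, decision threshold 0.5. Layer widths
are modest capacity for a 516-dim input at the few-thousand-compound scale
this model targets.

## Evaluation protocols

* **Split**: 7:2:1 train/validation/test with largest-remainder rounding
  (5140 records → 3598/1028/514), stratified by label by default since the
  positive:negative ratio (≈0.9) is mildly imbalanced. Stratified
  allocation uses per-class largest remainder and then moves single
  records to restore the exact global sizes.
* **Cross-validation**: stratified 5-fold over the supplied data with each
  fold trained `repeats` times (5 by default) from fresh seeds derived
  from the master seed; reports mean ± SD per fold (across repeats) and
  pooled over all k×repeats runs. When a 10% test split is held out
  beforehand, CV operates on the remaining 90% — both protocols are
  independently invokable.
* **Metrics**: accuracy (TP+TN)/(TP+TN+FP+FN), precision TP/(TP+FP),
  recall TP/(TP+FN), F1 = 2PR/(P+R), and AUC by the Mann–Whitney rank
  statistic with midrank tie handling. Undefined metrics (no actual
  positives, single-class AUC) are NaN plus an explicit flag, never a
  silent 0. Reports print percent with one decimal.
* **Ablation**: six named variants (full, −MolWt, −MolLogP, −NumHDonors,
  −NumHAcceptors, −MorganFingerprint) rerun the whole pipeline with
  identical seeds on 516, 515×4, and 4 columns respectively.
* **External validation**: two panels of known class are featurized with
  the *training* standardizer (the only leakage-free choice), scored, and
  reported as per-class accuracy plus the false-negative rate on the
  hazardous panel; unfeaturizable compounds are excluded from denominators
  with a warning.

## Synthetic data

The feature generator draws two Gaussian classes in ℝ⁵¹⁶ (noise SD 1.0)
whose means differ by `class_separation` on `n_informative` dimensions,
then binarizes the first 512 dimensions by thresholding at 0 to mimic
fingerprint bits. Defaults — separation 3.0 on 20 dimensions, 300
compounds per class — define a high-signal dataset that a working pipeline
should classify almost perfectly, while separation 0 is an exchangeable
null. `informative_dims` can pin the signal to chosen columns (used to
plant a signal in a single descriptor).

What this emulates, and what it does not: real fingerprint bits are
strongly correlated (substructures co-occur) and descriptor distributions
are heavy-tailed; the generator's independent dimensions have neither
property. Consequently the synthetic matrix is nearly incompressible —
held-out reconstruction MSE stays near 1 no matter how long the
autoencoder trains — so reconstruction-generalization behaviour is
exercised on featurized real molecules (the SMILES pool), where
correlated bits give the autoencoder genuine structure to compress.
Passing tests demonstrate that the machinery learns what is learnable
under known conditions, not that any particular accuracy transfers to a
specific regulatory dataset.

The SMILES table generator samples (with replacement by default) from a
curated pool of 24 hazard-plausible industrial chemicals / solvents /
pesticides and 24 benign sugars, amino acids and buffer components; every
entry parses in RDKit, so fixture featurization produces zero rejects.
The pool labels serve fixtures only and are not a toxicological claim
about individual compounds.

## Numerical and design choices

* Population (n-denominator) SD in standardization; fit on training data
  only to avoid leakage.
* Softmaxes use max-subtraction; sigmoids are computed in the
  numerically safe branch form; BCE clips probabilities at 1e-12.
* Multi-fragment SMILES (salts) are featurized as given and logged;
  invalid SMILES are rejected with a reason and never imputed, and
  dataset-level featurization continues past failures.
* Duplicate SMILES keep the first occurrence; a conflicting label logs a
  warning. Duplicate ids are an error.
* One master seed drives weight initialization, shuffling and fold
  assignment through named sub-streams (CRC-derived, < 2³¹), so any
  component run is independently reproducible and two runs with the same
  seed produce byte-identical reports and bundles.
* NaN/Inf training loss aborts with a diagnostic rather than continuing.

## Problem sizes used in tests and the verification script

Training-dependent tests and `scripts/acceptance.py` run desk-scale
configurations chosen once: n = 600 synthetic compounds; the
cross-validation check uses the default layer sizes with 100 autoencoder
and 150 MoE epochs (5-fold, one repeat); the shuffled-label control and
the planted-signal ablation use a 64/16/16 network with 2 experts (the
chance-level and feature-ranking properties they check do not depend on
capacity). These sizes keep a full verification run in the low minutes on
one CPU while leaving each tested property comfortably inside its
assertion band.

## Known limitations

* The fingerprint hash is the toolkit's circular-fingerprint
  implementation; bit-level equality with vectors produced by other
  toolkit versions is not guaranteed.
* Hyperparameters were not tuned against any external benchmark; the
  defaults are reasonable capacity, not optimized values.
* The classifier outputs an uncalibrated probability; the 0.5 threshold
  is a policy default, not a calibrated operating point.
* Class imbalance handling is limited to stratified splitting; no
  reweighting or resampling is implemented.
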