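# Methods

`lmdpnet` predicts the progression of Alzheimer's disease over annual
followup visits from longitudinal records in which imaging modalities,
biomarkers, and even the diagnosis itself are arbitrarily missing.  This
note describes the model, the synthetic cohort it is validated on, and the
numerical choices that were genuinely open.

## Data model

A patient is an ordered sequence of visits at months `s_t` (M0, M12, ...,
M60).  Each visit carries a diagnosis `y_t ∈ {CN, MCI, AD}` (or missing),
six regional brain volumes (ventricles, hippocampus, whole brain,
entorhinal, fusiform, mid-temporal; ml), demographics (age, gender,
education), the APOE4 allele count, and optionally an MRI and/or a PET
volume scaled to [0, 1].  Two derived per-visit vectors drive everything
downstream:

* the **mask** `m_t ∈ {0,1}` — one bit per input element (one per imaging
  modality, per biomarker, per demographic/genetic element, one for the
  diagnosis) marking what was actually observed;
* the **interval** `δ_t` — per element, the time since that element was
  last observed: `δ_1 = 0`, and for `t > 1`
  `δ_t = s_t − s_{t−1}` if the element was observed at `t−1`, else
  `s_t − s_{t−1} + δ_{t−1}` (the gap telescopes back to the last
  observation).

Preprocessing follows common practice for merged longitudinal cohorts:
biomarkers are divided by the patient's intracranial volume and z-scored;
age is propagated from the baseline age by elapsed months and z-scored with
education; gender and APOE4 are one-hot encoded.  Normalization statistics
are computed on each training split only (recomputed inside every
cross-validation fold), and the biomarker transform is inverted when errors
are reported in ml.

## Multimodal imaging fusion (product of experts)

Each modality `c` has its own variational encoder producing a diagonal
Gaussian `(μ_t^(c), σ_t^(c))` over a shared latent space.  For any nonzero
subset `n` of the observed modalities the experts are fused by a product of
experts:

    T^(c) = (σ^(c))⁻²            (precisions add)
    σ_fused = (Σ_observed T^(c))^(−1/2)
    μ_fused = (Σ_observed μ^(c) T^(c)) · σ_fused²

No universal prior expert enters the product — only observed modalities
contribute.  A reparameterized sample `z = μ + σ ⊙ ε` from each fused
subset is pushed through **every** modality decoder, so the model learns to
reconstruct PET from MRI alone and vice versa; that cross-modal path is
what replaces a missing modality at inference time.  For the downstream
predictor the fused **mean** of the subset matching exactly the observed
pattern is used (sampling noise would make the downstream input stochastic).

The representation loss per visit and subset is a Gaussian reconstruction
negative log-likelihood plus the KL of the fused posterior to N(0, I):

    Lf = Σ_t Σ_n [ Σ_observed-targets ‖x − x̂‖² / (2 σ_x²)
                   + KL(N(μ_fused, σ_fused) ‖ N(0, I)) ]

`σ_x` is the observation noise of the imaging likelihood (default 0.02,
matching the synthetic generator's voxel noise).  Making this scale
explicit matters: with an implicit unit variance the reconstruction gain
from encoding the disease signal is smaller than its KL cost and the
optimum of the objective is a collapsed posterior.  The KL uses the
standard closed form `½ Σ (μ² + σ² − 2 ln σ − 1)`; a variant reading
`½ Σ (μ² + σ − ln σ − 1)` is available behind `kl_form="as_printed"` for
fidelity experiments (both vanish at the prior).

## Imputation

The per-visit model input is the concatenation
`u_t = [μ_fused | tabular features | diagnosis one-hot]` with a matching
slot-level mask.  Missing entries are filled by the previous step's own
forecasts `û_t = [x̂_{t−1}, ŷ_{t−1}]` through the binary gate
`u = m ⊙ ũ + (1 − m) ⊙ û`; at the first visit, where no forecast exists,
training-split global means fill the gaps (zero for z-scored slots, class
frequencies for the diagnosis slots).  Because masks are binary, every
entry is exactly one of {observed value, forecast, global mean} — never a
blend.  The diagnosis component of `û` is the previous softmax probability
vector, which is differentiable and information-preserving.

## The recurrent cell

The cell extends an LSTM for irregular, partially observed sequences:

* **Hidden decay** — `γ_t = exp(−max(0, W_γ δ_t + b_γ))`, `ĥ_t = h_{t−1} ⊙ γ_t`:
  the longer an input has gone unobserved, the less the previous hidden
  state should count.
* **Mask-conditioned gates** — candidate, output and forget gates all take
  `W_u u_t + W_h ĥ_t + W_m m_t + b` through a sigmoid, so the cell knows
  which inputs are real and which are imputed.
* **Auxiliary-function forget gate** — the raw forget gate `f` is pushed
  toward 0 or 1 by

      g(f) = f − sin(fπ) cos(fπ) / β

  which is bounded on [0, 1], monotone iff β ≥ π, symmetric about 0.5
  (`g(f) + g(1−f) = 1`), fixes the endpoints, and satisfies
  `|g(f) − 0.5| ≥ |f − 0.5|` everywhere (sharpening).  β = π is the
  minimal admissible value and the default; it is an analytic constant,
  never trained.  The cell state is coupled:
  `c_t = g ⊙ c_{t−1} + (1 − g) ⊙ ĉ_t` with a sigmoid candidate, and
  `h_t = o ⊙ tanh(c_t)` with `h_0 = 0`.

Two baselines ship for ablations: a standard uncoupled LSTM (tanh
candidate, separate input gate, no masks or decay) and "LSTM-Mask" (the
cell above without the auxiliary function).  A forget-coupled variant of
the vanilla cell is also available.

## Prediction and objective

A residual head forecasts the next visit's features
(`x̂_{t+1} = W_g h_t + u_t`, so zero weights give a persistence forecast)
and a softmax head classifies the next diagnosis.  The objective is the
equal-weight sum `L = Lp + Li + Lf`: cross-entropy over visits with an
observed diagnosis, L1 forecast error over observed biomarker entries, and
the representation loss.  Adam with learning rate 0.002; batch size 32;
hidden size 128.

Training and evaluation share one protocol: all inputs after an anchor
visit (the "current" visit; `n_history` earlier visits are available) are
withheld and the model rolls forward autoregressively for K followup
visits, feeding its own forecasts back through the imputation gate.  The
diagnosis input at the anchor visit is hidden by default
(`diagnosis_mask_prob = 1`), so the model cannot simply copy the current
label.  Patients already diagnosed AD at baseline are always placed in the
training split — the method targets patients at earlier stages.

## Synthetic cohort

The generator emulates the structure of a merged longitudinal Alzheimer's
cohort so that every stage is testable without credentialed data access:

* up to six annual visits; diagnosis paths drawn with probabilities
  proportional to the real cohort's path counts (stable CN / stable MCI /
  AD / CN→MCI / MCI→AD / CN→AD ≈ 426 : 361 : 184 : 101 : 289 : 8), with
  transitions at uniformly random interior visits and no reversals;
* a per-patient nondecreasing scalar **atrophy state** shared by all
  modalities; baseline biomarkers are coupled to it (AD baselines have
  smaller regional volumes and larger ventricles) and scale with the
  patient's ICV, so ICV division removes nuisance variance as intended;
* per-stage monthly biomarker slopes — negative for every region except
  the ventricles, which grow;
* two toy 3-D modalities (default 16×20×16, an 8-fold per-axis reduction
  of a realistic 128×160×128 crop) rendered as distinct smooth blob
  layouts of the atrophy scalar plus voxel noise (σ = 0.02), clipped to
  [0, 1].  The blob supports are wide enough that the atrophy-explained
  variance dominates the noise floor, so cross-modal reconstruction is
  learnable by design;
* element-wise missingness at the real cohort's rates (MRI 45.8%, PET
  77.8%, diagnosis 31.0%, biomarkers 47.5–54.4%), MCAR, with the baseline
  diagnosis always kept and an optional whole-visit missingness mechanism.

What the generator does **not** emulate: real neuroanatomy or PET physics,
visit-structured (non-MCAR) missingness, measurement batch effects, and
any correlation between progression speed and baseline severity —
transition times are uniform random, which makes long-horizon labels
intrinsically harder to predict than in real data.  Passing tests on this
cohort demonstrate that the pipeline learns the signal it was built to
learn; they are not evidence about real-data performance.

## Numerical choices

* **Differentiation.** All models run on a small reverse-mode autodiff tape
  over numpy (float64), written for this package; the networks involved
  are small MLPs and a single recurrent cell, for which a dynamic tape
  over BLAS matmuls is fast enough on one CPU core.
* **Encoders/decoders** are two-layer MLPs on flattened volumes (tanh
  hidden layer of 256 units, latent dimension 16 by default, sigmoid
  output so reconstructions stay in (0, 1)).  At this resolution and
  cohort size a convolutional stack adds cost without accuracy: the
  rendering manifold is low-dimensional.  A 64-dim latent was measurably
  worse — it overfits the recurrent classifier at ~160 training patients.
* **VAE trainability.** Four initialization/annealing choices keep the
  printed objective trainable in 30 epochs: the encoder input is centered
  at the training-mean volume (otherwise the static background produces
  aligned gradient steps that saturate the tanh layer within one epoch);
  the decoder output bias starts at the logit of the mean volume; the σ
  head starts near 0.01 and the μ head uses a 10× wider init, so decoders
  see a usable latent signal-to-noise ratio from the first step; and the
  KL weight ramps linearly over training.
* **Scale matching.** The fused mean is standardized to unit per-dimension
  scale (running training statistics, stored in the checkpoint) before
  joining the z-scored tabular features, per the assembly contract that
  all components are normalized.
* **Cell initialization.** Forget-gate bias +1 (retain state early), decay
  weights zero (no decay until learned) — both standard.
* **Degenerate inputs.** Zero-variance normalization slots fall back to
  σ = 1; never-observed slots to mean 0/σ 1 with a warning; a fold whose
  evaluation labels miss a class drops that class from the macro average
  with a warning; an all-missing imaging batch contributes zero
  representation loss with a warning.

## Evaluation

Accuracy, macro one-vs-rest precision/recall, and macro one-vs-rest ROC
AUC (mAUC) over observed followup diagnoses; MAE (ml) and MRE (%) on
inverse-normalized biomarker forecasts; voxel-mean MSE and
PSNR = 10·log10(1/MSE) (peak 1) for cross-modal reconstruction, compared
against predicting the training-set mean volume.  Cross-validation is
patient-level, 5-fold by default, with fold statistics recomputed per fold.

The end-to-end demonstration trains 200 synthetic patients for 30 epochs
with one historical visit available at evaluation (`n_history = 1`, K = 4)
— the minimal history consistent with the cohort inclusion rule that every
patient has at least two diagnosed visits.  With no history at all the
synthetic baseline signal approaches the majority rate, because transition
times in the generator are pure chance; this is a limitation of the
synthetic design, not of the model.  Problem sizes throughout (cohort of
200, 16×20×16 volumes, 30 epochs, 20-epoch tabular ablations over three
seeds) were chosen so the full validation runs on a single CPU core in a
few minutes.

## Known limitations

* MCAR missingness is optimistic relative to the visit-structured
  missingness of real cohorts.
* The rollout feeds softmax probabilities (not sampled labels) back as
  inputs; predicted trajectories are therefore smooth and can lag sharp
  transitions.
* Equal task weights are the default; the loss components have very
  different scales, and dynamic weighting is an obvious extension point
  (weights are exposed in the configuration).
* The gate-ablation ordering (auxiliary-function cell above the vanilla
  LSTM) is reproduced on the tabular main protocol but is within seed noise
  when both cells are trained long enough on easier protocols.
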