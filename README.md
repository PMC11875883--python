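# lmdpnet

Longitudinal multimodal disease-progression prediction under modality
uncertainty: forecasting the clinical course of Alzheimer's disease
(CN → MCI → AD) over annual followup visits from records in which imaging
modalities, biomarker measurements, whole visits, and even the diagnosis
itself are arbitrarily missing.

It is aimed at researchers modelling longitudinal clinical cohorts
(ADNI-style merged tables plus MRI/PET volumes) who need a predictor that
degrades gracefully with missing data, and ships with a seeded synthetic
cohort generator so the entire pipeline is testable without credentialed
data access.

## The model

Three components are chained end to end:

1. **Product-of-experts imaging fusion.** Each modality *c* has a
   variational encoder emitting a diagonal Gaussian
   (μ<sup>(c)</sup>, σ<sup>(c)</sup>) over a shared latent space.  Any
   subset of observed modalities is fused by multiplying the expert
   densities: precisions add, T<sup>(c)</sup> = σ<sup>(c)−2</sup>,

   σ<sub>fused</sub> = (Σ<sub>obs</sub> T<sup>(c)</sup>)<sup>−1/2</sup>,
   μ<sub>fused</sub> = (Σ<sub>obs</sub> μ<sup>(c)</sup>T<sup>(c)</sup>)·σ<sub>fused</sub>².

   Samples from every fused subset are decoded by **every** modality
   decoder, so a missing PET can be reconstructed from MRI alone.

2. **Mask/decay-aware imputation and recurrence.** Per visit *t* the input
   u<sub>t</sub> = [μ<sub>fused</sub> | tabular | diagnosis one-hot] is
   gated elementwise by the observation mask m<sub>t</sub>:
   u = m⊙ũ + (1−m)⊙û, where û is the model's own forecast from the
   previous step (training-split global means at the first visit).  The
   recurrent cell decays the previous hidden state by
   γ<sub>t</sub> = exp(−max(0, W<sub>γ</sub>δ<sub>t</sub> + b<sub>γ</sub>)),
   where δ<sub>t</sub> is the per-element time since last observation, and
   feeds m<sub>t</sub> into every gate.

3. **An auxiliary-function forget gate.** The forget gate *f* is
   reformulated as

   g(f) = f − sin(fπ)cos(fπ)/β,  β = π,

   which pushes gate outputs toward 0 or 1 while staying bounded on [0, 1],
   monotone (exactly at the minimal admissible β = π), and symmetric about
   0.5.  The cell state is coupled: c<sub>t</sub> = g⊙c<sub>t−1</sub> +
   (1−g)⊙ĉ<sub>t</sub>.

Training minimizes the equal-weight sum of progression cross-entropy,
biomarker L1 forecast error, and the fusion ELBO (reconstruction +
KL-to-prior over all modality subsets), with Adam at learning rate 0.002.
See `docs/methods.md` for assumptions, parameter defaults, and numerical
choices.

## Worked example

Generate a tabular-only synthetic cohort, train with one historical visit,
and score held-out patients:

```python
from lmdpnet import synthetic_cohort as sc, train_eval as te

cfg = sc.CohortConfig(n_patients=120, render_images=False, seed=0)
cohort = sc.apply_missingness(sc.generate_cohort(cfg), cfg)
train, test = cohort[:96], cohort[96:]

tc = te.TrainConfig(epochs=20, use_imaging=False, n_history=1,
                    k_followup=4, seed=0)
model, log = te.train_model(train, tc)
print(log.tail(3).to_string(index=False))

scorable = [s for s in test if s.visits[0].diagnosis != "AD"]
report = te.evaluate(model, scorable)
```

This prints the tail of the loss trace and the held-out metrics:

```
 epoch       Lp       Li  Lf   Ltotal
    18 3.141051 4.606586 0.0 7.747637
    19 3.107803 4.565690 0.0 7.673493
    20 3.074149 4.557272 0.0 7.631421
     acc: 0.5082
precision: 0.4581
   recall: 0.4866
     mauc: 0.7050
   mae_ml: 5.5574
  mre_pct: 6.7495
 n_scored: 61
```

Reading the numbers: over four followup years the model classifies 51% of
the 61 observed followup diagnoses correctly, ranks the three classes with
a macro one-vs-rest AUC of 0.71, and forecasts regional brain volumes with
a mean absolute error of 5.6 ml (6.7% relative).  `Lf` is zero because this example uses no
imaging; with `render_images=True` and `use_imaging=True` the fusion ELBO
joins the objective and `evaluate_reconstruction` reports cross-modal
PSNR/MSE.

The same workflow is available from the shell:

```bash
lmdpnet simulate --n-patients 200 --seed 0 --out cohort/
lmdpnet train cohort/ --checkpoint model.npz --epochs 30
lmdpnet evaluate cohort/ --checkpoint model.npz --n-history 1 --k-followup 4
lmdpnet ablate cohort/ --design gate --seeds 0,1,2
```

Ablation designs: `gate` (vanilla LSTM / LSTM-Mask / auxiliary-function
cell at β = 2π and β = π), `history` (0–4 past visits), `diagnosis`
(current diagnosis hidden vs given), `modality` (MRI / PET / both),
`hidden` (64 / 128 / 256 hidden units).

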