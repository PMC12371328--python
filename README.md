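# phylodiff

Conditional diffusion-model imputation for time-series gut-microbiome
profiles, with phylum-aware convolutions and host-metadata conditioning.

Longitudinal stool-sampling studies (infant cohorts sampled at 0, 6, 12,
18, 24 months; clinical cohorts on monthly schedules) routinely lose
timepoints — a missed collection leaves a hole in every taxon's series at
once, and downstream analyses that expect complete profiles (trajectory
clustering, disease prediction from sequences) degrade or break.
`phylodiff` reconstructs the missing profiles. It is a library first
(importable API + `examples/`), with a thin `phylodiff` CLI for shell use.

## The model

Relative abundances are compositional; after a 0.01% detection filter
they are mapped with the centred log-ratio transform

    clr(x + δ) = ln(x + δ) − mean_k ln(x + δ),     δ = ½·min{x > 0},

with δ fitted on training folds only. Imputation uses a conditional
denoising diffusion model: the forward process corrupts hidden timepoints,
x_t = √ᾱ_t·x₀ + √(1−ᾱ_t)·ε, and a denoising network ε̂(x_t^ta, t | x₀^co)
is trained to predict the injected noise over the hidden entries,

    min_θ  E_{x₀,ε,t} ‖ ε − ε_θ(x_t^ta, t | x₀^co) ‖²₂ ,

conditioning on the subject's observed timepoints. Sampling the learned
reverse chain, with observed entries pinned, yields posterior draws of the
missing profiles; the point estimate is the per-entry median.

The denoiser respects microbiome structure: taxa are grouped into phylum
blocks and ordered so correlated taxa are adjacent (descending geometric
mean of within-block |Spearman ρ|), and each block gets its own 1-D
convolution at the input stage, followed by residual layers with
transformer encoders over the temporal and the feature axis. Categorical
host metadata (country, allergy status, …) can be embedded with a feature
tokenizer (token = b + one-hotᵀW ∈ R⁸) and concatenated either along the
feature axis (width K + n·d) or the channel axis (C + n·d channels).

The package also ships the surrounding study harness: MCAR and
diversity-informed MNAR mask construction, classical baselines (linear
interpolation on the age axis, LOCF, within-subject mean), subject-level
five-fold cross-validation reporting MAE = (1/K)·Σ|y − ŷ| per hidden
timepoint on the clr scale, a bootstrap cohort simulator (210/90 split
with measurement noise and zero-redistribution renormalisation), a
bidirectional-GRU outcome classifier scored by ROC/PR AUC, and a
synthetic-cohort generator used throughout the tests. The neural pieces
run on a small numpy autodiff engine included in the package
(`phylodiff.nn`); there is no GPU or framework dependency.

## Worked example

```python
import numpy as np
from phylodiff import (FixtureSpec, generate, clr_transform, order_features,
                       parse_taxonomy, mcar_mask, make_schedule,
                       DenoiserConfig, PhylumDenoiser, TrainConfig,
                       train, impute)

profile, metadata, labels = generate(FixtureSpec(S=24, L=5, K=24,
                                                 ar_rho=0.9, seed=5))
clr = clr_transform(profile)
phyla = [parse_taxonomy(l)[0] for l in profile.feature_labels]
obs = profile.observed.astype(bool)
ordering = order_features(clr.values[obs], phyla)
x = ordering.apply(clr.values)
```

`examples/02_train_and_impute.py` continues from here — standardizes,
trains 150 epochs, hides 30% of timepoints, and prints:

```
trained 150 epochs: loss 1.006 -> 0.249 (ε-prediction MSE over hidden entries)
diffusion imputer   MAE (clr scale): 0.312
linear              MAE (clr scale): 0.293
locf                MAE (clr scale): 0.323
mean                MAE (clr scale): 0.313
```

The loss falling from ≈1 (the variance of the standard-normal noise, i.e.
an uninformed predictor) to 0.25 shows the denoiser is learning; the MAEs
compare reconstruction error of the hidden timepoints across methods —
lower is better, and with strong temporal autocorrelation the methods
that exploit neighbouring timepoints (diffusion, linear) lead the
within-subject mean. Under the full cross-validated protocol
(`phylodiff.evaluation.run_sweep`, 500 epochs) the trained diffusion
imputer beats mean imputation in 5 of 5 folds (MAE 0.260 vs 0.276 at
r = 0.3, MCAR).

Other entry points: `examples/01_preprocess_and_order.py` (filter, clr,
phylum-block ordering), `examples/03_masking_mechanisms.py` (MCAR/MNAR),
`examples/04_downstream_prediction.py` (cohort simulation + BiRNN), and
the CLI (`phylodiff preprocess|mask|train|impute|evaluate|
simulate-downstream|predict|fixtures`).

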