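# Methods

`phylodiff` imputes missing timepoints in longitudinal gut-microbiome
relative-abundance profiles with a conditional denoising-diffusion model
whose denoiser is adapted to microbiome data in two ways: taxa are grouped
into phylum blocks and re-ordered so that correlated taxa are adjacent, and
the denoiser's input stage applies a separate 1-D convolution to each
phylum block. This note documents the model, the numerical choices, the
synthetic data the package is validated on, and the limits of what those
validations show.

## Data model and preprocessing

A cohort is a tensor of relative abundances `x ∈ [0,1]^{S×L×K}` (subjects ×
timepoints × taxa) with a subject-level observation mask over timepoints; a
0 in the mask is a stool sample that was never collected. Preprocessing:

1. **Detection filter.** Relative abundances strictly below 0.01%
   (`1e-4`) are set to exactly 0; values at the threshold are kept. The
   filter is idempotent.
2. **clr transform.** Compositions are mapped to
   `clr(x+δ) = ln(x+δ) − mean_k ln(x+δ)` with a single global pseudo-count
   δ equal to half the smallest strictly positive abundance **in the
   fitting set** (the training folds). One global δ keeps the train and
   test transforms identical and leaks no held-out information. All model
   training, imputation and error reporting happen on the clr scale;
   compositions are recovered with the softmax inverse only for
   diagnostics (Shannon diversity, zero proportion).
3. **Feature ordering.** Within each phylum, Spearman correlations are
   computed between all taxon pairs over the training subjects' observed
   timepoints, and each taxon is scored by the geometric mean of its
   absolute correlations with the other block members (the self term is
   excluded and the exponent is `1/(m−1)`; including the constant self
   term would only make the exponent ambiguous). Taxa sort by descending
   score within their block; ties keep input order. A taxon with zero rank
   variance is unrankable: it scores 0 and sorts to the block edge, and
   its undefined pairs are dropped from the other members' geometric means
   — counting them as zeros would collapse every score in the block to 0
   and destroy the ordering. Blocks are concatenated by descending size,
   ties alphabetical.

## Missingness

Masks operate on whole timepoints, matching the deployment scenario of a
missed sample collection.

- **MCAR**: each observed timepoint is hidden independently with
  probability `r`; a subject's draw is repeated until it has at least one
  hidden and one retained timepoint. The redraw makes the realized rate a
  truncated-binomial mean — at `L = 5` the bias is `+0.069` at `r = 0.3`,
  `0` at `r = 0.5` — which the tests check against the exact truncated
  expectation.
- **MNAR**: per subject, the `⌈r·L_obs⌉` observed timepoints with the
  highest Shannon diversity are hidden (capped at `L_obs − 1`),
  deterministically; diversity ties break toward the earlier timepoint.
  This is the simplest reading of selective missingness driven by high
  alpha diversity; sampling proportionally to diversity would be the
  main alternative.
- **Self-supervised split**: during training, each subject's observed
  timepoints are split afresh every iteration into conditional and target
  sets by an MCAR draw whose ratio is sampled uniformly from
  {0.1, …, 0.9} — the same grid the evaluation sweeps.

## Diffusion model

The forward process corrupts the clr profile at hidden timepoints with
Gaussian noise over `T` steps, `x_t = √ᾱ_t·x_0 + √(1−ᾱ_t)·ε`; the β
schedule is quadratic in √β from `1e-4` to `0.5` with `T = 50` by default
(`T = 25` in the desk-scale experiment profile; `ᾱ_T < 0.01` in both). The
denoiser `ε̂(x_t^ta, x^co, m^co, t)` is trained to predict the injected
noise with mean squared error **over target entries only**; conditional
timepoints enter clean, and only target entries are ever noised.

Architecture (all sizes configurable):

- **Input stage**: the conditional plane, the noisy target plane and the
  conditional-mask plane are stacked as channels of an `[L × K]` image.
  Each phylum block receives its own 1-D convolution along the feature
  axis (kernel 3, same padding, shared output width `C`); block outputs
  are concatenated back to width `K` and rectified. The mask plane lets
  the network distinguish a masked-out zero from a true zero.
- **Residual stack**: each layer adds a sinusoidal diffusion-step
  embedding (passed through a 2-layer MLP) and learned feature/timepoint
  positional embeddings, applies one single-layer transformer encoder
  over the temporal axis and one over the feature axis, then a gated
  `tanh ⊙ sigmoid` projection; a residual branch (scaled by 1/√2) feeds
  the next layer and a skip branch is accumulated. Positional content is
  re-injected at every layer so axis identity survives the mixing.
- **Output stage**: the skip sum (scaled by 1/√n_layers) is projected to
  one channel.
- **Metadata**: categorical host covariates are embedded with a feature
  tokenizer — per variable, token `= b + one-hot(value)ᵀ W ∈ R^d`, `d = 8`
  — and injected either as `n·d` extra pseudo-feature columns
  ("spatial", internal width `K + n·d`) or as `n·d` constant channels
  ("channel", `C + n·d` channels). Level 0 of every vocabulary is
  reserved for values unseen at fit time. Metadata are static per subject
  and broadcast over time; they condition both training and imputation
  but are never part of the error metric.

Training uses Adam (lr `1e-3`, step decay ×0.1 at 75% and ×0.01 at 90% of
epochs, batch 16 by default; the cross-validation profile uses batch 8,
500 epochs) and is fully seeded. The model trains on per-feature
standardized clr values (mean/SD fitted on training rows): the ε-objective
assumes data of roughly unit scale, and clr features span very different
ranges (rare taxa sit near `ln δ`). Predictions are de-standardized before
scoring, so all reported MAEs are in clr units.

Imputation samples the conditional reverse chain: target entries start
from standard normal noise and are denoised over `T` steps with the
standard posterior variance `σ_t² = β_t(1−ᾱ_{t−1})/(1−ᾱ_t)` (`σ_1 = 0`),
while conditional entries are held fixed throughout and copied bitwise
into every draw. The point estimate is the per-entry median over draws
(50 by default, 25 in the experiment profile), a robust summary of the
sampled posterior. All draws run through the denoiser as one batch.

## Evaluation harness

Five-fold cross-validation splits **subjects**, never samples, so no
timepoint of a held-out subject influences the pseudo-count, feature
ordering, standardization or model weights (asserted by a test that
perturbs held-out data and checks the fitted state is unchanged).
Per cell of the grid (missingness structure × ratio × method), the error
of an imputed timepoint is the mean absolute error over its K taxa on the
clr scale; errors average over hidden timepoints within subject, subjects
within fold, and mean (SD) across folds is reported. The intra-fold
averaging order (timepoints → subjects → folds) is a convention choice;
alternatives reweight subjects with many hidden timepoints.

Baselines run per subject and per taxon on the same clr tensors: linear
interpolation and the edge fallbacks operate on the **age axis** (actual
timepoint values), which matters on non-uniform schedules; LOCF back-fills
leading gaps; mean imputation uses the within-subject mean (the
cross-subject mean at a timepoint is the natural alternative but answers
a different question — it ignores the subject's own baseline).

## Downstream predictive task

To test whether imputation preserves host-status signal, a labelled cohort
is simulated from complete profiles: subjects split 7:3 into disjoint
pools, 210/90 samples bootstrapped within pool, and per sample Gaussian
noise added to every abundance (mean drawn once per sample uniformly from
(1e-4, 2e-4), SD 1e-4), clipped at zero, renormalised onto the simplex,
and passed through the detection floor with the removed mass redistributed
equally over the surviving taxa (so rows still sum to 1 exactly and exact
zeros stay exact). A bidirectional GRU (hidden 64 by default) reads the
clr sequence in both directions; the concatenated final states feed one
dense sigmoid unit trained with binary cross-entropy. Performance is
ROC-AUC (pairwise concordance, ties ½) and PR-AUC (trapezoidal).
The degradation experiment hides test timepoints at `r = 0.5` and fills
them with a registered imputer (linear interpolation in the shipped
experiments) before scoring.

## Synthetic cohorts

The generator draws, per subject, a latent Gaussian field with AR(1)
dependence across time (coefficient `ar_rho`) and equicorrelation
(`block_corr`) within phylum blocks, adds per-taxon baselines, a subject
random intercept (SD 0.6), and metadata-linked shifts to designated taxa,
then maps through a softmax to the simplex and applies the same 0.01%
floor + redistribution as preprocessing. The logistic-normal construction
was chosen over a Dirichlet because it controls temporal and block
correlation independently on the latent scale. Sparsity is induced by
marking a `sparsity_target` fraction of taxa as rare (baseline shifted by
−7 on the log scale) so they usually fall below the floor.

What the fixtures emulate: compositionality, temporal dependence, phylum
correlation, zero inflation, inter-individual variation, metadata effects.
What they do not: realistic marginal abundance distributions, taxonomic
co-occurrence networks, sequencing depth artefacts, or age trends shared
across subjects. Passing the tests therefore demonstrates that the
machinery is correct and that the model extracts temporal structure when
it exists — not that it matches any particular real cohort's error rates.

Realized generator moments recover the configured parameters; note that lag-1
autocorrelation must be estimated from the latent field (exposed via
`generate(..., return_latents=True)`): with only 5 timepoints per series,
the per-series centred estimator is biased by approximately `−(1+3ρ)/L`
and would under-report ρ = 0.9 as ≈ 0.15.

## Problem sizes in the shipped experiments

The test suite and the reproduction script run deliberately small
configurations chosen as the smallest sizes at which the qualitative
claims are stable: cohorts of 20–40 subjects × 5 timepoints × 24 taxa in
3 phylum blocks, a denoiser with 32–48 channels and 2 residual layers,
`T = 25`, 50–500 epochs, 25 posterior draws, and 5-fold subject
cross-validation at `r = 0.3`. The full-size defaults (`C = 64`, 4 layers,
`T = 50`, 200 epochs, 50 draws) remain available through the
configuration objects.

## Known limitations

- The reverse sampler inherits DDPM discretisation error; at desk scale
  the learned imputer beats within-subject mean imputation consistently
  but does not yet overtake linear interpolation on strongly
  autocorrelated synthetic cohorts.
- Continuous covariates are not tokenized; metadata must be categorical.
- Whole-timepoint masks only; taxon-level (cell-wise) missingness is out
  of scope.
- The engine is CPU-only numpy; wall-clock scales roughly linearly in
  `S·L·K·C²` per epoch.
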