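# Methods

## Problem setting

Morphological cardiac aging is difficult to observe directly: longitudinal
imaging with decade-scale gaps barely exists, and repeated visits differ in
slice position. `cardiosynth` implements the alternative: learn a
*covariate-conditioned* generative model from cross-sectional data (one scan
per subject, subjects of different ages) that can shift a given scan toward
an older or younger apparent age, and evaluate whether the synthetic shifts
carry the morphology the covariate actually controls.

Because population cardiac MR is access-restricted, the package ships a
phantom cohort generator in which the covariate → morphology mapping is
known exactly. Every downstream claim is then checkable against ground
truth instead of visual impression.

## Generative model

The generator `G` is a U-Net of residual blocks (two per level at the
reference scale, channel multipliers 1,2,2,4, single-head spatial
self-attention at the two coarsest resolutions, group normalization with 8
groups). It does not output an image: it outputs a residual **mapping**
`m ∈ [−1,1]^{H×W}` — the maximal modification allowed — and the synthetic
image is

    x̃ = clip(x + m, 0, 1),          m = tanh(raw network output).

A smooth tanh bound was chosen over a hard clip for the mapping so
gradients keep flowing at saturation; the output clip is hard, with
pass-through gradients inside the interval.

The critic `D` mirrors the generator's encoder and ends in adaptive average
pooling plus a linear head, one scalar score per image.

**Conditioning.** A scalar covariate is embedded with the Transformer
sinusoidal embedding `e[2i] = sin(v/C^{2i/d})`, `e[2i+1] = cos(v/C^{2i/d})`
(`C = 10 000`, `d = 32` at reference scale), passed through a small shared
MLP, and injected into **every** residual block by *conditional biasing*:
a per-block linear head maps the embedding to one scalar per feature
channel, added to the feature map immediately **before** the block's second
group normalization. The generator is conditioned on the **gap**
`a_d = a_t − a_s`; the critic on the covariate of the image it is scoring
(true value for real images, target value for synthetic ones). The
covariate enters in natural units (years, kg/m², phase index); a
`covariate_scale` switch exists but defaults to 1.

## Objectives

Critic (minimized):

    L_D = E[D(x̃, a_t)] − E[D(x, a)] + λ_GP · E[(‖∇_x̂ D(x̂, a_t)‖₂ − 1)²]

with `x̂ = ε·x + (1−ε)·x̃`, `ε ~ U(0,1)` drawn independently per batch
element, and the gradient norm taken flat over all pixels of a sample.
Generator (minimized):

    L_G = −E[D(x̃, a_t)] + λ_cc · E[‖x − G(G(x, a_d), −a_d)‖₁]

λ_GP = 10, λ_cc = 1. The alternating minimization is the standard reading
of the single min–max objective. The cycle term attaches to the generator
update only; the critic's real term uses an independently drawn real batch
presented with its own true covariates.

Training uses AdamW (lr 10⁻⁴, weight decay 10⁻⁴, β = (0.9, 0.999)) for both
networks, batch size 12, 300 epochs at reference scale, with a warm-up
schedule: 50 critic updates per generator update for the first 20 epochs,
5 afterwards (the Wasserstein estimate needs a near-optimal critic).
Augmentation — multiplicative low-order polynomial bias field, monotone
histogram remap, gamma contrast, each with probability 0.5 — is applied to
both the critic's real batch and the generator's source batch, before the
generator. Raw images are center-cropped by 90 columns (odd counts remove
the extra column on the right), bilinearly resized to 128², and min–max
rescaled to [0,1]; constant images map to zeros to avoid 0/0.

Covariate gaps during training are drawn uniformly on ±25 years, resampled
so the target stays inside the cohort's age range (the sampling law for
target covariates is a free design choice; uniform-truncated is the least
informative option and is configurable).

## Autodiff backend

No deep-learning framework is assumed: the networks run on a small numpy
reverse-mode autodiff (`cardiosynth.nn`) whose backward rules are
themselves composed of differentiable primitives. That makes gradients
graph nodes that can be differentiated again — required for the gradient
penalty, whose *parameter* gradient is a derivative of the critic's *input*
gradient. Convolution is im2col (`unfold`/`fold` as a linear adjoint
pair); group normalization is fused with a closed-form backward whose
statistics are rebuilt in-graph so second-order derivatives stay exact.
First- and second-order gradients are verified against finite differences
in the test suite (relative error ≲ 10⁻⁹ in float64).

## Phantom cohort

Each phantom is a four-chamber-like arrangement of anti-aliased disks
(LV cavity, myocardial annulus, RV, two atria, aorta; labels 1–6) on a dark
background, rendered back-to-front (aorta last) at 128² reference scale and
scaled linearly to other sizes; intensities lie in [0,1] with Gaussian
pixel noise (default sd 0.01) added to the image only, never the mask.
The covariate law is linear with per-subject Gaussian jitter:

* septum width `s(age) = 4 + 0.10·(age−45)` px (increases),
* LV cavity radius `r(age) = 22 − 0.15·(age−45)` px (decreases),
* aortic radius `ρ(age) = 6 + 0.12·(age−45)` px (increases),
* BMI widens a peripheral fat band (`0.2 px` per unit above 18),
* the ES phase shrinks both ventricular cavities (×0.72) and thickens the
  myocardium (×1.35).

Slopes were set so a 20-year gap moves each structure by ≈2–4 rendered
pixels at 128² — large enough to be learnable, small enough to stay
heart-like. The linear-plus-jitter law is the simplest one enabling exact
parameter-recovery tests. Ages follow either a uniform law or a truncated
normal (mean 64.1, sd 7.7, range 45–82). Sex is carried as metadata (an
optional global scale factor exists, off by default — the generative model
itself is not sex-conditioned).

For small-image experiments `toy_phantom_config` steepens the slopes
(0.20/0.18/0.16 px·yr⁻¹ at the reference parameterization, LV intercept
raised to 26 px) because the aging signal of interest is *pixel-scale*
morphology change: naively scaling the reference law to 32² would leave
sub-pixel, unlearnable effects.

What the phantom does **not** emulate: MR physics (coil bias fields,
k-space artifacts — the augmentation model only mimics their low-frequency
appearance), anatomical shape variability beyond disks, pathology, 3-D
structure, valve anatomy. Passing tests therefore demonstrate that the
*method* recovers a known covariate→morphology law from cross-sectional
data at desk scale; they are not evidence about real cardiac MR.

## Evaluation protocol

* **Predicted-covariate MAE.** A small residual CNN regressor is trained on
  the cohort; for each gap `g`, every test image is synthesized at
  `a_t = a_s + g` and scored by `|regressor(x̃) − a_t|`. The **zero-order
  baseline** scores the *unmodified* image against the moving target, so a
  perfect regressor yields exactly `|g|` — the error a do-nothing model
  incurs. On noiseless, jitter-free phantoms the regressor reaches held-out
  MAE < 2 years (age is geometrically decodable), making the baseline
  comparison meaningful.
* **FID.** Features come from the penultimate (pooled) layer of a small CNN
  classifier trained on cohort age quartiles — the scale-appropriate
  counterpart of a dataset-specific deep feature extractor; FID values are
  therefore comparable only within one extractor. The Frechet distance uses
  the symmetric product `Σ_a^{1/2} Σ_b Σ_a^{1/2}` eigendecomposition;
  eigenvalues below −10⁻⁸ (relative) raise, small negatives clamp to 0.
  Ledoit–Wolf shrinkage kicks in when a feature cloud has fewer samples
  than dimensions.
* **PSNR** with peak 1.0 (images live in [0,1]); identical images report a
  +∞ sentinel.
* **Volumetrics.** LV area = LV-label pixel count; septum width = mean of
  the three narrowest pure-myocardium scanline gaps between the LV and RV
  cavities (the gap is minimal on the line through the cavity centers;
  row and column scans tolerate the jittered rotation); EF =
  (ED−ES)/ED on areas. Normalized variation is reported against the
  **population mean** of the original distribution (a per-subject variant
  exists as an option).
* **Rule-based segmentation** recovers phantom labels from intensities:
  core pixels within 0.04 of a tissue's nominal intensity, a geometric
  prior demoting myocardium-intensity components not adjacent to the LV
  (the sub-pixel fat band blends through the same intensity), and
  ambiguous pixels split between their two *locally present* tissues at
  the intensity midpoint, which reproduces the renderer's half-coverage
  boundary. Agreement with ground-truth masks is ≥98% at the 128²
  reference scale; at 32–64² the half-pixel boundary quantization
  (∝ perimeter/area) dominates and agreement sits a few points lower.

## Debiasing experiment

From a pool of phantoms, an imbalanced training set is built (default:
n = 1000 with 90% younger than 70). A trained generator synthesizes
aged versions of randomly chosen majority-side subjects with target ages
uniform over the minority interval (1/5/10/25% of n), labeled with their
*target* age and flagged synthetic. A fresh regressor is trained per
variant and scored on a fixed, age-balanced held-out set (200 subjects,
carved out before any training or synthetic-source role; identity overlap
is structurally impossible). Percentages are fractions of n_total; results
are reported mean ± sd over 5 seeds by default.

## Desk-scale study sizes

CPU-scale runs (tests and the acceptance script) use 32² phantoms, cohorts
of 500–1400, a width-8 two-level network, batch 8, and ~10 epochs with a
shortened warm-up (10:1 then 3:1 critic schedule, configurable) — chosen as
the smallest sizes at which the pipeline's qualitative behavior (cycle-loss
decrease, directional morphology shifts, debiasing trend) is measurable.
The reference-scale configuration (128², width 32, 50:1 warm-up, 300
epochs) is the package default for real training runs.

## Known limitations

* At desk scale the adversarial game runs for only a few hundred critic
  steps; the generator's covariate response is measurable but far from the
  asymptotic regime, and quantities derived from it (per-gap MAE, FID,
  monotonicity coefficients) carry correspondingly large run-to-run spread.
* FID magnitudes are extractor-specific and not comparable across
  extractors or to published values.
* The phantom's linear geometry law makes parameter recovery well-posed by
  construction; real anatomies offer no such guarantee.
* The critic conditions on a scalar covariate only; confounders (e.g. sex)
  are carried but not controlled.
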