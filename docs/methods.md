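# Methods

This note records the modelling choices behind `autoqc`, the parameters
that matter, what the synthetic benchmark does and does not emulate, and
the numerical conventions, in enough detail to reimplement the package.

## Reconstruction-based QC

All five model families share one contract: `reconstruct(x)` maps an
image to a same-shape image in the canonical `[0, 1]` intensity frame,
deterministically (stochastic encoders decode the posterior mean;
diffusion models use a seeded noise draw).  The anomaly score map is the
per-pixel reconstruction error `Λ = |x − x̂|` (a squared-error variant
is available; the train- and test-time losses need not coincide).
Models trained only on normal images reconstruct normal content well and
"normalise" abnormal content, so Λ concentrates on defects.

Canonical pixel range is `[0, 1]` for every public interface.  Integer
images are scaled by their dtype maximum (255 / 65535) so absolute
intensity survives; float images have no defined range and are min-max
scaled per image — a documented caveat, since it discards absolute
intensity and turns a uniformly dark frame into a full-range one.
Multi-channel input collapses to grayscale by channel mean.

## Image-level decision and localization

- Aggregators: `max(Λ)`, `mean(Λ)`, and `patch_max` — the maximum over
  sliding-window patch means (window 16 px, stride 8 by default; the
  final row/column of windows is edge-aligned so every pixel is covered).
  `max` is sensitive to single-pixel outliers, `mean` dilutes small
  defects; `patch_max` is the default because it matches the typical
  spatial scale of localized defects.
- Alarm threshold `AS*`: exhaustive scan over candidate thresholds
  (midpoints of consecutive sorted unique validation scores plus one
  candidate beyond each extreme) maximising accuracy of
  "abnormal iff AS > AS*".  Accuracy only changes at data points, so
  this scan is exact, not a heuristic.  Ties resolve to the smallest
  threshold (favouring sensitivity).
- Binarization threshold `λ*`: grid search over 200 evenly spaced
  quantiles of the pooled validation score values, maximising mean Dice
  over validation abnormal samples; ties resolve to the largest λ
  (favouring specificity).  Dice uses the 0/0 → 1 convention (an empty
  prediction against an empty ground truth is a perfect match).
- Both decision rules use strict `>`, so a score exactly at threshold
  does not alarm, and `λ* = max(Λ)` yields an empty mask.
- Masks are emitted only for alarmed frames (two-stage workflow); the
  curation mode skips thresholds entirely and returns a descending
  ranking by AS with lexicographic tie-breaks.
- A consequence of giving whole-frame defects all-ones masks: when they
  make up a sizeable share of the validation abnormals, Dice
  maximisation drives λ* toward the bottom of the score range (an
  all-ones prediction scores Dice 1.0 on them and still partially
  overlaps localized masks).  Localization quality is therefore best
  read from the threshold-free AUPRC; λ* fitted on localized defects
  only gives tighter masks.

## Models

Architectures are deliberately small (configurable `base_width`,
`n_levels`); channel widths double per level, capped at 8x.  One seed
controls weight initialisation, batch order and corruption noise, so
equal seed + config reproduces equal weights bit-for-bit.

- **AE** — conv encoder to a `d`-dim code, conv decoder with a sigmoid
  output.  Training inputs are corrupted by additive Gaussian noise
  (σ = 0.1 by default; 0 recovers plain autoencoding) while the target
  stays clean.  Loss: mean per-image p-norm of the residual, p = 1 by
  default for robustness to cell-texture detail.
- **VAE** — the encoder trunk feeds two linear heads (μ, log σ²); the
  KL divergence to N(0, I) is the closed diagonal-Gaussian form,
  weighted by `kl_weight` (default 1.0, the plain sum of the two loss
  terms).  Training samples `z` by reparameterisation; inference decodes
  μ so score maps are deterministic.
- **f-AnoGAN** — WGAN-GP (critic without normalisation layers,
  leaky-ReLU 0.2, 5 critic steps per generator step, gradient-penalty
  weight 10) followed by encoder training with G and D frozen under the
  izi_f loss with feature weight κ = 1; the feature space `f(·)` is the
  critic's penultimate (flattened final conv) activation.  The gradient
  penalty needs the derivative of the critic's *input gradient* with
  respect to the weights; the input gradient is built as an explicit
  composition of differentiable primitives (adjoint convs with flipped,
  channel-swapped kernels; scaled upsampling as the pooling adjoint;
  activation-derivative masks as constants, exact a.e. for
  piecewise-linear activations), so first-order backprop suffices.
- **DDPM** — a U-Net `f(x_t, t)` with sinusoidal time embeddings
  injected additively per level, trained on
  `E ||x₀ − f(x_t, t)||²` with `t ~ U{1..T}` — i.e. the denoiser
  predicts the clean image directly rather than the noise, which is
  what reconstruction QC needs.  Reconstruction corrupts the input to
  `t_test` once and applies a single network evaluation (no ancestral
  chain); full T-step generation from pure noise is deliberately out of
  scope.  U-Net activations are leaky-ReLU (slope 0.1): at these widths
  plain ReLU reproducibly collapsed into dead units that ignore the
  image input entirely.
- **pDDPM** — same network and loss, but per training sample one random
  patch is noised (clean context everywhere else) and the loss applies
  only on the patch.  Inference slides a patch grid (size 16, stride 8
  at desk scale; defaults are half the image side with half-overlap),
  noises one patch per network call, keeps the patch region of the
  output and averages overlaps per pixel.  Unweighted averaging is the
  simplest merge that maps a constant denoiser output to a constant
  image and is invariant to patch visit order.

Internally the diffusion models work in `[−1, 1]` (affine from the
canonical frame) and map back before scoring.

## Noise schedule

Linear β schedule.  Full-scale default: T = 1000, β from 1e-4 to 0.02.
The desk-scale profile compresses to T = 100 with β from 1e-3 to 0.2,
chosen so the terminal cumulative signal ᾱ_T is comparable to the
full-length schedule; `t_test` defaults to T/2.  The desk profile uses
`t_test = 15` (ᾱ ≈ 0.80): enough corruption that the denoiser must rely
on its learned prior, little enough that normal content is recoverable
at small model capacity.

## Synthetic benchmark

`generate_normal` renders sparse, non-overlapping dark elliptical cells
(smooth cosine edge profiles, random orientation) on a bright background
with additive Gaussian pixel noise — emulating brightfield imagery of
migrating immune cells.  A polarity flag inverts the scene for
fluorescence-like data.  Defaults: 64×64 px, 8 cells of radius 3–6 px,
background 0.75, cell contrast 0.35, noise σ 0.02.

Injected defects, with severity `s ∈ (0, 1]` scaling their strength:

| kind | model | mask |
|---|---|---|
| air_bubble | dark Gaussian ring + brightened interior disc | bubble disc |
| artifact | 1–3 dark high-contrast blobs/short streaks | blob support |
| z_shift | Gaussian blur, σ = 0.5 + 3.5·s px | whole frame |
| illumination | gain 1 + s, or additive linear gradient ±0.6·s | whole frame |
| contamination | 1–3 soft bright Gaussian spots, amplitude 0.6·s | spot support |

Localized defects modify pixels only inside their mask (the complement
is bit-identical), mean absolute change inside the mask is monotone in
severity, and everything is reproducible from the spec seed.  Whole-frame
defects get all-ones masks because defocus and global illumination have
no localisable boundary.  The benchmark generator writes train 32 /
positive 16 / negative 2-per-kind splits at desk scale with negative
severities drawn uniformly from [0.5, 1.0], plus a labelled validation
split (8 normals, 1 abnormal per kind) for threshold fitting.

What the generator does **not** emulate: physically accurate optics (no
PSF, no refraction ray-tracing), cell motion or time-lapse structure,
camera noise models beyond additive Gaussian, real annotator
imprecision in masks.  Passing tests therefore demonstrate that the
workflow recovers *these* defect classes under controlled conditions,
not field performance on any particular instrument.

## Desk-scale study and expected behaviour

The bundled reproduction (`scripts/acceptance.py`, also exercised by the
end-to-end tests) trains pDDPM (600 epochs, base width 8, 2 levels) and
an AE baseline (300 epochs, latent 64) on the 32 synthetic normals and
evaluates both with `patch_max` aggregation.  Problem sizes were chosen
as the smallest at which the method ranking is stable.  On this
benchmark pDDPM separates degraded from normal frames with AUC above
0.9 at the documented study seed, localises with mean Dice about 0.5,
and beats the AE baseline.  Illumination and bubble defects separate by
a wide margin; mild defocus is the hardest class, since blurring
*lowers* reconstruction error and the signal is only the gap to an even
lower expected error for sharp normals.  With 26 test frames, AUC moves
by roughly a tenth across benchmark seeds; the bounds asserted in the
test suite hold at the fixed study seed.

## Numerical conventions and degenerate inputs

- All network arithmetic in float32; score maps and metrics in float64.
- Masks are strictly binary {0, 1}; files use 0/255 semantics.
- `accuracy` rejects an all-zero count vector; AUROC requires both
  classes; AUPRC requires at least one positive pixel.  AUPRC is the
  step-wise (interpolation-free) area, pooled over all abnormal-sample
  pixels by default (a per-image mode exists); linear interpolation
  between PR points would inflate it.
- Degenerate generator inputs fail loudly: impossible cell packing,
  geometry outside the frame, zero-dynamic-range float images,
  severity 0.
- Non-finite training losses raise a divergence error rather than
  silently continuing.

## Known limitations

- Defocus (Z-shift) detection is weak at desk scale; at realistic
  training scale the normal-reconstruction error floor drops and the
  contrast improves, but a blur-specific heuristic (e.g. spectral
  sharpness) would be the practical complement.
- The numpy NN stack is single-threaded BLAS-bound; it is sized for
  64–128 px frames, not megapixel microscopy, for which the library
  design (contract + checkpoint format) would wrap a GPU framework.
- Thresholds are global per dataset; per-batch or per-plate drift is
  not modelled.
- The VAE at `kl_weight = 1.0` produces visibly smoothed
  reconstructions at these capacities; lower the weight for sharper
  reconstructions if the VAE baseline matters.
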