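# Methods

`pavision` is an end-to-end, self-contained pipeline for studying — and
learning to correct — the *visibility problem* of linear-array
photoacoustic (PA) imaging: the joint effect of the limited angular view
of a linear transducer and its resonant, band-limited impulse response.
Everything below is computed by the package itself; no external data is
required.

## Forward model

A 2D absorption map `X` (non-negative, max-normalized) is treated as a
set of instantaneous point sources.  Element `e` of the array receives
from a source at position `r`

    y_e(t) = a · D(θ) / √|r − r_e| · h(t − |r − r_e| / c),

with `c = 1500 m/s`, a soft cosine element directivity `D(θ) = cos θ`
(clipped at 90°), 2D cylindrical-spreading decay `1/√r`, and `h` the
transducer impulse response.  The whole-object RF matrix `Y` is the sum
over all nonzero pixels, so the acquisition is exactly linear in `X` and
the propagation matrix `A` (one column per grid pixel) reproduces
`simulate_rf` to machine precision — a property the tests assert.

**Impulse response.** `h` is a Gabor pulse: a sine carrier at the probe's
central frequency (15.6 MHz, an L22-8v-class array) under a Gaussian
envelope whose width is set by the −6 dB fractional bandwidth (default
0.6), truncated at ±4σ.  The sine (odd) phase makes the sampled pulse
exactly zero-mean on a symmetric grid: the missing DC is the cause of the
limited-bandwidth artefact (hollow interiors of large absorbers), and the
resonant band is what modulates the mBF image axially.  A measured
response would differ in detail but not in either mechanism.

**Sampling rule.** The destructive interference that hides elongated
structures only emerges if neighbouring sources are closer than half the
acoustic wavelength (λ ≈ 96 µm at 15.6 MHz).  All shipped configurations
use a 40 µm pixel pitch; `simulate_rf(..., supersample=k)` subdivides
coarser rasters.  With this respected, a thin vertical bar's dmBF energy
falls below 2% of the horizontal bar's under the default linear aperture,
and returns to exactly 1× under a virtual full-ring aperture — tying the
artefact to the geometry rather than to the implementation.

**Noise.** Additive white Gaussian RF noise is calibrated in *amplitude
SNR relative to a horizontal reference structure*: the peak RF of a thin
horizontal bar at mid-depth divided by the noise standard deviation.  The
default target of 60 reflects the hardware-like regime in which the
structures of interest (steep vessels) still have nearly no signal.

## Reconstruction

* **mBF** — delay-and-sum directly on the real-valued RF (`t = r/c`
  delays, linear interpolation in time, out-of-window samples contribute
  zero, no apodization, no f-number).  Signed and oscillatory; the
  network input.
* **dmBF** — modulus of DAS applied to the analytic (Hilbert-transformed)
  signals; the conventional envelope display and the DAS baseline in all
  comparisons.  Since both use the same linear interpolation, the
  envelope dominates the modulated image pixel-wise, which is asserted
  exactly.
* **L2 deconvolution** — `argmin ½‖Y−AX‖² + α/2‖X‖²` via FISTA with step
  `1/L` (power iteration on `AᵀA + αI`, 50 iterations) and relative-change
  stopping at 1e−6.  This is ridge regression, so a dense closed form
  `(AᵀA+αI)⁻¹AᵀY` serves as the exact oracle at test scale.  α defaults
  to 1.0 for the desk-scale system; `tune_alpha` maximizes sSSIM against
  a known target, the automated analogue of tuning by visual comparison.

## Phantom generator

Leaf-skeleton-like objects are drawn as recursive binary trees of
quadratic Bézier segments: per level the length shrinks (×0.6–0.75), the
half-width tapers (×0.78), and branch angles split ±28° with uniform
jitter (default ±25°).  Segments are rasterized anti-aliased (soft
1-pixel edge, running maximum).  The *first* primary branch is steered
within ~8° of the depth axis so every phantom contains structures inside
the blind cone of the linear aperture; remaining primaries are uniformly
oriented.  Under the default 1×1 cm configuration the foreground occupies
2–25% of the field across seeds (asserted over 50 seeds), and a
structure-tensor orientation histogram confirms near-vertical segments.

The generator is a stand-in for the ink-stained leaf photographs used as
experimental ground truth in the laboratory setting this package models:
it reproduces branching topology, orientation statistics and width
tapering, but not 3D projection effects, ink inhomogeneity, or manual
cutting artefacts.  Passing tests therefore demonstrate the method's
behaviour under a controlled, known ground truth — not performance on
photographs of physical samples.

## Paired datasets

Each pair is built by: drawing a phantom on the full field (default
1 cm², placed 2 mm below the probe face), thresholding the background at
0.05 and max-normalizing, simulating RF from the *whole* field, then
beamforming only the central patch (default 5.12 mm → 128 px at 40 µm;
desk scale 2.56 mm → 64 px).  Structures outside the patch therefore
still pollute the reconstruction, as in a real acquisition.  Inputs are
mBF images normalized by their maximum absolute value; targets are the
matching ground-truth patches in [0, 1].  Per-pair seeds are spawned from
the dataset seed and stored, making every pair individually reproducible;
HDF5 files carry `/train|/val|/test` groups with `input`/`target` arrays
plus pitch, seeds and a probe-config hash.

## Network and training

The corrector is a U-Net (encoder–decoder with skip concatenations):
two 3×3 conv + batch-norm + ReLU layers per scale block, dropout after
every block, 2×2 max pooling down, 2×2 transposed-convolution up, and a
single-filter 1×1 linear output (no final activation — the output is a
real-valued image, not a segmentation).  The full-scale preset (4 levels,
base 64 filters, 128×128 inputs) counts 31,042,369 trainable parameters.
Training minimizes MSE with Adam at learning rate 5e−4, first-moment
decay β₁ = 0.8 (the configuration's stated momentum, read as a fraction),
batches of 8, and early stopping on the validation loss with the
best-validation weights restored.

Because no deep-learning framework fits this package's footprint, the
layers, backward passes and optimizer are implemented in `pavision.nn` on
numpy with im2col-lowered convolutions in channels-last layout; all
gradients are validated against finite differences in double precision.
Training is seed-reproducible; the only caveat is that multithreaded
BLAS may reorder reductions, so bit-level reproducibility holds per
process configuration.  Repeated-inference statistics are computed from a
single batched forward pass, which keeps identical inputs bit-identical
and makes the zero-variance case exact.

**Desk-scale presets.** The `reduced` preset (4 levels, base 16, 64×64)
and `tiny` preset (3 levels, base 8, 32×32) make CPU-only training
practical.  Desk-scale runs raise the learning rate to 2e−3 and lower the
dropout rate to 0.2: with an order of magnitude fewer filters and only a
few hundred gradient steps, 50% dropout removes too much capacity to
converge, while the full-scale preset keeps the reference 0.5.  These are
architecture-scale adaptations fixed ahead of the evaluation runs, and
the same settings are used for every arm of every comparison.

## Uncertainty

MC dropout: the trained network is made stochastic by keeping dropout
active at inference (batch norm stays in inference mode); 20 forward
passes with seeded masks give a pixel-wise predictive mean and standard
deviation.  The acquisition-noise analogue repeats noisy simulations of
one object, beamforms and predicts each deterministically, and reports
the spread.  Calibration is quantified on foreground pixels (union of
truth and prediction supports, dilated 2 px — background clutter would
otherwise dominate rank statistics) by (i) the Spearman correlation
between the std map and the absolute-error map and (ii) the ratio of
mean std inside the top error decile to the bottom decile; the
co-location claim is operationalized as decile ratio > 2.

## Metrics

* **NCC**: local-sum-normalized 2D cross-correlation (template-matching
  normalization).  The correlation *map* is scalarized as its maximum
  when the prediction's interior (cropped by 3 px) slides over the truth
  within a ±3 px window, so sub-pixel registration residue is not
  penalized; window 0 reduces to zero-lag Pearson.  Affine intensity maps
  of either argument leave the score invariant.
* **sSSIM**: least-squares fit of scale and shift (`a·pred + b ≈ truth`)
  followed by SSIM with a Gaussian 11×11 window (σ = 1.5) and the truth's
  dynamic range.  Equals 1 iff the prediction is an exact affine rendering
  of the truth.
* **Registration**: similarity transform (rotation, translation,
  isotropic scale) maximizing Pearson correlation; coarse rotation×scale
  grid with FFT translation estimation, refined by Nelder–Mead.
  Recovers known transforms to 0.5 px / 0.5° / 1% scale in tests.

Undefined cases (constant images, zero-variance predictions) raise;
`evaluate_set` records such pairs as failures instead of dropping them.

## Experiments

**Simulation benchmark** (`run_simulation_benchmark`): seeded dataset,
network training, and paired evaluation of the network versus the dmBF
baseline on held-out test pairs — the desk-scale analogue of the
simulation-column comparison, at 64×64 with 150/15/15 pairs and ≤40
epochs of the reduced preset.

**Transfer learning** (`run_learning_curve`): the "experimental" domain
is emulated by a controlled shift — +5% central frequency, +10%
bandwidth, RF noise at SNR 60, and sound speed 1480 m/s in simulation
versus 1500 m/s assumed by the beamformer — so the network pretrained on
the nominal noiseless domain must adapt to a systematically mismatched
one, the mechanism to which the simulation-to-experiment gap is
attributed.  For each training-set size, repeats draw disjoint random
subsets of a fixed pool; both arms (scratch vs pretrained + fine-tuned)
share seeds, budgets and a common held-out test set.

**Input comparison** (`compare_inputs`): twin models trained on mBF
versus dmBF representations of identical acquisitions under identical
seeds, testing that the phase-bearing modulated image carries more
exploitable information than the envelope.

## Problem sizes and numerical choices

Desk-scale runs use a 64-element, 0.1 mm pitch aperture, 384 time samples
at 62.5 MHz, 64×64 patches at 40 µm, 150-pair training sets and ≤40
epochs (reduced preset), and 32×32 / 3-level nets for the learning-curve
sweeps; these sizes were chosen so that the full suite runs on a single
CPU while every qualitative effect (artefact formation, learnability,
transfer benefit, uncertainty co-location) remains measurable.
Degenerate inputs are rejected early (sub-16-px grids, sources behind the
probe, constant images); distances are clamped at 50 µm to keep on-element
sources finite; out-of-window delays contribute zero rather than clamping
to the window edge, avoiding edge streaks.

## Known limitations

* The forward model is 2D and homogeneous: no fluence model, no
  heterogeneous sound speed, no full-wave diffraction; artefact
  mechanisms, not waveform detail, are the modelling target.
* The impulse response and directivity are analytic conventions; a real
  probe's measured response would change quantitative scores.
* The synthetic domain shift is milder and better controlled than a true
  simulation-to-experiment gap; transfer-learning results demonstrate the
  direction of the effect, not its magnitude on laboratory data.
* MC-dropout uncertainty flags unstable (invented or poorly constrained)
  structures; it cannot flag structures that are missing because the data
  contain no trace of them.
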