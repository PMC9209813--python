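# Methods

`patkit` simulates fast (sparse-view) circular-scan photoacoustic tomography
(PAT) acquisitions, reconstructs them by delay-and-sum (DAS) beamforming,
and trains a hybrid dense-dilated U-Net (HD-UNet) to restore slow-scan image
quality from fast scans. This note records the model assumptions, the
tunable parameters, and the design choices made where the design was
genuinely open.

## Acoustic forward model

For a homogeneous, lossless, non-dispersive medium (speed of sound
c = 1500 m/s), the pressure recorded by an ideal point detector at position
r_d from an initial pressure distribution p0 is taken as

    p(r_d, t)  ∝  d/dt [ t · M(p0)(r_d, c t) ],

with M the circular-mean operator: the mean of p0 over the circle of radius
ct centred on r_d. Because t·M is, up to constants, the line integral of p0
over that circle, the simulator reduces to binning each nonzero pixel's mass
into time-of-flight bins (linear interpolation between adjacent 40 ns bins)
and differentiating along time. This is the exact 2D analogue of the
spherical-mean forward relation used throughout PAT; it shares its physics
with pseudospectral wave solvers for homogeneous media while remaining
linear, fast and free of numerical dispersion. It does not model acoustic
heterogeneity, attenuation, 3D (out-of-plane) propagation, or the 2D wake
(the slowly decaying tail of the 2D Green's function) — the last of these is
deliberately neglected, as DAS reconstruction only exploits wavefront
arrival times.

**Band-limited detection.** Non-ideal transducers convolve each A-line with
a zero-phase Gaussian-modulated sinusoid whose amplitude spectrum peaks at
the centre frequency (2.25 MHz for the single-transducer system, 5 MHz for
the eight-transducer system) with a −6 dB fractional bandwidth of 70%,
normalized to unit peak spectral magnitude. Ideal (ground-truth) detectors
use a delta kernel.

**Finite aperture.** The 13 mm flat active element is modelled as a segment
tangent to the scan circle, partitioned into 9 sub-element segments; each
pixel's mass is spread uniformly over the time-of-flight span of each
sub-segment (with 4-fold internal refinement, making the flat-element
integral second-order accurate: doubling the sub-element count changes the
sinogram by < 1% rms). This reproduces the tangential-resolution loss that
grows with radial offset.

**Noise.** Additive white Gaussian noise at an rms-defined SNR,
20·log10(rms_signal/rms_noise), over the whole sinogram: 40 dB for the
single-transducer presets, drawn uniformly from 10–20 dB for the
eight-transducer presets. The rms convention is stated explicitly because
several simulation toolboxes differ here.

**Geometry.** Detector positions lie on a circle of radius 37 mm (a
declared default: the 40 mm imaging disc plus clearance, inside the
82 mm computational grid). A scan of duration T at pulse repetition rate
PRR yields round(T·PRR/averaging) positions, spread uniformly; with eight
transducers the circle is divided into eight 45° sectors swept in parallel.
The eight-transducer system fires 2000 pulses/s but the presets retain
positions at an averaging factor of 2.5, reproducing the published counts
(0.3 s → 240 positions, 30 per transducer; 1.5 s → 1200; ground truth
1600). The recording window is 1500 samples of 40 ns, t = 0 at laser
firing, which covers the 77 mm maximum time-of-flight path with margin.

## Phantoms

Three families populate the 40 mm imaging disc on the 82×82 mm grid
(0.2 mm/pixel for the 1-UST presets, 0.1 mm for 8-UST):

* **Point targets** — discs of 0.5 mm diameter (the calibre of the pencil
  leads used for physical validation of such systems) at random
  non-overlapping positions, strengths uniform in [0.5, 1]. Five per
  phantom for training; a nine-point layout serves as a held-out test
  shape. Placement uses rejection sampling with a 1000-attempt cap.
* **Triangles** — thin (1-pixel) equilateral outlines, the numerical
  analogue of a horsehair phantom, with random centre, rotation and side
  length (8–24 mm), fully inside the disc; filled variants behind a flag.
* **Vessels** — emulating the cerebral venous sinuses of a rodent brain:
  one smooth trunk (a quadratic Bezier crossing the disc) plus 2–6 lateral
  branches at random angles, each rendered with a Gaussian cross-section
  (FWHM 0.3–1.0 mm, support truncated ~2σ off the ridge) and independent
  magnitude in [0.5, 1]. No published generator exists for these shapes;
  the parameter ranges were fixed once to match the published morphology
  and give 0.5–10% fill of the imaging disc.

Generators are pure functions of (grid, parameters, seed).

## Reconstruction and training pairs

DAS: I(x) = Σ_d s_d(|x − r_d|/c), with linear interpolation between time
samples, no apodization, evaluated on a fixed 128×128 grid covering the
40 mm field of view (0.3125 mm pitch). Delays outside the recorded window
contribute zero. A compiled (numba) loop and a vectorized NumPy path
implement identical arithmetic; tests pin them to each other and to a
brute-force double loop at 1e−9 relative.

Images are bipolar; they are normalized affinely to [0, 1],
(A − Amin)/(Amax − Amin), which preserves the bipolar structure as an
offset rather than clipping it.

A training pair consists of X = normalized DAS of a short noisy
finite-aperture scan (1–5 s, i.e. 10–50 positions, for the 1-UST preset;
0.3 s / 240 positions for 8-UST) and Ygt = normalized DAS of the dense
noise-free ideal-point-detector scan (4800 / 1600 positions). The ground
truth is itself a DAS reconstruction, not the raw phantom.

## Networks

All four variants share a 4-level U-shaped skeleton (three stride-2
down/up transitions; 16×16 bottleneck for 128×128 inputs). Every
convolution block is convolution → batch normalization → ReLU. At level l
the feature target is fl = 2^(l−1)·fi and the dense growth rate
kl = 2^(l−1)·8; each dense block runs fi/8 growth steps, every step
consuming the concatenation of the block input and all previous step
outputs.

* **HD-UNet**: encoder steps split kl into equal halves at dilation 1 and
  dilation 2 (capped at 2 to limit gridding artifacts); decoder steps are
  all dilation 1; a residual bridge (two 3×3 blocks at the bottleneck's
  feature-target width f4, with a 1×1-projected shortcut) closes the
  bottleneck.
* **FD-UNet**: standard dense blocks both paths, no bridge.
* **2D-DD-UNet**: each step learns the full kl at dilation 1 *and* at
  dilation 2 in both paths — the parameter-hungry design whose cost the
  hybrid split avoids (the built dd network has ~20% more parameters than
  hd at fi = 32).
* **U-Net**: plain double-convolution blocks.

Open details fixed here: fi defaults to 32 (16 in desk-scale tests); skip
connections are concatenations and carry the level's fl-channel block
input, which makes the decoder accounting exact (transposed conv → fl,
concat → 2·fl, 1×1 entry → fl, steps → 2·fl); the head is a 3×3 block then
a 3×3 convolution to one channel with ReLU and no batch norm, keeping
outputs in the [0, 1] target range; weights use fan-in (He) normal
initialization from a seeded generator.

The layer engine (convolution, transposed convolution, batch
normalization, with explicit backward passes, and Adam) is implemented on
NumPy arrays in `patkit.nn`; forward/backward passes are verified against
naive loop oracles and finite differences.

## Objective and metrics

L = k1·L_MAE + k2·L_FMAE with k1 = 1, k2 = 0.001. L_MAE is the mean
absolute pixel difference; L_FMAE is the mean over frequency bins of the
complex modulus of the difference of unnormalized 2D DFTs (the
unnormalized-forward-transform convention is pinned down by the test that a
constant image difference c yields FMAE exactly c). The FMAE term
penalizes the directional streak spectrum of sparse-view artifacts; its
small weight keeps the pixel term primary.

Evaluation: per-image pixelwise Pearson correlation (constant images are
excluded from the mean with a warning), SSIM (uniform 7-pixel window,
default stabilization constants, data range 1), PSNR (data range 1, capped
at 100 dB for identical images — a declared convention, since the reference
tables do not state theirs), and MAE, reported mean ± std.

## Training protocol

Adam, initial learning rate 1e−3, batch size 2, a fixed number of epochs
(100 at full scale; no early stopping), halving the learning rate after 5
epochs without validation-loss improvement (patience is a declared default;
floor 1e−6). Corpus split 90:5:5 into train/validation/test. Model
comparison uses repeated random resplitting (10 repeats at full scale):
fresh split and fresh networks per repeat, evaluation on that repeat's test
split, per-image metrics pooled across repeats. Splits, shuffling,
initialization and noise are all seeded; training is deterministic for a
fixed seed.

## Problem sizes

The full-scale corpus is 1500 pairs (1-UST) or 500 (8-UST) with fi = 32
networks — a long offline computation exposed as
`full_scale_protocol()` / `patkit pipeline --scale full`. The package's
default experiments use a desk-scale protocol chosen as the smallest
configuration that exhibits the method's qualitative behaviour: 100 pairs,
fi = 16, 10 epochs, batch 2. Under it the trained HD-UNet raises held-out
SSIM from ≈0.31 to ≈0.61 and PSNR from ≈19.9 to ≈23.7 dB over the raw
sparse inputs (seeded run; exact values are recomputed by the test suite).

## What the synthetic data does and does not show

The generator reproduces the published study conditions: grid geometry,
detector counts and bandwidths, SNRs, dataset sizes and splits. It does
not reproduce k-Wave's full-wave propagation (heterogeneity, attenuation,
numerical dispersion, 2D wake), optical fluence variation, or experimental
electronics noise beyond additive white Gaussian noise. Passing tests
therefore demonstrate the pipeline's internal correctness and the
restoration network's learning behaviour under the declared forward model —
not parity with in vivo image quality. The published full-scale
cross-validated metrics (e.g. HD-UNet PSNR ≈ 35 dB on the 1-UST corpus)
require the full-scale protocol and are expected to be approached only
approximately under this analytical forward substitute.

One behavioural property of the substitute model is worth recording: the
global SSIM between normalized sparse inputs and the dense ideal-detector
ground truth is *not* monotone in detector count over the very sparse
10–50 range. Averaged over 60 phantoms the means are ≈0.355, 0.348,
0.316, 0.365, 0.384 for 10–50 positions: a systematic dip at 30 positions
(strongest for triangle phantoms, whose three-fold symmetry resonates with
30 uniformly spaced detectors) and a mild advantage for the emptiest
10-position images, whose large flat background locally matches the ground
truth's flat background. Each added detector first contributes fresh arc
clutter; arcs only begin to cancel beyond ~100 positions, after which SSIM
climbs steeply (≈0.77 at 300, ≈0.83 at 1000+). The effect persists with
noise-free ideal-detector inputs and with a band-limited ground-truth
detector, so it is a property of delay-and-sum plus a global SSIM in this
regime, not of the noise model or bandwidth mismatch.

## Numerical choices

* float32 network arithmetic (BLAS sgemm); float64 losses and metrics.
* DAS and the forward projector default to the compiled backend; the
  vectorized NumPy path is retained and cross-checked.
* Normalization rejects constant images; SNR insertion rejects all-zero
  signals; scan planning rejects sub-single-pulse windows.
* Tie-breaks: argmax conventions follow NumPy (first maximum); the plateau
  scheduler counts non-improvement epochs strictly (equal loss is not an
  improvement).
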