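# Methods

This note records the models, parameter choices and numerical decisions
behind `ecgpaper`, and what its synthetic benchmarks do and do not show.

## Synthetic ECG generator

`ecg_source.synthesize_ecg` builds each lead as a sum of five Gaussian
kernels per beat (P, Q, R, S, T), with per-lead amplitude vectors chosen to
follow textbook 12-lead morphology (dominant R laterally, rS pattern in
V1–V2 with R-wave progression across the precordium, globally negative aVR).
Wave centers sit at −0.20, −0.035, 0, +0.035 and +0.28 s relative to the R
peak, with widths 45/12/22/16/70 ms at 60 bpm; both scale mildly with the RR
interval so fast rates compress the ST segment. Beat onsets follow an RR
process with 2% Gaussian jitter (coefficient of variation ≪ 0.2), clipped to
±50% of the mean RR. All randomness flows from a single integer seed through
one `numpy` generator per call.

This generator is a stand-in for real recordings: it produces identifiable
P-QRS-T morphology, realistic amplitudes (≤ ~1.3 mV peaks) and a stable
baseline, which is what the rendering/digitization loop needs. It does *not*
model pathology, beat-to-beat morphology variability, respiratory amplitude
modulation, or inter-lead timing physiology, so passing round trips certify
the imaging pipeline, not clinical realism of the waveforms.

Physiological noise (`add_physiological_noise`) mixes baseline wander (sum
of 0.05–0.45 Hz sinusoids), amplitude-modulated mains interference, 20–100 Hz
band-passed "muscle" noise and white noise, then scales the mixture so the
pooled whole-record SNR (all leads, all samples) equals the target exactly.
Pooling per record rather than per lead was an open choice; per-record
matches how the evaluation metrics are pooled.

## Paper rendering

Geometry: origin top-left, x = column = time, y = row; amplitude increases
upward (smaller row index). At *D* DPI the fine grid pitch is D/25.4 px and
line positions accumulate in floating point with per-line subpixel coverage,
so the mean pitch is exact even when D/25.4 is not an integer. Defaults
follow the standard format: 25 mm/s, 10 mm/mV, 3×4 segment layout filled
column-major plus one lead-II rhythm strip, 2.5 s segments, an 11×8.5 in
landscape canvas (1700×2200 px at 200 DPI), and a 1 mV × 0.2 s calibration
pulse at each row start. Asynchronous mode offsets row *r* segments by
*r*·segment_len, mimicking swept single-channel machines.

Traces are drawn crisp rather than anti-aliased: the per-column sample pixel
carries the pure trace color, and vertical jumps between adjacent columns
are filled with a lighter connector tone (70% toward the background). This
keeps the trace 8-connected for component analysis while guaranteeing that
the darkest pixel of each column is the true sample — which is what makes
the ground-truth polylines exact oracles for the extractor. Ground truth per
segment is `row = baseline − round(sample·px_per_mV)` for every column.

## Degradations

- **Creases** are line families at a configurable inclination whose offsets
  are the n-quantiles of the page's perpendicular extent ("spaced
  linearly"); the darkening field is convolved with a normalized Gaussian
  kernel G(x,y) = exp(−(x²+y²)/2σ²)/(2πσ²) evaluated on the integer grid.
  Displacing the kernel center produces the asymmetric shadow of obliquely
  lit folds.
- **Wrinkles** are synthesized by image quilting: random patches of a seed
  texture placed raster-scan with overlap, joined along the dynamic-
  programming minimum-error-boundary cut on e = (B_ov1 − B_ov2)², with
  out-of-range predecessors treated as +∞ and ties broken to the leftmost
  predecessor (determinism). Corner overlaps intersect the vertical and
  horizontal cut masks. Patch 48 px and overlap 8 px (patch/6) are the
  classic texture-synthesis choices. The bundled seed texture is synthetic
  (band-limited noise with directional streaks) so the artifact ships as
  text-only source; any grayscale wrinkle photograph can be substituted.
  The wrinkle blend with the page is multiplicative in luminance,
  `out = img · (1 − α + α·tex/mean(tex))` — the blend mode was an open
  choice; multiplicative matches how uneven illumination acts on print.
- **Viewpoint** changes use the full 3×3 homogeneous matrix; images are
  inverse-warped with bilinear sampling, polylines mapped by the forward
  matrix with division by w′. The affine special case (g = h = 0, i = 1)
  preserves parallelism.
- **Pixel noise** follows the stated per-pixel models: additive N(0, η),
  additive Poisson(λ) (one draw per pixel, not scaled shot noise), both
  clipped to [0, 255], and salt-and-pepper that sets all three channels of a
  pixel jointly to 0 or 255 with probability p/2 each. Salt-and-pepper is
  applied last in the default stack so its extremes survive color
  operations. Color temperature scales channels by a blackbody white-point
  approximation normalized at 6600 K (exact identity there; orange below,
  blue above, with mean(R)−mean(B) monotone in K).

Every operation is seeded and logged in the image's append-only provenance
list, so a degraded page can be replayed exactly.

## Rectification

Rotation is estimated from the Radon transform of the ink image
(255 − luminance, mean-removed): the skew angle maximizes the variance over
ρ of the projection profile, the standard document-skew criterion (the
sinogram "reveals" the angle but no formula is fixed by the source method;
this criterion is our design decision). The search covers ±45° at 0.25°,
refined once at 0.05°, on a page downscaled to ≤512 px along its long side —
at that scale the estimate is still well inside ±0.5° for skews up to ±15°.
Derotation rotates about the image center with bilinear sampling and maps
ground truth with the matching matrix (convention verified against rendered
ink). Only pure rotation is compensated; shear and perspective are not
inverted.

## Cleanup

**Inpainting** is a fast-marching scheme: masked pixels are processed in
increasing distance-map order (eikonal update from known neighbors) and
filled with the distance-weighted first-order estimate
Iq(p) = I(q) + ∇I(q)·(p − q) over known pixels within a 3-px radius,
gradients switching to one-sided differences at unknown neighbors. The
first-order term makes the fill exact on linear intensity fields up to
discretization; the operation is idempotent on its own output. In synthetic
mode the text mask is the union of overlay ink masks dilated by 2 px; a
pluggable detector returning bounding boxes fills the same role for real
scans.

**Grid removal** has two routes:

- *Residual denoiser*: each RGB channel is split into 30×30 patches with
  5-px overlap (stride 25; the final row/column of tiles is re-anchored
  flush with the edge so coverage is complete), scaled to [0, 1], passed
  through a DnCNN-style network that predicts the grid component
  v = y − x, subtracted, and re-stitched with exponential distance weights
  exp(−d/τ), τ = 5 px (the overlap width; the cited stitching method's
  constant is not fixed anywhere authoritative). The full architecture is
  17 layers (Conv+ReLU; 15× Conv+BatchNorm+ReLU; single-filter Conv) with
  64 filters of 7×7, trained on the loss
  ℓ(Θ) = 1/(2N) Σ‖R(y_i;Θ) − (y_i − x_i)‖²_F with Adam (lr 10⁻³, batch 128),
  early stopping, ≤30 epochs. The network and its training loop are
  implemented in NumPy (im2col convolutions, manual backprop); the output
  convolution is zero-initialized so the residual branch starts at the
  exact identity and departs only where the data demands — this markedly
  improves both grid-energy removal and near-identity behavior on clean
  patches at desk scale.
- *Classical*: pixels whose color matches the red grid hue
  (R exceeding G and B by a margin, above a brightness floor) are
  suppressed and filled with the page-background estimate (median of
  non-grid pixels). Fast-marching inpainting of the removed pixels is
  available (`fill="inpaint"`) but the flat fill is the default: on a full
  page the grid covers a double-digit percentage of pixels and the pure-
  Python inpainter would dominate runtime for no measurable accuracy gain
  on synthetic pages.

**Desk-scale preset.** The test suite trains on 2000 toy patches for ≤5
epochs. At that data scale the full 17×64×7² network cannot be trained
meaningfully on a CPU within a test run, so the desk preset uses the same
layer pattern at depth 5 with 8 filters of 5×5, batch 8, lr 10⁻²; the full
spec remains the default for real training. Toy pairs hold a random-walk
trace on white plus a periodic line grid at the 200-DPI fine pitch with
random phase (composited like ink: the grid vanishes where the trace is
already dark); 20% of pairs carry no grid, anchoring the residual at zero on
grid-free content.

## Extraction

Strips are found from the row-mean intensity profile Ī(x) smoothed by an
L = 11 moving average (edges handled by replicating boundary values, an
open choice). Significant minima are those below (max+min)/2, merged when
closer than 5 mm; strip boundaries sit at the smoothed maxima between
consecutive minima.

Binarization thresholds each pixel against its 3×3 local mean minus an
offset (default 10). Component analysis uses 4-connectivity; components
under the height/width/area thresholds are dropped and nearby fragments are
fused iteratively when their outer boundaries approach within `fuse_dist`
pixels (nearest boundary-pixel distance on outer pixels only — the
criterion that actually re-joins gap-separated trace fragments). Module
defaults at 200 DPI are min_h = min_w = 3 px, min_area = 10 px,
fuse_dist = 10 px, tuned on synthetic fixtures; the round-trip driver
relaxes the minimums to 1/1/2 because its rendered traces are exactly one
pixel thick, and skips fusion since it consumes the union mask.

The trace is extracted per column from the mask blurred with a 1×3 mean
filter: among the column's own foreground pixels, the one with the lowest
blurred intensity wins (ties → smallest row), so fragments continuous with
their neighbors are preferred; restricting candidates to the column's
foreground — ranked by true grayscale, where available — is what lets the
sample pixel beat its lighter connector neighbors. Columns with no
foreground are flagged missing and linearly interpolated.

Calibration: the coarse grid pitch is the fine-pitch autocorrelation peak
(row- and column-mean ink profiles, parabolic sub-pixel refinement) scaled
by 5, then refined by climbing to ever higher-order harmonic peaks — the
i-th peak localizes the period i times more precisely, which matters because
a 0.3% pitch error becomes a 9-sample time-axis drift over a 10 s strip.
Amplitude conversion is (baseline − ŷ)·0.5/coarse_px with the baseline per
segment taken as the mode of the extracted rows (flat segments dominate).
The sampling rate is D/1.016 when the DPI is trusted, else coarse_px/0.2 at
standard paper speed. Estimates are resampled to the reference rate and
aligned at the integer lag maximizing cross-correlation within ±0.5 s.

For multi-lead rows the driver uses ground-truth time windows to split a row
into its four lead segments (synthetic mode); equal-width quartering is the
fallback without ground truth.

## Evaluation

SNR and SNR_med are computed per record over all aligned samples (leads
concatenated); an exact match (zero noise power denominator) is reported as
a flagged 200 dB sentinel. Cohort summaries give the 2.5th/97.5th
percentiles (linear interpolation) and mean ± std over the values strictly
inside that range. R peaks are local maxima above an adaptive threshold
with a 200 ms refractory period; RR error is the mean |ΔRR| in ms over
order-matched consecutive intervals. QRS/QT interval comparison accepts any
pluggable delineator; only R-peak/RR measurement is built in.

## Benchmark sizes and what they show

The bundled acceptance suite runs at desk scale: 20 seeded pages for skew
recovery, 20 seeded records for the clean round trip (SNR ≥ 20 dB per
record, RR error ≤ 10 ms — our bar for *distortionless* pages; published
full-pipeline figures on heavily distorted external data are necessarily
lower), 100 random surfaces for the seam-cut oracle, 50 masks for the
component oracle, and the 2000-patch/5-epoch denoiser run. These sizes were
chosen so the whole suite completes in a few minutes on one CPU while still
exercising every stage; they certify correctness of the implementation, not
performance on real scanned archives.

## Known limitations

- The handwriting overlay is a parametric warp of one base font (seven
  style presets), not a learned handwriting model; it provides determinism
  and ink masks, not visual realism.
- Text removal in real-scan mode depends on an external detector; only the
  interface and ground-truth-mask path are provided.
- Only rotation is rectified; uninverted shear/perspective degrade
  extraction accuracy accordingly.
- The classical grid-removal route assumes a reddish grid distinguishable
  from the (dark) trace by hue.
- WFDB support covers single-segment format-16 records, the common case for
  this workflow.
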