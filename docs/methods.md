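# Methods

This note documents the models, parameters and numerical choices behind
`memfoci`, and what the synthetic-data validation does and does not
demonstrate about real microscopy data.

## Imaging model

Movies are simulated on the acquisition geometry of the motivating
experiments: 64-nm pixels, 100-ms frame interval, 200 frames (20 s)
unless configured otherwise. Each focus is rendered as an isotropic 2-D
Gaussian of σ = 0.13 µm (a diffraction-limited GFP PSF), with peak
amplitude `A·exp(−k_b·t)` for a photobleaching rate k_b = 0.02 s⁻¹
(so a 20-s movie bleaches to e^−0.4 ≈ 67 %). Pixel values are
`Poisson(background + signal) + N(0, σ_read)`, clipped at zero and
stored as 16-bit counts; defaults are 100 photons background and
σ_read = 2. Focus amplitudes default to 1000 photons at the peak with a
lognormal focus-to-focus brightness spread (σ_log = 0.2), reflecting
variable copy number per assembly. The bright-field channel renders the
cell footprints ~30 % darker than their background with mild blur, which
is what the threshold-based segmentation consumes.

Coordinates: x runs along image columns, y along rows, in micrometres;
the centre of pixel (r, c) is at ((c+0.5)·px, (r+0.5)·px).

## Motion models

All motion is simulated in the 2-D TIRF plane; membrane curvature is
ignored because every downstream measurement is a 2-D projection.

* **directed** — straight path at speed v with a random fixed heading
  (plus a Brownian component if D > 0; the class default is D = 0).
* **random** — 2-D Brownian motion, per-axis step variance 2·D·Δt.
* **confined** — Brownian motion reflected inside a disc of radius
  R = 0.15 µm centred on the start position, for a dwell time drawn from
  a gamma(2, 0.8 s) distribution (mean 1.6 s, median ≈ 1.34 s), then
  free Brownian motion. Reflected dynamics are integrated with sub-frame
  steps (step SD ≤ R/3): with whole-frame steps the discrete reflected
  walk's stationary distribution is interior-biased and the MSD plateau
  lands at ~0.85·R² instead of the continuum value R² (the uniform-disc
  pair-distance identity E|r₁−r₂|² = R²).
* **blended** — two-state switching between the random and directed
  modes at 1 s⁻¹, with a fresh heading on each directed entry. This is
  the generator's stand-in for motion that defeats single-model MSD
  classification.

Within cells, every step is additionally reflected at the rod boundary
(a capsule: rectangle with semicircular caps, default 4.0 × 0.9 µm;
the width is a typical *B. subtilis* rod diameter, the length matches
the ~4-µm cells of the motivating data).

Focus turnover is a stationary birth–death process per cell: the initial
count is Poisson(density × area) and new foci arrive at rate
density × area / τ with exponential lifetimes τ = 2 s ("short-lived"
foci; the value is the package's choice, as no lifetime is printed for
the system). The time-averaged focus count per µm² therefore equals the
scenario density.

## Scenario presets

| preset | density (µm⁻²) | mixture conf/rand/dir/blend | D (µm²/s) | v (µm/s) | intensity |
|--------|----------------|------------------------------|-----------|----------|-----------|
| wt     | 0.3            | 60/12/13/15                  | 0.02      | 0.40     | ×1.00     |
| rif    | 0.8            | 40/17/13/30                  | 0.03      | 0.48     | ×1.22     |
| mutant | 1.2            | 60/12/13/15                  | 0.02      | 0.40     | ×1.75     |

The printed study values fix the densities, the constrained fractions,
the kinetic parameters and the intensity multipliers; the split of the
non-constrained remainder between directed and random (only their sum is
printed) is a package choice.

## Detection and tracking

The LoG scale is σ = d/(2√2) with d = 0.3 µm, the convention that makes
the filter respond maximally to a Gaussian blob of diameter d. The
quality threshold is calibrated per movie as median + k·1.4826·MAD of
the scale-normalised response with k = 5: a robust noise-floor estimate,
deliberately insensitive to how many spots the movie contains, so paired
sparse/crowded conditions are detected with equal sensitivity (an
absolute camera-count threshold would not transfer between detectors).
Tied 2×2 response plateaus (a spot centred on a pixel corner) are merged
into a single detection before quadratic sub-pixel refinement (offsets
clipped to ±0.5 px). On rendered wild-type movies this detector localises
to ~3 nm median error with ≥ 97 % per-frame recall.

Linking maximises the number of links within the 0.3-µm radius and,
among those, minimises the total squared displacement (Jonker–Volgenant
assignment with a dominating sentinel cost for forbidden pairs); ties
are broken deterministically by detection order. There is no gap
closing: a missed detection terminates the track, exactly as with a
simple LAP tracker configured with zero gaps. The ≥ 10-frame duration
filter is inclusive.

Per-cell bookkeeping assigns a track to the ROI holding the majority of
its detections. Point-in-ROI tests use the mask dilated by one pixel:
localisation is sub-pixel while masks are pixelated, and strict pixel
membership systematically drops membrane-edge foci (~4 % of positions on
rendered data).

## MSD classification

The time-averaged MSD uses overlapping windows at all lags 1…N−1. Model
fits use only the first min(10, N−1) lags: long lags of a single-track
MSD carry large, serially correlated fluctuations that add noise, not
information. All three models carry a constant offset c absorbing the
static localisation-noise floor (4σ² for isotropic noise of SD σ).

Selection is by AIC over the fitted window with three safeguards, all
calibrated on simulated trajectories at the preset conditions and frozen
before any acceptance measurement:

1. *Plateau identifiability* — the constrained model nests the linear
   one (P → ∞ gives MSD → 4D_c·t), so it is eligible only when its
   fitted corner time P/(4D_c) lies inside the lag window; otherwise the
   fit is exercising its linear limit, not detecting a plateau.
2. *Akaike-weight margin* — the winner needs weight ≥ 0.45, else the
   curve is ambiguous and the track is left unclassified.
3. *Absolute goodness* — the median squared residual of the winner,
   normalised by the Qian-type standard error of an overlapping-window
   time-averaged MSD point (relative variance (2n²+1)/(3n(N−n+1)) at lag
   n), must be ≤ 0.15. A median (not a mean) is used because a pure
   Brownian track's correlated MSD wobble throws occasional large
   single-lag residuals, while model-family misfit (blended motion) is
   systematic across lags. This criterion replaces a naive r² floor,
   which would penalise exactly the near-flat plateau curves of strongly
   confined tracks (tiny total variance makes r² meaningless there).

Constrained foci in this system escape after their dwell, so a genuine
constrained track often shows a plateau-then-upturn MSD that no single
model fits. A first-exit override captures the class's defining
behaviour ("confined at the same position before measurable movement"):
a track whose displacement stays within r_conf = 0.15 µm of the centroid
of its first five positions for at least max(0.9 s, 30 % of its
duration) — capped at 1.6 s, the class's mean dwell, which is decisive
evidence on its own — is labelled constrained regardless of model
selection. The centroid reference matters because a track that is a
mid-dwell fragment of a confined focus starts anywhere in the domain;
measured from an off-centre first point, exits of up to 2R would be
seen. The 0.9-s floor is the duration of a minimum-length ten-frame
track.

Kinetic parameters: v comes from the directed fit over the classification
window; D is re-extracted from a linear fit to the first four lags only
(the short-window optimum — with ten fitted lags the per-track *median*
D̂ runs ~15 % low from skewed long-lag noise even though the mean is
unbiased). The reported confinement time is the first exit from
r_conf = 0.15 µm around the literal first position, censored at the
track end; censored values are excluded from medians and reported
separately.

On noise-free 200-frame single-class simulations (n = 500 per class)
this classifier is ≥ 95 % correct for random, directed and non-escaping
confined motion, and sends the majority of blended tracks to
unclassified. On fully rendered wild-type movies it recovers the
generated 60 % constrained fraction within a few points.

## Quantification and statistics

Focus density is (in-ROI detections / frames) / area per cell; focus
intensity is the per-track mean of 3×3-pixel window means (raw counts,
background included); motion fractions attribute each track's class to
every frame it spans, normalise within frames over the foci present, and
average over frames with ≥ 1 focus (frames weighted equally). Line scans
rotate the cell horizontal and average, per position along the major
axis, the in-ROI pixels within 0.2 µm of the ROI outline ("membrane
band"; the band width is a package choice). Group comparisons use the
two-tailed Mann-Whitney U test — exact by enumeration for combined
n ≤ 16 without ties, tie-corrected normal approximation otherwise — with
the conventional star mapping (ns at p ≥ 0.05 up to **** at p < 10⁻⁴)
and 1.5×IQR boxplot outliers.

## Validation design and problem sizes

Everything is validated against forward simulations whose parameters are
the preset study conditions. The acceptance script uses 500 directed
tracks of 30 frames with 20-nm localisation noise for the speed
recovery; 1,000 confined-then-escape trajectories with track durations
drawn from the generator's 2-s exponential lifetime (≥ 10 frames) for
the confinement-time recovery — under that regime, censoring by track
end trims the long-dwell tail and the uncensored median sits at the
dwell median (~1.3 s), exactly as a lifetime-limited experiment would
measure it, whereas artificial 10-s tracks would add the ~0.2-s
escape-travel delay and read ~1.6 s; nine wild-type movies of 12 cells
each (512×512 px, 200 frames) for the constrained-fraction and density
recovery; and three paired movies differing only by the ×1.22 intensity
multiplier and the 0.8/µm² density for the intensity shift. The test
suite runs the same checks at smaller sizes. These sizes give a few
hundred cells/tracks per quantity, enough that the Monte-Carlo error is
small against each tolerance.

## What passing does and does not show

The generator emulates the measurement chain (PSF, shot noise, read
noise, bleaching, pixelation, cell geometry, focus turnover) but not
several properties of real data: molecule exchange between foci is
reduced to bleaching plus noise rather than assembly kinetics; the PSF
is a symmetric Gaussian without aberrations or EM-gain excess noise;
cells never touch, divide or drift; membrane curvature is flattened; and
the blended class is one specific two-state process, not the full zoo of
anomalous motion. Recovery on synthetic data therefore demonstrates the
internal consistency and statistical calibration of the pipeline under
the stated physics — not detector- or sample-specific performance.
Classification of 10-frame tracks is intrinsically noisy at these
diffusion scales; population fractions are reliable, individual
10-frame labels are not. The exact decision thresholds of the original
MATLAB-era classifier this reconstructs are not published, so
track-by-track equivalence with it cannot be asserted.
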