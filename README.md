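# memfoci

Single-particle tracking and motion classification of membrane-tethered
fluorescent foci in bacterial TIRF time-lapse movies — with a
ground-truthed synthetic movie generator so every stage of the analysis
can be validated without raw microscopy data.

The package targets the kind of experiment in which a membrane-bound
protein (the motivating system is RNase Y–sfGFP in rod-shaped *Bacillus
subtilis*) forms short-lived, diffraction-limited assemblies ("foci")
that are imaged by TIRF microscopy at 100-ms frame intervals and 64-nm
pixels. It answers the questions such experiments ask: how many foci per
µm² of cell surface, how bright are they, and how do they move?

## The analysis

1. **Cell segmentation** — bright-field images are Otsu-thresholded into
   per-cell ROIs (8-connected components, minimum area, border cells
   removed); cell area is `|pixels| · (64 nm)²` and each rod is
   normalised to horizontal orientation via its second image moments.
2. **Detection and tracking** — foci are detected per frame with a
   scale-normalised Laplacian-of-Gaussian filter (σ = d/2√2 for an
   expected blob diameter d = 0.3 µm), localised to sub-pixel precision
   by quadratic interpolation, and linked frame-to-frame by a linear
   assignment problem with a 0.3-µm radius and no gap closing. Only
   tracks of ≥ 10 consecutive frames (1 s) are analysed. Focus intensity
   is the mean raw count in the 3×3-pixel window at the spot.
3. **MSD motion classification** — for each track the time-averaged mean
   square displacement

       MSD(t) = ⟨|r(t′+t) − r(t′)|²⟩

   is fitted with three models: directed transport `MSD = (vt)² + c`,
   2-D Brownian diffusion `MSD = 4Dt + c`, and constrained diffusion
   `MSD = P(1 − e^{−4D_c t/P}) + c` whose plateau P relates to the
   confinement domain radius as P = R². AIC model selection with
   identifiability and goodness-of-fit safeguards assigns each track to
   directed / random / constrained / unclassified; D is reported for
   random tracks only and v for directed tracks only. The confinement
   time of constrained foci is the first exit from a 0.15-µm radius.
4. **Quantification and statistics** — per-cell focus density (mean
   detections per frame ÷ cell area), per-focus time-averaged intensity,
   per-frame motion-class fractions averaged at the single-cell level,
   axial membrane line scans, and two-tailed Mann-Whitney comparisons
   between conditions with the usual significance stars.

The **synthetic generator** simulates all of it forward: rod-shaped
cells (4.0 × 0.9 µm), foci appearing and disappearing with exponential
2-s lifetimes at a target surface density, moving by one of four models
(directed, Brownian, confined-then-escape with gamma-distributed dwell
times, or two-state blended motion), rendered as Gaussian PSF spots with
photobleaching, Poisson photon noise and Gaussian read noise. Scenario
presets encode the study conditions: `wt` (0.3 foci/µm², 60 % confined,
D = 0.02 µm²/s, v = 0.4 µm/s), `rif` (transcription arrest: 0.8 foci/µm²,
40 % confined, intensity ×1.22) and `mutant` (density ×4, intensity
×1.75).

## Worked example

```python
import numpy as np
from memfoci import (ImagingConfig, TrackingConfig, analyze_movie,
                     render_movie, simulate_cell_population, wt_scenario)

imaging = ImagingConfig(image_shape=(384, 384))   # 24.6 x 24.6 um, 200 frames
scenario = wt_scenario(n_cells=8)
rng = np.random.default_rng(7)
truth, cells = simulate_cell_population(scenario, imaging, rng)
movie, bright_field = render_movie(truth, imaging, rng, cells=cells)
result = analyze_movie(movie, bright_field, imaging, TrackingConfig())

print(f"cells: {len(result.cells)}   tracks (>=10 frames): "
      f"{result.tracks['track_id'].nunique()}")
print(f"mean per-cell focus density: "
      f"{result.cells['focus_density_per_um2'].mean():.3f} foci/um^2")
for cls, entry in result.kinetics.items():
    print(f"{cls:>13s}: fraction {entry['fraction']:.2f}"
          + (f"   median {entry['median']:.3g}" if entry["count"] else ""))
```

prints

```
cells: 8   tracks (>=10 frames): 61
mean per-cell focus density: 0.323 foci/um^2
     directed: fraction 0.21   median 0.387
       random: fraction 0.16   median 0.0128
  constrained: fraction 0.62   median 1
 unclassified: fraction 0.00
```

i.e. the pipeline recovered the generated wild-type conditions from the
rendered movie: a focus density near 0.3/µm², ~60 % constrained foci, a
median speed of ~0.39 µm/s for directed tracks (units µm/s), a median
D ≈ 0.013 µm²/s for the (few) random tracks in this single movie, and a
median confinement time of ~1 s for constrained foci (units s; the
per-class `median` column is v, D or confinement time respectively).

The same pipeline runs from the shell:

```sh
memfoci simulate --scenario wt --seed 3 --out sim/
memfoci segment sim/bright_field.tif cells.csv
memfoci track sim/movie.tif tracks.csv
memfoci classify tracks.csv fits.csv
memfoci report --scenario wt --scenario rif --seed 1 --out report/
```

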