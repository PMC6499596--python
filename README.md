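# focikit

Automated quantification of ionizing-radiation-induced 53BP1 nuclear foci,
DNA-repair kinetics classification, and rare-cell capture statistics —
with a fully ground-truthed synthetic fluorescence-microscopy generator.

## Who this is for

Cells repair radiation-induced DNA double-strand breaks at different
speeds, and the number of 53BP1 foci per nucleus is the standard live-cell
readout of that repair capacity. A cell that resolves >85% of its foci
within 2 h of irradiation ("fast resolver") is rare — roughly 1 in 100 —
and cannot be found by whole-cell fluorescence, because GFP-53BP1
redistributes into foci without changing total nuclear intensity. Finding
such cells requires counting spots in images, per nucleus, at two or more
timepoints, and tracking each nucleus between them. `focikit` implements
that pipeline end to end for anyone who needs per-cell focus counts,
resolution-kinetics comparisons between cell populations, or the
efficiency/purity arithmetic of magnetic single-cell capture experiments.

## What it computes

- **Detection** — nuclei by Otsu segmentation on the diffuse nucleoplasmic
  GFP background (log-domain, scale-equivariant), filtered on size,
  saturation and shape; foci by difference-of-Gaussians band-pass
  enhancement (masked normalized convolution) and per-nucleus
  automatically-thresholded local maxima.
- **Kinetics** — cross-timepoint nucleus matching (mutual nearest
  centroid), per-cell resolution fraction `1 − n_t1/n_t0`, strict >0.85
  fast-resolver classification, smoothed normalized count histograms,
  pooled-variance Student t-tests, intensity–count Pearson correlation,
  and a median-matching resolution speed ratio.
- **Capture statistics** — capture efficiency and its OLS slope across
  experiments, purity/contamination, fold enrichment, and exact-match
  in-silico PCR (both strands, inclusive product length) for the
  dog/mouse mitochondrial cytochrome-b species check.
- **Simulation** — seeded synthetic fields with known ground truth:
  hard-core nucleus placement, per-cell GFP-conserving rendering, Poisson +
  read noise, per-cell exponential focus resolution with a rare fast
  subpopulation, debris distractors, and a binomial model of repeated
  magnetic capture. See `docs/methods.md` for the model and its limits.

## Worked example

Simulate one 20-nucleus field imaged at 45 and 120 min post-IR, detect and
track, then summarize:

```python
import numpy as np
import focikit as fk

layout = fk.SimLayout(800, 800, 20)
kinetics = fk.KineticsParams(timepoints_min=(45, 120))
images, truth = fk.generate_time_course(
    layout, fk.OpticsModel(), fk.NoiseModel(), kinetics, seed=11)

params = fk.DetectionParams()
r45 = fk.quantify_field(images[0], params, timepoint_min=45)
r120 = fk.quantify_field(images[1], params, timepoint_min=120)

gate = float(np.median(np.sqrt(r45["records"]["area_px"] / np.pi)))
matches = fk.match_cells(r45["records"], r120["records"], gate)
tracks = fk.build_tracks(matches, r45["table"], r120["table"])

summary = fk.summarize({45: r45["table"]["focus_count"].to_numpy(),
                        120: r120["table"]["focus_count"].to_numpy()})
print(summary.stats.to_string(index=False))
print(f"tracked cells: {len(tracks)}")
print(f"mean resolution fraction: {tracks['resolution_fraction'].mean():.3f}")
print(f"fast resolvers (>85% resolved): {int(tracks['fast_resolver'].sum())}")
```

prints

```
 timepoint_min  n_cells  mean       sd  median
          45.0       20  9.80 2.166734    10.0
         120.0       20  7.15 2.183069     7.0
tracked cells: 20
mean resolution fraction: 0.263
fast resolvers (>85% resolved): 0
```

Read: all 20 nuclei were segmented and tracked; the population carried
~10 foci/cell at 45 min and resolved ~26% of them by 2 h — the bulk
behaviour — and this 20-cell field happens to contain none of the ~1%
fast-resolving cells (the ground truth agrees: `truth.cells.fast_resolver`
is all False for this seed).

The same stages are scriptable from a shell:

```bash
focikit simulate --seed 11 --out run/        # TIFFs + ground-truth CSVs
focikit detect run/images/*.tif --out run/   # per-nucleus focus counts
focikit kinetics run/focus_counts.csv        # population summary
focikit pcr-check                            # cytochrome-b primer check
focikit report --seed 11 --out run/          # full pipeline + JSON report
```

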