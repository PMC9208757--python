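# hcmotion

Quantification of amoeboid-like single-cell migration in time-lapse
fluorescence microscopy, built around the measurement chain used for
horizontal-cell (HC) migration in the developing zebrafish retina: these
interneurons detach from the apical surface, adopt a multipolar morphology
and migrate through the crowded inner nuclear layer with frequent direction
changes, reversible cell/nuclear deformations, speed-dependent front-biased
protrusions and a rear-enriched stable-F-actin cortex — the hallmarks of
amoeboid movement.

The package is for quantitative cell biologists who track single cells in
2D (drift-corrected, max-projected) movies and want the full set of
morphodynamic readouts from one toolkit:

* **`simgen`** — synthetic time-lapse generator (image stacks + complete
  ground truth) so every stage is testable without microscope data;
* **`register`** — automated XY drift estimation (consecutive-frame
  subpixel cross-correlation, cumulative composition) and correction;
* **`segment`** — seeded region-based contour segmentation of one cell per
  frame, propagated by centroid reseeding;
* **`shape`** — per-contour perimeter *P* (µm), area *A* (µm²), sphericity
  `100 · 4πA/P²` (%), elongation ratio (major/minor equivalent-ellipse
  diameters, ≥ 1), and mitotic-rounding detection (joint sphericity-max /
  elongation-min frame);
* **`kinematics`** — instantaneous velocities `v_t = (x_{t+1} − x_t)/Δt`,
  per-cell 25th/75th speed-percentile stratification, signed depth relative
  to tissue layers (e.g. the outer plexiform layer), centrosome-to-centre
  offset with front/back labels;
* **`protrusion`** — the angle `θ = arccos(v̂ · û)` between the movement
  direction and the centroid-to-tip unit vector (0° = front, 180° = back),
  aggregated into normalized angular histograms for all / low-speed /
  high-speed frames;
* **`polarity`** — 3-px-wide line scans along the movement axis, clipped to
  the cell contour and oriented front→back, averaged into an intensity
  profile with a rear-enrichment index (back-third / front-third mean);
* **`imgio`** — TIFF/CSV/YAML I/O (MTrackJ-style track tables) and the
  `hcmotion` CLI.

## Worked example

Generate a synthetic movie and run the full pipeline:

```sh
hcmotion run-all --seed 0 --out run0
```

which prints the manifest path (`run0/manifest.json`) and writes every
result table. Inspecting a few of them:

```python
>>> import pandas as pd
>>> pd.read_csv("run0/speed_thresholds.csv")
   p25_um_min  p75_um_min
0    0.348132    0.983649
>>> h = pd.read_csv("run0/angle_histograms.csv")
>>> h[h.condition == "high"].head(3)[["bin_lo_deg", "bin_hi_deg", "frequency"]]
    bin_lo_deg  bin_hi_deg  frequency
18         0.0        20.0   0.476190
19        20.0        40.0   0.476190
20        40.0        60.0   0.047619
>>> pd.read_csv("run0/polarity_summary.csv").rear_enrichment_index[0]
2.499227
```

Reading: this cell's low/high-speed cutoffs are 0.35 and 0.98 µm/min; at
high speed nearly half of all protrusions point within 20° of the movement
direction (front bias), and the cortical marker is ~2.5× brighter over the
back third of the cell than the front third (rear polarization) — the
generator's defaults build in exactly these behaviours, and the pipeline
recovers them.

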