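# coralcasa

Computer-assisted sperm analysis (CASA) for coral: an open re-implementation
of a darkfield video motility/concentration pipeline — head detection,
maximum-displacement track linking, VCL/VAP/VSL kinematics, four-class
motility binning, concentration quantitation across three instruments
(chamber video, haemocytometer, flow cytometer), capture QC, and
fertilisation dose planning.  A ground-truthed synthetic capture simulator
makes every stage testable with no microscopy data.

## Pipeline overview

For each captured field (multi-page TIFF, 8/16-bit grayscale; or a
pre-detected centroid CSV):

1. **artefact mask** — pixels bright in *every* frame, in components larger
   than the head-size gate, are masked (static dust/salt blooms) and dilated
   by one head diameter;
2. **detection** — per-frame global threshold (Otsu by default, fixed
   override available), connected components gated to head areas of
   5–150 µm², intensity-weighted centroids in µm;
3. **linking** — optimal bipartite assignment between consecutive frames
   under a closed `cell_travel_max` displacement bound (a 5 µm bound at
   60 Hz follows straight paths up to exactly 300 µm/s; faster paths split,
   and `split-risk` reporting warns about it).  No gap closing;
4. **kinematics** — VCL (raw path length / duration), VAP (moving-average
   smoothed path, endpoints preserved), VSL (net displacement / duration),
   maximum excursion from the first position;
5. **classification** — *static* if the track never leaves
   0.8 × head-diameter of its start; otherwise *slow* (< 20 µm/s),
   *motile* (20–80 µm/s inclusive) or *progressive* (> 80 µm/s) on VAP
   (configurable to VCL/VSL; thresholds configurable per species);
6. **quantitation** — concentration from mean detections per frame and the
   imaged chamber volume (field area × 20 µm depth); total/progressive
   motility percentages (static excluded from "motile"); motile
   concentration = total × motile fraction;
7. **QC** — flags for < 5 fields, < 200 cells, concentration outside the
   8×10⁶–5×10⁷ cells/mL working range or the 1–3×10⁷ ideal band, uniform
   chamber flow (median step drift > 10 µm/s), stale wells, and track-split
   risk.

All coordinates are µm with the origin at the field's top-left corner
(y down) and 0-based frame indices.

## CLI

```bash
coralcasa simulate --out-dir sim --n-fields 5 --seed 1 --concentration 2e7
coralcasa analyze sim/field_*.tif --out-dir out --sample-id demo \
    --set cell_travel_max_um=5
coralcasa report out/sample.json --out batch.csv
coralcasa hemocytometer --cc 50 --n 3 --cd 1e4 --d 2
coralcasa flow --events 1e4 --dilution 2            # 10 µL default: ×100/mL
coralcasa dilution-plan --concentration 1e9
coralcasa fert-plan --target-ratio 5e3 --motile-concentration 2e6 --eggs 100
coralcasa fert-corr records.csv --plot fig.png
```

`analyze` writes `tracks.csv`, `kinematics.csv` and a deterministic
`sample.json` (QC flags + diagnostics + the full settings used).  Settings
live in a TOML file whose keys map 1:1 to `--set key=value` overrides;
`static_tail_filter` is permanently `False` (enabling it drops tail-less
static cells, under-counting concentration and inflating motility) and
attempting to set it is a validation error.

## Simulator

`simulate_tracks` places a Poisson number of cells
(mean = concentration × field volume) and moves them by class: clipped
Gaussian jitter (static), persistent random walks (slow/motile), and
near-straight swimming (progressive), with optional uniform drift and
partial tracks at the field boundary.  `render_frames` draws Gaussian spots
whose half-maximum area equals the head area, plus optional saturated bloom
discs and Gaussian noise.  `synth_fert_dataset` generates fertilisation
records with a known log-linear dose response.  Everything is reproducible
from a seed.  Per-class speed ranges are validated to sit inside their
classification bins and are deliberately configurable — they vary by
species and by month.

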