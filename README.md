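# motilimap

Spatio-temporal mapping and quantitative classification of gut motility
from time-lapse recordings of tubular organs (ex vivo intestine
preparations), with the pre/post-treatment statistics used to assess
hormonal effects such as cholecystokinin (CCK) administration.

## The problem

Intestinal motility is driven by smooth-muscle contractions that locally
narrow the gut. Filming a mounted intestine and segmenting it frame by
frame yields, for every frame, a profile of gut diameter along the organ.
Stacking these profiles over time gives a **diameter matrix** `D[x, t]`
(position × time) — a kymogram in which contractions appear as dark bands
on the familiar gray-scale spatio-temporal (ST) map. This package turns
such recordings into quantitative motility statistics:

1. **Extraction** — binary mask stacks are converted into calibrated
   diameter matrices: the long axis is split into 0.5-mm regions of
   interest and the transverse extent of the foreground in each bin is the
   local diameter. Recordings at 3.5 frames/s are analysed at 1.2 frames/s
   (every third frame).
2. **Detection** — per frame, contraction cells are local minima of the
   diameter profile at least `depth_threshold` deep (prominence relative to
   the lower flanking local maximum), extended to contiguous neighbours of
   similar diameter; each cell carries the contraction amplitude
   (flanking-maximum minus minimum diameter). Connected components of
   cells (8-connectivity) across the position × time grid are **contraction
   events**.
3. **Classification** — each event gets an initiation site, propagating
   distance, duration, amplitude (% of the local maximum diameter), and a
   linear regression of position on time over its cells:

   * distance ≤ 1.0 mm → **standing contraction** (mixing/segmentation),
   * distance > 1.0 mm and r² ≥ 0.8 → **ripple** (fast, linear propagation),
   * distance > 1.0 mm and r² < 0.8 → **slow propagating contraction**;

   velocity = |slope|, direction anterograde (oral→anal) for slope > 0,
   retrograde for slope < 0.
4. **Summary & statistics** — events are binned into four morphological
   segments (default length fractions 0.39/0.23/0.23/0.15, Segment 1 =
   anterior bulbous, Segment 4 = hindgut) and reported as contractions per
   minute per mm (cpm). Treatment contrasts use per-replicate
   log₂(after/before) ratios tested against 0 with one-sample t-tests
   (90% CI; `*` for 0.05 ≤ p < 0.1, `**` for p < 0.05), quartile-based
   low/medium/high parameter categories, Kruskal–Wallis + Dunn across
   contraction types, ANOVA + Tukey across segments, and gut-length
   reduction metrics.

A synthetic-kymograph generator (`motilimap.synth`) injects contraction
events with known type, velocity, amplitude and path into simulated
diameter matrices, so every stage is testable end to end without recorded
video.

## Worked example

```python
import numpy as np
from motilimap import (SimulationSpec, GroundTruthEvent, generate_matrix,
                       build_cell_matrix, label_events, event_features,
                       classify_event, assign_segment, summarize, filter_events)

spec = SimulationSpec(length_mm=60.0, n_frames=720, noise_sd_mm=0.02, seed=7)
events_in = [
    GroundTruthEvent(type="ripple", onset_time_s=120.0, initiation_site_mm=15.0,
                     velocity_mm_per_s=0.25, direction="anterograde", duration_s=30.0,
                     amplitude_frac=0.30, halfwidth_mm=1.0, kernel="square",
                     envelope="square"),
    GroundTruthEvent(type="standing", onset_time_s=300.0, initiation_site_mm=50.0,
                     velocity_mm_per_s=0.0, direction="none", duration_s=10.0,
                     amplitude_frac=0.40, halfwidth_mm=0.25, kernel="square",
                     envelope="square"),
]
dm, _ = generate_matrix(spec, events_in)
events = label_events(build_cell_matrix(dm))
for ev in events:
    event_features(ev, dm.total_length_mm, dm=dm)
    classify_event(ev)
    ev.segment = assign_segment(min(ev.initiation_site_frac, 100.0))
events = filter_events(events, min_amplitude_frac=0.05)
```

prints, after the loop above:

```
2 events above the 5% amplitude floor
event 2: ripple   S1  site 14.25 mm  distance 9.00 mm  duration 30.0 s  amplitude 30.7%  velocity 0.253 mm/s  anterograde
event 6: standing S3  site 49.75 mm  distance 0.50 mm  duration 10.0 s  amplitude 39.2%  velocity 0.000 mm/s  none
```

Both injected events are recovered: the 0.25 mm/s anterograde ripple is
detected at 0.253 mm/s (1.2% error) with its 30% amplitude measured as
30.7%, and the non-propagating contraction is classified standing. The few
single-frame noise artifacts fall below the 5% relative-amplitude floor
and are dropped. `summarize(events, (0, 600), dm.total_length_mm)` then
gives the per-segment frequency table in cpm (e.g. one ripple initiating
in Segment 1 over 10 minutes of a 23.4-mm segment → 0.0043 cpm).

## Command line

```sh
motilimap extract  --masks stack.tif --px-per-mm 10 --fps 3.5 --keep-every 3 -o dm.csv
motilimap detect   --matrix dm.csv -o events.csv --cells-output cells.csv
motilimap render   --matrix dm.csv --map gray -o st_gray.png
motilimap summarize --events events.csv --window 0,600 --total-length 60 -o summary.json
motilimap compare  --table prepost.csv -o report.csv
motilimap simulate --seed 1 -o sim.csv --truth-output truth.csv
motilimap run      -c config.yaml -o outdir
```

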