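# Methods

## Diameter measurement

A recording is a stack of binary masks (foreground = intestine) with
spatial calibration `px_per_mm` and frame rate `fps`. The long (oral–anal)
axis runs along image rows, oral end at row 0; a flag flips recordings
mounted the other way up. Analysis uses every `keep_every`-th frame
(default 3, taking a 3.5 frames/s acquisition to ~1.2 frames/s, the rate at
which motility patterns are stable against further temporal refinement).

The long axis is split into consecutive bins of `roi_width_mm` (default
0.5 mm). The diameter of a bin in a frame is the transverse extent of the
foreground — the inclusive pixel distance between the outermost foreground
pixels — reduced over the bin's rows with the maximum (a mean-extent
reducer is available). Bins beyond the intestine's longitudinal extent in a
frame are *missing* (NaN), never zero, so longitudinal shortening is not
mistaken for contraction. Gut length per frame is the longitudinal
foreground extent; the recording's reference length (used for fractional
positions) is the maximum over frames. How length should be measured on a
slack-mounted, weighted preparation is not uniquely defined; the
longitudinal-extent rule is this package's choice.

Positions are reported at bin centres: bin `i` spans
`[i*dx, (i+1)*dx)` and is reported at `(i+0.5)*dx`.

## ST maps

The gray-scale ST map normalizes each position by subtracting its temporal
mean diameter over the analysed window (a global-mean mode exists behind a
flag), then linearly interpolates nine values between each pair of adjacent
positions, and maps the minimum deviation to black and the maximum to white
(a value exactly halfway renders 128; constant input renders uniform 128).
Missing cells render in a sentinel orange outside the gray ramp. Time runs
down the vertical axis. Interpolation is for rendering only: detection
and the binary map operate on the native grid. On the binary map, standing
contractions are black, ripples red, slow propagating contractions green,
background white; events are drawn in list order, later events winning on
overlap.

## Contraction extraction

Per frame, the diameter profile is scanned for local minima at least
`depth_threshold` deep, where depth is the prominence of the minimum —
its diameter relative to the lower of its two flanking local maxima
(plateau minima are kept in full; profile edges cannot be minima, so a
monotone taper end is not a contraction). The threshold is "one diameter
unit": one pixel-equivalent at acquisition scale, 0.1 mm by default
(10 px/mm); it is a parameter because the appropriate unit depends on the
recording scale. Each minimum extends to the maximal contiguous run of
neighbours whose diameter is within `similarity_tol` of the minimum
(default: equal to `depth_threshold`; the notion of "similar diameter" is
not otherwise quantified). Every cell of a run carries the run's
amplitude: flanking local maximum minus run minimum, using the lower of
the two flanks (conservative; a nearest-flank convention is available,
and a run touching the profile edge uses its single available flank).

Cells from all frames form an amplitude matrix (NaN where no contraction).
Connected components under 8-connectivity are contraction events: diagonal
moves join cells across frames, so a contraction advancing up to one bin
per frame remains one event; 4-connectivity is available and splits
strictly diagonal chains. Events whose peak relative amplitude falls below
`min_amplitude_frac` (default 0.05, matching the smallest relative
amplitude seen in practice; 0 disables) are dropped after feature
computation.

## Event features and classification

For an event's cell set:

* **initiation site** — position of the earliest cell (ties broken to the
  oral-most position, for deterministic output);
* **distance** — positional extent (max − min, mm), also as % of gut length;
* **duration** — temporal extent (s);
* **amplitude %** — deepest cell's amplitude over the temporal maximum
  diameter at that cell's position within the analysis window (the window,
  not the full recording, is used so pre/post windows are self-contained);
* **slope, r²** — least squares of position (response) on time over all
  cells; r² is the squared Pearson correlation, identical to the OLS
  coefficient of determination for a simple regression;
* **velocity** = |slope|; **direction** from the slope sign (anterograde =
  oral→anal for positive slope; `none` for single-frame events).

Classification applies the distance rule first: distance ≤ 1.0 mm →
standing, regardless of r². Among propagating events, r² ≥ 0.8 → ripple,
r² < 0.8 → slow propagating; a propagating event with undefined r²
(degenerate regression) falls back to slow. Both boundaries are inclusive
as stated.

Initiation sites map to segments by cumulative length fractions (default
0.39/0.23/0.23/0.15), right-boundary inclusive (a site exactly at a
boundary belongs to the more oral segment; site 0 is Segment 1). Frequency
is contractions per minute per mm of segment length, counting events by
initiation time within the window and segment lengths as ratio × reference
length.

## Statistics

* **Quartile categories** — low (≤ Q1), medium, high (≥ Q3) with quartiles
  by linear interpolation between order statistics (plotting position
  (k−1)/(n−1)). The convention is recorded in the output because category
  membership near cutoffs depends on it; all-equal samples are flagged
  degenerate.
* **Pre/post contrasts** — per-replicate log₂(after/before) ratios; pairs
  with a zero or missing side are excluded (never zero-filled) and the
  exclusion count reported. One-sample t-test against 0 with a 90%
  confidence interval and tiers `*` (0.05 ≤ p < 0.1) and `**` (p < 0.05);
  zero-variance samples are flagged undefined rather than given a p-value.
* **Across types** — Kruskal–Wallis (tie-corrected) followed by Dunn's
  pairwise z-tests on pooled ranks with tie correction; p-values adjusted
  with Holm by default (Bonferroni or none available, since the post hoc
  adjustment convention varies between tools).
* **Across segments** — one-way ANOVA followed by Tukey HSD with a compact
  letter display (groups with adjusted p ≥ α share a letter).
* **Length reduction** — percent reduction = (mean length in the 10-min
  before-window − minimum length in the 10-min after-window) / before
  mean; shortening events are local minima of the length trace with
  prominence ≥ 1% of the before-window mean length (the definition of a
  discrete shortening episode is this package's reading), reported as
  events per minute per window.

## Synthetic data

The generator emulates an ex vivo recording: baseline diameter `D0(x)`
(default a linear oral-bulbous taper from 3.0 mm to 1.5 mm over a 60-mm
gut; a flat profile is available for controlled experiments), sampled at
dx = 0.5 mm and dt = 1/1.2 s over 10-minute windows. Each injected event
subtracts `a · D0(x) · K((x − c(t))/w) · H(t)`: relative amplitude `a`,
spatial kernel `K` (Gaussian, or square pulse for unambiguous footprints
and threshold edge cases), temporal envelope `H` (raised-cosine ramps or
square), and a centre `c(t)` moving at the event's velocity from its
initiation site. Slow propagating events add a cosine path jitter with an
integer number of cycles centred on the event midpoint; the cosine is even
about the midpoint and therefore orthogonal to the linear trend, so the
path's best-fit slope equals the drift velocity exactly while the target
generative r² is set in closed form from the wave amplitude
(r² = var_lin / (var_lin + A²/2)). Gaussian noise is added and values are
clipped at 0. Identical spec + seed give bit-identical output; overlapping
events are flagged.

Mask rasterization draws each position bin as a horizontal band of
`round(d · px_per_mm)` pixels centred on a fixed axis, so measurement
recovers the matrix within half a pixel.

### Controlled single-event experiments

`simulate_single_event` builds one isolated event per matrix on a flat
2.25-mm baseline with square kernels, sized around the event's exact path
(3-mm spatial, 6-frame temporal margins). Amplitudes are uniform on
5–85% and velocities log-uniform over the observed ranges (ripples
0.002–1.694 mm/s, slow 0.001–1.471 mm/s). Design constraints, fixed from
analysis of the measurement geometry rather than tuned on outcomes:

* **Path length** of propagating events is uniform on 5–14 mm. A linear
  event's detected r² is depressed by the finite spatial width of its
  per-frame cell runs (residual variance ≈ h²/3 against path variance
  L²/12); L ≥ 5 mm with h = 1 mm keeps a perfectly linear footprint's r²
  ≳ 0.85, clear of the 0.8 boundary.
* **Kernel half-widths**: standing 0.25 mm (footprint ≤ 2 bins, distance
  well under the 1.0-mm standing bound); ripples max(1.0, 0.625 × per-frame
  step); slow max(2.0, 0.625 × step). The step-proportional floor keeps
  consecutive frames' runs 8-connected for fast events (a 1.69 mm/s ripple
  advances 2.8 bins per frame); the wider slow-event kernel also reduces
  run-mean quantization so the detected slope recovers the drift velocity
  within 5% despite the wavy path.
* **Durations** snap to the frame grid so the square envelope covers an
  exact, symmetric sample of the path (keeping the discrete cosine jitter
  orthogonal to time).
* The **flat baseline** isolates detection/classification accuracy: on a
  tapered baseline the lower-flank amplitude convention absorbs the
  baseline drop across the flank gap, which would dominate the error for
  the shallowest (5%) events. The taper remains the default for realistic
  simulations.

Slow-event generative r² targets are uniform on 0.25–0.6, well below the
0.8 boundary; within-frame spread only lowers the detected r² further, so
classification guard bands (±0.1 mm around 1.0 mm, ±0.02 around r² = 0.8)
are never entered by construction.

### Rate-based simulations

For statistics-level experiments, per-segment event counts are Poisson with
mean rate × minutes × segment length. The pre/post effect simulations use
baseline per-segment ripple rates equal to the observed per-segment median
cpm divided by ln 2 — the mean of an exponential distribution with that
median, matching the strongly right-skewed parameter distributions — over
a 60-mm gut and 10-minute windows, with 12 replicates per experiment.

### What the generator does not emulate

Real recordings have segmentation errors, peristaltic baseline drift,
overlapping and branching contractions, gut bending, and longitudinal
shortening coupled to contractions; none of these are modelled. Passing
recovery tests therefore demonstrates correctness of the measurement and
classification chain under the stated model, not robustness to real-world
segmentation noise.

## Numerical choices and degenerate inputs

* Missing data: NaN everywhere; minima detection splits profiles at NaN;
  stretches shorter than 3 finite samples yield no minima.
* Ties at the initiation site go to the oral-most position; plateau minima
  are merged into one run.
* Gray rendering uses banker's rounding (midpoint → 128).
* Zero-variance ratio samples, single-cell events (undefined r²/velocity)
  and all-missing rows are flagged rather than silently given values.
* The delimited-text diameter format stores calibration in a `#` header
  line and round-trips losslessly (`repr` precision); `NA` is the missing
  token.

## Known limitations

* Diameter is the transverse foreground extent, which overestimates the
  lumen-relevant diameter on a bent gut; the method assumes a straightened
  preparation.
* Sub-pixel minima localization and model-based wave fitting are out of
  scope; velocity resolution is limited by the 0.5-mm × 0.83-s grid.
* The amplitude floor and the depth threshold's physical unit are
  recording-scale dependent and must be set deliberately for new setups.
* Within-run pre/post comparisons on a single recording are descriptive;
  the t-test machinery needs replicate organs.
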