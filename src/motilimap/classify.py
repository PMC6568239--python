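"""Event features, contraction-type classification, and per-window summaries.

Every contraction event gets geometric features (initiation site,
propagating distance, duration, amplitude) and, for multi-frame events, a
linear regression of intestinal position on time whose slope and r-squared
drive the classification:

* standing contraction -- propagating distance <= 1.0 mm (checked first);
* ripple               -- distance > 1.0 mm and regression r^2 >= 0.8;
* slow propagating     -- distance > 1.0 mm and r^2 < 0.8.

Velocity is |slope|; direction comes from the slope sign (positive =
anterograde, oral toward anal). Initiation sites are expressed as a
percentage of total gut length and mapped onto four morphological segments
whose default length fractions are 0.39/0.23/0.23/0.15 (Segment 1 =
anterior bulbous, Segment 4 = hindgut).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .detect import ContractionEvent
from .io_masks import DiameterMatrix

__all__ = [
    "STANDING_MAX_DISTANCE_MM",
    "RIPPLE_MIN_R2",
    "SegmentScheme",
    "MotilitySummary",
    "event_features",
    "classify_event",
    "assign_segment",
    "summarize",
]

#: largest propagating distance (mm) of a standing (non-propagating) contraction
STANDING_MAX_DISTANCE_MM = 1.0
#: smallest position-vs-time r-squared of a ripple among propagating events
RIPPLE_MIN_R2 = 0.8

TYPES = ("standing", "ripple", "slow")


@dataclass(frozen=True)
class SegmentScheme:
    """Fractional partition of the intestine into consecutive segments.

    ``ratios`` are the per-segment length fractions, oral end first; they
    must be positive and sum to 1. The default is the four-segment ballan
    wrasse scheme (0.39, 0.23, 0.23, 0.15).
    """

    ratios: tuple[float, ...] = (0.39, 0.23, 0.23, 0.15)

    def __post_init__(self) -> None:
        r = np.asarray(self.ratios, dtype=float)
        if (r <= 0).any():
            raise ValueError("segment ratios must be > 0")
        if abs(r.sum() - 1.0) > 1e-9:
            raise ValueError(f"segment ratios must sum to 1, got {r.sum()}")

    @property
    def n_segments(self) -> int:
        return len(self.ratios)

    @property
    def boundaries(self) -> np.ndarray:
        """Cumulative right boundaries as fractions of gut length."""
        b = np.cumsum(self.ratios)
        b[-1] = 1.0
        return b

    def segment_lengths_mm(self, total_length_mm: float) -> np.ndarray:
        return np.asarray(self.ratios) * total_length_mm


@dataclass(eq=False)
class MotilitySummary:
    """Per-segment/per-type frequencies and pooled parameter distributions.

    ``frequency_cpm`` is a (segments x types) table of contractions per
    minute per mm of segment length, counted by initiation site within the
    window. Direction proportions (as percentages summing to 100 over
    events with a defined direction) and parameter distributions are pooled
    per type; types with no directed events have proportions ``None``.
    """

    window: tuple[float, float]
    total_length_mm: float
    scheme: SegmentScheme
    frequency_cpm: "object"  # pandas DataFrame, index=segment, columns=type
    counts: "object"  # same layout, raw counts
    direction_proportions: dict
    distributions: dict

    def to_dict(self) -> dict:
        return {
            "window_s": list(self.window),
            "total_length_mm": self.total_length_mm,
            "segment_ratios": list(self.scheme.ratios),
            "frequency_cpm": {
                str(seg): {t: float(v) for t, v in row.items()}
                for seg, row in self.frequency_cpm.iterrows()
            },
            "counts": {
                str(seg): {t: int(v) for t, v in row.items()}
                for seg, row in self.counts.iterrows()
            },
            "direction_proportions": self.direction_proportions,
            "distributions": {
                t: {k: [float(x) for x in v] for k, v in d.items()}
                for t, d in self.distributions.items()
            },
        }


# ---------------------------------------------------------------------------
# features


def _ols_position_on_time(times: np.ndarray, positions: np.ndarray):
    """Simple least squares of position (response) on time.

    Returns (slope, r2); either may be None when undefined (no time spread
    for the slope; no spread in either variable for r2). r2 is the squared
    Pearson correlation, identical to the OLS coefficient of determination
    for a simple regression.
    """
    t = np.asarray(times, dtype=float)
    x = np.asarray(positions, dtype=float)
    st = t.var()
    sx = x.var()
    if t.size < 2 or st == 0:
        return None, None
    cov = ((t - t.mean()) * (x - x.mean())).mean()
    slope = cov / st
    if sx == 0:
        return slope, None
    r2 = (cov * cov) / (st * sx)
    return slope, float(min(r2, 1.0))


def event_features(
    e: ContractionEvent,
    total_length_mm: float,
    dm: DiameterMatrix | None = None,
    window: tuple[float, float] | None = None,
) -> ContractionEvent:
    """Fill an event's derived features in place (and return it).

    * initiation site: position of the earliest cell (tie at equal times:
      the oral-most, i.e. smallest, position);
    * distance/duration: position and time extents of the cell set;
    * slope/r2 from the position-on-time regression over all cells;
      velocity = |slope|, direction from the slope sign ('none' for
      single-frame events or zero slope);
    * amplitude_pct: the deepest cell's amplitude as a percentage of the
      temporal maximum diameter at that cell's position, taken over the
      analysis ``window`` (whole recording if no window) of ``dm``.

    Site and distance percentages are relative to ``total_length_mm``.
    """
    if total_length_mm is None or not total_length_mm > 0:
        raise ValueError("total_length_mm must be > 0")
    pos = e.pos_mm
    t = e.time_s

    tmin = t.min()
    e.initiation_site_mm = float(pos[t == tmin].min())
    e.initiation_site_frac = 100.0 * e.initiation_site_mm / total_length_mm
    e.distance_mm = float(pos.max() - pos.min())
    e.distance_frac = 100.0 * e.distance_mm / total_length_mm
    e.duration_s = float(t.max() - tmin)

    slope, r2 = _ols_position_on_time(t, pos)
    e.slope_mm_per_s = slope
    e.r2 = r2
    e.velocity_mm_per_s = abs(slope) if slope is not None else None
    if slope is None or slope == 0:
        e.direction = "none"
    else:
        e.direction = "anterograde" if slope > 0 else "retrograde"

    if dm is not None:
        i_deep = int(np.argmax(e.amp_mm))
        row = dm.values[e.pos_idx[i_deep]]
        if window is not None:
            times = dm.times_s
            sel = (times >= window[0]) & (times <= window[1])
            row = row[sel]
        dmax = np.nanmax(row) if np.isfinite(row).any() else np.nan
        if np.isfinite(dmax) and dmax > 0:
            e.amplitude_pct = 100.0 * float(e.amp_mm[i_deep]) / float(dmax)
    return e


def classify_event(e: ContractionEvent) -> str:
    """Label an event standing / ripple / slow propagating.

    The distance rule is checked first: any event whose footprint spans at
    most 1.0 mm is standing regardless of r^2. Propagating events split on
    r^2 >= 0.8 (ripple) vs < 0.8 (slow); a propagating event with undefined
    r^2 falls back to slow.
    """
    if e.distance_mm is None:
        raise ValueError(f"event {e.id}: features not computed")
    if e.distance_mm <= STANDING_MAX_DISTANCE_MM:
        e.type = "standing"
    elif e.r2 is not None and e.r2 >= RIPPLE_MIN_R2:
        e.type = "ripple"
    else:
        e.type = "slow"
    return e.type


def assign_segment(initiation_site_frac: float, scheme: SegmentScheme | None = None) -> int:
    """Map an initiation site (% of gut length) to a 1-based segment index.

    Boundaries are inclusive on the right: a site exactly at a boundary
    belongs to the earlier (more oral) segment; fraction 0 is Segment 1.
    """
    if scheme is None:
        scheme = SegmentScheme()
    if not 0 <= initiation_site_frac <= 100:
        raise ValueError(f"initiation site fraction {initiation_site_frac} outside [0, 100]")
    f = initiation_site_frac / 100.0
    if f == 0:
        return 1
    return int(np.searchsorted(scheme.boundaries, f, side="left")) + 1


# ---------------------------------------------------------------------------
# summaries


def summarize(
    events: list[ContractionEvent],
    window: tuple[float, float],
    total_length_mm: float,
    scheme: SegmentScheme | None = None,
) -> MotilitySummary:
    """Per-segment, per-type contraction frequencies and parameter pools.

    Frequency is contractions per minute per mm of segment length (cpm),
    counting events whose initiation time falls inside ``window`` by the
    segment of their initiation site. Direction proportions are computed per
    type over events with a defined direction.
    """
    import pandas as pd

    if scheme is None:
        scheme = SegmentScheme()
    t0, t1 = window
    if not t1 > t0:
        raise ValueError("window must have positive duration")
    minutes = (t1 - t0) / 60.0
    seg_lengths = scheme.segment_lengths_mm(total_length_mm)

    segs = range(1, scheme.n_segments + 1)
    counts = pd.DataFrame(0, index=list(segs), columns=list(TYPES))
    counts.index.name = "segment"
    directions: dict[str, dict[str, int]] = {t: {"anterograde": 0, "retrograde": 0} for t in TYPES}
    dists: dict[str, dict[str, list]] = {
        t: {"amplitude_pct": [], "distance_frac": [], "duration_s": [], "velocity_mm_per_s": []}
        for t in TYPES
    }

    for ev in events:
        if ev.type is None or ev.initiation_site_frac is None:
            raise ValueError(f"event {ev.id}: classify and compute features first")
        onset = ev.time_s.min()
        if not (t0 <= onset <= t1):
            continue
        seg = ev.segment or assign_segment(ev.initiation_site_frac, scheme)
        ev.segment = seg
        counts.loc[seg, ev.type] += 1
        if ev.direction in ("anterograde", "retrograde"):
            directions[ev.type][ev.direction] += 1
        for key in dists[ev.type]:
            val = getattr(ev, key)
            if val is not None:
                dists[ev.type][key].append(float(val))

    freq = counts.div(seg_lengths * minutes, axis=0)

    dir_props: dict[str, dict | None] = {}
    for t in TYPES:
        n = sum(directions[t].values())
        dir_props[t] = (
            None
            if n == 0
            else {k: 100.0 * v / n for k, v in directions[t].items()}
        )

    return MotilitySummary(
        window=(float(t0), float(t1)),
        total_length_mm=float(total_length_mm),
        scheme=scheme,
        frequency_cpm=freq,
        counts=counts,
        direction_proportions=dir_props,
        distributions=dists,
    )
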