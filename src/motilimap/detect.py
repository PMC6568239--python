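"""Contraction extraction from diameter matrices.

A contraction shows up in one frame's spatial diameter profile as a local
minimum. Per frame, minima whose depth (prominence relative to the lower of
the two flanking local maxima) reaches ``depth_threshold`` are extracted;
each minimum is then extended to the contiguous neighbours whose diameter is
similar (within ``similarity_tol``) to the minimum, and every cell of the
resulting run is assigned the run's amplitude (flanking maximum minus
minimum diameter). Cells from all frames form a sparse amplitude matrix
(NaN where no contraction); connected components of that matrix are the
contraction events.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

from .io_masks import DiameterMatrix

__all__ = [
    "ContractionCellMatrix",
    "ContractionEvent",
    "find_local_minima",
    "extend_minima",
    "cell_amplitude",
    "build_cell_matrix",
    "label_events",
    "filter_events",
    "events_to_dataframe",
    "cells_to_dataframe",
]

#: default minimum diameter drop (mm) defining a local minimum: one
#: pixel-equivalent at a 10 px/mm acquisition scale
DEFAULT_DEPTH_THRESHOLD_MM = 0.1


@dataclass(eq=False)
class ContractionCellMatrix:
    """Amplitude (mm) where a contraction cell was detected, NaN elsewhere.

    Aligned cell-for-cell with the source diameter matrix.
    """

    amplitude: np.ndarray
    dx_mm: float
    dt_s: float
    total_length_mm: float
    depth_threshold: float
    similarity_tol: float

    def __post_init__(self) -> None:
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        finite = self.amplitude[np.isfinite(self.amplitude)]
        if finite.size and finite.min() <= 0:
            raise ValueError("cell amplitudes must be > 0 wherever present")


@dataclass(eq=False)
class ContractionEvent:
    """One connected cluster of contraction cells and its derived features.

    Cells are parallel arrays of position index, frame index and amplitude;
    positions/times in physical units come from ``dx_mm``/``dt_s``. Feature
    fields are filled by :func:`motilimap.classify.event_features` and the
    type label by :func:`motilimap.classify.classify_event`.
    """

    id: int
    pos_idx: np.ndarray
    t_idx: np.ndarray
    amp_mm: np.ndarray
    dx_mm: float
    dt_s: float
    # derived features (classify module)
    initiation_site_mm: float | None = None
    initiation_site_frac: float | None = None
    distance_mm: float | None = None
    distance_frac: float | None = None
    duration_s: float | None = None
    amplitude_pct: float | None = None
    slope_mm_per_s: float | None = None
    r2: float | None = None
    velocity_mm_per_s: float | None = None
    direction: str | None = None
    type: str | None = None
    segment: int | None = None

    def __post_init__(self) -> None:
        self.pos_idx = np.asarray(self.pos_idx, dtype=int)
        self.t_idx = np.asarray(self.t_idx, dtype=int)
        self.amp_mm = np.asarray(self.amp_mm, dtype=float)
        if not (self.pos_idx.size == self.t_idx.size == self.amp_mm.size > 0):
            raise ValueError("an event needs >= 1 cell with matching arrays")

    @property
    def n_cells(self) -> int:
        return self.pos_idx.size

    @property
    def pos_mm(self) -> np.ndarray:
        """Bin-centre positions of the cells (mm, oral end = 0)."""
        return (self.pos_idx + 0.5) * self.dx_mm

    @property
    def time_s(self) -> np.ndarray:
        return self.t_idx * self.dt_s


# ---------------------------------------------------------------------------
# per-frame extraction


def find_local_minima(profile: np.ndarray, depth_threshold: float) -> np.ndarray:
    """Indices of local diameter minima at least ``depth_threshold`` deep.

    Depth is the prominence of the minimum: its diameter relative to the
    lower of its two flanking local maxima. Plateau minima are returned in
    full. Missing (NaN) samples split the profile; stretches shorter than 3
    finite samples yield nothing, and profile edges cannot be minima.
    """
    profile = np.asarray(profile, dtype=float)
    out: list[np.ndarray] = []
    for start, stop in _finite_runs(profile):
        if stop - start < 3:
            continue
        seg = profile[start:stop]
        _, props = signal.find_peaks(
            -seg, prominence=depth_threshold, plateau_size=(1, None)
        )
        for le, re in zip(props["left_edges"], props["right_edges"]):
            out.append(np.arange(start + le, start + re + 1))
    if not out:
        return np.array([], dtype=int)
    return np.unique(np.concatenate(out))


def _finite_runs(x: np.ndarray):
    """(start, stop) index pairs of maximal finite stretches of ``x``."""
    finite = np.isfinite(x)
    padded = np.concatenate(([False], finite, [False]))
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    stops = np.flatnonzero(d == -1)
    return list(zip(starts, stops))


def _group_runs(indices: np.ndarray) -> list[np.ndarray]:
    """Split a sorted index array into maximal consecutive runs."""
    if indices.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(indices) > 1)
    return np.split(indices, breaks + 1)


def extend_minima(
    profile: np.ndarray, minima: np.ndarray, similarity_tol: float
) -> np.ndarray:
    """Grow each detected minimum to neighbours of similar diameter.

    Each minimum (plateau) extends to the maximal contiguous run of finite
    neighbours whose diameter is within ``similarity_tol`` of the minimum's
    value. Returns the sorted union of all runs.
    """
    profile = np.asarray(profile, dtype=float)
    minima = np.asarray(minima, dtype=int)
    if minima.size == 0:
        return np.array([], dtype=int)
    cells: set[int] = set()
    for run in _group_runs(minima):
        v = float(np.min(profile[run]))
        lo, hi = int(run[0]), int(run[-1])
        while lo - 1 >= 0 and np.isfinite(profile[lo - 1]) and abs(profile[lo - 1] - v) <= similarity_tol:
            lo -= 1
        while (
            hi + 1 < profile.size
            and np.isfinite(profile[hi + 1])
            and abs(profile[hi + 1] - v) <= similarity_tol
        ):
            hi += 1
        cells.update(range(lo, hi + 1))
    return np.array(sorted(cells), dtype=int)


def cell_amplitude(
    profile: np.ndarray, run: np.ndarray, flank: str = "lower"
) -> float:
    """Amplitude (mm) of one contraction run: flanking maximum minus minimum.

    The flanking local maximum on each side is found by walking outward from
    the run edge while the diameter is non-decreasing. ``flank='lower'``
    (default) uses the lower of the two; ``flank='nearest'`` uses the flank
    on the side whose maximum is nearer to the run. A run touching the
    profile edge (or missing data) on one side uses the single available
    flank.
    """
    if flank not in ("lower", "nearest"):
        raise ValueError("flank must be 'lower' or 'nearest'")
    profile = np.asarray(profile, dtype=float)
    run = np.asarray(run, dtype=int)
    v = float(np.min(profile[run]))

    def walk(edge: int, step: int) -> tuple[float, int] | None:
        j = edge
        best = profile[j]
        while 0 <= j + step < profile.size and np.isfinite(profile[j + step]) and profile[j + step] >= best:
            j += step
            best = profile[j]
        if j == edge:  # no rise at all on this side
            return None
        return float(best), abs(j - edge)

    left = walk(int(run[0]), -1)
    right = walk(int(run[-1]), +1)
    if left is None and right is None:
        return 0.0
    if left is None:
        return right[0] - v
    if right is None:
        return left[0] - v
    if flank == "lower":
        return min(left[0], right[0]) - v
    return (left if left[1] <= right[1] else right)[0] - v


def build_cell_matrix(
    dm: DiameterMatrix,
    depth_threshold: float = DEFAULT_DEPTH_THRESHOLD_MM,
    similarity_tol: float | None = None,
    flank: str = "lower",
) -> ContractionCellMatrix:
    """Run minima extraction + similar-diameter extension + amplitude on
    every frame of a diameter matrix.

    ``similarity_tol`` defaults to ``depth_threshold``. Frames whose profile
    is degenerate (fewer than 3 finite samples) simply contribute no cells.
    """
    if similarity_tol is None:
        similarity_tol = depth_threshold
    amp = np.full(dm.values.shape, np.nan)
    for t in range(dm.n_frames):
        profile = dm.values[:, t]
        minima = find_local_minima(profile, depth_threshold)
        if minima.size == 0:
            continue
        cells = extend_minima(profile, minima, similarity_tol)
        for run in _group_runs(cells):
            a = cell_amplitude(profile, run, flank=flank)
            if a > 0:
                amp[run, t] = a
    return ContractionCellMatrix(
        amp,
        dx_mm=dm.dx_mm,
        dt_s=dm.dt_s,
        total_length_mm=float(dm.total_length_mm),
        depth_threshold=depth_threshold,
        similarity_tol=similarity_tol,
    )


# ---------------------------------------------------------------------------
# event labeling


def label_events(cm: ContractionCellMatrix, connectivity: int = 8) -> list[ContractionEvent]:
    """Group contraction cells into events by connected-component labeling.

    Under the default 8-connectivity diagonal moves join cells across
    frames, so a contraction advancing one bin per frame stays one event;
    under 4-connectivity a strictly diagonal chain splits into one event
    per cell. An isolated single-frame run is one event. The returned
    events partition the cells.
    """
    if connectivity == 8:
        structure = np.ones((3, 3), dtype=int)
    elif connectivity == 4:
        structure = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]])
    else:
        raise ValueError("connectivity must be 4 or 8")
    mask = np.isfinite(cm.amplitude)
    labels, n = ndimage.label(mask, structure=structure)
    events = []
    for lab in range(1, n + 1):
        pos_idx, t_idx = np.nonzero(labels == lab)
        events.append(
            ContractionEvent(
                id=lab,
                pos_idx=pos_idx,
                t_idx=t_idx,
                amp_mm=cm.amplitude[pos_idx, t_idx],
                dx_mm=cm.dx_mm,
                dt_s=cm.dt_s,
            )
        )
    return events


def filter_events(
    events: list[ContractionEvent],
    min_amplitude_frac: float = 0.05,
    min_duration_s: float = 0.0,
) -> list[ContractionEvent]:
    """Drop events below a relative-amplitude (and optional duration) floor.

    ``min_amplitude_frac`` is compared against the event's peak amplitude
    relative to the local maximum diameter (``amplitude_pct``/100, filled by
    the classify module); 0 disables the floor. The defaults echo the
    smallest relative amplitude observed in practice (5%).
    """
    kept = []
    for ev in events:
        if min_amplitude_frac > 0:
            if ev.amplitude_pct is None:
                raise ValueError(
                    f"event {ev.id}: amplitude_pct not computed; run event_features first"
                )
            if ev.amplitude_pct / 100.0 < min_amplitude_frac:
                continue
        dur = ev.duration_s
        if dur is None:
            dur = (ev.t_idx.max() - ev.t_idx.min()) * ev.dt_s
        if dur < min_duration_s:
            continue
        kept.append(ev)
    return kept


# ---------------------------------------------------------------------------
# tabular export


def events_to_dataframe(events: list[ContractionEvent]):
    """One row per event with all derived features."""
    import pandas as pd

    cols = [
        "id",
        "n_cells",
        "onset_time_s",
        "initiation_site_mm",
        "initiation_site_frac",
        "distance_mm",
        "distance_frac",
        "duration_s",
        "amplitude_pct",
        "slope_mm_per_s",
        "r2",
        "velocity_mm_per_s",
        "direction",
        "type",
        "segment",
    ]
    rows = []
    for ev in events:
        row = {c: getattr(ev, c, None) for c in cols}
        row["n_cells"] = ev.n_cells
        row["onset_time_s"] = float(ev.time_s.min())
        rows.append(row)
    return pd.DataFrame(rows, columns=cols)


def cells_to_dataframe(events: list[ContractionEvent]):
    """One row per contraction cell: event id, position, time, amplitude."""
    import pandas as pd

    rows = []
    for ev in events:
        for p, t, a in zip(ev.pos_mm, ev.time_s, ev.amp_mm):
            rows.append(
                {"event_id": ev.id, "position_mm": p, "time_s": t, "amplitude_mm": a}
            )
    return pd.DataFrame(rows, columns=["event_id", "position_mm", "time_s", "amplitude_mm"])
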