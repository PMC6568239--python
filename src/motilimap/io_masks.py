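"""Mask-stack input and diameter measurement.

Converts time-lapse stacks of binary intestine masks into calibrated
diameter matrices (position along the gut x time) and whole-gut length
traces, and reads/writes diameter matrices as delimited text.

Conventions: the long (oral-anal) axis of the intestine runs along image
rows with the oral end at row 0; the transverse axis runs along columns.
Missing measurements are ``NaN``, never 0, so that longitudinal shortening
is not mistaken for a contraction.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "MaskStack",
    "DiameterMatrix",
    "LengthTrace",
    "load_mask_stack",
    "threshold_frames",
    "downsample_frames",
    "measure_diameters",
    "measure_length",
    "read_diameter_matrix",
    "write_diameter_matrix",
    "write_length_trace",
    "read_length_trace",
]

MISSING_TOKEN = "NA"


class CalibrationError(ValueError):
    """Raised when a stack lacks the spatial/temporal calibration needed."""


class ParseError(ValueError):
    """Raised on malformed delimited-text input; names the offending cell."""


@dataclass(eq=False)
class MaskStack:
    """An ordered stack of binary segmentation masks of one intestine.

    Parameters
    ----------
    frames : ndarray of bool, shape (n_frames, n_rows, n_cols)
        Foreground (True) marks the intestine.
    px_per_mm : float
        Spatial calibration, pixels per millimetre (> 0).
    fps : float
        Frames per second of this stack as provided (> 0).
    oral_at_row0 : bool
        Orientation flag: True when the oral end is at row 0 and the long
        axis runs along rows (the default mounting, oral end up).
    """

    frames: np.ndarray
    px_per_mm: float
    fps: float
    oral_at_row0: bool = True

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=bool)
        if self.frames.ndim != 3:
            raise ValueError("frames must be a (n_frames, rows, cols) array")
        if not self.px_per_mm > 0:
            raise CalibrationError("px_per_mm must be > 0")
        if not self.fps > 0:
            raise CalibrationError("fps must be > 0")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    def degenerate_frames(self) -> np.ndarray:
        """Indices of frames with an empty foreground."""
        return np.flatnonzero(~self.frames.any(axis=(1, 2)))

    def oriented(self) -> "MaskStack":
        """Return a copy with the oral end at row 0 (flip rows if needed)."""
        if self.oral_at_row0:
            return self
        return replace(self, frames=self.frames[:, ::-1, :], oral_at_row0=True)


@dataclass(eq=False)
class DiameterMatrix:
    """Positions x frames grid of intestinal diameters in mm.

    Rows are positions along the intestine (oral end first), columns are
    analysed frames. Missing measurements are NaN. ``total_length_mm`` is
    the reference gut length used for fractional positions.
    """

    values: np.ndarray
    dx_mm: float = 0.5
    dt_s: float = 1 / 1.2
    total_length_mm: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (positions x frames)")
        if not (self.dx_mm > 0 and self.dt_s > 0):
            raise CalibrationError("dx_mm and dt_s must be > 0")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.values, initial=0.0) < 0:
                raise ValueError("diameters must be >= 0 (missing values are NaN)")
        if self.total_length_mm is None:
            self.total_length_mm = self.values.shape[0] * self.dx_mm

    @property
    def n_positions(self) -> int:
        return self.values.shape[0]

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]

    @property
    def positions_mm(self) -> np.ndarray:
        """Bin-centre positions along the gut in mm (oral end = 0)."""
        return (np.arange(self.n_positions) + 0.5) * self.dx_mm

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_s


@dataclass(eq=False)
class LengthTrace:
    """Per-frame total intestine length in mm; NaN for empty frames."""

    length_mm: np.ndarray
    dt_s: float

    def __post_init__(self) -> None:
        self.length_mm = np.asarray(self.length_mm, dtype=float)
        if self.length_mm.ndim != 1:
            raise ValueError("length_mm must be 1-D")
        if not self.dt_s > 0:
            raise CalibrationError("dt_s must be > 0")

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.length_mm.size) * self.dt_s


# ---------------------------------------------------------------------------
# loading


def threshold_frames(images: np.ndarray, threshold: float) -> np.ndarray:
    """Fixed-threshold convenience binarization (foreground = intensity >= t).

    Provided for convenience only; the analysis expects pre-segmented masks.
    """
    return np.asarray(images) >= threshold


def load_mask_stack(
    path: str,
    px_per_mm: float | None = None,
    fps: float | None = None,
    oral_at_row0: bool | None = None,
) -> MaskStack:
    """Load a mask stack from a multi-page TIFF or a directory of images.

    Calibration is taken from the arguments, falling back to a sidecar
    ``<path>.yaml``/``.json`` (or ``metadata.yaml``/``.json`` inside a
    directory) with keys ``px_per_mm``, ``fps`` and optional
    ``oral_at_row0``.
    """
    import tifffile

    meta = _read_sidecar(path)
    px_per_mm = px_per_mm if px_per_mm is not None else meta.get("px_per_mm")
    fps = fps if fps is not None else meta.get("fps")
    if oral_at_row0 is None:
        oral_at_row0 = bool(meta.get("oral_at_row0", True))
    if px_per_mm is None or fps is None:
        raise CalibrationError(
            f"px_per_mm and fps required (not found in arguments or sidecar for {path})"
        )

    if os.path.isdir(path):
        import imageio.v3 as iio

        names = sorted(
            f
            for f in os.listdir(path)
            if f.lower().endswith((".png", ".tif", ".tiff"))
        )
        if not names:
            raise FileNotFoundError(f"no PNG/TIFF frames in directory {path}")
        frames = np.stack(
            [np.asarray(iio.imread(os.path.join(path, n))) for n in names]
        )
    else:
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
    if frames.ndim == 4:  # RGB(A): any nonzero channel is foreground
        frames = frames.any(axis=-1)
    return MaskStack(frames > 0, float(px_per_mm), float(fps), oral_at_row0)


def _read_sidecar(path: str) -> dict:
    import json

    import yaml

    candidates = []
    if os.path.isdir(path):
        candidates = [os.path.join(path, "metadata" + ext) for ext in (".yaml", ".yml", ".json")]
    else:
        stem = os.path.splitext(path)[0]
        candidates = [stem + ext for ext in (".yaml", ".yml", ".json")]
        candidates += [path + ext for ext in (".yaml", ".yml", ".json")]
    for cand in candidates:
        if os.path.exists(cand):
            with open(cand) as fh:
                if cand.endswith(".json"):
                    return json.load(fh)
                return yaml.safe_load(fh) or {}
    return {}


# ---------------------------------------------------------------------------
# frame downsampling


def downsample_frames(stack: MaskStack, keep_every: int) -> MaskStack:
    """Keep frames 0, keep_every, 2*keep_every, ... and divide fps accordingly.

    The acquisition protocol records at 3.5 frames/s and analyses every third
    frame (~1.2 frames/s); ``keep_every=3`` reproduces that.
    """
    if not isinstance(keep_every, (int, np.integer)) or keep_every < 1:
        raise ValueError(f"keep_every must be a positive integer, got {keep_every!r}")
    if keep_every == 1:
        return stack
    return replace(
        stack,
        frames=stack.frames[::keep_every],
        fps=stack.fps / keep_every,
    )


# ---------------------------------------------------------------------------
# measurement


def _row_extents_px(frame: np.ndarray) -> np.ndarray:
    """Per-row transverse extent (outermost-foreground distance, px).

    Rows without foreground get 0. The extent counts pixels inclusively:
    a 12-px-wide band has extent 12.
    """
    any_fg = frame.any(axis=1)
    first = frame.argmax(axis=1)
    last = frame.shape[1] - 1 - frame[:, ::-1].argmax(axis=1)
    ext = np.where(any_fg, last - first + 1, 0)
    return ext.astype(float)


def measure_diameters(
    stack: MaskStack,
    roi_width_mm: float = 0.5,
    reducer: str = "max",
) -> DiameterMatrix:
    """Sample intestinal diameter in transverse bins of width ``roi_width_mm``.

    For each frame, the long axis (rows) is split into consecutive bins of
    ``roi_width_mm``; the diameter of a bin is the transverse extent of the
    foreground within it (distance between the outermost foreground pixels
    across the bin), reduced over the bin's rows with ``reducer`` ('max',
    the default, or 'mean' over foreground rows). Bins beyond the
    intestine's extent in a frame are NaN.
    """
    if not roi_width_mm > 0:
        raise ValueError("roi_width_mm must be > 0")
    if reducer not in ("max", "mean"):
        raise ValueError("reducer must be 'max' or 'mean'")
    stack = stack.oriented()
    bin_px = int(round(roi_width_mm * stack.px_per_mm))
    if bin_px < 1:
        raise CalibrationError(
            f"roi_width_mm={roi_width_mm} is below one pixel at {stack.px_per_mm} px/mm"
        )
    n_rows = stack.frames.shape[1]
    n_bins = n_rows // bin_px
    if n_bins == 0:
        raise ValueError("image shorter than one ROI bin along the long axis")

    out = np.full((n_bins, stack.n_frames), np.nan)
    for t in range(stack.n_frames):
        ext = _row_extents_px(stack.frames[t])[: n_bins * bin_px]
        ext = ext.reshape(n_bins, bin_px)
        has_fg = ext > 0
        any_fg = has_fg.any(axis=1)
        if reducer == "max":
            vals = ext.max(axis=1)
        else:
            with np.errstate(invalid="ignore"):
                vals = np.where(
                    any_fg, ext.sum(axis=1) / np.maximum(has_fg.sum(axis=1), 1), 0.0
                )
        out[any_fg, t] = vals[any_fg] / stack.px_per_mm

    # reference length: the largest longitudinal extent seen over the series
    lt = measure_length(stack)
    total = float(np.nanmax(lt.length_mm)) if np.isfinite(lt.length_mm).any() else None
    return DiameterMatrix(
        out, dx_mm=roi_width_mm, dt_s=1.0 / stack.fps, total_length_mm=total
    )


def measure_length(stack: MaskStack) -> LengthTrace:
    """Per-frame intestine length: longitudinal foreground extent in mm."""
    stack = stack.oriented()
    lengths = np.full(stack.n_frames, np.nan)
    for t, frame in enumerate(stack.frames):
        rows = np.flatnonzero(frame.any(axis=1))
        if rows.size:
            lengths[t] = (rows[-1] - rows[0] + 1) / stack.px_per_mm
    if np.isnan(lengths).any():
        warnings.warn("empty frames in stack: length trace contains NaN")
    return LengthTrace(lengths, dt_s=1.0 / stack.fps)


# ---------------------------------------------------------------------------
# delimited-text round trip


def write_diameter_matrix(dm: DiameterMatrix, path: str, sep: str = ",") -> None:
    """Write a diameter matrix as delimited text (rows = positions).

    The first line is a ``#`` metadata comment with the calibration; the
    second is a header of frame times in seconds. Missing cells are 'NA'.
    """
    with open(path, "w") as fh:
        fh.write(
            f"# dx_mm={dm.dx_mm!r} dt_s={dm.dt_s!r} total_length_mm={dm.total_length_mm!r}\n"
        )
        fh.write(sep.join(f"{t!r}" for t in dm.times_s.tolist()) + "\n")
        for row in dm.values:
            fh.write(
                sep.join(MISSING_TOKEN if np.isnan(v) else repr(v) for v in row.tolist())
                + "\n"
            )


def read_diameter_matrix(
    path: str,
    dx_mm: float | None = None,
    dt_s: float | None = None,
    sep: str = ",",
) -> DiameterMatrix:
    """Read a delimited-text diameter matrix written by `write_diameter_matrix`
    or any plain numeric grid (rows = positions, columns = frames).

    Calibration comes from the ``#`` metadata line when present, else from
    the arguments. A leading numeric header row of times, if present, is
    used to infer ``dt_s``.
    """
    meta: dict = {}
    rows: list[list[float]] = []
    header_times: list[float] | None = None
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    start = 0
    if lines and lines[0].startswith("#"):
        for tok in lines[0][1:].split():
            if "=" in tok:
                k, v = tok.split("=", 1)
                meta[k] = None if v == "None" else float(v)
        start = 1

    data_lines = lines[start:]
    n_cols = None
    for i, ln in enumerate(data_lines):
        cells = [c.strip() for c in ln.split(sep)]
        parsed: list[float] = []
        bad_col = None
        for j, c in enumerate(cells):
            if c == MISSING_TOKEN:
                parsed.append(np.nan)
                continue
            try:
                parsed.append(float(c))
            except ValueError:
                bad_col = j
                break
        if bad_col is not None:
            if i == 0 and header_times is None and not rows:
                raise ParseError(
                    f"{path}: non-numeric cell {cells[bad_col]!r} at row 1, column {bad_col + 1}"
                )
            raise ParseError(
                f"{path}: non-numeric cell {cells[bad_col]!r} at row {i + 1}, column {bad_col + 1}"
            )
        if n_cols is None:
            n_cols = len(parsed)
        elif len(parsed) != n_cols:
            raise ParseError(
                f"{path}: ragged row {i + 1} has {len(parsed)} cells, expected {n_cols}"
            )
        rows.append(parsed)

    if not rows:
        raise ParseError(f"{path}: no data rows")
    # a uniformly spaced time row starting at 0 is a header (as written by
    # write_diameter_matrix); data rows are diameters and never start at 0 s
    first = np.array(rows[0])
    if (
        len(rows) > 1
        and not np.isnan(first).any()
        and first.size > 1
        and first[0] == 0.0
        and np.all(np.diff(first) > 0)
        and np.allclose(np.diff(first), first[1] - first[0])
    ):
        header_times = rows[0]
        rows = rows[1:]

    values = np.array(rows, dtype=float)
    if header_times is not None and dt_s is None and "dt_s" not in meta:
        meta["dt_s"] = header_times[1] - header_times[0] if len(header_times) > 1 else None
    dx = meta.get("dx_mm", dx_mm)
    dt = meta.get("dt_s", dt_s)
    if dx is None or dt is None:
        raise CalibrationError(f"{path}: dx_mm/dt_s not in file metadata; pass them explicitly")
    return DiameterMatrix(
        values, dx_mm=dx, dt_s=dt, total_length_mm=meta.get("total_length_mm")
    )


def write_length_trace(trace: LengthTrace, path: str, sep: str = ",") -> None:
    with open(path, "w") as fh:
        fh.write(f"# dt_s={trace.dt_s!r}\n")
        fh.write(f"time_s{sep}length_mm\n")
        for t, l in zip(trace.times_s.tolist(), trace.length_mm.tolist()):
            fh.write(f"{t!r}{sep}{MISSING_TOKEN if np.isnan(l) else repr(l)}\n")


def read_length_trace(path: str, sep: str = ",") -> LengthTrace:
    with open(path) as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    dt = None
    if lines and lines[0].startswith("#"):
        for tok in lines[0][1:].split():
            if tok.startswith("dt_s="):
                dt = float(tok.split("=", 1)[1])
        lines = lines[1:]
    if lines and lines[0].startswith("time_s"):
        lines = lines[1:]
    times, lengths = [], []
    for i, ln in enumerate(lines):
        cells = ln.split(sep)
        if len(cells) != 2:
            raise ParseError(f"{path}: row {i + 1} has {len(cells)} cells, expected 2")
        times.append(float(cells[0]))
        lengths.append(np.nan if cells[1] == MISSING_TOKEN else float(cells[1]))
    if dt is None:
        dt = times[1] - times[0] if len(times) > 1 else 1.0
    return LengthTrace(np.array(lengths), dt_s=dt)
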