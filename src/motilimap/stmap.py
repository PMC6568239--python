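"""Gray-scale and binary spatio-temporal (ST) map construction.

An ST map displays gut diameter with position along the intestine on one
axis and time on the other; contractions appear as dark bands. The
gray-scale map is built from the diameter matrix after per-position
temporal normalization and spatial linear interpolation (interpolation is
for rendering only -- detection runs on the native grid). The binary map
colors detected contraction events by type on the native grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .io_masks import DiameterMatrix

__all__ = [
    "NormalizedMatrix",
    "normalize",
    "interpolate_spatial",
    "render_gray_map",
    "render_binary_map",
    "save_png",
]

#: sentinel RGB for missing cells, outside the gray ramp
MISSING_COLOR = (255, 128, 0)

#: event-type colors on the binary map (background is white)
TYPE_COLORS = {
    "standing": (0, 0, 0),
    "ripple": (255, 0, 0),
    "slow": (0, 160, 0),
}


@dataclass(eq=False)
class NormalizedMatrix:
    """Diameter deviations (mm) after subtracting a per-position temporal mean."""

    values: np.ndarray
    dx_mm: float
    dt_s: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (positions x frames)")


def normalize(dm: DiameterMatrix | NormalizedMatrix, per_position: bool = True) -> NormalizedMatrix:
    """Subtract the average diameter over the recorded period from each cell.

    By default the mean is per position over its non-missing frames, so
    each row of the output has (numerically) zero temporal mean. With
    ``per_position=False`` a single global mean is subtracted instead.
    Missing cells stay missing; an all-missing row stays missing with a
    warning.
    """
    values = np.asarray(dm.values, dtype=float)
    if values.shape[1] < 2:
        raise ValueError("normalization needs at least 2 frames")
    if per_position:
        all_missing = np.isnan(values).all(axis=1)
        if all_missing.any():
            warnings.warn(
                f"{int(all_missing.sum())} all-missing position row(s) left missing"
            )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            means = np.nanmean(values, axis=1, keepdims=True)
        means = np.where(np.isnan(means), 0.0, means)
        out = values - means
    else:
        out = values - np.nanmean(values)
    return NormalizedMatrix(out, dx_mm=dm.dx_mm, dt_s=dm.dt_s)


def interpolate_spatial(m: NormalizedMatrix, n_insert: int = 9) -> NormalizedMatrix:
    """Insert ``n_insert`` equally spaced linear interpolants between each
    pair of adjacent positions, per frame (default nine, the smoothing used
    for the gray-scale maps).

    Output row count is ``(n-1)*(n_insert+1)+1`` and ``dx_mm`` is divided
    by ``n_insert+1``. Original samples are preserved exactly at their grid
    points; a pair with a missing endpoint yields missing interpolants.
    """
    if n_insert < 0:
        raise ValueError("n_insert must be >= 0")
    if m.values.shape[0] < 2:
        raise ValueError("interpolation needs at least 2 positions")
    if n_insert == 0:
        return NormalizedMatrix(m.values.copy(), m.dx_mm, m.dt_s)

    step = n_insert + 1
    n, t = m.values.shape
    out = np.full(((n - 1) * step + 1, t), np.nan)
    out[::step] = m.values
    w = (np.arange(1, step) / step)[:, None, None]  # (n_insert, 1, 1)
    a = m.values[:-1][None]  # (1, n-1, t)
    b = m.values[1:][None]
    interp = (1 - w) * a + w * b  # NaN endpoints propagate
    for k in range(n_insert):
        out[k + 1 :: step][: n - 1] = interp[k]
    return NormalizedMatrix(out, dx_mm=m.dx_mm / step, dt_s=m.dt_s)


def render_gray_map(m: NormalizedMatrix) -> np.ndarray:
    """Render a normalized matrix as an 8-bit image.

    Returns an RGB uint8 array of shape (n_frames, n_positions, 3): time
    runs down the vertical axis, position along the horizontal axis. The
    minimum value maps to black (0), the maximum to white (255), linearly
    in between (a value halfway between rounds to 128). Missing cells get
    the sentinel `MISSING_COLOR`. A constant matrix renders mid-gray (128)
    with a warning.
    """
    vals = m.values.T  # (frames, positions)
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValueError("no finite values to render")
    lo, hi = np.nanmin(vals), np.nanmax(vals)
    if hi == lo:
        warnings.warn("constant matrix: rendering uniform mid-gray")
        gray = np.full(vals.shape, 128, dtype=np.uint8)
    else:
        with np.errstate(invalid="ignore"):
            gray = np.round((vals - lo) / (hi - lo) * 255.0)
        gray = np.where(finite, gray, 0).astype(np.uint8)
    img = np.repeat(gray[:, :, None], 3, axis=2)
    img[~finite] = MISSING_COLOR
    return img


def render_binary_map(events, shape: tuple[int, int]) -> np.ndarray:
    """Render classified contraction events as a binary ST map.

    ``shape`` is the native (n_positions, n_frames) grid of the source
    diameter matrix (no interpolation). Background is white; each event's
    cells are colored by its type (standing black, ripples red, slow
    propagating green). Events are drawn in list order, so on overlap the
    later event in the list wins.
    """
    n_pos, n_frames = shape
    img = np.full((n_frames, n_pos, 3), 255, dtype=np.uint8)
    for ev in events:
        color = TYPE_COLORS.get(ev.type)
        if color is None:
            raise ValueError(f"event {ev.id}: unclassified or unknown type {ev.type!r}")
        pos_idx = np.asarray(ev.pos_idx)
        t_idx = np.asarray(ev.t_idx)
        if (
            pos_idx.min() < 0
            or pos_idx.max() >= n_pos
            or t_idx.min() < 0
            or t_idx.max() >= n_frames
        ):
            raise ValueError(f"event {ev.id}: cell outside the {shape} grid")
        img[t_idx, pos_idx] = color
    return img


def save_png(img: np.ndarray, path: str) -> None:
    """Write an RGB uint8 image to PNG."""
    import imageio.v3 as iio

    iio.imwrite(path, img)
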