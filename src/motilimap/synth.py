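"""Synthetic kymograph generation with known ground truth.

Generates diameter matrices, mask stacks and length traces containing
injected contraction events of the three motility types, so that detection,
classification and the pre/post statistics can be tested end to end without
recorded videos.

The generative model subtracts, from a baseline diameter profile ``D0(x)``
(an oral-bulbous linear taper by default), one localized narrowing per
event::

    D(x, t) = D0(x) * (1 - sum_e  a_e * K((x - c_e(t)) / w_e) * H_e(t)) + noise

where ``a_e`` is the relative amplitude, ``K`` a spatial kernel (Gaussian,
or a square pulse for threshold edge cases), ``H_e`` a temporal envelope
(smooth raised-cosine ramps or square), and ``c_e(t)`` the contraction
centre, moving at the event's velocity from its initiation site. Slow
propagating events add a cosine waviness (integer number of cycles, so the
wave is orthogonal to the linear trend and the path's best-fit slope stays
exactly the drift velocity) that pushes the path's linearity (r^2) below
the ripple threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .classify import SegmentScheme
from .detect import ContractionEvent
from .io_masks import DiameterMatrix, LengthTrace, MaskStack

__all__ = [
    "GroundTruthEvent",
    "SimulationSpec",
    "baseline_profile",
    "generate_matrix",
    "generate_masks",
    "generate_length_trace",
    "simulate_single_event",
    "sample_segment_counts",
    "ground_truth_to_contractions",
]


@dataclass
class GroundTruthEvent:
    """A simulator record of one injected contraction.

    ``amplitude_frac`` is the fractional narrowing of the local baseline
    diameter (0-1). ``halfwidth_mm`` is the spatial kernel scale: the
    Gaussian sigma, or the half-width of the square pulse. Waviness
    (``wave_amp_mm`` over ``wave_cycles`` full cosine cycles) models the
    irregular path of slow propagating contractions.
    """

    type: str  # standing | ripple | slow
    onset_time_s: float
    initiation_site_mm: float
    velocity_mm_per_s: float
    direction: str  # anterograde | retrograde | none
    duration_s: float
    amplitude_frac: float
    halfwidth_mm: float
    kernel: str = "gaussian"  # gaussian | square
    envelope: str = "smooth"  # smooth | square
    wave_amp_mm: float = 0.0
    wave_cycles: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.amplitude_frac < 1:
            raise ValueError("amplitude_frac must be in (0, 1)")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be > 0")
        if self.velocity_mm_per_s < 0:
            raise ValueError("velocity_mm_per_s must be >= 0")
        if self.kernel not in ("gaussian", "square"):
            raise ValueError("kernel must be 'gaussian' or 'square'")
        if self.envelope not in ("smooth", "square"):
            raise ValueError("envelope must be 'smooth' or 'square'")

    @property
    def sign(self) -> int:
        return {"anterograde": 1, "retrograde": -1}.get(self.direction, 0)

    def center_path(self, t_rel: np.ndarray) -> np.ndarray:
        """Contraction centre (mm) at times ``t_rel`` since onset."""
        t_rel = np.asarray(t_rel, dtype=float)
        c = self.initiation_site_mm + self.sign * self.velocity_mm_per_s * t_rel
        if self.wave_amp_mm and self.wave_cycles:
            # integer-cycle cosine centred on the event midpoint: even about
            # the midpoint, hence orthogonal to the linear trend
            T = self.duration_s
            c = c + self.wave_amp_mm * (
                np.cos(2 * np.pi * self.wave_cycles * (t_rel - T / 2) / T)
                - np.cos(np.pi * self.wave_cycles)  # start/end at offset 0
            )
        return c

    def envelope_at(self, t_rel: np.ndarray) -> np.ndarray:
        t_rel = np.asarray(t_rel, dtype=float)
        eps = 1e-9 * max(1.0, self.duration_s)  # guard frame-grid rounding
        active = (t_rel >= -eps) & (t_rel <= self.duration_s + eps)
        if self.envelope == "square":
            return active.astype(float)
        ramp = min(5.0, self.duration_s / 4.0)
        h = np.ones_like(t_rel)
        if ramp > 0:
            up = np.clip(t_rel / ramp, 0, 1)
            down = np.clip((self.duration_s - t_rel) / ramp, 0, 1)
            h = 0.5 * (1 - np.cos(np.pi * up)) * 0.5 * (1 - np.cos(np.pi * down)) * 4
            h = np.minimum(h, 1.0)
        return np.where(active, h, 0.0)

    def kernel_at(self, x: np.ndarray, c: float) -> np.ndarray:
        d = np.abs(np.asarray(x, dtype=float) - c)
        if self.kernel == "square":
            return (d <= self.halfwidth_mm).astype(float)
        return np.exp(-0.5 * (d / self.halfwidth_mm) ** 2)

    def path_regression(self, dt_s: float) -> tuple[float, float | None]:
        """Best-fit slope and r^2 of the noiseless centre path sampled at
        the frame interval -- the generative ground truth for velocity and
        linearity."""
        n = max(int(math.floor(self.duration_s / dt_s + 1e-9)), 1)
        t = np.arange(n + 1) * dt_s
        c = self.center_path(t)
        st = t.var()
        if st == 0:
            return 0.0, None
        cov = ((t - t.mean()) * (c - c.mean())).mean()
        slope = cov / st
        sc = c.var()
        r2 = None if sc == 0 else float(cov * cov / (st * sc))
        return float(slope), r2


@dataclass
class SimulationSpec:
    """Geometry, calibration and noise of one simulated recording.

    Defaults mirror the study geometry: a 60 mm intestine sampled in 0.5 mm
    bins at 1.2 frames/s, with an oral-bulbous taper from 3.0 mm down to
    1.5 mm. ``profile='flat'`` gives a constant baseline at the mean
    diameter, used for controlled parameter-recovery experiments.
    """

    length_mm: float = 60.0
    dx_mm: float = 0.5
    dt_s: float = 1 / 1.2
    n_frames: int = 720  # 10 minutes
    d_oral_mm: float = 3.0
    d_anal_mm: float = 1.5
    profile: str = "taper"  # taper | flat
    noise_sd_mm: float = 0.0
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.length_mm <= 0 or self.dx_mm <= 0 or self.dt_s <= 0:
            raise ValueError("length_mm, dx_mm, dt_s must be > 0")
        if self.n_frames < 1:
            raise ValueError("n_frames must be >= 1")
        if self.profile not in ("taper", "flat"):
            raise ValueError("profile must be 'taper' or 'flat'")
        if self.noise_sd_mm < 0:
            raise ValueError("noise_sd_mm must be >= 0")

    @property
    def n_positions(self) -> int:
        return int(round(self.length_mm / self.dx_mm))

    @property
    def positions_mm(self) -> np.ndarray:
        return (np.arange(self.n_positions) + 0.5) * self.dx_mm

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.dt_s


def baseline_profile(spec: SimulationSpec) -> np.ndarray:
    """Baseline diameter D0(x) over the spec's position bins."""
    x = spec.positions_mm
    if spec.profile == "flat":
        return np.full(x.shape, 0.5 * (spec.d_oral_mm + spec.d_anal_mm))
    frac = x / spec.length_mm
    return spec.d_oral_mm + (spec.d_anal_mm - spec.d_oral_mm) * frac


def generate_matrix(
    spec: SimulationSpec,
    events: list[GroundTruthEvent] | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[DiameterMatrix, list[GroundTruthEvent]]:
    """Render a diameter matrix with the given injected events.

    Identical spec + seed give bit-identical output. Overlapping events are
    allowed but flagged with a warning. Values are clipped at >= 0.
    """
    events = list(events or [])
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    x = spec.positions_mm
    t = spec.times_s
    d0 = baseline_profile(spec)
    values = np.tile(d0[:, None], (1, spec.n_frames))

    footprints = []
    for ev in events:
        t_rel = t - ev.onset_time_s
        h = ev.envelope_at(t_rel)
        active = np.flatnonzero(h > 0)
        dip = np.zeros_like(values)
        centres = ev.center_path(t_rel[active])
        for j, ti in enumerate(active):
            dip[:, ti] = ev.amplitude_frac * d0 * ev.kernel_at(x, centres[j]) * h[ti]
        values -= dip
        footprints.append(dip > 1e-12)

    for i in range(len(footprints)):
        for j in range(i + 1, len(footprints)):
            if (footprints[i] & footprints[j]).any():
                warnings.warn(f"events {i} and {j} overlap in the matrix")
                break

    if spec.noise_sd_mm > 0:
        values = values + rng.normal(0.0, spec.noise_sd_mm, size=values.shape)
    values = np.clip(values, 0.0, None)
    dm = DiameterMatrix(
        values, dx_mm=spec.dx_mm, dt_s=spec.dt_s, total_length_mm=spec.length_mm
    )
    return dm, events


def generate_masks(dm: DiameterMatrix, px_per_mm: float = 10.0) -> MaskStack:
    """Rasterize a diameter matrix into a symmetric tube mask stack.

    Each position bin becomes ``dx_mm * px_per_mm`` image rows whose
    foreground is a horizontal band of ``round(d * px_per_mm)`` pixels
    centred on a fixed axis, so `measure_diameters` on the result recovers
    the matrix within one pixel-equivalent. NaN diameters yield empty rows.
    """
    if px_per_mm < 10:
        warnings.warn(
            f"px_per_mm={px_per_mm} is coarse; sub-0.1 mm amplitudes may not be resolved"
        )
    rows_per_bin = int(round(dm.dx_mm * px_per_mm))
    if rows_per_bin < 1:
        raise ValueError("px_per_mm too small: a position bin maps to < 1 image row")
    finite = dm.values[np.isfinite(dm.values)]
    max_px = int(np.ceil((finite.max() if finite.size else 1.0) * px_per_mm))
    n_cols = max_px + 8
    centre = n_cols // 2
    n_rows = dm.n_positions * rows_per_bin

    frames = np.zeros((dm.n_frames, n_rows, n_cols), dtype=bool)
    for tix in range(dm.n_frames):
        col = dm.values[:, tix]
        for i, d in enumerate(col):
            if not np.isfinite(d) or d <= 0:
                continue
            w = int(round(d * px_per_mm))
            if w < 1:
                continue
            c0 = centre - w // 2
            frames[tix, i * rows_per_bin : (i + 1) * rows_per_bin, c0 : c0 + w] = True
    return MaskStack(frames, px_per_mm=px_per_mm, fps=1.0 / dm.dt_s)


def generate_length_trace(
    spec: SimulationSpec,
    dips: list[tuple[float, float, float]] | None = None,
    sustained: tuple[float, float] | None = None,
    rng: np.random.Generator | None = None,
    noise_sd_mm: float = 0.0,
) -> tuple[LengthTrace, dict]:
    """Baseline gut length with injected transient dips and an optional
    sustained post-treatment reduction.

    ``dips`` are (time_s, prominence_frac, duration_s) shortening episodes
    (cosine-shaped); ``sustained=(t0, frac)`` drops the baseline by ``frac``
    from time ``t0`` on. Ground truth (injected dips and reduction) is
    returned alongside.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed)
    t = spec.times_s
    length = np.full(t.shape, float(spec.length_mm))
    if sustained is not None:
        t0, frac = sustained
        length[t >= t0] = spec.length_mm * (1.0 - frac)
    for time_s, prom_frac, dur in dips or []:
        rel = (t - time_s) / dur
        inside = (rel >= 0) & (rel <= 1)
        pulse = np.zeros_like(t)
        pulse[inside] = 0.5 * (1 - np.cos(2 * np.pi * rel[inside]))
        length = length - spec.length_mm * prom_frac * pulse
    if noise_sd_mm > 0:
        length = length + rng.normal(0.0, noise_sd_mm, size=length.shape)
    truth = {"dips": list(dips or []), "sustained": sustained}
    return LengthTrace(length, dt_s=spec.dt_s), truth


# ---------------------------------------------------------------------------
# controlled single-event experiments (parameter recovery)

#: velocity ranges (mm/s) of the two propagating types, spanning the
#: observed extremes; sampled log-uniformly
VELOCITY_RANGE = {"ripple": (0.002, 1.694), "slow": (0.001, 1.471)}
#: relative amplitude range common to all types
AMPLITUDE_RANGE = (0.05, 0.85)
#: net path length range (mm) for propagating events; the lower bound keeps
#: a perfectly linear footprint's regression r^2 clear of the 0.8 threshold
#: given the finite spatial width of contraction cells
PATH_RANGE_MM = (5.0, 14.0)


def simulate_single_event(
    rng: np.random.Generator,
    etype: str,
    dx_mm: float = 0.5,
    dt_s: float = 1 / 1.2,
    baseline_mm: float = 2.25,
    noise_sd_mm: float = 0.0,
) -> tuple[DiameterMatrix, GroundTruthEvent, SimulationSpec]:
    """One isolated event of the given type in its own flat-baseline matrix.

    Square spatial and temporal kernels make the injected footprint
    unambiguous, so detection and classification accuracy can be measured
    against exact ground truth. The matrix is sized around the event's path
    with 3 mm spatial and 6-frame temporal margins. Kernel half-widths are
    set from the per-frame step of the centre path so a single event stays
    one 8-connected component.
    """
    amplitude = rng.uniform(*AMPLITUDE_RANGE)
    if etype == "standing":
        velocity = 0.0
        duration = rng.uniform(2.0, 30.0)
        direction = "none"
        halfwidth = 0.25
        wave_amp, wave_cycles = 0.0, 0
    elif etype in ("ripple", "slow"):
        lo, hi = VELOCITY_RANGE[etype]
        velocity = math.exp(rng.uniform(math.log(lo), math.log(hi)))
        path_mm = rng.uniform(*PATH_RANGE_MM)
        duration = path_mm / velocity
        direction = "anterograde" if rng.random() < 0.5 else "retrograde"
        if etype == "ripple":
            wave_amp, wave_cycles = 0.0, 0
            step_mm = velocity * dt_s
            halfwidth = max(1.0, 0.625 * step_mm)
        else:
            r_target = rng.uniform(0.25, 0.6)
            wave_cycles = int(rng.integers(1, 4))
            # wave amplitude giving the target generative r^2:
            # r2 = var_lin / (var_lin + A^2/2), var_lin = (v T)^2 / 12
            wave_amp = path_mm * math.sqrt((1 - r_target) / (6 * r_target))
            step_mm = (velocity + wave_amp * 2 * np.pi * wave_cycles / duration) * dt_s
            halfwidth = max(2.0, 0.625 * step_mm)
    else:
        raise ValueError(f"unknown event type {etype!r}")

    # snap the duration to the frame grid (exact square envelope)
    duration = max(round(duration / dt_s), 3) * dt_s
    t0 = 6 * dt_s
    n_frames = int(round(duration / dt_s)) + 13

    # size the gut around the exact path extent
    probe = GroundTruthEvent(
        type=etype,
        onset_time_s=t0,
        initiation_site_mm=0.0,
        velocity_mm_per_s=velocity,
        direction=direction,
        duration_s=duration,
        amplitude_frac=amplitude,
        halfwidth_mm=halfwidth,
        kernel="square",
        envelope="square",
        wave_amp_mm=wave_amp,
        wave_cycles=wave_cycles,
    )
    t_rel = np.arange(int(round(duration / dt_s)) + 1) * dt_s
    path = probe.center_path(t_rel)
    margin = halfwidth + 3.0
    site = margin - path.min()
    event = replace(probe, initiation_site_mm=site)
    length_mm = (path.max() - path.min()) + 2 * margin

    spec = SimulationSpec(
        length_mm=max(length_mm, 10 * dx_mm),
        dx_mm=dx_mm,
        dt_s=dt_s,
        n_frames=n_frames,
        d_oral_mm=baseline_mm,
        d_anal_mm=baseline_mm,
        profile="flat",
        noise_sd_mm=noise_sd_mm,
    )
    dm, _ = generate_matrix(spec, [event], rng=rng)
    return dm, event, spec


# ---------------------------------------------------------------------------
# rate-based event sampling (statistics-level simulations)


def sample_segment_counts(
    rng: np.random.Generator,
    rates_cpm: np.ndarray,
    window_min: float,
    segment_lengths_mm: np.ndarray,
) -> np.ndarray:
    """Poisson event counts per segment for one window.

    ``rates_cpm`` are contractions per minute per mm of segment length, so
    the Poisson mean per segment is rate * minutes * segment length.
    """
    lam = np.asarray(rates_cpm) * window_min * np.asarray(segment_lengths_mm)
    return rng.poisson(lam)


def ground_truth_to_contractions(
    gts: list[GroundTruthEvent],
    dx_mm: float = 0.5,
    dt_s: float = 1 / 1.2,
    total_length_mm: float = 60.0,
) -> list[ContractionEvent]:
    """Materialize ground-truth events as classified contraction events.

    Builds minimal single-cell events carrying the ground-truth features and
    type label, for exercising the summary and statistics stages directly at
    the event level (no rasterization/detection round trip).
    """
    from .classify import assign_segment

    out = []
    for i, gt in enumerate(gts, start=1):
        slope, r2 = gt.path_regression(dt_s)
        ev = ContractionEvent(
            id=i,
            pos_idx=[int(gt.initiation_site_mm / dx_mm)],
            t_idx=[int(round(gt.onset_time_s / dt_s))],
            amp_mm=[max(gt.amplitude_frac, 1e-6)],
            dx_mm=dx_mm,
            dt_s=dt_s,
        )
        ev.initiation_site_mm = gt.initiation_site_mm
        ev.initiation_site_frac = 100.0 * gt.initiation_site_mm / total_length_mm
        ev.distance_mm = gt.velocity_mm_per_s * gt.duration_s
        ev.distance_frac = 100.0 * ev.distance_mm / total_length_mm
        ev.duration_s = gt.duration_s
        ev.amplitude_pct = 100.0 * gt.amplitude_frac
        ev.slope_mm_per_s = slope
        ev.r2 = r2
        ev.velocity_mm_per_s = abs(slope)
        ev.direction = gt.direction
        ev.type = gt.type
        ev.segment = assign_segment(min(ev.initiation_site_frac, 100.0))
        out.append(ev)
    return out
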