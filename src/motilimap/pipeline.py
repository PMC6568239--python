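"""End-to-end analysis pipeline: extract -> detect -> classify -> summarize.

One `RunConfig` carries every stage parameter; `run_pipeline` executes the
stages in order into a run directory with provenance (config echo + hash,
package versions) so an identical config reproduces identical event tables.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import numpy as np

from . import classify as _classify
from . import detect as _detect
from . import io_masks as _io
from . import stmap as _stmap

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]


class PipelineError(RuntimeError):
    """A stage failure; the message names the stage and offending input."""


@dataclass
class RunConfig:
    """All pipeline parameters; serializes losslessly to YAML/JSON."""

    # input: exactly one of masks / diameter_csv
    masks: str | None = None
    diameter_csv: str | None = None
    px_per_mm: float | None = None
    fps: float | None = None
    oral_at_row0: bool = True
    # extraction
    keep_every: int = 3
    roi_width_mm: float = 0.5
    # detection
    depth_threshold: float = _detect.DEFAULT_DEPTH_THRESHOLD_MM
    similarity_tol: float | None = None
    connectivity: int = 8
    flank: str = "lower"
    min_amplitude_frac: float = 0.05
    # classification / summary
    segment_ratios: tuple[float, ...] = (0.39, 0.23, 0.23, 0.15)
    window: tuple[float, float] | None = None  # analysis window (s); None = full
    # pre/post comparison
    treatment_time_s: float | None = None
    compare_window_s: float = 600.0
    # calibration fallbacks for CSV input
    dx_mm: float | None = None
    dt_s: float | None = None
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["segment_ratios"] = list(self.segment_ratios)
        d["window"] = list(self.window) if self.window else None
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if d.get("segment_ratios") is not None:
            d["segment_ratios"] = tuple(d["segment_ratios"])
        if d.get("window") is not None:
            d["window"] = tuple(d["window"])
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        import yaml

        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path: str) -> None:
        import yaml

        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _stage(name: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError(f"stage '{name}' failed: {exc}") from exc


def run_pipeline(config: RunConfig, outdir: str) -> str:
    """Run all stages into ``outdir`` and return its path.

    Outputs: diameter matrix CSV, length trace CSV (mask input only),
    event/cell CSVs, gray and binary ST-map PNGs, summary JSON, and a
    ``run.json`` provenance record with the config and its hash.
    """
    os.makedirs(outdir, exist_ok=True)

    # --- load / extract ------------------------------------------------
    trace = None
    if config.diameter_csv is not None:
        if not os.path.exists(config.diameter_csv):
            raise PipelineError(f"stage 'load': input not found: {config.diameter_csv}")
        dm = _stage(
            "load",
            _io.read_diameter_matrix,
            config.diameter_csv,
            dx_mm=config.dx_mm,
            dt_s=config.dt_s,
        )
    elif config.masks is not None:
        if not os.path.exists(config.masks):
            raise PipelineError(f"stage 'load': input not found: {config.masks}")
        stack = _stage(
            "load",
            _io.load_mask_stack,
            config.masks,
            px_per_mm=config.px_per_mm,
            fps=config.fps,
            oral_at_row0=config.oral_at_row0,
        )
        stack = _stage("downsample", _io.downsample_frames, stack, config.keep_every)
        dm = _stage("measure", _io.measure_diameters, stack, config.roi_width_mm)
        trace = _stage("measure", _io.measure_length, stack)
    else:
        raise PipelineError("stage 'load': config needs 'masks' or 'diameter_csv'")

    _io.write_diameter_matrix(dm, os.path.join(outdir, "diameter_matrix.csv"))
    if trace is not None:
        _io.write_length_trace(trace, os.path.join(outdir, "length_trace.csv"))

    window = config.window or (0.0, float((dm.n_frames - 1) * dm.dt_s))
    total_length = float(dm.total_length_mm)
    scheme = _classify.SegmentScheme(tuple(config.segment_ratios))

    # --- detect ----------------------------------------------------------
    cm = _stage(
        "detect",
        _detect.build_cell_matrix,
        dm,
        depth_threshold=config.depth_threshold,
        similarity_tol=config.similarity_tol,
        flank=config.flank,
    )
    events = _stage("detect", _detect.label_events, cm, config.connectivity)

    # --- classify --------------------------------------------------------
    for ev in events:
        _stage("classify", _classify.event_features, ev, total_length, dm=dm, window=window)
        _stage("classify", _classify.classify_event, ev)
        ev.segment = _classify.assign_segment(min(ev.initiation_site_frac, 100.0), scheme)
    events = _stage(
        "classify", _detect.filter_events, events, config.min_amplitude_frac
    )

    _detect.events_to_dataframe(events).to_csv(
        os.path.join(outdir, "events.csv"), index=False
    )
    _detect.cells_to_dataframe(events).to_csv(
        os.path.join(outdir, "cells.csv"), index=False
    )

    # --- summarize -------------------------------------------------------
    summary = _stage(
        "summarize", _classify.summarize, events, window, total_length, scheme
    )
    summary_dict = summary.to_dict()

    # --- pre/post comparison (within-run descriptive) ---------------------
    if config.treatment_time_s is not None:
        t0 = config.treatment_time_s
        w = config.compare_window_s
        before = _stage(
            "compare", _classify.summarize, events, (t0 - w, t0), total_length, scheme
        )
        after = _stage(
            "compare", _classify.summarize, events, (t0, t0 + w), total_length, scheme
        )
        rows = []
        for seg in before.frequency_cpm.index:
            for typ in before.frequency_cpm.columns:
                b = float(before.frequency_cpm.loc[seg, typ])
                a = float(after.frequency_cpm.loc[seg, typ])
                rows.append(
                    {
                        "metric": f"freq_cpm[S{seg},{typ}]",
                        "before": b,
                        "after": a,
                        "log2_ratio": float(np.log2(a / b)) if a > 0 and b > 0 else None,
                    }
                )
        import pandas as pd

        pd.DataFrame(rows).to_csv(os.path.join(outdir, "pre_post.csv"), index=False)
        summary_dict["pre_post_windows"] = {"before": [t0 - w, t0], "after": [t0, t0 + w]}

    with open(os.path.join(outdir, "summary.json"), "w") as fh:
        json.dump(summary_dict, fh, indent=2)

    # --- render ----------------------------------------------------------
    norm = _stage("render", _stmap.normalize, dm)
    interp = _stage("render", _stmap.interpolate_spatial, norm, 9)
    _stmap.save_png(_stmap.render_gray_map(interp), os.path.join(outdir, "st_gray.png"))
    _stmap.save_png(
        _stmap.render_binary_map(events, dm.values.shape),
        os.path.join(outdir, "st_binary.png"),
    )

    # --- provenance --------------------------------------------------------
    import motilimap

    with open(os.path.join(outdir, "run.json"), "w") as fh:
        json.dump(
            {
                "config": config.to_dict(),
                "config_hash": config.hash(),
                "n_events": len(events),
                "versions": {
                    "motilimap": getattr(motilimap, "__version__", "unknown"),
                    "numpy": np.__version__,
                },
            },
            fh,
            indent=2,
        )
    return outdir
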