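"""Readers and writers for the interchange formats.

All tables are UTF-8 CSV with a mandatory header, comma separators and '.'
decimals.  TIFF stacks are grayscale, frame-major, one file per channel.
Coordinates are (row, col), origin top-left, 0-based; times are seconds
with frame i at i / fps.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .ratiometry import DeltaTrace
from .stats import EggStageTable, GenotypeSummary
from .synthgen import (
    COMPARTMENT_CODES,
    EVENT_COLUMNS,
    KIND_CODES,
    CompartmentTraces,
    DualChannelMovie,
    Ellipse,
    EventLog,
    RoiGeometry,
    ScenarioConfig,
)
from .transients import ClassifiedTransient, RecordingSummary

__all__ = [
    "write_events_csv", "read_events_csv",
    "write_traces_csv", "read_traces_csv",
    "write_movie_tiffs", "read_movie_tiffs",
    "write_rois_json", "read_rois_json",
    "write_config_yaml", "read_config_yaml",
    "write_detected_csv", "write_summary_json",
    "read_egg_table_csv", "read_polygons_csv", "read_landmarks_csv",
]


class FormatError(ValueError):
    """A file violates its column/format contract."""


def write_events_csv(events: EventLog, path) -> None:
    events.events.to_csv(path, index=False, float_format="%.9g")


def read_events_csv(path, duration_s: float) -> EventLog:
    df = pd.read_csv(path)
    missing = set(EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    bad = set(df["compartment"].astype(str)) - set(COMPARTMENT_CODES)
    if bad:
        raise FormatError(f"{path}: unknown compartment codes {sorted(bad)}")
    bad = set(df["kind"].astype(str)) - set(KIND_CODES)
    if bad:
        raise FormatError(f"{path}: unknown kind codes {sorted(bad)}")
    df = df[EVENT_COLUMNS].astype(
        {"event_time_s": float, "offset_s": float, "amplitude_dRR": float}
    )
    return EventLog(events=df, duration_s=duration_s)


def write_traces_csv(path, traces: dict[str, DeltaTrace],
                     n_voxels: Optional[np.ndarray] = None) -> None:
    """Write dR/R traces keyed by compartment ('A', 'P', 'whole')."""
    first = next(iter(traces.values()))
    cols: dict[str, np.ndarray] = {"time_s": first.time_s}
    for name, tr in traces.items():
        cols[f"dRR_{name}"] = tr.dRR
    if n_voxels is not None:
        cols["n_voxels"] = n_voxels
    pd.DataFrame(cols).to_csv(path, index=False, float_format="%.12g")


def read_traces_csv(path) -> dict[str, DeltaTrace]:
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise FormatError(f"{path}: missing time_s column")
    trace_cols = [c for c in df.columns if c.startswith("dRR_")]
    if not trace_cols:
        raise FormatError(f"{path}: no dRR_* columns")
    t = df["time_s"].to_numpy(float)
    return {
        c[len("dRR_"):]: DeltaTrace(
            time_s=t, dRR=df[c].to_numpy(float), baseline_R0=float("nan"),
            compartment=c[len("dRR_"):],
        )
        for c in trace_cols
    }


def write_movie_tiffs(movie: DualChannelMovie, gcamp_path, mcherry_path) -> None:
    tifffile.imwrite(gcamp_path, movie.gcamp)
    tifffile.imwrite(mcherry_path, movie.mcherry)


def read_movie_tiffs(gcamp_path, mcherry_path, frame_rate_hz: float) -> DualChannelMovie:
    for p in (gcamp_path, mcherry_path):
        if not Path(p).exists():
            raise FormatError(f"missing channel file: {p}")
    g = tifffile.imread(gcamp_path)
    m = tifffile.imread(mcherry_path)
    if g.ndim == 2:
        g = g[None]
    if m.ndim == 2:
        m = m[None]
    if g.shape != m.shape:
        raise FormatError(
            f"channel shapes differ: gcamp {g.shape} vs mcherry {m.shape}"
        )
    return DualChannelMovie(
        gcamp=g.astype(np.float32), mcherry=m.astype(np.float32), frame_rate_hz=frame_rate_hz
    )


def write_rois_json(geom: RoiGeometry, path) -> None:
    obj = {
        "anterior": {"center": list(geom.anterior.center),
                     "semi_axes": list(geom.anterior.semi_axes)},
        "posterior": {"center": list(geom.posterior.center),
                      "semi_axes": list(geom.posterior.semi_axes)},
        "background": list(geom.background),
    }
    Path(path).write_text(json.dumps(obj, indent=2))


def read_rois_json(path) -> RoiGeometry:
    obj = json.loads(Path(path).read_text())
    try:
        return RoiGeometry(
            anterior=Ellipse(tuple(obj["anterior"]["center"]),
                             tuple(obj["anterior"]["semi_axes"])),
            posterior=Ellipse(tuple(obj["posterior"]["center"]),
                              tuple(obj["posterior"]["semi_axes"])),
            background=tuple(obj["background"]),
        )
    except (KeyError, TypeError) as e:
        raise FormatError(f"{path}: malformed ROI file ({e})") from e


def write_config_yaml(config: ScenarioConfig, path) -> None:
    d = asdict(config)
    d["roi_geometry"] = None if config.roi_geometry is None else {
        "anterior": {"center": list(config.roi_geometry.anterior.center),
                     "semi_axes": list(config.roi_geometry.anterior.semi_axes)},
        "posterior": {"center": list(config.roi_geometry.posterior.center),
                      "semi_axes": list(config.roi_geometry.posterior.semi_axes)},
        "background": list(config.roi_geometry.background),
    }
    d["image_shape"] = list(config.image_shape)
    for k in ("offset_dist", "amp_twitch", "amp_egglaying"):
        d[k] = list(d[k])
    Path(path).write_text(yaml.safe_dump({"vmsync_version": __version__, "scenario": d}))


def read_config_yaml(path) -> ScenarioConfig:
    obj = yaml.safe_load(Path(path).read_text())
    d = obj["scenario"] if "scenario" in obj else obj
    d = dict(d)
    if d.get("roi_geometry") is not None:
        g = d["roi_geometry"]
        d["roi_geometry"] = RoiGeometry(
            anterior=Ellipse(tuple(g["anterior"]["center"]), tuple(g["anterior"]["semi_axes"])),
            posterior=Ellipse(tuple(g["posterior"]["center"]),
                              tuple(g["posterior"]["semi_axes"])),
            background=tuple(g["background"]),
        )
    d["image_shape"] = tuple(d["image_shape"])
    for k in ("offset_dist", "amp_twitch", "amp_egglaying"):
        d[k] = tuple(d[k])
    return ScenarioConfig(**d)


def write_detected_csv(transients: list[ClassifiedTransient], path) -> None:
    pd.DataFrame(
        [
            {
                "time_s": tr.time_s,
                "category": tr.category,
                "delay_s": tr.delay_s,
                "peak_dRR": tr.peak_dRR,
                "magnitude_class": tr.magnitude_class,
            }
            for tr in transients
        ],
        columns=["time_s", "category", "delay_s", "peak_dRR", "magnitude_class"],
    ).to_csv(path, index=False, float_format="%.9g")


def write_summary_json(path, summary: RecordingSummary, provenance: dict) -> None:
    obj = {
        "duration_min": summary.duration_min,
        "n_single_A": summary.n_single_A,
        "n_single_P": summary.n_single_P,
        "n_double_sync": summary.n_double_sync,
        "n_double_delayed": summary.n_double_delayed,
        "n_peaks_merged": summary.n_peaks_merged,
        "peaks_per_min": summary.peaks_per_min,
        "frac_sync_double": summary.frac_sync_double,
        "mean_delay_s": summary.mean_delay_s,
        "provenance": provenance,
    }
    Path(path).write_text(json.dumps(obj, indent=2, allow_nan=True, sort_keys=True))


def genotype_summary_dict(g: GenotypeSummary) -> dict:
    return {
        "label": g.label,
        "n_animals": g.n_animals,
        "mean_peaks_per_min": g.mean_peaks_per_min,
        "ci_peaks_per_min": list(g.ci_peaks_per_min),
        "frac_sync_double": g.frac_sync_double,
        "ci_frac_sync_double": list(g.ci_frac_sync_double),
        "mean_delay_s": g.mean_delay_s,
        "ci_delay_s": list(g.ci_delay_s),
        "n_transients": g.n_transients,
        "n_doubles": g.n_doubles,
    }


def read_egg_table_csv(path) -> EggStageTable:
    df = pd.read_csv(path)
    need = {"genotype", "stage", "count"}
    if not need <= set(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(need)}")
    return EggStageTable.from_records(df)


def read_polygons_csv(path) -> dict[tuple[str, str], np.ndarray]:
    """polygons.csv -> {(animal_id, muscle_id): (n, 2) vertex array}."""
    df = pd.read_csv(path)
    need = {"animal_id", "muscle_id", "vertex_index", "x_um", "y_um"}
    if not need <= set(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(need)}")
    out = {}
    for (aid, mid), grp in df.groupby(["animal_id", "muscle_id"]):
        grp = grp.sort_values("vertex_index")
        out[(str(aid), str(mid))] = grp[["x_um", "y_um"]].to_numpy(float)
    return out


def read_landmarks_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    need = {"animal_id", "muscle_id", "ax", "ay", "tx", "ty", "slit_dx", "slit_dy"}
    if not need <= set(df.columns):
        raise FormatError(f"{path}: expected columns {sorted(need)}")
    return df
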