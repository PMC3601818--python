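"""Ground-truthed synthetic vulval-muscle recordings.

The egg-laying vulval muscles of *C. elegans* form two electrically coupled
compartments, anterior (A) and posterior (P), that fire Ca2+ transients
during locomotion.  In wild-type animals nearly all transients involve both
compartments and are unresolvable in time ("synchronous doubles"); in
Notch-pathway mutants that lack the vm2 muscle arms the two compartments
decouple and fire with a substantial A/P onset offset.

This module generates recordings of that physiology with a known ground
truth at three levels of realism:

``sample_events``
    a seeded event log (times, compartments, A/P offsets, amplitudes);
``render_traces``
    ideal per-compartment dR/R time series obtained by convolving the event
    log with a difference-of-exponentials indicator kernel ("trace mode");
``render_movie``
    a two-channel (GCaMP + mCherry) voxel movie with elliptical compartment
    ROIs, realistic count levels and additive Gaussian noise ("movie mode").

Two named scenarios calibrate the generator to the published phenotypes:
``wildtype()`` (90% of double events synchronous, nonzero offsets uniform on
0.5-1.5 s, so the expected measured mean delay is 0.1 s) and ``mutant()``
(no synchronous events, offsets uniform on 0.3-1.3 s, 1.1x event rate, so
the expected mean delay is 0.8 s and the expected peak-frequency ratio over
wild type is 2.0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional

import numpy as np
import pandas as pd
from skimage.draw import ellipse as _draw_ellipse

__all__ = [
    "Ellipse",
    "RoiGeometry",
    "ScenarioConfig",
    "EventLog",
    "CompartmentTraces",
    "DualChannelMovie",
    "wildtype",
    "mutant",
    "default_geometry",
    "sample_events",
    "render_traces",
    "render_movie",
    "indicator_kernel",
    "kernel_peak_delay",
]

#: Peaks closer than this cannot be told apart in a ratiometric trace; double
#: events emitted with a smaller intended offset would be mis-labelled in the
#: ground truth, so configs forbid offset supports that dip below it.
RESOLUTION_S = 0.25

BIT_DEPTH = 16
_MAX_COUNT = 2**BIT_DEPTH - 1

#: Events are never placed closer than this to the end of the recording so
#: that the late edge cannot truncate a transient before its peak.
_END_MARGIN_S = 2.0


class ConfigurationError(ValueError):
    """Raised when a ScenarioConfig or ROI geometry is invalid."""


@dataclass(frozen=True)
class Ellipse:
    """Axis-aligned ellipse in (row, col) voxel coordinates."""

    center: tuple[float, float]
    semi_axes: tuple[float, float]

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        m = np.zeros(shape, dtype=bool)
        rr, cc = _draw_ellipse(
            self.center[0], self.center[1], self.semi_axes[0], self.semi_axes[1], shape=shape
        )
        m[rr, cc] = True
        return m


@dataclass(frozen=True)
class RoiGeometry:
    """Anterior/posterior compartment ellipses plus a background rectangle.

    The background rectangle is (row0, row1, col0, col1), half-open.
    """

    anterior: Ellipse
    posterior: Ellipse
    background: tuple[int, int, int, int]

    def masks(self, shape: tuple[int, int]) -> dict[str, np.ndarray]:
        a = self.anterior.mask(shape)
        p = self.posterior.mask(shape)
        bg = np.zeros(shape, dtype=bool)
        r0, r1, c0, c1 = self.background
        bg[r0:r1, c0:c1] = True
        return {"A": a, "P": p, "background": bg}

    def validate(self, shape: tuple[int, int]) -> None:
        for e in (self.anterior, self.posterior):
            if (
                e.center[0] + e.semi_axes[0] > shape[0]
                or e.center[0] - e.semi_axes[0] < 0
                or e.center[1] + e.semi_axes[1] > shape[1]
                or e.center[1] - e.semi_axes[1] < 0
            ):
                raise ConfigurationError(f"ROI ellipse {e} exceeds frame shape {shape}")
        m = self.masks(shape)
        if not m["A"].any() or not m["P"].any():
            raise ConfigurationError("compartment ROI rasterizes to zero voxels")
        if (m["A"] & m["P"]).any():
            raise ConfigurationError("anterior and posterior ROIs overlap")
        if ((m["A"] | m["P"]) & m["background"]).any():
            raise ConfigurationError("background region overlaps a compartment ROI")


def default_geometry(shape: tuple[int, int]) -> RoiGeometry:
    """Two side-by-side ellipses flanking the vulva plus a corner background.

    Sized so that at 256x256 the two compartments together cover ~500
    voxels, matching the typical per-frame voxel count of the real
    recordings.
    """
    h, w = shape
    semi = (0.03125 * h, 0.039 * w)
    return RoiGeometry(
        anterior=Ellipse(center=(0.40 * h, 0.50 * w), semi_axes=semi),
        posterior=Ellipse(center=(0.60 * h, 0.50 * w), semi_axes=semi),
        background=(int(0.02 * h), int(0.15 * h), int(0.05 * w), int(0.35 * w)),
    )


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterization of a synthetic recording.

    Rates are in events (not peaks) per minute; a double event contributes
    one peak to a summed ratiometric trace when synchronous and two when
    delayed.  Amplitudes are ideal peak dR/R fractions.  Count levels are on
    the 16-bit acquisition scale.
    """

    frame_rate_hz: float = 20.0
    duration_s: float = 360.0
    image_shape: tuple[int, int] = (64, 64)
    roi_geometry: Optional[RoiGeometry] = None
    event_rate_per_min: float = 5.0
    double_fraction: float = 1.0
    sync_prob: float = 0.9
    offset_dist: tuple[float, float] = (0.5, 1.5)
    amp_twitch: tuple[float, float] = (0.3, 1.0)
    amp_egglaying: tuple[float, float] = (1.5, 3.0)
    egglaying_prob: float = 0.1
    tau_rise_s: float = 0.05
    tau_decay_s: float = 0.4
    gcamp_rest_mean: float = 2000.0
    mcherry_mean: float = 5000.0
    background_mean: float = 200.0
    background_sd: float = 20.0
    noise_sd: float = 50.0
    rate_multiplier: float = 1.0
    refractory_s: float = 2.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.frame_rate_hz <= 0 or self.duration_s <= 0:
            raise ConfigurationError("frame_rate_hz and duration_s must be positive")
        for name in ("double_fraction", "sync_prob", "egglaying_prob"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v} outside [0, 1]")
        for name in ("offset_dist", "amp_twitch", "amp_egglaying"):
            lo, hi = getattr(self, name)
            if not (math.isfinite(lo) and math.isfinite(hi)) or lo > hi or lo < 0:
                raise ConfigurationError(f"{name}=({lo}, {hi}) is not a valid range")
        if self.sync_prob < 1.0 and self.double_fraction > 0.0:
            if self.offset_dist[0] < RESOLUTION_S:
                raise ConfigurationError(
                    f"offset_dist support must lie above the {RESOLUTION_S} s resolution "
                    "threshold when sync_prob < 1; intended-resolved events would be "
                    "unresolvable"
                )
        if self.event_rate_per_min < 0 or self.rate_multiplier < 0:
            raise ConfigurationError("rates must be nonnegative")
        if self.tau_rise_s <= 0 or self.tau_decay_s <= 0:
            raise ConfigurationError("kernel time constants must be positive")
        if min(self.gcamp_rest_mean, self.mcherry_mean, self.background_mean) < 0:
            raise ConfigurationError("count levels must be nonnegative")
        if self.background_sd < 0 or self.noise_sd < 0:
            raise ConfigurationError("noise scales must be nonnegative")
        if self.refractory_s < 0:
            raise ConfigurationError("refractory_s must be nonnegative")

    @property
    def geometry(self) -> RoiGeometry:
        return self.roi_geometry if self.roi_geometry is not None else default_geometry(self.image_shape)

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


def wildtype(**overrides) -> ScenarioConfig:
    """Wild-type scenario: coupled compartments, 90% synchronous doubles."""
    return replace(ScenarioConfig(), **overrides) if overrides else ScenarioConfig()


def mutant(**overrides) -> ScenarioConfig:
    """Notch-mutant scenario: fully decoupled compartments, 1.1x event rate."""
    base = ScenarioConfig(sync_prob=0.0, offset_dist=(0.3, 1.3), rate_multiplier=1.1)
    return replace(base, **overrides) if overrides else base


EVENT_COLUMNS = ["event_time_s", "compartment", "offset_s", "amplitude_dRR", "kind"]
COMPARTMENT_CODES = ("A", "P", "both")
KIND_CODES = ("twitch", "egg_laying")


@dataclass(frozen=True)
class EventLog:
    """Ground-truth event table.

    ``event_time_s`` is the onset of whichever compartment fires first;
    ``offset_s`` is the signed posterior-minus-anterior onset offset (zero
    for single-compartment or synchronous events).
    """

    events: pd.DataFrame
    duration_s: float

    def __post_init__(self) -> None:
        ev = self.events
        missing = set(EVENT_COLUMNS) - set(ev.columns)
        if missing:
            raise ValueError(f"EventLog missing columns: {sorted(missing)}")
        bad = set(ev["compartment"]) - set(COMPARTMENT_CODES)
        if bad:
            raise ValueError(f"unknown compartment codes: {sorted(bad)}")
        bad = set(ev["kind"]) - set(KIND_CODES)
        if bad:
            raise ValueError(f"unknown event kinds: {sorted(bad)}")
        t = ev["event_time_s"].to_numpy(float)
        if len(t) and (np.any(np.diff(t) <= 0) or t.min() < 0 or t.max() > self.duration_s):
            raise ValueError("event times must be strictly increasing within [0, duration]")
        off = ev["offset_s"].to_numpy(float)
        if np.any((ev["compartment"] != "both") & (off != 0)):
            raise ValueError("offset_s must be 0 for single-compartment events")

    def __len__(self) -> int:
        return len(self.events)

    def onsets(self, compartment: str) -> np.ndarray:
        """Onset times and amplitudes for one compartment as (times, amps)."""
        ev = self.events
        if compartment == "A":
            sel = ev["compartment"].isin(["A", "both"])
            shift = np.maximum(-ev.loc[sel, "offset_s"].to_numpy(float), 0.0)
        elif compartment == "P":
            sel = ev["compartment"].isin(["P", "both"])
            shift = np.maximum(ev.loc[sel, "offset_s"].to_numpy(float), 0.0)
        else:
            raise ValueError(f"compartment must be 'A' or 'P', got {compartment!r}")
        return (
            ev.loc[sel, "event_time_s"].to_numpy(float) + shift,
            ev.loc[sel, "amplitude_dRR"].to_numpy(float),
        )


def sample_events(config: ScenarioConfig) -> EventLog:
    """Draw a seeded event log for one recording.

    Event onsets follow a delayed-renewal process: successive inter-onset
    gaps are ``refractory_s`` plus an exponential whose mean is chosen so
    the overall mean rate equals ``event_rate_per_min * rate_multiplier``.
    The hard 2 s gap emulates the once-per-body-bend rhythm of the real
    transients and keeps successive indicator kernels from piling up.  Each
    event involves both compartments with probability ``double_fraction``;
    a double is synchronous (offset 0) with probability ``sync_prob`` and
    otherwise receives an offset drawn from ``offset_dist`` with a random
    sign.
    """
    rng = np.random.default_rng(config.seed)
    rate = config.event_rate_per_min * config.rate_multiplier
    empty = pd.DataFrame({c: pd.Series(dtype=t) for c, t in zip(
        EVENT_COLUMNS, [float, object, float, float, object])})
    if rate == 0:
        return EventLog(events=empty, duration_s=config.duration_s)
    mean_gap = 60.0 / rate
    if mean_gap <= config.refractory_s:
        raise ConfigurationError(
            f"event rate {rate}/min incompatible with {config.refractory_s} s refractory gap"
        )
    exp_mean = mean_gap - config.refractory_s
    t_max = config.duration_s - _END_MARGIN_S
    rows: list[tuple] = []
    t = 0.0
    while True:
        t += config.refractory_s + rng.exponential(exp_mean)
        if t > t_max:
            break
        if rng.random() < config.double_fraction:
            comp = "both"
            if rng.random() < config.sync_prob:
                offset = 0.0
            else:
                offset = rng.uniform(*config.offset_dist) * (1.0 if rng.random() < 0.5 else -1.0)
        else:
            comp = "A" if rng.random() < 0.5 else "P"
            offset = 0.0
        if rng.random() < config.egglaying_prob:
            kind, amp = "egg_laying", rng.uniform(*config.amp_egglaying)
        else:
            kind, amp = "twitch", rng.uniform(*config.amp_twitch)
        rows.append((t, comp, offset, amp, kind))
    if not rows:
        return EventLog(events=empty, duration_s=config.duration_s)
    return EventLog(
        events=pd.DataFrame(rows, columns=EVENT_COLUMNS), duration_s=config.duration_s
    )


def kernel_peak_delay(tau_rise_s: float, tau_decay_s: float) -> float:
    """Time from onset to kernel maximum."""
    if math.isclose(tau_rise_s, tau_decay_s, rel_tol=1e-9):
        return tau_rise_s
    return (
        tau_rise_s * tau_decay_s / (tau_decay_s - tau_rise_s)
        * math.log(tau_decay_s / tau_rise_s)
    )


def indicator_kernel(t: np.ndarray, tau_rise_s: float, tau_decay_s: float) -> np.ndarray:
    """Difference-of-exponentials indicator response, unit peak, causal.

    K(t) = (exp(-t/tau_d) - exp(-t/tau_r)) / K_max for t >= 0, else 0.  For
    tau_r == tau_d the limit is the alpha function (t/tau) e^(1 - t/tau).
    """
    t = np.asarray(t, dtype=float)
    if math.isclose(tau_rise_s, tau_decay_s, rel_tol=1e-9):
        tau = tau_decay_s
        k = np.where(t >= 0, (t / tau) * np.exp(1.0 - t / tau), 0.0)
        return k
    tp = kernel_peak_delay(tau_rise_s, tau_decay_s)
    norm = math.exp(-tp / tau_decay_s) - math.exp(-tp / tau_rise_s)
    tt = np.maximum(t, 0.0)
    return (t >= 0) * (np.exp(-tt / tau_decay_s) - np.exp(-tt / tau_rise_s)) / norm


@dataclass(frozen=True)
class CompartmentTraces:
    """Ideal (noise-free) per-compartment dR/R traces."""

    time_s: np.ndarray
    dRR_A: np.ndarray
    dRR_P: np.ndarray
    frame_rate_hz: float


def render_traces(events: EventLog, config: ScenarioConfig) -> CompartmentTraces:
    """Superpose the indicator kernel at every event onset, per compartment."""
    times = config.times
    traces = {}
    for comp in ("A", "P"):
        onsets, amps = events.onsets(comp)
        tr = np.zeros_like(times)
        for onset, amp in zip(onsets, amps):
            tr += amp * indicator_kernel(times - onset, config.tau_rise_s, config.tau_decay_s)
        traces[comp] = tr
    return CompartmentTraces(
        time_s=times, dRR_A=traces["A"], dRR_P=traces["P"], frame_rate_hz=config.frame_rate_hz
    )


@dataclass(frozen=True)
class DualChannelMovie:
    """Two-channel voxel recording, (frame, row, col), counts on the 16-bit scale.

    Counts are clipped to [0, 2**bit_depth - 1] but kept as float32 so the
    noiseless ratio ground truth survives exactly.
    """

    gcamp: np.ndarray
    mcherry: np.ndarray
    frame_rate_hz: float
    bit_depth: int = BIT_DEPTH

    def __post_init__(self) -> None:
        if self.gcamp.shape != self.mcherry.shape:
            raise ValueError("gcamp and mcherry channels must share shape")
        if self.gcamp.ndim != 3:
            raise ValueError("channels must be (frame, row, col) arrays")
        hi = 2**self.bit_depth - 1
        for name, ch in (("gcamp", self.gcamp), ("mcherry", self.mcherry)):
            if ch.size and (ch.min() < 0 or ch.max() > hi):
                raise ValueError(f"{name} counts outside [0, {hi}]")

    @property
    def n_frames(self) -> int:
        return self.gcamp.shape[0]

    @property
    def frame_shape(self) -> tuple[int, int]:
        return self.gcamp.shape[1:]

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz


def render_movie(events: EventLog, config: ScenarioConfig) -> DualChannelMovie:
    """Render an event log into a two-channel voxel movie.

    mCherry is Ca2+-insensitive: ROI voxels sit at ``mcherry_mean`` and the
    rest of the frame at ``background_mean``.  GCaMP voxels inside a
    compartment follow ``gcamp_rest_mean * (1 + dR/R(t))`` for that
    compartment's ideal trace, so the per-voxel ratio ground truth inside a
    ROI is ``(gcamp_rest_mean / mcherry_mean) * (1 + dR/R)`` before noise.
    Noise is additive Gaussian: sd ``noise_sd`` inside ROIs, ``background_sd``
    elsewhere.
    """
    geom = config.geometry
    geom.validate(config.image_shape)
    masks = geom.masks(config.image_shape)
    roi_any = masks["A"] | masks["P"]
    traces = render_traces(events, config)
    n, (h, w) = config.n_frames, config.image_shape

    rng = np.random.default_rng(
        None if config.seed is None else np.random.SeedSequence([config.seed, 1])
    )

    mcherry = np.full((n, h, w), config.background_mean, dtype=np.float32)
    mcherry[:, roi_any] = config.mcherry_mean
    gcamp = np.full((n, h, w), config.background_mean, dtype=np.float32)
    gcamp[:, masks["A"]] = (config.gcamp_rest_mean * (1.0 + traces.dRR_A))[:, None].astype(np.float32)
    gcamp[:, masks["P"]] = (config.gcamp_rest_mean * (1.0 + traces.dRR_P))[:, None].astype(np.float32)

    for ch in (gcamp, mcherry):
        if config.noise_sd > 0:
            n_roi = int(roi_any.sum())
            ch[:, roi_any] += rng.normal(0.0, config.noise_sd, size=(n, n_roi)).astype(np.float32)
        if config.background_sd > 0:
            n_bg = int((~roi_any).sum())
            ch[:, ~roi_any] += rng.normal(0.0, config.background_sd, size=(n, n_bg)).astype(
                np.float32
            )
        np.clip(ch, 0, _MAX_COUNT, out=ch)

    return DualChannelMovie(gcamp=gcamp, mcherry=mcherry, frame_rate_hz=config.frame_rate_hz)
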