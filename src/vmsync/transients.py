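"""Ca2+ transient detection, A/P pairing, and per-recording summaries.

Peaks are local maxima of a dR/R trace above a 15% amplitude floor with a
minimum topographic prominence, at least 250 ms apart.  Anterior and
posterior peak trains are then paired within a "body bend" window (2 s by
default): a matched pair closer than 250 ms cannot be resolved into two
peaks in a summed ratiometric trace and is classified as a synchronous
double with zero delay; a pair at or beyond 250 ms is a delayed double
whose delay is the unsigned peak-time difference; unmatched peaks are
singles.  Transients below 150% dR/R correspond to sub-egg-laying twitch
contractions.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.signal import find_peaks

from .ratiometry import DeltaTrace

__all__ = [
    "Peak",
    "ClassifiedTransient",
    "RecordingSummary",
    "detect_peaks",
    "pair_and_classify",
    "classify_magnitude",
    "summarize_recording",
    "analyze_recording",
    "CATEGORIES",
]

CATEGORIES = ("single_A", "single_P", "double_sync", "double_delayed")

DETECTION_THRESHOLD = 0.15  # dR/R fraction; "peaks above 15%"
RESOLVE_THRESHOLD_S = 0.25  # peaks closer than this merge in a summed trace
TWITCH_CUTOFF = 1.5  # dR/R fraction; twitches are < 150%
PAIRING_WINDOW_S = 2.0  # operationalizes "within a single body bend"


@dataclass(frozen=True)
class Peak:
    time_s: float
    dRR: float
    compartment: str  # "A" | "P"


@dataclass(frozen=True)
class ClassifiedTransient:
    """One physiological event assembled from one or two peaks.

    ``time_s`` is the earlier constituent peak time; ``delay_s`` the
    unsigned A/P peak separation (0 for synchronous doubles and singles);
    ``signed_delay_s`` keeps t_P - t_A for diagnostics.
    """

    time_s: float
    category: str
    delay_s: float
    peak_dRR: float
    magnitude_class: str = ""
    signed_delay_s: float = 0.0

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.category != "double_delayed" and self.delay_s != 0.0:
            raise ValueError("only delayed doubles carry a nonzero delay")


@dataclass(frozen=True)
class RecordingSummary:
    """Per-animal statistics for one recording.

    ``n_peaks_merged`` counts a synchronous double as one peak and a delayed
    double as two, matching what a summed ratiometric trace shows (the A and
    P signals add, so an unresolved double appears as a single larger peak).
    ``mean_delay_s`` is over all doubles, synchronous ones contributing 0;
    NaN when there are no doubles.
    """

    duration_min: float
    n_single_A: int
    n_single_P: int
    n_double_sync: int
    n_double_delayed: int
    mean_delay_s: float

    @property
    def n_transients(self) -> int:
        return self.n_single_A + self.n_single_P + self.n_double_sync + self.n_double_delayed

    @property
    def n_doubles(self) -> int:
        return self.n_double_sync + self.n_double_delayed

    @property
    def n_peaks_merged(self) -> int:
        return self.n_single_A + self.n_single_P + self.n_double_sync + 2 * self.n_double_delayed

    @property
    def peaks_per_min(self) -> float:
        return self.n_peaks_merged / self.duration_min

    @property
    def frac_sync_double(self) -> float:
        n = self.n_transients
        return self.n_double_sync / n if n else float("nan")


def detect_peaks(
    trace: DeltaTrace,
    threshold: float = DETECTION_THRESHOLD,
    min_separation_s: float = RESOLVE_THRESHOLD_S,
    min_prominence: float = 0.10,
    compartment: Optional[str] = None,
) -> list[Peak]:
    """Local maxima with dR/R >= threshold and prominence >= min_prominence.

    Maxima closer than ``min_separation_s`` are resolved by keeping the
    higher one.  The trace must be uniformly sampled and finite (interpolate
    missing frames first).
    """
    t, y = trace.time_s, trace.dRR
    if len(t) > 1:
        dt = np.diff(t)
        if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-12):
            raise ValueError("detect_peaks requires a uniformly sampled trace")
    if np.any(~np.isfinite(y)):
        raise ValueError("trace contains non-finite samples; interpolate before detection")
    fs = trace.frame_rate_hz
    distance = max(1, int(round(min_separation_s * fs)))
    idx, _ = find_peaks(y, height=threshold, prominence=min_prominence, distance=distance)
    comp = compartment if compartment is not None else trace.compartment
    return [Peak(time_s=float(t[i]), dRR=float(y[i]), compartment=comp) for i in idx]


def pair_and_classify(
    peaks_A: Sequence[Peak],
    peaks_P: Sequence[Peak],
    pairing_window_s: float = PAIRING_WINDOW_S,
    resolve_threshold_s: float = RESOLVE_THRESHOLD_S,
    magnitude_cutoff: float = TWITCH_CUTOFF,
) -> list[ClassifiedTransient]:
    """Greedy chronological A/P pairing followed by synchrony classification.

    Peaks are consumed in overall time order: the earliest unmatched peak
    of either compartment pairs with the nearest unmatched peak of the
    opposite compartment within ``pairing_window_s`` (ties broken toward
    the earlier peak).  Walking the merged train chronologically keeps
    pairing aligned with the underlying per-body-bend events even when
    consecutive events interleave (an anterior-major sweep can grab the
    following event's posterior peak).  |t_P - t_A| < ``resolve_threshold_s``
    makes a synchronous double (delay 0); at or beyond the threshold, a
    delayed double with delay |t_P - t_A|; unmatched peaks become singles.
    """
    times_A = [p.time_s for p in peaks_A]
    times_P = [p.time_s for p in peaks_P]
    if sorted(times_A) != times_A or sorted(times_P) != times_P:
        raise ValueError("peak lists must be time-sorted")
    unmatched = {
        "A": list(range(len(peaks_A))),
        "P": list(range(len(peaks_P))),
    }
    trains = {"A": peaks_A, "P": peaks_P}
    other = {"A": "P", "P": "A"}
    transients: list[ClassifiedTransient] = []
    while unmatched["A"] or unmatched["P"]:
        comp = min(
            (c for c in ("A", "P") if unmatched[c]),
            key=lambda c: trains[c][unmatched[c][0]].time_s,
        )
        i = unmatched[comp].pop(0)
        pk = trains[comp][i]
        best: Optional[int] = None
        for j in unmatched[other[comp]]:
            d = abs(trains[other[comp]][j].time_s - pk.time_s)
            if d > pairing_window_s:
                continue
            if best is None or d < abs(trains[other[comp]][best].time_s - pk.time_s) - 1e-12:
                best = j
        if best is None:
            transients.append(
                ClassifiedTransient(
                    time_s=pk.time_s, category=f"single_{comp}", delay_s=0.0, peak_dRR=pk.dRR
                )
            )
            continue
        unmatched[other[comp]].remove(best)
        mate = trains[other[comp]][best]
        pa, pp = (pk, mate) if comp == "A" else (mate, pk)
        signed = pp.time_s - pa.time_s
        sep = abs(signed)
        if sep < resolve_threshold_s:
            cat, delay = "double_sync", 0.0
        else:
            cat, delay = "double_delayed", sep
        transients.append(
            ClassifiedTransient(
                time_s=min(pa.time_s, pp.time_s),
                category=cat,
                delay_s=delay,
                peak_dRR=max(pa.dRR, pp.dRR),
                signed_delay_s=signed,
            )
        )
    transients.sort(key=lambda tr: tr.time_s)
    return [classify_magnitude(tr, cutoff=magnitude_cutoff) for tr in transients]


def classify_magnitude(
    transient: ClassifiedTransient, cutoff: float = TWITCH_CUTOFF
) -> ClassifiedTransient:
    """Twitch below the cutoff, egg-laying at or above it."""
    cls = "twitch" if transient.peak_dRR < cutoff else "egg_laying"
    return replace(transient, magnitude_class=cls)


def summarize_recording(
    transients: Sequence[ClassifiedTransient], duration_min: float = 6.0
) -> RecordingSummary:
    """Collapse classified transients into per-recording statistics."""
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    counts = {c: 0 for c in CATEGORIES}
    delays = []
    for tr in transients:
        counts[tr.category] += 1
        if tr.category in ("double_sync", "double_delayed"):
            delays.append(tr.delay_s)
    return RecordingSummary(
        duration_min=duration_min,
        n_single_A=counts["single_A"],
        n_single_P=counts["single_P"],
        n_double_sync=counts["double_sync"],
        n_double_delayed=counts["double_delayed"],
        mean_delay_s=float(np.mean(delays)) if delays else float("nan"),
    )


def analyze_recording(
    dRR_A: DeltaTrace,
    dRR_P: DeltaTrace,
    threshold: float = DETECTION_THRESHOLD,
    min_separation_s: float = RESOLVE_THRESHOLD_S,
    min_prominence: float = 0.10,
    pairing_window_s: float = PAIRING_WINDOW_S,
    resolve_threshold_s: float = RESOLVE_THRESHOLD_S,
    magnitude_cutoff: float = TWITCH_CUTOFF,
) -> tuple[list[ClassifiedTransient], RecordingSummary]:
    """Detect + pair + classify + summarize one two-compartment recording."""
    pa = detect_peaks(dRR_A, threshold, min_separation_s, min_prominence, compartment="A")
    pp = detect_peaks(dRR_P, threshold, min_separation_s, min_prominence, compartment="P")
    transients = pair_and_classify(
        pa, pp, pairing_window_s, resolve_threshold_s, magnitude_cutoff
    )
    duration_min = (dRR_A.time_s[-1] + 1.0 / dRR_A.frame_rate_hz) / 60.0
    return transients, summarize_recording(transients, duration_min=duration_min)
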