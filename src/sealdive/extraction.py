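"""Raw-trace processing: zero-offset correction, trips, dives, phases.

The processing chain mirrors standard dive-analysis practice for archival
time-depth recorders: correct transducer drift so surface readings sit at
0 m, split the record into foraging trips using the wet/dry sensor, detect
dives as submerged excursions exceeding a depth threshold (default 4 m,
excluding travel/wave artefacts), and partition each dive into descent,
bottom and ascent phases plus the post-dive surface interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TDRTrace",
    "Trip",
    "Dive",
    "zero_offset_correct",
    "detect_trips",
    "detect_dives",
    "segment_phases",
    "post_dive_intervals",
    "read_tdr_csv",
    "write_tdr_csv",
    "dives_to_frame",
]

#: Depth (m) at or below which a corrected sample counts as "at the surface".
SURFACE_EPS = 0.5


@dataclass
class TDRTrace:
    """Regularly sampled depth record from a time-depth recorder.

    Parameters
    ----------
    time : ndarray
        Sample times, seconds since the epoch, strictly increasing with a
        constant step.
    depth : ndarray
        Depth in metres, positive downward. May contain small negative
        values before zero-offset correction (transducer offset).
    wet : ndarray of bool
        Conductivity (wet/dry) sensor channel.
    temp : ndarray, optional
        Water temperature in deg C.
    sampling_interval : float
        Nominal sampling step in seconds.
    """

    time: np.ndarray
    depth: np.ndarray
    wet: np.ndarray
    sampling_interval: float
    temp: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.depth = np.asarray(self.depth, dtype=float)
        self.wet = np.asarray(self.wet, dtype=bool)
        if self.sampling_interval <= 0:
            raise ValueError("sampling_interval must be positive")
        if self.time.ndim != 1 or len(self.time) != len(self.depth):
            raise ValueError("time and depth must be 1-d and equal length")
        if len(self.time) > 1:
            steps = np.diff(self.time)
            if np.any(steps <= 0):
                raise ValueError("time must be strictly increasing")
            if np.any(np.abs(steps - self.sampling_interval) > self.sampling_interval):
                raise ValueError("time step departs from sampling_interval")
        if not np.all(np.isfinite(self.depth)):
            raise ValueError("depth must be finite")

    def __len__(self) -> int:
        return len(self.time)


@dataclass(frozen=True)
class Trip:
    """One foraging trip delimited by the wet/dry sensor."""

    start: int  # first wet sample index
    end: int  # one past the last wet sample index
    departure: float  # seconds since epoch
    return_time: float

    @property
    def duration_days(self) -> float:
        return (self.return_time - self.departure) / 86400.0

    def contains(self, t: float) -> bool:
        return self.departure <= t < self.return_time


@dataclass
class Dive:
    """A single detected dive with optional phase and label annotations.

    Sample indices are half-open ``[start, end)`` into the source trace, so
    phase durations partition the dive duration exactly.
    """

    start: int
    end: int
    t_start: float
    t_end: float
    max_depth: float
    duration: float
    bottom_start: Optional[int] = None  # first sample of the bottom phase
    bottom_end: Optional[int] = None  # one past the last bottom sample
    descent_s: Optional[float] = None
    bottom_s: Optional[float] = None
    ascent_s: Optional[float] = None
    post_dive_interval: Optional[float] = None
    shape: Optional[str] = None
    diel: Optional[str] = None

    @property
    def has_phases(self) -> bool:
        return self.bottom_start is not None

    @property
    def bottom_fraction(self) -> float:
        if self.bottom_s is None or self.duration <= 0:
            raise ValueError("phases not segmented")
        return self.bottom_s / self.duration


def _rolling_quantile(x: np.ndarray, window: int, q: float) -> np.ndarray:
    s = pd.Series(x)
    return s.rolling(window, min_periods=1, center=True).quantile(q).to_numpy()


def zero_offset_correct(
    trace: TDRTrace,
    window_short: float = 300.0,
    window_long: float = 7200.0,
    quantile: float = 0.05,
) -> TDRTrace:
    """Remove pressure-transducer drift so surface readings equal 0 m.

    A two-pass running low-quantile filter estimates the time-varying
    surface offset: a short centred window captures local surface readings
    between dives, a long window smooths that estimate across dive bouts.
    The offset is subtracted and negative depths clamped to zero. The input
    trace is not modified.

    Parameters
    ----------
    window_short, window_long : float
        Filter windows in seconds; each must cover at least one sample.
    quantile : float
        Low quantile tracking the surface, in (0, 0.5).
    """
    if not (0 < quantile < 0.5):
        raise ValueError("quantile must be in (0, 0.5)")
    if window_short < trace.sampling_interval or window_long < trace.sampling_interval:
        raise ValueError("windows must cover at least one sampling interval")
    if len(trace) == 0 or not np.any(np.isfinite(trace.depth)):
        raise ValueError("trace has no usable depth samples")
    n_short = max(1, int(round(window_short / trace.sampling_interval)))
    n_long = max(1, int(round(window_long / trace.sampling_interval)))
    first = _rolling_quantile(trace.depth, n_short, quantile)
    offset = _rolling_quantile(first, n_long, quantile)
    corrected = np.clip(trace.depth - offset, 0.0, None)
    return replace(trace, depth=corrected)


def detect_trips(trace: TDRTrace, min_dry: float = 10.0) -> list[Trip]:
    """Split a record into foraging trips using the wet/dry channel.

    A trip is a maximal wet interval; dry spells shorter than ``min_dry``
    minutes are treated as sensor flicker and bridged.
    """
    wet = trace.wet.copy()
    if not wet.any():
        return []
    min_dry_samples = int(round(min_dry * 60.0 / trace.sampling_interval))
    # bridge interior dry flickers
    idx = np.flatnonzero(wet)
    lo, hi = idx[0], idx[-1]
    dry_runs = _bool_runs(~wet[lo : hi + 1])
    for a, b in dry_runs:
        if (b - a) < min_dry_samples:
            wet[lo + a : lo + b] = True
    trips = []
    for a, b in _bool_runs(wet):
        departure = trace.time[a]
        return_time = trace.time[a] + (b - a) * trace.sampling_interval
        trips.append(Trip(start=a, end=b, departure=departure, return_time=return_time))
    return trips


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, end) runs of True in a boolean array."""
    if len(mask) == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    return list(zip(edges[::2], edges[1::2]))


def detect_dives(
    trace: TDRTrace,
    threshold: float = 4.0,
    surface_eps: float = SURFACE_EPS,
    min_samples: int = 3,
) -> list[Dive]:
    """Detect dives: maximal submerged excursions strictly deeper than ``threshold``.

    The trace must already be zero-offset corrected. A dive runs from the
    first sample below ``surface_eps`` to one past the last, and is kept
    only if its maximum depth strictly exceeds ``threshold`` (default 4 m:
    shallower excursions are travel or wave artefacts, not foraging) and it
    spans at least ``min_samples`` samples.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    dt = trace.sampling_interval
    dives = []
    for a, b in _bool_runs(trace.depth > surface_eps):
        if (b - a) < min_samples:
            continue
        seg = trace.depth[a:b]
        mdd = float(seg.max())
        if mdd > threshold:
            dives.append(
                Dive(
                    start=a,
                    end=b,
                    t_start=float(trace.time[a]),
                    t_end=float(trace.time[a] + (b - a) * dt),
                    max_depth=mdd,
                    duration=(b - a) * dt,
                )
            )
    return dives


def segment_phases(dive: Dive, trace: TDRTrace, bottom_frac: float = 0.75) -> Dive:
    """Partition a dive into descent, bottom and ascent phases.

    The bottom phase spans the first to the last sample at or below
    ``bottom_frac`` of maximum dive depth; descent precedes it, ascent
    follows. The three half-open intervals partition ``[start, end)``, so
    phase durations sum exactly to dive duration. A V-shaped dive yields a
    bottom phase of a single sample (the apex).
    """
    d = trace.depth[dive.start : dive.end]
    dt = trace.sampling_interval
    at_bottom = np.flatnonzero(d >= bottom_frac * dive.max_depth)
    i0, i1 = int(at_bottom[0]), int(at_bottom[-1]) + 1
    out = replace(
        dive,
        bottom_start=dive.start + i0,
        bottom_end=dive.start + i1,
        descent_s=i0 * dt,
        bottom_s=(i1 - i0) * dt,
        ascent_s=(len(d) - i1) * dt,
    )
    return out


def post_dive_intervals(dives: Sequence[Dive]) -> list[Dive]:
    """Set each dive's post-dive surface interval from its successor.

    ``PDI_i = t_start(i+1) - t_end(i)``; the last dive of a trip has no
    post-dive interval. Dives must be time-ordered and non-overlapping.
    """
    out = []
    for i, dv in enumerate(dives):
        if i + 1 < len(dives):
            pdi = dives[i + 1].t_start - dv.t_end
            if pdi < 0:
                raise ValueError("dives overlap or are out of order")
        else:
            pdi = None
        out.append(replace(dv, post_dive_interval=pdi))
    return out


# ---------------------------------------------------------------------------
# CSV I/O (dialect shared with the synthetic generator)

def write_tdr_csv(path, trace: TDRTrace, seal_id: str) -> None:
    """Write a trace in the TDR CSV dialect (SAST timestamps, +02:00)."""
    ts = pd.to_datetime(np.round(trace.time).astype("int64"), unit="s", utc=True)
    ts = ts.tz_convert("Etc/GMT-2")  # fixed +02:00 offset (SAST)
    df = pd.DataFrame(
        {
            "seal_id": seal_id,
            "timestamp": ts.strftime("%Y-%m-%dT%H:%M:%S%z"),
            "depth_m": np.round(trace.depth, 3),
            "wet": trace.wet.astype(int),
        }
    )
    if trace.temp is not None:
        df["temp_c"] = np.round(trace.temp, 2)
    df.to_csv(path, index=False)


def read_tdr_csv(path) -> tuple[str, TDRTrace]:
    """Read a trace written by :func:`write_tdr_csv`; returns (seal_id, trace)."""
    df = pd.read_csv(path)
    t = pd.to_datetime(df["timestamp"], utc=True).astype("int64").to_numpy() / 1e9
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 5.0
    temp = df["temp_c"].to_numpy(dtype=float) if "temp_c" in df else None
    trace = TDRTrace(
        time=t,
        depth=df["depth_m"].to_numpy(dtype=float),
        wet=df["wet"].to_numpy(dtype=bool),
        sampling_interval=dt,
        temp=temp,
    )
    return str(df["seal_id"].iloc[0]), trace


def dives_to_frame(dives: Sequence[Dive], seal_id: str = "", trip_id: int = 1) -> pd.DataFrame:
    """Tabulate dives as the dive-table CSV layout."""
    rows = []
    for i, dv in enumerate(dives, start=1):
        rows.append(
            {
                "seal_id": seal_id,
                "trip_id": trip_id,
                "dive_id": i,
                "t_start": dv.t_start,
                "t_end": dv.t_end,
                "duration_s": dv.duration,
                "max_depth_m": dv.max_depth,
                "bottom_s": dv.bottom_s,
                "pdi_s": dv.post_dive_interval,
                "shape": dv.shape,
                "diel": dv.diel,
            }
        )
    return pd.DataFrame(rows)
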