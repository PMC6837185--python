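"""Per-trip and per-seal foraging-effort metrics.

Dive rate is the vertical distance covered per hour of trip,
``DR = sum(2 * MDD) / TD`` with MDD the maximum depth of each dive and TD
the trip duration in hours — every metre descended is also ascended.
Because dive depth and duration distributions are strongly right-skewed,
per-trip summaries report modal and median statistics rather than means.
Body condition index (BCI) is the residual, in kg, of the cohort ordinary
least-squares regression of body mass on standard length: mass-for-length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from sealdive.extraction import Dive, Trip

__all__ = ["Morphometrics", "TripSummary", "histogram_mode", "dive_rate", "bci", "trip_summary"]


@dataclass(frozen=True)
class Morphometrics:
    """Standard capture measurements for one seal."""

    sl: float  # standard length, cm
    mass: float  # kg
    ag: float  # axillary girth, cm
    ffl: Optional[float] = None  # fore-flipper length, cm

    def __post_init__(self) -> None:
        if self.sl <= 0 or self.mass <= 0 or self.ag <= 0:
            raise ValueError("lengths and mass must be positive")
        if self.ffl is not None and self.ffl <= 0:
            raise ValueError("fore-flipper length must be positive")

    @property
    def ffl_sl(self) -> Optional[float]:
        return None if self.ffl is None else self.ffl / self.sl


@dataclass
class TripSummary:
    """Effort metrics for one foraging trip."""

    trip_days: float
    n_dives: int
    dive_rate_m_h: float
    modal_depth_m: float
    median_depth_m: float
    max_depth_m: float
    modal_duration_min: float
    median_duration_min: float
    max_duration_min: float
    nocturnal_pct: float
    benthic_pct: float
    time_to_first_dive_h: float
    defined: bool = True


def histogram_mode(x: np.ndarray, bin_width: float) -> float:
    """Midpoint of the most populated histogram bin (bins anchored at 0).

    Ties break toward the smaller (shallower/shorter) bin, making the mode
    deterministic for a given bin width.
    """
    x = np.asarray(x, dtype=float)
    if len(x) == 0:
        return float("nan")
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    idx = np.floor(x / bin_width).astype(np.int64)
    counts = np.bincount(idx - idx.min())
    best = int(np.argmax(counts)) + idx.min()  # argmax takes the first maximum
    return (best + 0.5) * bin_width


def dive_rate(dives: Sequence[Dive] | np.ndarray, td_hours: float) -> float:
    """Vertical distance travelled per hour of trip (m/h).

    ``dives`` may be Dive objects or a plain array of maximum depths.
    """
    if td_hours <= 0:
        raise ValueError("trip duration must be positive")
    if len(dives) == 0:
        return 0.0
    if isinstance(dives[0], Dive):
        mdd = np.array([dv.max_depth for dv in dives])
    else:
        mdd = np.asarray(dives, dtype=float)
    return float(2.0 * mdd.sum() / td_hours)


def bci(seals) -> np.ndarray:
    """Body condition index: residuals of cohort OLS of mass on standard length.

    Accepts a sequence of :class:`Morphometrics`, or a DataFrame with
    ``sl_cm`` and ``mass_kg`` columns. Returns residuals in kg; they sum to
    zero and are uncorrelated with SL by construction.
    """
    if isinstance(seals, pd.DataFrame):
        sl = seals["sl_cm"].to_numpy(dtype=float)
        mass = seals["mass_kg"].to_numpy(dtype=float)
    else:
        sl = np.array([s.sl for s in seals], dtype=float)
        mass = np.array([s.mass for s in seals], dtype=float)
    if len(sl) < 3:
        raise ValueError("need at least 3 seals for a cohort regression")
    if np.var(sl) == 0:
        raise ValueError("standard length is constant; regression undefined")
    slope, intercept = np.polyfit(sl, mass, 1)
    return mass - (slope * sl + intercept)


def trip_summary(
    trip: Trip,
    dives: Sequence[Dive],
    depth_bin: float = 0.5,
    dur_bin_min: float = 0.1,
) -> TripSummary:
    """Summarize one classified trip.

    Modal statistics use histogram bins of ``depth_bin`` metres and
    ``dur_bin_min`` minutes (modes are conventionally reported to 0.1
    precision); medians and maxima are exact. An empty trip yields a
    summary flagged ``defined=False`` with NaN statistics.
    """
    td_days = trip.duration_days
    if len(dives) == 0:
        return TripSummary(
            trip_days=td_days, n_dives=0, dive_rate_m_h=0.0,
            modal_depth_m=float("nan"), median_depth_m=float("nan"),
            max_depth_m=float("nan"), modal_duration_min=float("nan"),
            median_duration_min=float("nan"), max_duration_min=float("nan"),
            nocturnal_pct=float("nan"), benthic_pct=float("nan"),
            time_to_first_dive_h=float("nan"), defined=False,
        )
    depths = np.array([dv.max_depth for dv in dives])
    durs_min = np.array([dv.duration for dv in dives]) / 60.0
    shapes = [dv.shape for dv in dives]
    diels = [dv.diel for dv in dives]
    return TripSummary(
        trip_days=td_days,
        n_dives=len(dives),
        dive_rate_m_h=dive_rate(dives, td_days * 24.0),
        modal_depth_m=histogram_mode(depths, depth_bin),
        median_depth_m=float(np.median(depths)),
        max_depth_m=float(depths.max()),
        modal_duration_min=histogram_mode(durs_min, dur_bin_min),
        median_duration_min=float(np.median(durs_min)),
        max_duration_min=float(durs_min.max()),
        nocturnal_pct=(
            100.0 * diels.count("night") / len(dives)
            if all(d is not None for d in diels) else float("nan")
        ),
        benthic_pct=(
            100.0 * shapes.count("BENTHIC") / len(dives)
            if all(s is not None for s in shapes) else float("nan")
        ),
        time_to_first_dive_h=(dives[0].t_start - trip.departure) / 3600.0,
    )
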