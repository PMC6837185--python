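"""Dive-shape and diel classification.

Each dive receives exactly one shape label:

``PURSUIT``
    a partial ascent from a first nadir followed by a second, faster
    descent to a substantially greater depth (interpreted as chasing a
    single prey item encountered at the schooling-prey layer);
``BENTHIC``
    a flat bottom phase (low depth variation) at a depth shared with
    adjacent dives, the signature of seafloor foraging over level
    bathymetry;
``V``
    negligible bottom time (spike profile);
``U``
    everything else — the canonical flat-bottomed pelagic foraging dive.

Precedence is PURSUIT > BENTHIC > V > U: a pursuit dive may terminate near
the seafloor and a V spike carries no bottom phase to test for flatness.
Diel class is assigned from the dive start time against civil twilight
(sun 6 deg below the horizon) at the colony, or fixed clock times.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from sealdive.extraction import Dive, TDRTrace, Trip, segment_phases
from sealdive.twilight import twilight_crossings

__all__ = [
    "ShapeParams",
    "TwilightSpec",
    "classify_shape",
    "classify_dives",
    "assign_diel",
    "shape_summary",
]

SHAPE_LABELS = ("U", "V", "PURSUIT", "BENTHIC")


@dataclass(frozen=True)
class ShapeParams:
    """Thresholds for the shape rules (all configurable).

    Defaults are tuned to canonical profile exemplars: a V dive spends
    under 10 % of its duration in the bottom phase; a pursuit dive ascends
    at least 5 m before re-descending at >= 1.2x the first descent rate to
    >= 1.25x the first nadir; a benthic dive has bottom-depth CV <= 5 % and
    a maximum depth within 10 % of at least two adjacent dives.
    """

    v_bottom_frac_max: float = 0.10
    pursuit_reversal_min: float = 5.0
    pursuit_deepen_min: float = 0.25
    pursuit_rate_ratio_min: float = 1.2
    benthic_cv_max: float = 0.05
    benthic_seq_tol: float = 0.10
    benthic_seq_n: int = 3
    benthic_bottom_samples_min: int = 3
    #: flatness is judged on samples at or below this fraction of maximum
    #: depth, so the test is not diluted by descent/ascent ramp samples
    #: that fall inside the (75 % of max) bottom phase on deep dives
    benthic_flat_frac: float = 0.90
    #: minimum fraction of the bottom phase spent at near-bottom depth;
    #: rejects pelagic dives whose ragged bottoms merely pass the CV test
    benthic_flat_cover_min: float = 0.60

    def __post_init__(self) -> None:
        for name in ("v_bottom_frac_max", "pursuit_deepen_min", "benthic_cv_max", "benthic_seq_tol"):
            if not (0 < getattr(self, name) < 1):
                raise ValueError(f"{name} must be in (0, 1)")
        if self.pursuit_rate_ratio_min < 1:
            raise ValueError("pursuit_rate_ratio_min must be >= 1")
        if self.benthic_seq_n < 2:
            raise ValueError("benthic_seq_n must be >= 2")


@dataclass(frozen=True)
class TwilightSpec:
    """Night/day boundary definition.

    Either solar geometry at a site (``latitude``/``longitude`` with the
    civil-twilight ``sun_altitude``) or fixed local clock times
    (``fixed_dusk``/``fixed_dawn``), which take precedence when given and
    make classification exactly reproducible in tests. Local time is SAST
    (UTC ``tz_offset_hours``).
    """

    latitude: float = -29.5695
    longitude: float = 16.9967
    sun_altitude: float = -6.0
    fixed_dusk: Optional[_dt.time] = None
    fixed_dawn: Optional[_dt.time] = None
    tz_offset_hours: float = 2.0

    def __post_init__(self) -> None:
        if not -90 <= self.latitude <= 90:
            raise ValueError("latitude must be in [-90, 90]")
        if self.fixed_dusk is not None and self.fixed_dusk == self.fixed_dawn:
            raise ValueError("dusk and dawn must differ")


def _is_pursuit(depth: np.ndarray, times: np.ndarray, params: ShapeParams) -> bool:
    """Detect the reversal-then-deeper-faster signature within one dive."""
    m = int(np.argmax(depth))
    if m < 2:
        return False
    # deepest reversal before the final nadir: the point with the largest
    # ascent from the running maximum depth
    cummax = np.maximum.accumulate(depth[: m + 1])
    rise = cummax - depth[: m + 1]
    j = int(np.argmax(rise))  # shallowest point of the reversal
    reversal = float(rise[j])
    if reversal < params.pursuit_reversal_min:
        return False
    k = int(np.argmax(depth[: j + 1]))  # first nadir
    if k == 0 or depth[k] <= 0:
        return False
    if depth[m] < (1 + params.pursuit_deepen_min) * depth[k]:
        return False
    t1 = times[k] - times[0]
    t2 = times[m] - times[j]
    if t1 <= 0 or t2 <= 0:
        return False
    # rates from in-dive differences: the first sample is already submerged
    rate1 = (depth[k] - depth[0]) / t1
    rate2 = (depth[m] - depth[j]) / t2
    if rate1 <= 0:
        return False
    return rate2 >= params.pursuit_rate_ratio_min * rate1


def _is_benthic(
    dive: Dive, trace: TDRTrace, neighbours: Sequence[Dive], params: ShapeParams
) -> bool:
    d = trace.depth[dive.start : dive.end]
    near_bottom = d[d >= params.benthic_flat_frac * dive.max_depth]
    nb = dive.bottom_end - dive.bottom_start
    if len(near_bottom) < params.benthic_bottom_samples_min or nb < 1:
        return False
    if len(near_bottom) / nb < params.benthic_flat_cover_min:
        return False
    mean = near_bottom.mean()
    if mean <= 0 or near_bottom.std() / mean > params.benthic_cv_max:
        return False
    close = sum(
        1
        for other in neighbours
        if other is not dive
        and abs(other.max_depth - dive.max_depth) <= params.benthic_seq_tol * dive.max_depth
    )
    return close >= params.benthic_seq_n - 1


def classify_shape(
    dive: Dive,
    trace: TDRTrace,
    neighbours: Sequence[Dive] = (),
    params: Optional[ShapeParams] = None,
) -> str:
    """Assign one of U/V/PURSUIT/BENTHIC to a phase-segmented dive.

    ``neighbours`` are the adjacent dives of the same trip (used by the
    benthic consistent-depth rule); an empty sequence disables that rule.
    """
    params = params or ShapeParams()
    if not dive.has_phases:
        dive = segment_phases(dive, trace)
    d = trace.depth[dive.start : dive.end]
    t = trace.time[dive.start : dive.end]
    if _is_pursuit(d, t, params):
        return "PURSUIT"
    if _is_benthic(dive, trace, neighbours, params):
        return "BENTHIC"
    if dive.bottom_fraction < params.v_bottom_frac_max:
        return "V"
    return "U"


def classify_dives(
    dives: Sequence[Dive],
    trace: TDRTrace,
    params: Optional[ShapeParams] = None,
    twilight: Optional[TwilightSpec] = None,
) -> list[Dive]:
    """Label every dive of a trip with shape (and diel class when twilight is given).

    Benthic adjacency is evaluated against the ``benthic_seq_n - 1``
    nearest dives on each side, so the rule is symmetric in sequence
    direction.
    """
    params = params or ShapeParams()
    dives = [dv if dv.has_phases else segment_phases(dv, trace) for dv in dives]
    win = params.benthic_seq_n - 1
    out = []
    for i, dv in enumerate(dives):
        neigh = dives[max(0, i - win) : i] + dives[i + 1 : i + 1 + win]
        dv.shape = classify_shape(dv, trace, neigh, params)
        if twilight is not None:
            dv.diel = assign_diel(dv, twilight)
        out.append(dv)
    return out


def _local_datetime(epoch_s: float, tz_offset_hours: float) -> _dt.datetime:
    tz = _dt.timezone(_dt.timedelta(hours=tz_offset_hours))
    return _dt.datetime.fromtimestamp(epoch_s, tz)


def assign_diel(dive, twilight: TwilightSpec) -> str:
    """Night or day, from the dive start time.

    Night is the half-open window [dusk, dawn): a dive starting exactly at
    dawn counts as day. Dives are short relative to twilight, so the start
    time decides the class for the whole dive.
    """
    t = dive.t_start if isinstance(dive, Dive) else float(dive)
    local = _local_datetime(t, twilight.tz_offset_hours)
    if twilight.fixed_dusk is not None and twilight.fixed_dawn is not None:
        tod = local.time()
        dusk, dawn = twilight.fixed_dusk, twilight.fixed_dawn
        if dusk > dawn:  # night wraps midnight (the usual case)
            return "night" if (tod >= dusk or tod < dawn) else "day"
        return "night" if dusk <= tod < dawn else "day"
    midnight_utc = (
        _dt.datetime(local.year, local.month, local.day, tzinfo=_dt.timezone.utc)
        - _dt.timedelta(hours=twilight.tz_offset_hours)
    ).timestamp()
    # same-local-date dawn and dusk; night = before dawn or from dusk onward
    dawn, dusk = twilight_crossings(
        midnight_utc, twilight.latitude, twilight.longitude, twilight.sun_altitude
    )
    return "night" if (t < dawn or t >= dusk) else "day"


def shape_summary(trip: Optional[Trip], dives: Sequence[Dive]) -> dict:
    """Per-trip shape and diel proportions.

    Returns a dict with one proportion per shape label (fractions summing
    to 1), ``nocturnal_pct``, the dive count and a ``defined`` flag which
    is False for an empty trip (proportions are NaN then).
    """
    n = len(dives)
    if n == 0:
        out = {f"prop_{s}": float("nan") for s in SHAPE_LABELS}
        out.update(nocturnal_pct=float("nan"), n_dives=0, defined=False)
        return out
    shapes = [dv.shape for dv in dives]
    if any(s is None for s in shapes):
        raise ValueError("all dives must be shape-labelled first")
    out = {f"prop_{s}": shapes.count(s) / n for s in SHAPE_LABELS}
    diels = [dv.diel for dv in dives]
    out["nocturnal_pct"] = (
        100.0 * diels.count("night") / n if all(d is not None for d in diels) else float("nan")
    )
    out["n_dives"] = n
    out["defined"] = True
    return out
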