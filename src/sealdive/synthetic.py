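"""Synthetic TDR generator with known ground truth.

Emulates multi-day central-place foraging trips of a lactating fur seal:
dives of four shapes (U, V, pursuit, benthic) placed by an inhomogeneous
Poisson process with diel structure, post-dive surface intervals inflated
beyond a configurable aerobic dive limit, bathymetry-limited benthic
depths, slow pressure-transducer drift and Gaussian sensor noise. Every
emitted dive is recorded in a parallel truth table, so downstream stages
(zero-offset correction, dive detection, shape classification, bADL
estimation, clustering) can be validated against exact labels.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from sealdive.extraction import TDRTrace

__all__ = [
    "ShapeDepthParams",
    "PDIModel",
    "DriftModel",
    "SimConfig",
    "SimTruth",
    "simulate_dive_profile",
    "simulate_trip",
    "simulate_population",
]

SHAPES = ("U", "V", "PURSUIT", "BENTHIC")


@dataclass(frozen=True)
class ShapeDepthParams:
    """Per-shape dive geometry distributions.

    Maximum depth is lognormal (``depth_median`` m, ``depth_sigma`` log-sd);
    vertical speeds are in m/s; ``bottom_frac`` is the fraction of dive
    duration spent in the bottom phase (U/benthic shapes).
    """

    depth_median: float
    depth_sigma: float
    descent_rate: float = 1.0
    ascent_rate: float = 1.0
    bottom_frac: float = 0.5
    bottom_frac_sd: float = 0.05


@dataclass(frozen=True)
class PDIModel:
    """Post-dive interval: base + penalty beyond the aerobic limit.

    ``pdi = base + slope * max(0, duration - true_adl) + lognormal noise``.
    The additive lognormal keeps the surface interval strictly positive and
    right-skewed, as wet/dry records show.
    """

    base: float = 60.0
    slope: float = 2.0
    noise_mu: float = 1.6  # log-seconds; median ~5 s
    noise_sigma: float = 0.6


@dataclass(frozen=True)
class DriftModel:
    """Additive surface-offset: slow linear transducer drift (m/day)."""

    rate_m_per_day: float = 1.0
    initial_offset: float = 0.0

    def offset(self, t: np.ndarray, t0: float) -> np.ndarray:
        return self.initial_offset + self.rate_m_per_day * (np.asarray(t) - t0) / 86400.0


def _default_diel_weights() -> np.ndarray:
    """Hourly dive-rate weights (dives/h) with dusk/dawn peaks.

    Night-heavy with crepuscular maxima and a midday lull; mean ~8 dives/h,
    matching the observed per-trip dive counts. The published study gives
    no per-hour rates, so the shape is a module default.
    """
    w = np.array(
        [10, 10, 9, 9, 8, 10, 12, 10, 6, 4, 3, 2,
         2, 2, 3, 4, 6, 10, 14, 13, 11, 10, 10, 10],
        dtype=float,
    )
    return w * (8.0 / w.mean())


def _default_depth_params() -> dict[str, ShapeDepthParams]:
    return {
        "U": ShapeDepthParams(depth_median=20.0, depth_sigma=0.8, bottom_frac=0.5),
        "V": ShapeDepthParams(depth_median=10.0, depth_sigma=0.7, bottom_frac=0.0),
        "PURSUIT": ShapeDepthParams(depth_median=40.0, depth_sigma=0.4, bottom_frac=0.15),
        "BENTHIC": ShapeDepthParams(depth_median=150.0, depth_sigma=0.0, bottom_frac=0.5,
                                    bottom_frac_sd=0.02),
    }


@dataclass
class SimConfig:
    """Study-condition parameters for one simulated foraging trip."""

    sampling_interval: float = 5.0
    trip_duration_days: float = 5.0
    #: dives/hour by hour-of-day (length 24)
    dive_rate_target: np.ndarray = field(default_factory=_default_diel_weights)
    #: proportions over SHAPES; the observed cohort mixture
    shape_mixture: dict = field(
        default_factory=lambda: {"U": 0.531, "V": 0.134, "PURSUIT": 0.171, "BENTHIC": 0.164}
    )
    depth_params: dict = field(default_factory=_default_depth_params)
    seafloor_depth: float = 150.0
    true_adl: float = 231.0
    pdi_model: PDIModel = field(default_factory=PDIModel)
    drift_model: DriftModel = field(default_factory=DriftModel)
    noise_sd: float = 0.2
    #: trip departure, seconds since epoch (default a winter night, SAST)
    start_time: float = float(pd.Timestamp("2006-07-02T22:00:00+02:00").timestamp())
    #: hours treated as night when biasing benthic dives toward daylight
    night_hours: frozenset = frozenset({18, 19, 20, 21, 22, 23, 0, 1, 2, 3, 4, 5, 6})
    #: multiplier on the benthic mixture weight during night hours
    #: (1.0 = no diel bias; the benthic archetype suppresses night dives)
    benthic_night_suppression: float = 1.0
    #: probability of repeating the previous dive's shape (bout structure;
    #: benthic dives occur in runs of consistent depth, as over level
    #: bathymetry). Repeats preserve the marginal shape mixture.
    shape_persistence: float = 0.70
    seed: Optional[int] = None

    def validate(self) -> None:
        if abs(sum(self.shape_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("shape_mixture must sum to 1")
        if set(self.shape_mixture) - set(SHAPES):
            raise ValueError(f"unknown shape in mixture: {set(self.shape_mixture) - set(SHAPES)}")
        if self.sampling_interval <= 0 or self.trip_duration_days <= 0:
            raise ValueError("sampling_interval and trip_duration_days must be positive")
        if np.any(np.asarray(self.dive_rate_target) < 0) or len(self.dive_rate_target) != 24:
            raise ValueError("dive_rate_target must be 24 non-negative hourly rates")
        if self.seafloor_depth <= 0 or self.true_adl <= 0 or self.noise_sd < 0:
            raise ValueError("depths, ADL must be positive; noise_sd non-negative")

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SimTruth:
    """Ground truth emitted alongside a simulated trace."""

    dives: pd.DataFrame  # t_start, t_end, shape, max_depth_m, duration_s, exceeded_adl, pdi_s
    trip_start: float
    trip_end: float
    drift: Optional[np.ndarray]
    seed: Optional[int]


# ---------------------------------------------------------------------------
# Single-dive profile construction


def simulate_dive_profile(
    shape: str,
    *,
    max_depth: float,
    duration: Optional[float] = None,
    bottom_frac: float = 0.5,
    first_nadir: Optional[float] = None,
    reversal: float = 10.0,
    rate_ratio: float = 1.5,
    descent_rate: float = 1.0,
    sampling_interval: float = 5.0,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Construct a noise-free depth profile of one dive.

    Shapes
    ------
    U : descent, contiguous bottom period at >= 75 % of maximum depth
        occupying ``bottom_frac`` of the duration, ascent.
    V : symmetric spike; only the apex sample lies in the top quartile of
        depth.
    PURSUIT : descent to ``first_nadir``, partial ascent of ``reversal``
        metres, then a second, faster descent (mean rate ``rate_ratio``
        times the first) to ``max_depth``.
    BENTHIC : flat bottom at ``max_depth`` (the seafloor) with bottom-depth
        coefficient of variation < 2 %.

    Returns depth samples (m), surface to surface, at ``sampling_interval``.
    """
    if shape not in SHAPES:
        raise ValueError(f"unknown dive shape: {shape!r}")
    if max_depth <= 0:
        raise ValueError("max_depth must be positive")
    dt = sampling_interval

    if shape in ("U", "BENTHIC"):
        if duration is None:
            raise ValueError(f"{shape} profile needs a duration")
        n = int(round(duration / dt))
        if n < 3:
            raise ValueError("duration must span at least 3 sampling intervals")
        n_bottom = max(1, int(round(bottom_frac * n)))
        n_desc = max(1, (n - n_bottom) // 2)
        n_asc = max(1, n - n_bottom - n_desc)
        n_bottom = n - n_desc - n_asc
        desc = np.linspace(0, max_depth, n_desc + 1)[1:]
        bottom = np.full(n_bottom, max_depth)
        if rng is not None and n_bottom > 1:
            if shape == "BENTHIC":
                # level seafloor: bottom-depth CV well under 2 %
                bottom = bottom * (1 + rng.normal(0, 0.0075, n_bottom)).clip(0.9, 1.0)
            else:
                # pelagic U: ragged bottom (school chasing), still >= 75 % of max
                bottom = bottom * rng.uniform(0.78, 1.0, n_bottom)
        asc = np.linspace(max_depth, 0, n_asc + 2)[1:-1]
        prof = np.concatenate([desc, bottom, asc])
    elif shape == "V":
        # spike profile: linear shoulders to 70 % of depth, a single apex
        # sample, so only the apex lies in the top quartile of depth
        if duration is None:
            duration = 2 * max_depth / descent_rate
        n = int(round(duration / dt))
        if n < 3:
            raise ValueError("duration must span at least 3 sampling intervals")
        shoulder = 0.6 * max_depth
        n_desc = (n - 1) // 2
        n_asc = n - 1 - n_desc
        desc = np.linspace(0, shoulder, n_desc + 1)[1:]
        asc = np.linspace(shoulder, 0, n_asc + 1)[:-1]
        prof = np.concatenate([desc, [max_depth], asc])
    else:  # PURSUIT
        if first_nadir is None:
            first_nadir = 0.5 * max_depth
        if not (0 < first_nadir < max_depth):
            raise ValueError("first_nadir must lie strictly between 0 and max_depth")
        r1 = descent_rate
        r2 = rate_ratio * r1
        n1 = max(2, int(round(first_nadir / (r1 * dt))))
        n_pause = 2  # brief levelling at the first nadir (apparent bottom phase)
        n_rev = max(1, int(round(reversal / (r1 * dt))))
        shallowest = first_nadir - reversal
        if shallowest <= 0:
            raise ValueError("reversal exceeds first nadir depth")
        n2 = max(1, int(np.ceil((max_depth - shallowest) / (r2 * dt))))
        n_out = max(2, int(round(max_depth / (r1 * dt))))
        seg1 = np.linspace(0, first_nadir, n1 + 1)[1:]
        pause = np.full(n_pause, first_nadir)
        rev = np.linspace(first_nadir, shallowest, n_rev + 1)[1:]
        seg2 = np.linspace(shallowest, max_depth, n2 + 1)[1:]
        out = np.linspace(max_depth, 0, n_out + 1)[1:-1]
        prof = np.concatenate([seg1, pause, rev, seg2, out])
        if len(prof) < 3:
            raise ValueError("duration must span at least 3 sampling intervals")
    # profiles contain submerged samples only: trim boundary samples that a
    # 0.5 m surface threshold would not count, so truth duration equals the
    # detector's on noise-free traces
    prof = prof[prof > 0.55]
    if len(prof) < 3:
        raise ValueError("dive too shallow/short to span 3 submerged samples")
    return prof


# ---------------------------------------------------------------------------
# Whole-trip simulation


def _draw_dive(config: SimConfig, shape: str, rng: np.random.Generator) -> np.ndarray:
    """Draw geometry for one dive of the given shape and build its profile."""
    p = config.depth_params[shape]
    if shape == "BENTHIC":
        depth = config.seafloor_depth * (1 + rng.normal(0, 0.01))
        travel = depth / p.descent_rate + depth / p.ascent_rate
        bf = np.clip(rng.normal(p.bottom_frac, p.bottom_frac_sd), 0.2, 0.8)
        duration = travel / (1 - bf)
        return simulate_dive_profile(
            "BENTHIC", max_depth=depth, duration=duration, bottom_frac=bf,
            sampling_interval=config.sampling_interval, rng=rng,
        )
    depth = float(rng.lognormal(np.log(p.depth_median), p.depth_sigma)) if p.depth_sigma > 0 else p.depth_median
    depth = min(depth, config.seafloor_depth)  # bathymetry caps pelagic dives too
    depth = max(depth, 5.0)
    if shape == "U":
        bf = np.clip(rng.normal(p.bottom_frac, p.bottom_frac_sd), 0.2, 0.8)
        travel = depth / p.descent_rate + depth / p.ascent_rate
        duration = max(travel / (1 - bf), 3 * config.sampling_interval)
        return simulate_dive_profile(
            "U", max_depth=depth, duration=duration, bottom_frac=bf,
            sampling_interval=config.sampling_interval, rng=rng,
        )
    if shape == "V":
        # at least 12 samples so the apex is under a tenth of the duration
        duration = max(2 * depth / p.descent_rate, 12 * config.sampling_interval)
        return simulate_dive_profile(
            "V", max_depth=depth, duration=duration,
            sampling_interval=config.sampling_interval,
        )
    # PURSUIT: first nadir in the pelagic layer, final nadir much deeper
    nadir1 = depth
    deepen = rng.uniform(1.8, 2.8)
    nadir2 = min(nadir1 * deepen, config.seafloor_depth * 0.95)
    if nadir2 <= nadir1 * 1.3:
        nadir2 = nadir1 * 1.3
    reversal = max(5.0, 0.25 * nadir1)
    return simulate_dive_profile(
        "PURSUIT", max_depth=nadir2, first_nadir=nadir1, reversal=reversal,
        rate_ratio=rng.uniform(1.4, 1.8), descent_rate=config.depth_params["PURSUIT"].descent_rate,
        sampling_interval=config.sampling_interval,
    )


def _hour_of_day(t: float) -> int:
    """Hour of day in SAST (UTC+2) for an epoch timestamp."""
    return int(((t + 7200.0) % 86400.0) // 3600.0)


def _simulate_truth_dives(config: SimConfig, rng: np.random.Generator):
    """Place dives sequentially along the trip; returns (records, profiles)."""
    dt = config.sampling_interval
    t0 = config.start_time
    t_end = t0 + config.trip_duration_days * 86400.0
    rates = np.asarray(config.dive_rate_target, dtype=float)
    max_rate = rates.max()
    shapes = list(config.shape_mixture)
    base_w = np.array([config.shape_mixture[s] for s in shapes])
    records, profiles = [], []
    t = t0
    while True:
        if max_rate <= 0:
            break
        # thinned Poisson: candidate gap at the envelope rate
        t += rng.exponential(3600.0 / max_rate)
        if t >= t_end:
            break
        hour = _hour_of_day(t)
        if rng.uniform() >= rates[hour] / max_rate:
            continue
        # snap the dive start onto the sampling grid
        start = t0 + np.ceil((t - t0) / dt) * dt
        if records and rng.uniform() < config.shape_persistence:
            shape = records[-1]["shape"]
        else:
            w = base_w.copy()
            if "BENTHIC" in shapes and hour in config.night_hours:
                w[shapes.index("BENTHIC")] *= config.benthic_night_suppression
            w = w / w.sum()
            shape = shapes[rng.choice(len(shapes), p=w)]
        prof = _draw_dive(config, shape, rng)
        duration = len(prof) * dt
        end = start + duration
        if end >= t_end:
            break
        pdi = config.pdi_model.base
        excess = max(0.0, duration - config.true_adl)
        pdi += config.pdi_model.slope * excess
        pdi += rng.lognormal(config.pdi_model.noise_mu, config.pdi_model.noise_sigma)
        pdi = np.ceil(pdi / dt) * dt  # next dive also starts on the grid
        records.append(
            {
                "t_start": start,
                "t_end": end,
                "shape": shape,
                "max_depth_m": float(prof.max()),
                "duration_s": duration,
                "exceeded_adl": duration > config.true_adl,
                "pdi_s": pdi,
            }
        )
        profiles.append(prof)
        # the recovery gap is a floor: the next dive may start later still
        t = end + pdi
    # record realized post-dive intervals (recovery floor + waiting time)
    for i in range(len(records)):
        if i + 1 < len(records):
            records[i]["pdi_s"] = records[i + 1]["t_start"] - records[i]["t_end"]
        else:
            records[i]["pdi_s"] = np.nan
    return records, profiles


def simulate_trip(config: SimConfig, seed: Optional[int] = None) -> tuple[TDRTrace, SimTruth]:
    """Simulate one foraging trip; returns the observed trace and its truth.

    The trace is wet for the whole trip and dry for one hour before and
    after it. Transducer drift and Gaussian sensor noise are applied after
    the truth table is recorded, so truth depths are noise-free.
    """
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    dt = config.sampling_interval
    records, profiles = _simulate_truth_dives(config, rng)

    pad = 3600.0
    t_first = config.start_time - pad
    n_total = int(round((config.trip_duration_days * 86400.0 + 2 * pad) / dt))
    time = t_first + dt * np.arange(n_total)
    depth = np.zeros(n_total)
    for rec, prof in zip(records, profiles):
        i = int(round((rec["t_start"] - t_first) / dt))
        depth[i : i + len(prof)] = prof
    wet = (time >= config.start_time) & (
        time < config.start_time + config.trip_duration_days * 86400.0
    )
    drift = config.drift_model.offset(time, config.start_time)
    observed = depth + drift + rng.normal(0, config.noise_sd, n_total)
    trace = TDRTrace(time=time, depth=observed, wet=wet, sampling_interval=dt)
    truth = SimTruth(
        dives=pd.DataFrame(
            records,
            columns=["t_start", "t_end", "shape", "max_depth_m",
                     "duration_s", "exceeded_adl", "pdi_s"],
        ),
        trip_start=config.start_time,
        trip_end=config.start_time + config.trip_duration_days * 86400.0,
        drift=drift,
        seed=seed,
    )
    return trace, truth


def simulate_duration_pdi(
    n: int,
    true_adl: float = 231.0,
    pdi_model: Optional[PDIModel] = None,
    duration_median: float = 150.0,
    duration_sigma: float = 0.6,
    duration_max: float = 600.0,
    seed: Optional[int] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw duration/post-dive-interval pairs with the aerobic-limit structure.

    Dive durations are lognormal (median ``duration_median`` s, truncated
    at ``duration_max``); surface intervals follow the post-dive interval
    model: flat baseline below ``true_adl``, rising at the penalty slope
    above it, with additive lognormal noise. This is the minimal data the
    bADL estimator consumes, without simulating full depth traces.
    """
    if n < 1:
        raise ValueError("n must be positive")
    m = pdi_model or PDIModel()
    rng = np.random.default_rng(seed)
    d = rng.lognormal(np.log(duration_median), duration_sigma, n).clip(15.0, duration_max)
    pdi = m.base + m.slope * np.clip(d - true_adl, 0.0, None)
    pdi = pdi + rng.lognormal(m.noise_mu, m.noise_sigma, n)
    return d, pdi


# ---------------------------------------------------------------------------
# Population-level simulation (foraging-strategy archetypes)


def pelagic_archetype() -> SimConfig:
    """Night-active epipelagic forager: shallow U/V dives, little benthic."""
    cfg = SimConfig()
    return cfg.replace(
        shape_mixture={"U": 0.62, "V": 0.20, "PURSUIT": 0.15, "BENTHIC": 0.03},
        depth_params={
            **_default_depth_params(),
            "U": ShapeDepthParams(depth_median=15.0, depth_sigma=0.6, bottom_frac=0.5),
            "V": ShapeDepthParams(depth_median=8.0, depth_sigma=0.6, bottom_frac=0.0),
        },
        trip_duration_days=4.5,
    )


def benthic_archetype() -> SimConfig:
    """Day-active benthic forager: deep flat-bottom dives, few nocturnal.

    Long benthic dives carry heavy post-dive recovery, so the realized
    daytime dive rate saturates well below the requested envelope; night
    rates are kept very low so the nocturnal proportion stays small.
    """
    cfg = SimConfig()
    day_weights = np.array(
        [0.5, 0.5, 0.5, 0.5, 0.5, 0.5, 1, 6, 10, 12, 12, 12,
         12, 12, 12, 10, 6, 2, 0.5, 0.5, 0.5, 0.5, 0.5, 0.5],
        dtype=float,
    )
    return cfg.replace(
        shape_mixture={"U": 0.15, "V": 0.05, "PURSUIT": 0.05, "BENTHIC": 0.75},
        dive_rate_target=day_weights,
        seafloor_depth=170.0,
        trip_duration_days=5.5,
        benthic_night_suppression=0.05,
    )


def simulate_population(
    n_pelagic: int,
    n_benthic: int,
    configs: Optional[tuple[SimConfig, SimConfig]] = None,
    seed: Optional[int] = None,
) -> tuple[pd.DataFrame, list[str]]:
    """Simulate a two-strategy seal population from truth tables.

    Returns per-seal trip summaries (the six clustering features: trip
    duration, modal dive duration, modal dive depth, dive rate, %
    nocturnal, % benthic) and the true strategy label per seal. Summaries
    are computed from the generator's truth records.
    """
    if n_pelagic < 1 or n_benthic < 1:
        raise ValueError("both group sizes must be >= 1")
    from sealdive.effort import histogram_mode  # late import avoids a cycle

    cfg_p, cfg_b = configs if configs is not None else (pelagic_archetype(), benthic_archetype())
    rng = np.random.default_rng(seed)
    rows, labels = [], []
    plan = [("pelagic", cfg_p)] * n_pelagic + [("benthic", cfg_b)] * n_benthic
    for i, (label, cfg) in enumerate(plan):
        sub_seed = int(rng.integers(0, 2**31 - 1))
        sub_rng = np.random.default_rng(sub_seed)
        records, _ = _simulate_truth_dives(cfg, sub_rng)
        d = pd.DataFrame(records)
        if len(d) == 0:
            raise RuntimeError("archetype produced a trip with no dives")
        hours = ((d["t_start"] + 7200.0) % 86400.0) // 3600.0
        nocturnal = hours.astype(int).isin(cfg.night_hours)
        td_hours = cfg.trip_duration_days * 24.0
        rows.append(
            {
                "seal": f"sim{i + 1:02d}",
                "trip_days": cfg.trip_duration_days,
                # a 30 s duration bin keeps the mode stable for bimodal
                # (short pelagic / long benthic) duration distributions
                "modal_duration_s": histogram_mode(d["duration_s"].to_numpy(), 30.0),
                "modal_depth_m": histogram_mode(d["max_depth_m"].to_numpy(), 5.0),
                "dive_rate_m_h": 2.0 * d["max_depth_m"].sum() / td_hours,
                "nocturnal_pct": 100.0 * nocturnal.mean(),
                "benthic_pct": 100.0 * (d["shape"] == "BENTHIC").mean(),
            }
        )
        labels.append(label)
    return pd.DataFrame(rows).set_index("seal"), labels
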