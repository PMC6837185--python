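"""Shared fixtures: simulated trips at study-default conditions.

Session-scoped so the (cheap but not free) trace simulations run once.
"""

from __future__ import annotations

import numpy as np
import pytest

from sealdive.extraction import (
    detect_dives,
    post_dive_intervals,
    segment_phases,
    zero_offset_correct,
)
from sealdive.synthetic import DriftModel, SimConfig, simulate_trip


@pytest.fixture(scope="session")
def default_trip():
    """Three-day trip at default (noisy, drifting) study conditions."""
    return simulate_trip(SimConfig(trip_duration_days=3.0), seed=42)


@pytest.fixture(scope="session")
def noise_free_trip():
    """Two-day trip with no sensor noise and no transducer drift."""
    cfg = SimConfig(
        trip_duration_days=2.0, noise_sd=0.0, drift_model=DriftModel(rate_m_per_day=0.0)
    )
    return simulate_trip(cfg, seed=11)


@pytest.fixture(scope="session")
def corrected_default(default_trip):
    trace, truth = default_trip
    return zero_offset_correct(trace), truth


@pytest.fixture(scope="session")
def processed_default(corrected_default):
    """Phase-segmented, PDI-assigned dives of the default noisy trip."""
    trace, truth = corrected_default
    dives = [segment_phases(d, trace) for d in detect_dives(trace)]
    return post_dive_intervals(dives), trace, truth


def match_truth(dives, truth, tol_s=15.0):
    """Pair detected dives with truth records by start time."""
    det_start = np.array([d.t_start for d in dives])
    pairs = []
    for _, row in truth.dives.iterrows():
        j = int(np.argmin(np.abs(det_start - row.t_start)))
        pairs.append((dives[j], row) if abs(det_start[j] - row.t_start) <= tol_s else (None, row))
    return pairs
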