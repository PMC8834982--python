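"""Shared fixtures: the expensive BD runs are session-scoped so the
permeation pipeline, Ohmic/area-law properties and the oracle-equivalence
check all reuse the same trajectories."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest

from poregate import (
    ChannelSpec,
    cumulative_charge,
    detect_crossings,
    estimate_current,
    simulate_pore_bd,
)

BD_DT = 0.005  # ns; step SD 1.4 Å vs pore radius 5 Å


def conductance_of(spec: ChannelSpec, duration: float, seed: int,
                   voltage: float | None = None):
    """Full permeation chain on one BD run; returns (estimate, series, traj)."""
    if voltage is not None:
        spec = dataclasses.replace(spec, voltage=voltage)
    traj = simulate_pore_bd(
        spec, duration, BD_DT, spec.matched_ion_count(), seed
    )
    events = detect_crossings(traj, gate_halfwidth=10.0, pore_radius=spec.pore_radius)
    series = cumulative_charge(events, traj.times)
    est = estimate_current(series, spec.voltage)
    return est, series, traj


@pytest.fixture(scope="session")
def open_channel_spec() -> ChannelSpec:
    return ChannelSpec()


@pytest.fixture(scope="session")
def open_run(open_channel_spec):
    """Long open-pore run at +40 mV with well over 2000 crossing events."""
    return conductance_of(open_channel_spec, duration=1400.0, seed=2024)


@pytest.fixture(scope="session")
def open_run_neg(open_channel_spec):
    """Same channel and seed at −40 mV (used for sign symmetry)."""
    spec = dataclasses.replace(open_channel_spec, voltage=-40.0)
    return conductance_of(spec, duration=800.0, seed=2024)


@pytest.fixture(scope="session")
def ohmic_runs(open_channel_spec):
    """Runs at ±20 mV with over 1000 events each (I–V linearity)."""
    out = {}
    for v in (20.0, -20.0):
        spec = dataclasses.replace(open_channel_spec, voltage=v)
        out[v] = conductance_of(spec, duration=1300.0, seed=909)
    return out


@pytest.fixture(scope="session")
def obstructed_runs(open_channel_spec):
    """Runs at obstruction fractions 0.25 and 0.5 for the area law."""
    out = {}
    for f, dur in ((0.25, 1800.0), (0.5, 2400.0)):
        spec = dataclasses.replace(open_channel_spec, obstruction_fraction=f)
        out[f] = conductance_of(spec, duration=dur, seed=777)
    return out
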