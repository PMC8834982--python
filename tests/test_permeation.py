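"""Unit tests for crossing detection, charge accumulation and currents."""

from __future__ import annotations

import math

import numpy as np
import pytest

from poregate import (
    ChargeSeries,
    CrossingEvent,
    ElectrolyteSpec,
    IonTrajectory,
    TrajectoryError,
    ValidationError,
    cumulative_charge,
    current_ratio,
    detect_crossings,
    estimate_current,
    estimate_diffusion_msd,
    field_from_voltage,
    renormalization_factor,
    simulate_bulk_bd,
)
from poregate.specs import SpeciesSpec


def make_traj(z_paths: dict[int, np.ndarray], box_z: float = 80.0,
              valences: dict[int, int] | None = None) -> IonTrajectory:
    """Trajectory from scripted z-paths (x=y=0, inside the pore)."""
    ids = sorted(z_paths)
    n_frames = len(next(iter(z_paths.values())))
    positions = np.zeros((n_frames, len(ids), 3))
    for col, i in enumerate(ids):
        positions[:, col, 2] = z_paths[i]
    valences = valences or {i: 1 for i in ids}
    return IonTrajectory(
        times=np.arange(n_frames) * 0.1,
        positions=positions,
        ids=np.array(ids),
        species=np.array(["K+" if valences[i] > 0 else "Cl-" for i in ids]),
        valence=np.array([valences[i] for i in ids]),
        box=np.array([40.0, 40.0, box_z]),
        voltage=40.0,
    )


def reference_state_machine(z: np.ndarray, gate: float, box_z: float) -> list[int]:
    """Independent brute-force per-frame crossing detector (the oracle)."""
    events = []
    state = 0
    for t in range(len(z)):
        if t > 0 and abs(z[t] - z[t - 1]) > box_z / 2:
            state = 1 if z[t] > gate else (-1 if z[t] < -gate else 0)
            continue
        side = 1 if z[t] > gate else (-1 if z[t] < -gate else 0)
        if side != 0:
            if state != 0 and side != state:
                events.append(side)
            state = side
    return events


class TestDetectCrossings:
    def test_resident_ion_never_crosses(self):
        z = np.full(50, -18.0) + 0.5 * np.sin(np.arange(50))
        assert detect_crossings(make_traj({0: z})) == []

    def test_single_monotone_traversal_with_jitter(self):
        rng = np.random.default_rng(0)
        z = np.linspace(-20, 20, 200) + rng.uniform(-3, 3, 200)
        events = detect_crossings(make_traj({0: z}), gate_halfwidth=10.0)
        assert len(events) == 1
        assert events[0].direction == 1

    def test_double_back_inside_gate_not_double_counted(self):
        # enters the gate, dithers around the mid-plane, exits upward once
        z = np.array([-15, -12, -8, -2, 3, -3, 2, -1, 4, 8, 12, 15], dtype=float)
        events = detect_crossings(make_traj({0: z}), gate_halfwidth=10.0)
        assert len(events) == 1

    def test_periodic_wrap_resets_without_event(self):
        # ion leaves upward, wraps to the bottom bulk: no traversal happened
        z = np.array([12, 15, 25, 35, -38, -30, -20, -15, -12], dtype=float)
        events = detect_crossings(make_traj({0: z}, box_z=80.0), gate_halfwidth=10.0)
        assert events == []

    def test_scripted_paths_match_reference_state_machine(self):
        rng = np.random.default_rng(7)
        box_z = 80.0
        paths = {}
        for i in range(50):
            steps = rng.normal(scale=4.0, size=400)
            z = np.cumsum(steps) - 20.0
            z = (z + box_z / 2) % box_z - box_z / 2  # wrap into the box
            paths[i] = z
        traj = make_traj(paths, box_z=box_z)
        ours = detect_crossings(traj, gate_halfwidth=10.0)
        got = {}
        for ev in ours:
            got.setdefault(ev.ion_id, []).append(ev.direction)
        for i, z in paths.items():
            assert got.get(i, []) == reference_state_machine(z, 10.0, box_z), i

    def test_radial_gate_vetoes_outside_pore(self):
        z = np.linspace(-20, 20, 100)
        traj = make_traj({0: z})
        traj.positions[:, 0, 0] = 9.0  # passes the mid-plane at rho = 9 Å
        assert detect_crossings(traj, pore_radius=5.0, pore_radius_margin=2.0) == []
        assert len(detect_crossings(traj, pore_radius=8.0, pore_radius_margin=2.0)) == 1

    def test_non_uniform_times_raise(self):
        traj = make_traj({0: np.linspace(-20, 20, 50)})
        traj.times = traj.times.copy()
        traj.times[-1] += 0.05
        with pytest.raises(TrajectoryError):
            detect_crossings(traj)


class TestCumulativeCharge:
    def test_open_state_event_counts_sum(self):
        # 238 cations downward plus 529 anions upward: |q_tot| = 767 e
        events = [
            CrossingEvent(i, "K+", 1, 0.1 + i * 1e-3, -1) for i in range(238)
        ] + [
            CrossingEvent(1000 + i, "Cl-", -1, 0.2 + i * 1e-3, 1)
            for i in range(529)
        ]
        series = cumulative_charge(events, np.linspace(0, 10, 101))
        assert abs(series.q_tot[-1]) == 767
        assert series.event_counts() == {"K+": 238, "Cl-": 529}

    def test_no_events_is_identically_zero(self):
        series = cumulative_charge([], np.linspace(0, 5, 51))
        assert np.all(series.q_tot == 0)

    def test_up_then_down_cancels(self):
        events = [
            CrossingEvent(0, "K+", 1, 1.0, 1),
            CrossingEvent(0, "K+", 1, 2.0, -1),
        ]
        series = cumulative_charge(events, np.linspace(0, 5, 51))
        assert series.q_tot[-1] == 0
        assert abs(series.q_tot[np.searchsorted(series.times, 1.5)]) == 1

    def test_event_outside_range_raises(self):
        with pytest.raises(ValidationError):
            cumulative_charge(
                [CrossingEvent(0, "K+", 1, 99.0, 1)], np.linspace(0, 5, 51)
            )

    def test_every_event_changes_q_by_one(self):
        rng = np.random.default_rng(3)
        events = [
            CrossingEvent(
                i,
                "K+" if rng.random() < 0.5 else "Cl-",
                1 if rng.random() < 0.5 else -1,
                float(rng.uniform(0, 10)),
                1 if rng.random() < 0.5 else -1,
            )
            for i in range(200)
        ]
        # fix valence/species consistency
        events = [
            CrossingEvent(e.ion_id, "K+" if e.valence > 0 else "Cl-",
                          e.valence, e.time, e.direction)
            for e in events
        ]
        # evaluate on a grid containing every (distinct) event time, so each
        # event is resolved individually
        times = np.unique(
            np.concatenate([[0.0, 10.0], [e.time for e in events]])
        )
        series = cumulative_charge(events, times)
        jumps = np.diff(series.q_tot)
        assert np.all(np.abs(jumps[jumps != 0]) == 1)
        assert abs(series.q_tot[-1]) <= len(events)


class TestEstimateCurrent:
    @staticmethod
    def exact_slope_series(slope: float, duration: float = 500.0) -> ChargeSeries:
        t = np.linspace(0, duration, 5001)
        return ChargeSeries(
            times=t, q_tot=slope * t, n_cation=np.zeros_like(t),
            n_anion=np.zeros_like(t),
        )

    def test_open_state_conductance_arithmetic(self):
        # a current of 148.43 pA at 40 mV is a conductance of 3.71 nS
        series = self.exact_slope_series(148.43 / 160.2176634)
        est = estimate_current(series, voltage=40.0, renorm=1.0)
        assert est.current == pytest.approx(148.43, abs=0.01)
        assert round(est.conductance, 2) == 3.71

    def test_renormalized_hand_value(self):
        est = estimate_current(
            self.exact_slope_series(1.534), voltage=40.0, renorm=0.586
        )
        assert est.current == pytest.approx(144.0, abs=0.1)

    def test_flat_series_reports_zero_current_and_flagged_r2(self):
        t = np.linspace(0, 10, 101)
        series = ChargeSeries(t, np.zeros_like(t), np.zeros_like(t), np.zeros_like(t))
        est = estimate_current(series, voltage=40.0)
        assert est.current == 0.0
        assert est.conductance == 0.0
        assert math.isnan(est.r_squared)

    def test_zero_voltage_rejected(self):
        with pytest.raises(ValidationError):
            estimate_current(self.exact_slope_series(1.0), voltage=0.0)

    def test_conductance_linear_in_renormalization(self):
        series = self.exact_slope_series(2.0)
        ests = [estimate_current(series, 40.0, renorm=r) for r in (0.25, 0.5, 1.0)]
        assert ests[0].conductance == pytest.approx(ests[2].conductance * 0.25)
        assert ests[1].conductance == pytest.approx(ests[2].conductance * 0.5)


class TestRenormalization:
    def test_printed_coefficients(self):
        assert renormalization_factor(3.273e-5, 1.918e-5) == pytest.approx(
            0.5860, abs=1e-4
        )

    def test_identity_and_half(self):
        assert renormalization_factor(2e-5, 2e-5) == 1.0
        assert renormalization_factor(2e-5, 1e-5) == 0.5

    def test_nonpositive_rejected(self):
        with pytest.raises(ValidationError):
            renormalization_factor(0.0, 1e-5)


class TestCurrentRatio:
    def test_open_state_printed_ratio(self):
        events = [CrossingEvent(i, "K+", 1, i * 1e-3, -1) for i in range(238)]
        events += [CrossingEvent(500 + i, "Cl-", -1, i * 1e-3, 1) for i in range(529)]
        assert round(current_ratio(events), 1) == 2.2

    def test_constructed_table_ratio(self):
        events = [CrossingEvent(i, "K+", 1, i * 1e-3, -1) for i in range(100)]
        events += [CrossingEvent(500 + i, "Cl-", -1, i * 1e-3, 1) for i in range(221)]
        assert round(current_ratio(events), 2) == 2.21

    def test_equal_counts_give_unity(self):
        events = [CrossingEvent(0, "K+", 1, 0.1, 1), CrossingEvent(1, "Cl-", -1, 0.2, 1)]
        assert current_ratio(events) == 1.0

    def test_no_cation_events_is_undefined_not_infinite(self):
        events = [CrossingEvent(0, "Cl-", -1, 0.1, 1)]
        assert math.isnan(current_ratio(events))


class TestDiffusionMSD:
    def test_recovers_generator_diffusion_within_5_percent(self):
        d_in = 2.0e-5
        spec = ElectrolyteSpec(
            species=(SpeciesSpec("K+", 1, d_in, 0.01), SpeciesSpec("Cl-", -1, d_in, 0.01)),
        )
        traj = simulate_bulk_bd(spec, 5.0, 0.005, seed=9, n_ions_per_species=250)
        est = estimate_diffusion_msd(traj, max_lag_fraction=0.2)
        assert est.d_sim == pytest.approx(d_in, rel=0.05)
        assert est.r_squared > 0.99

    def test_static_particles_have_zero_diffusion(self):
        pos = np.zeros((200, 5, 3))
        traj = IonTrajectory(
            times=np.arange(200) * 0.1,
            positions=pos,
            ids=np.arange(5),
            species=np.array(["K+"] * 5),
            valence=np.ones(5, dtype=int),
            box=np.array([50.0, 50.0, 50.0]),
        )
        assert estimate_diffusion_msd(traj).d_sim == 0.0

    def test_pure_drift_flagged_by_low_r2(self):
        # MSD of noise-free drift grows as v²τ²; the linear fit must flag it
        t = np.arange(300) * 0.1
        pos = np.zeros((300, 8, 3))
        pos[:, :, 2] = 0.8 * t[:, None]
        traj = IonTrajectory(
            times=t,
            positions=pos - np.round(pos / 60.0) * 60.0,
            ids=np.arange(8),
            species=np.array(["K+"] * 8),
            valence=np.ones(8, dtype=int),
            box=np.array([60.0, 60.0, 60.0]),
        )
        est = estimate_diffusion_msd(traj, max_lag_fraction=0.5)
        assert est.r_squared < 0.97

    def test_too_few_frames_refused(self):
        traj = simulate_bulk_bd(ElectrolyteSpec(), 0.0, 0.005, seed=1)
        with pytest.raises(TrajectoryError):
            estimate_diffusion_msd(traj)

    def test_two_seeds_agree_on_diffusion(self):
        spec = ElectrolyteSpec()
        ests = []
        for seed in (1, 2):
            traj = simulate_bulk_bd(spec, 5.0, 0.005, seed=seed, n_ions_per_species=250)
            ests.append(estimate_diffusion_msd(traj, max_lag_fraction=0.2))
        assert ests[0].d_sim == pytest.approx(ests[1].d_sim, rel=0.1)


class TestFieldFromVoltage:
    def test_printed_box_value(self):
        # printed to three significant figures
        assert field_from_voltage(40.0, 90.2) == pytest.approx(4.43e6, abs=0.005e6)

    def test_zero_and_antisymmetry(self):
        assert field_from_voltage(0.0, 90.2) == 0.0
        assert field_from_voltage(-40.0, 90.2) == -field_from_voltage(40.0, 90.2)

    def test_zero_length_rejected(self):
        with pytest.raises(ValidationError):
            field_from_voltage(40.0, 0.0)
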