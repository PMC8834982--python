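"""From ion trajectories to crossing events, currents and conductances.

The chain implemented here: detect complete pore traversals with a
hysteresis state machine (:func:`detect_crossings`), accumulate the signed
transported charge ``q_tot(t) = (+1)·n_K+(t) + (−1)·n_Cl−(t)``
(:func:`cumulative_charge`), regress its slope and renormalize by the ratio
of experimental to simulated bulk diffusion coefficients to obtain the
current and conductance (:func:`estimate_current`), and estimate the bulk
diffusion coefficient from the ensemble mean-squared displacement
(:func:`estimate_diffusion_msd`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import stats

from . import units
from .specs import ValidationError
from .trajectory import IonTrajectory, TrajectoryError


@dataclass(frozen=True)
class CrossingEvent:
    """One complete directional traversal of the pore by one ion."""

    ion_id: int
    species: str
    valence: int
    time: float          # ns
    direction: int       # +1: −z → +z, −1: +z → −z

    def __post_init__(self):
        if self.direction not in (-1, 1):
            raise ValidationError("direction must be ±1")


@dataclass
class ChargeSeries:
    """Cumulative signed transported charge on a uniform time grid.

    ``q_tot`` changes only at events, by exactly ``valence × direction`` =
    ±1 e for monovalent ions. Signed per-species counters (``n_cation``,
    ``n_anion``) are direction-aware; plain event counts are kept for the
    current-ratio statistic.
    """

    times: np.ndarray
    q_tot: np.ndarray
    n_cation: np.ndarray
    n_anion: np.ndarray
    events: list[CrossingEvent] = field(default_factory=list)

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.q_tot = np.asarray(self.q_tot, dtype=float)
        self.n_cation = np.asarray(self.n_cation, dtype=float)
        self.n_anion = np.asarray(self.n_anion, dtype=float)

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def event_counts(self) -> dict[str, int]:
        """Plain (direction-insensitive) event counts per species."""
        out: dict[str, int] = {}
        for ev in self.events:
            out[ev.species] = out.get(ev.species, 0) + 1
        return out


@dataclass
class CurrentEstimate:
    """Regression-derived current, renormalized conductance and selectivity."""

    raw_slope: float          # e/ns
    r_squared: float
    renorm_factor: float
    current: float            # pA (signed)
    conductance: float        # nS (≥ 0)
    voltage: float            # mV
    current_ratio: float      # anion/cation event ratio (nan if undefined)
    events_per_species: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)

    def report(self) -> dict:
        """Rounded, publication-style numbers (2 decimals nS, 1 decimal ratio)."""
        return {
            "current_pA": round(self.current, 2),
            "conductance_nS": round(self.conductance, 2),
            "current_ratio": (
                round(self.current_ratio, 1)
                if math.isfinite(self.current_ratio)
                else None
            ),
            "r_squared": round(self.r_squared, 3)
            if math.isfinite(self.r_squared)
            else None,
        }


@dataclass
class DiffusionEstimate:
    """MSD-based bulk diffusion coefficient, in cm²/s."""

    d_sim: float
    fit_window: tuple[float, float]   # ns
    r_squared: float
    d_exp: float | None = None

    def renormalization(self) -> float:
        if self.d_exp is None:
            raise ValidationError("no experimental reference diffusion set")
        return renormalization_factor(self.d_sim, self.d_exp)


# ---------------------------------------------------------------------------
# crossing detection


def detect_crossings(
    traj: IonTrajectory,
    gate_halfwidth: float = 10.0,
    pore_radius_margin: float = 2.0,
    pore_radius: float | None = None,
) -> list[CrossingEvent]:
    """Detect complete pore traversals with a hysteresis state machine.

    An ion is *committed below* once ``z < origin_z − gate_halfwidth`` and
    *committed above* once ``z > origin_z + gate_halfwidth``; an event is
    emitted each time the committed side flips, so jitter around the
    mid-plane is never double counted. A periodic z-wrap between frames
    (``|Δz| > box_z/2``) resets the state without an event — those ions went
    around through the bulk, not through the pore. Ions that start inside
    the gate are uncommitted until they first leave it; traversals still in
    flight at either end of the trajectory are discarded.

    If ``pore_radius`` is given, the mid-plane passage must occur at radial
    distance below ``pore_radius + pore_radius_margin``.
    """
    if traj.n_frames < 2:
        raise TrajectoryError("need at least 2 frames to detect crossings")
    if gate_halfwidth <= 0:
        raise ValidationError("gate_halfwidth must be > 0")
    steps = np.diff(traj.times)
    if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
        raise TrajectoryError("non-uniform time step")

    o = traj.origin_z
    half_box_z = traj.box[2] / 2.0
    r_limit = None if pore_radius is None else pore_radius + pore_radius_margin
    events: list[CrossingEvent] = []

    for i in range(traj.n_particles):
        z = traj.positions[:, i, 2]
        commit = np.zeros(len(z), dtype=np.int8)
        commit[z > o + gate_halfwidth] = 1
        commit[z < o - gate_halfwidth] = -1
        wrap = np.abs(np.diff(z)) > half_box_z
        # segment boundaries at wrap resets
        bounds = np.concatenate(([0], np.flatnonzero(wrap) + 1, [len(z)]))
        for a, b in zip(bounds[:-1], bounds[1:]):
            idx = a + np.flatnonzero(commit[a:b])
            if len(idx) < 2:
                continue
            vals = commit[idx]
            flips = np.flatnonzero(np.diff(vals) != 0)
            for k in flips:
                prev_frame, this_frame = idx[k], idx[k + 1]
                direction = int(vals[k + 1])
                if r_limit is not None:
                    seg = z[prev_frame : this_frame + 1] - o
                    flip_rel = np.flatnonzero(np.sign(seg) == direction)
                    j = prev_frame + int(flip_rel[0])
                    rho = math.hypot(
                        traj.positions[j, i, 0], traj.positions[j, i, 1]
                    )
                    if rho >= r_limit:
                        continue
                events.append(
                    CrossingEvent(
                        ion_id=int(traj.ids[i]),
                        species=str(traj.species[i]),
                        valence=int(traj.valence[i]),
                        time=float(traj.times[this_frame]),
                        direction=direction,
                    )
                )
    events.sort(key=lambda ev: (ev.time, ev.ion_id))
    return events


def cumulative_charge(events: list[CrossingEvent], times: np.ndarray) -> ChargeSeries:
    """Accumulate ``q_tot(t)`` and signed per-species counts on a time grid."""
    times = np.asarray(times, dtype=float)
    events = sorted(events, key=lambda ev: (ev.time, ev.ion_id))
    if events:
        t0, t1 = times[0], times[-1]
        for ev in events:
            if not t0 <= ev.time <= t1:
                raise ValidationError(
                    f"event at t={ev.time} ns outside the series time range"
                )
    ev_times = np.array([ev.time for ev in events])
    dq = np.array([ev.valence * ev.direction for ev in events], dtype=float)
    d_cat = np.array(
        [ev.direction if ev.valence > 0 else 0 for ev in events], dtype=float
    )
    d_an = np.array(
        [ev.direction if ev.valence < 0 else 0 for ev in events], dtype=float
    )
    # number of events with time <= t for each grid point
    k = np.searchsorted(ev_times, times, side="right") if events else np.zeros(
        len(times), dtype=int
    )
    cum = lambda x: np.concatenate(([0.0], np.cumsum(x)))[k]  # noqa: E731
    return ChargeSeries(
        times=times,
        q_tot=cum(dq) if events else np.zeros(len(times)),
        n_cation=cum(d_cat) if events else np.zeros(len(times)),
        n_anion=cum(d_an) if events else np.zeros(len(times)),
        events=list(events),
    )


# ---------------------------------------------------------------------------
# currents and diffusion


def renormalization_factor(d_sim: float, d_exp: float) -> float:
    """Diffusion renormalization D_exp / D_sim applied to simulated currents."""
    if d_sim <= 0 or d_exp <= 0:
        raise ValidationError("diffusion coefficients must be > 0")
    return d_exp / d_sim


def current_ratio(events: list[CrossingEvent]) -> float:
    """Anion/cation event-count ratio (I_Cl−/I_K+ proxy for selectivity).

    Counts completed traversals regardless of direction. Returns ``nan``
    when no cation event exists (undefined, not infinite).
    """
    n_cat = sum(1 for ev in events if ev.valence > 0)
    n_an = sum(1 for ev in events if ev.valence < 0)
    if n_cat == 0:
        return math.nan
    return n_an / n_cat


def estimate_current(
    series: ChargeSeries,
    voltage: float,
    renorm: float = 1.0,
    grid: str = "frame",
) -> CurrentEstimate:
    """OLS slope of ``q_tot(t)`` → renormalized current and conductance.

    ``current = slope [e/ns] × 160.2176634 pA/(e/ns) × renorm`` and
    ``conductance = |current| / |voltage|`` (nS = pA/mV). The regression
    runs on the uniformly resampled frame grid by default; ``grid="event"``
    regresses on the event times instead.
    """
    if voltage == 0:
        raise ValidationError("voltage must be non-zero")
    if grid == "frame":
        t, q = series.times, series.q_tot
    elif grid == "event":
        t = np.array([ev.time for ev in series.events])
        q = np.cumsum([ev.valence * ev.direction for ev in series.events])
    else:
        raise ValidationError("grid must be 'frame' or 'event'")
    if len(np.unique(t)) < 2:
        raise ValidationError("need at least 2 distinct times")

    if np.ptp(q) == 0:
        slope, r2 = 0.0, math.nan   # flat series: R² undefined
    else:
        fit = stats.linregress(t, q)
        slope, r2 = float(fit.slope), float(fit.rvalue**2)

    current = slope * units.E_PER_NS_TO_PA * renorm
    conductance = abs(current) / abs(voltage)
    counts = series.event_counts()
    return CurrentEstimate(
        raw_slope=slope,
        r_squared=r2,
        renorm_factor=renorm,
        current=current,
        conductance=conductance,
        voltage=voltage,
        current_ratio=current_ratio(series.events),
        events_per_species=counts,
    )


def estimate_diffusion_msd(
    traj: IonTrajectory,
    max_lag_fraction: float = 0.2,
    d_exp: float | None = None,
) -> DiffusionEstimate:
    """Bulk diffusion coefficient from the ensemble MSD slope (MSD = 6Dτ).

    Positions are unwrapped across the periodic box first. The slope is fit
    through the origin over lags up to ``max_lag_fraction`` of the
    trajectory duration; the reported R² is that of the same linear model,
    so ballistic (drift-dominated, MSD ∝ τ²) data is flagged by a low R².
    """
    if traj.n_frames < 100:
        raise TrajectoryError("need at least 100 frames for MSD estimation")
    if not 0 < max_lag_fraction <= 1:
        raise ValidationError("max_lag_fraction must lie in (0, 1]")
    pos = traj.unwrapped_positions()
    n_frames = traj.n_frames
    max_lag = max(2, int(max_lag_fraction * (n_frames - 1)))
    lags = np.arange(1, max_lag + 1)
    msd = np.empty(len(lags))
    for j, lag in enumerate(lags):
        disp = pos[lag:] - pos[:-lag]
        msd[j] = np.mean(np.sum(disp**2, axis=-1))
    tau = lags * traj.dt

    slope = float(np.dot(tau, msd) / np.dot(tau, tau))  # through origin
    pred = slope * tau
    ss_res = float(np.sum((msd - pred) ** 2))
    ss_tot = float(np.sum((msd - msd.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else (1.0 if ss_res == 0 else 0.0)

    d_a2ns = max(slope / 6.0, 0.0)
    return DiffusionEstimate(
        d_sim=d_a2ns / units.CM2_PER_S_TO_A2_PER_NS,
        fit_window=(float(tau[0]), float(tau[-1])),
        r_squared=r2,
        d_exp=d_exp,
    )


def field_from_voltage(voltage: float, box_length: float) -> float:
    """Uniform field E = V/L in V/m from voltage (mV) over a box length (Å)."""
    if box_length <= 0:
        raise ValidationError("box_length must be > 0")
    return (voltage * 1e-3) / (box_length * 1e-10)


def events_to_frame(events: list[CrossingEvent]):
    """Events as a pandas DataFrame (CSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "id": [ev.ion_id for ev in events],
            "species": [ev.species for ev in events],
            "valence": [ev.valence for ev in events],
            "time_ns": [ev.time for ev in events],
            "direction": [ev.direction for ev in events],
        }
    )
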