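"""Synthetic-data generators.

Three generators provide every input the analysis chain consumes:

* :func:`simulate_pore_bd` — overdamped Brownian (Langevin) dynamics of
  charged point ions in a periodic box containing an impermeable slab
  pierced by a cylindrical pore, under a uniform electric field set by the
  applied voltage. This is the desk-scale stand-in for channel permeation
  simulations; its steady-state current is Ohmic at small voltage and
  proportional to the open pore cross-section.
* :func:`simulate_bulk_bd` — free Brownian motion in a membrane-free box,
  used to exercise MSD-based diffusion estimation against a known input D.
* :func:`make_toy_ensemble` — toy β-barrel + N-tail coordinate ensembles
  with controllable ellipticity and tail placement.

:func:`analytic_pore_conductance` is the closed-form Nernst–Einstein oracle
for the cylindrical pore.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import units
from .conformations import ConformationEnsemble
from .specs import (
    ChannelSpec,
    ElectrolyteSpec,
    ToyEnsembleSpec,
    ValidationError,
)
from .trajectory import IonTrajectory

_CHUNK = 2000  # RNG/stepping chunk size (steps)


def _species_arrays(species, n_per_species):
    """Per-particle D (Å²/ns), valence, name arrays."""
    d = np.repeat(
        [sp.diffusion_coeff * units.CM2_PER_S_TO_A2_PER_NS for sp in species],
        n_per_species,
    )
    val = np.repeat([sp.valence for sp in species], n_per_species)
    names = np.repeat([sp.name for sp in species], n_per_species)
    return d, val, names


def _check_bd_args(max_d_a2ns, dt, duration, pore_radius=None):
    if dt <= 0:
        raise ValidationError("dt must be > 0")
    if duration < 0:
        raise ValidationError("duration must be >= 0")
    if pore_radius is not None:
        step_sd = math.sqrt(2.0 * max_d_a2ns * dt)
        if step_sd >= pore_radius / 2.0:
            raise ValidationError(
                f"dt too large: per-coordinate step SD sqrt(2*D*dt) = "
                f"{step_sd:.3g} Å must stay below pore_radius/2 = "
                f"{pore_radius / 2.0:.3g} Å"
            )
    if 0 < duration < 100 * dt:
        raise ValidationError("duration must be at least 100*dt (or 0)")


def analytic_pore_conductance(spec: ChannelSpec) -> float:
    """Closed-form conductance of the open cylindrical pore, in nS.

    Bulk Nernst–Einstein conductivity
    ``κ = (e²/kT)·N_A·Σᵢ cᵢ·zᵢ²·Dᵢ`` combined with the geometric factor of a
    cylinder of length ``L_p`` and open cross-section ``πr²(1−f)``:
    ``G = κ·πr²·(1−f)/L_p``.
    """
    if spec.pore_radius == 0:
        return 0.0
    if spec.pore_length == 0:
        raise ValidationError("pore_length must be > 0")
    spec.validate()
    kt = units.kt_joule(spec.temperature)
    kappa = 0.0  # S/m
    for sp in spec.species:
        c_si = sp.concentration * 1000.0          # mol/m³
        d_si = sp.diffusion_coeff * 1.0e-4        # m²/s
        kappa += (
            units.ELEMENTARY_CHARGE_C**2 / kt * units.AVOGADRO
            * c_si * sp.valence**2 * d_si
        )
    r_m = spec.pore_radius * 1e-10
    l_m = spec.pore_length * 1e-10
    g_siemens = kappa * math.pi * r_m**2 * (1.0 - spec.obstruction_fraction) / l_m
    return g_siemens * 1e9


def _initial_positions(rng, spec: ChannelSpec, n: int) -> np.ndarray:
    """Uniform positions in the accessible region, by rejection sampling."""
    box = np.asarray(spec.box)
    out = np.empty((n, 3))
    filled = 0
    half_l = spec.pore_length / 2.0
    while filled < n:
        cand = (rng.random((2 * n, 3)) - 0.5) * box
        in_slab = np.abs(cand[:, 2]) < half_l
        rho2 = cand[:, 0] ** 2 + cand[:, 1] ** 2
        ok = ~in_slab | (rho2 < spec.pore_radius**2)
        good = cand[ok]
        take = min(n - filled, len(good))
        out[filled : filled + take] = good[:take]
        filled += take
    return out


def simulate_pore_bd(
    spec: ChannelSpec,
    duration: float,
    dt: float,
    n_ions_per_species: int,
    seed: int,
    save_interval: float | None = None,
    obstruction_release_time: float | None = None,
) -> IonTrajectory:
    """Brownian dynamics of ions through the slab pore under voltage.

    Per step each coordinate moves by ``(D/kT)·q·E·dt`` (drift along −z for
    positive charge at positive voltage, with E = V/L_z) plus Gaussian noise
    of SD ``sqrt(2·D·dt)``. The box is periodic in all directions; moves
    ending inside the slab outside the admissible pore radius are rejected
    (hard steric wall). Inside the obstruction z-range the admissible radius
    is ``r·sqrt(1−f)``, so the open cross-section scales as ``1−f``. If
    ``obstruction_release_time`` is given, the obstruction vanishes at that
    time (a scripted reopening, used to emulate bistable trajectories).

    Frames are saved every ``save_interval`` ns (default ``10·dt``). The same
    (spec, seed) yields bit-identical output.
    """
    spec.validate()
    if n_ions_per_species < 1:
        raise ValidationError("n_ions_per_species must be >= 1")
    d_arr, val_arr, name_arr = _species_arrays(spec.species, n_ions_per_species)
    _check_bd_args(d_arr.max(), dt, duration, spec.pore_radius)
    if duration == 0:
        raise ValidationError("pore simulation requires duration > 0")

    if save_interval is None:
        save_interval = 10 * dt
    stride = max(1, round(save_interval / dt))
    n_steps = int(round(duration / dt))
    n = len(d_arr)
    box = np.asarray(spec.box)
    half_l = spec.pore_length / 2.0
    r2_pore = spec.pore_radius**2
    f = spec.obstruction_fraction
    r2_eff = r2_pore * (1.0 - f)
    if spec.obstruction_zrange is None:
        obs_lo, obs_hi = -half_l, half_l
    else:
        obs_lo, obs_hi = spec.obstruction_zrange
    release_step = (
        math.inf
        if obstruction_release_time is None
        else obstruction_release_time / dt
    )

    # drift along -z for positive charge at positive voltage (field E = V/L_z)
    beta_v = units.beta_e_per_volt(spec.temperature)  # e/(kT) per volt
    drift_z = -val_arr * d_arr * beta_v * (spec.voltage * 1e-3) / box[2] * dt
    sigma = np.sqrt(2.0 * d_arr * dt)

    rng = np.random.default_rng(seed)
    pos = _initial_positions(rng, spec, n)

    n_saved = n_steps // stride + 1
    saved = np.empty((n_saved, n, 3))
    saved[0] = pos
    save_idx = 1

    step = 0
    while step < n_steps:
        chunk = min(_CHUNK, n_steps - step)
        noise = rng.standard_normal((chunk, n, 3))
        for k in range(chunk):
            prop = pos + sigma[:, None] * noise[k]
            prop[:, 2] += drift_z
            # guard against jumping across the whole slab in one step;
            # evaluated on pre-wrap z so periodic recirculation stays legal
            z_raw = prop[:, 2]
            crossed = ((pos[:, 2] > half_l) & (z_raw < -half_l)) | (
                (pos[:, 2] < -half_l) & (z_raw > half_l)
            )
            prop -= box * np.round(prop / box)
            obstructed = f > 0.0 and (step + k) < release_step

            def _limit(p):
                zz = p[:, 2]
                if obstructed:
                    return np.where((zz >= obs_lo) & (zz <= obs_hi), r2_eff, r2_pore)
                return r2_pore

            def _illegal(p):
                zz = p[:, 2]
                in_slab = np.abs(zz) < half_l
                rho2 = p[:, 0] ** 2 + p[:, 1] ** 2
                return in_slab & (rho2 >= _limit(p))

            bad = _illegal(prop) | crossed
            if bad.any():
                fixed = prop[bad].copy()
                old = pos[bad]
                was_outside = np.abs(old[:, 2]) >= half_l
                # specular reflection off the slab face that was hit
                face = np.sign(old[:, 2]) * half_l
                fixed[was_outside, 2] = (
                    2.0 * face[was_outside] - fixed[was_outside, 2]
                )
                # specular reflection off the (possibly constricted) pore wall
                inside = ~was_outside
                if inside.any():
                    wall = np.sqrt(_limit(fixed[inside]))
                    rho = np.hypot(fixed[inside, 0], fixed[inside, 1])
                    new_rho = 2.0 * wall - rho
                    scale = np.where(
                        (new_rho > 0) & (rho > 0), new_rho / np.maximum(rho, 1e-12), -1.0
                    )
                    fixed[inside, 0] *= scale
                    fixed[inside, 1] *= scale
                fixed -= box * np.round(fixed / box)
                # fall back to rejection where the reflection failed
                still_bad = _illegal(fixed) | crossed[bad]
                fixed[still_bad] = old[still_bad]
                prop[bad] = fixed
            # well-stirred reservoirs: ions outside the slab get fresh
            # lateral positions each step (ideal-bath boundary, the
            # steric/field pore being the only resistive element)
            bulk = np.abs(prop[:, 2]) >= half_l
            n_bulk = int(bulk.sum())
            if n_bulk:
                prop[bulk, 0] = (rng.random(n_bulk) - 0.5) * box[0]
                prop[bulk, 1] = (rng.random(n_bulk) - 0.5) * box[1]
            pos = prop
            if (step + k + 1) % stride == 0:
                saved[save_idx] = pos
                save_idx += 1
        step += chunk

    times = np.arange(n_saved) * (stride * dt)
    return IonTrajectory(
        times=times,
        positions=saved[:save_idx],
        ids=np.arange(n),
        species=name_arr,
        valence=val_arr,
        box=box,
        voltage=spec.voltage,
        origin_z=0.0,
    )


def simulate_bulk_bd(
    spec: ElectrolyteSpec,
    duration: float,
    dt: float,
    seed: int,
    n_ions_per_species: int | None = None,
    save_interval: float | None = None,
) -> IonTrajectory:
    """Free Brownian motion in a periodic membrane-free box.

    Displacements are pure unbiased Gaussian steps with the input diffusion
    coefficient per species; positions are wrapped into the box. A
    ``duration`` of 0 returns the single initial frame.
    """
    spec.validate()
    d_list = [sp.diffusion_coeff * units.CM2_PER_S_TO_A2_PER_NS for sp in spec.species]
    _check_bd_args(max(d_list), dt, duration)
    box = np.asarray(spec.box)
    if n_ions_per_species is None:
        n_ions_per_species = max(
            1,
            round(
                max(sp.concentration for sp in spec.species)
                * units.MOL_PER_L_TO_PER_A3
                * float(np.prod(box))
            ),
        )
    d_arr, val_arr, name_arr = _species_arrays(spec.species, n_ions_per_species)
    n = len(d_arr)
    rng = np.random.default_rng(seed)
    x0 = (rng.random((n, 3)) - 0.5) * box

    if duration == 0:
        frames = x0[None]
        times = np.zeros(1)
    else:
        if save_interval is None:
            save_interval = dt
        stride = max(1, round(save_interval / dt))
        n_steps = int(round(duration / dt))
        sigma = np.sqrt(2.0 * d_arr * dt)
        steps = sigma[None, :, None] * rng.standard_normal((n_steps, n, 3))
        unwrapped = x0[None] + np.cumsum(steps, axis=0)
        unwrapped = np.concatenate([x0[None], unwrapped], axis=0)
        frames = unwrapped[::stride]
        frames = frames - box * np.round(frames / box)
        times = np.arange(len(frames)) * (stride * dt)

    return IonTrajectory(
        times=times,
        positions=frames,
        ids=np.arange(n),
        species=name_arr,
        valence=val_arr,
        box=box,
        voltage=0.0,
        origin_z=0.0,
    )


def make_toy_ensemble(spec: ToyEnsembleSpec) -> ConformationEnsemble:
    """Toy barrel + N-tail ensemble with seeded per-frame jitter.

    Barrel points sit on ``barrel_rings`` elliptic rings (semi-axes
    ``radius_a`` ≥ ``radius_b``) stacked along z over ``height``; the tail is
    a chain of ``tail_residues`` Cα-like points placed according to
    ``tail_placement``. All points are tagged via the ``segment`` column
    ("barrel" / "tail"); tail residues are numbered 1..n.
    """
    spec.validate()
    h = spec.height
    npr, nr = spec.barrel_points_per_ring, spec.barrel_rings

    angles = 2.0 * np.pi * np.arange(npr) / npr
    ring_x = spec.radius_a * np.cos(angles)
    ring_y = spec.radius_b * np.sin(angles)
    z_levels = np.linspace(-h / 2.0, h / 2.0, nr)
    barrel = np.column_stack(
        [
            np.tile(ring_x, nr),
            np.tile(ring_y, nr),
            np.repeat(z_levels, npr),
        ]
    )

    nt = spec.tail_residues
    if spec.tail_placement == "vertical":
        # runs along the pore axis, spanning at least half the barrel height
        tz = np.linspace(-0.4 * h, 0.4 * h, nt)
        tail = np.column_stack([np.full(nt, 1.5), np.zeros(nt), tz])
    elif spec.tail_placement == "horizontal-mid-pore":
        tx = np.linspace(-0.6 * spec.radius_b, 0.6 * spec.radius_b, nt)
        tail = np.column_stack([tx, np.zeros(nt), np.zeros(nt)])
    else:  # detached-below
        tz = -h / 2.0 - 4.0 - 3.0 * np.arange(nt)
        tail = np.column_stack([np.zeros(nt), np.zeros(nt), tz])

    template = np.vstack([tail, barrel])
    atoms = pd.DataFrame(
        {
            "res_id": np.concatenate(
                [np.arange(1, nt + 1), np.arange(nt + 1, nt + 1 + len(barrel))]
            ),
            "res_name": ["ALA"] * (nt + len(barrel)),
            "atom_name": ["CA"] * (nt + len(barrel)),
            "element": ["C"] * (nt + len(barrel)),
            "segment": ["tail"] * nt + ["barrel"] * len(barrel),
        }
    )

    rng = np.random.default_rng(spec.seed)
    coords = template[None] + spec.jitter_sd * rng.standard_normal(
        (spec.n_frames, len(template), 3)
    )
    return ConformationEnsemble(
        atoms,
        coords,
        condition=spec.tail_placement,
        provenance={"generator": "make_toy_ensemble", "seed": spec.seed},
    )
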