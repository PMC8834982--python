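"""Dual-boost accelerated-MD bias and the multi-walker exploration scheduler.

The accelerated-MD boost raises the potential wherever it lies below a
threshold energy E, by ``ΔV = (E−V)²/(α+E−V)``; the dual-boost variant adds
independent terms for the total potential energy and the dihedral energy.
A toy overdamped Langevin propagator on analytic landscapes exercises the
bias, and :func:`run_exploration` implements the multi-walker scheme:
propagate N walkers for a fixed segment, pool all conformers generated so
far, cluster the pool into N clusters, restart each walker from a cluster
representative, and repeat.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Callable

import numpy as np

from . import units
from .specs import ValidationError

# printed dual-boost threshold offsets per atom / residue / lipid (kcal/mol)
DEFAULT_GAMMA_P = 0.16
DEFAULT_GAMMA_D = 3.5
DEFAULT_GAMMA_D_PRIME = 30.0


@dataclass(frozen=True)
class AMDParams:
    """Dual-boost parameters. Energies in kcal/mol.

    ``E_p = E_p0 + γ_p·n_atoms`` (total-potential threshold) and
    ``E_d = E_d0 + γ_d·n_residues + γ_d'·n_lipids`` (dihedral threshold);
    α_p, α_d set how smoothly the boost saturates below each threshold.
    """

    e_p: float
    e_d: float
    alpha_p: float
    alpha_d: float
    e_p0: float = math.nan
    e_d0: float = math.nan
    gamma_p: float = DEFAULT_GAMMA_P
    gamma_d: float = DEFAULT_GAMMA_D
    gamma_d_prime: float = DEFAULT_GAMMA_D_PRIME
    n_atoms: int = 0
    n_residues: int = 0
    n_lipids: int = 0

    def __post_init__(self):
        if self.alpha_p <= 0 or self.alpha_d <= 0:
            raise ValidationError("alpha_p and alpha_d must be > 0")

    def to_dict(self) -> dict:
        return asdict(self)


def parameterize(
    e_p0: float,
    e_d0: float,
    n_atoms: int,
    n_residues: int,
    n_lipids: int = 0,
    gamma_p: float = DEFAULT_GAMMA_P,
    gamma_d: float = DEFAULT_GAMMA_D,
    gamma_d_prime: float = DEFAULT_GAMMA_D_PRIME,
    alpha_p: float | None = None,
    alpha_d: float | None = None,
) -> AMDParams:
    """Build dual-boost parameters from unbiased average energies and counts.

    Default α values follow the standard dual-boost convention
    ``α_p = γ_p·n_atoms`` and ``α_d = (1/5)·γ_d·n_residues`` (with a floor
    of 1 kcal/mol to stay positive for tiny toy systems).
    """
    if min(n_atoms, n_residues, n_lipids) < 0:
        raise ValidationError("counts must be >= 0")
    e_p = e_p0 + gamma_p * n_atoms
    e_d = e_d0 + gamma_d * n_residues + gamma_d_prime * n_lipids
    if alpha_p is None:
        alpha_p = max(gamma_p * n_atoms, 1.0)
    if alpha_d is None:
        alpha_d = max(gamma_d * n_residues / 5.0, 1.0)
    return AMDParams(
        e_p=e_p,
        e_d=e_d,
        alpha_p=alpha_p,
        alpha_d=alpha_d,
        e_p0=e_p0,
        e_d0=e_d0,
        gamma_p=gamma_p,
        gamma_d=gamma_d,
        gamma_d_prime=gamma_d_prime,
        n_atoms=n_atoms,
        n_residues=n_residues,
        n_lipids=n_lipids,
    )


def boost(v, e: float, alpha: float):
    """Single-term boost ``ΔV = (E−V)²/(α+E−V)`` for V < E, else 0.

    Accepts scalars or arrays. ΔV is non-negative, vanishes at V ≥ E, and
    is bounded above by E−V wherever it is active.
    """
    if alpha <= 0:
        raise ValidationError("alpha must be > 0")
    v = np.asarray(v, dtype=float)
    gap = e - v
    out = np.where(gap > 0, gap**2 / (alpha + np.abs(gap)), 0.0)
    return float(out) if out.ndim == 0 else out


def boost_derivative(v, e: float, alpha: float):
    """d(ΔV)/dV; the boosted force prefactor is ``1 + dΔV/dV = α²/(α+E−V)²``."""
    v = np.asarray(v, dtype=float)
    gap = e - v
    out = np.where(gap > 0, alpha**2 / (alpha + np.abs(gap)) ** 2 - 1.0, 0.0)
    return float(out) if out.ndim == 0 else out


def total_boost(v_total, v_dihedral, params: AMDParams):
    """Dual-boost ΔV(x): total-potential term plus dihedral term."""
    return boost(v_total, params.e_p, params.alpha_p) + boost(
        v_dihedral, params.e_d, params.alpha_d
    )


def gcbd_time_accounting(n_steps: float, dt_ps: float) -> float:
    """Simulated time in ns for a BD cycle count at a time step in ps."""
    if n_steps < 0 or dt_ps <= 0:
        raise ValidationError("need n_steps >= 0 and dt_ps > 0")
    return n_steps * dt_ps * 1e-3


# ---------------------------------------------------------------------------
# analytic toy landscapes


@dataclass(frozen=True)
class Landscape:
    """Analytic potential with an optionally designated dihedral-like term.

    ``potential``/``gradient`` define the full potential V(x);
    ``dihedral``/``dihedral_gradient`` single out the part of V treated as
    the dihedral energy by the dual boost (zero by default). x has shape
    (..., dim); energies in kcal/mol, lengths in Å.
    """

    dim: int
    potential: Callable
    gradient: Callable
    dihedral: Callable | None = None
    dihedral_gradient: Callable | None = None
    name: str = ""

    def v_d(self, x):
        if self.dihedral is None:
            return np.zeros(np.shape(x)[:-1])
        return self.dihedral(x)

    def grad_d(self, x):
        if self.dihedral_gradient is None:
            return np.zeros_like(x)
        return self.dihedral_gradient(x)


def harmonic_well(k: float = 1.0, dim: int = 1) -> Landscape:
    """V = ½·k·|x|², k in kcal/mol/Å²."""
    return Landscape(
        dim=dim,
        potential=lambda x: 0.5 * k * np.sum(x**2, axis=-1),
        gradient=lambda x: k * x,
        name=f"harmonic(k={k})",
    )


def double_well(barrier: float = 3.0, half_separation: float = 1.0) -> Landscape:
    """1D quartic double well ``V = h·((x/a)²−1)²`` with barrier h (kcal/mol)."""
    a = half_separation

    def v(x):
        u = (x[..., 0] / a) ** 2 - 1.0
        return barrier * u**2

    def g(x):
        u = (x[..., 0] / a) ** 2 - 1.0
        out = np.zeros_like(x)
        out[..., 0] = barrier * 4.0 * u * x[..., 0] / a**2
        return out

    return Landscape(dim=1, potential=v, gradient=g, name=f"double_well(h={barrier})")


def triple_well(barrier: float = 3.0, spacing: float = 2.0) -> Landscape:
    """1D triple well: three Gaussian basins at −s, 0, +s of depth ``barrier``."""
    s = spacing
    centers = np.array([-s, 0.0, s])
    w2 = (0.45 * s) ** 2

    def v(x):
        x0 = x[..., 0]
        wells = np.exp(-((x0[..., None] - centers) ** 2) / (2 * w2))
        return barrier * (1.0 - wells.max(axis=-1)) + 0.02 * (x0 / s) ** 4

    def g(x):
        x0 = x[..., 0]
        wells = np.exp(-((x0[..., None] - centers) ** 2) / (2 * w2))
        imax = wells.argmax(axis=-1)
        cmax = centers[imax]
        wmax = wells.max(axis=-1)
        out = np.zeros_like(x)
        out[..., 0] = (
            barrier * wmax * (x0 - cmax) / w2 + 0.08 * x0**3 / s**4
        )
        return out

    return Landscape(dim=1, potential=v, gradient=g, name=f"triple_well(h={barrier})")


# ---------------------------------------------------------------------------
# toy propagation


@dataclass
class ToyTrajectory:
    """Output of the toy propagator: positions plus per-step energy records."""

    times: np.ndarray          # (n_saved,)
    positions: np.ndarray      # (n_saved, n_walkers, dim)
    v_total: np.ndarray        # (n_saved, n_walkers)
    v_dihedral: np.ndarray
    delta_v: np.ndarray

    @property
    def n_walkers(self) -> int:
        return self.positions.shape[1]


def toy_propagate(
    landscape: Landscape,
    params: AMDParams | None,
    steps: int,
    dt: float,
    temperature: float,
    seed: int,
    x0: np.ndarray | None = None,
    diffusion: float = 1.0,
    save_stride: int = 1,
) -> ToyTrajectory:
    """Overdamped Langevin on the (optionally boosted) landscape.

    Each walker moves by ``−(D/kT)·∇(V+ΔV)·dt + √(2·D·dt)·ξ``. With
    ``params=None`` the bias is off. V, V_d and ΔV are recorded at every
    saved step; non-finite energies abort with a diagnostic. Same seed ⇒
    identical trajectory.
    """
    if steps < 0 or dt <= 0:
        raise ValidationError("need steps >= 0 and dt > 0")
    kt = units.kt_kcal_per_mol(temperature)
    rng = np.random.default_rng(seed)
    if x0 is None:
        x0 = np.zeros((1, landscape.dim))
    x = np.array(x0, dtype=float)
    if x.ndim == 1:
        x = x[None, :]
    n_walk = x.shape[0]
    sigma = math.sqrt(2.0 * diffusion * dt)
    mob = diffusion / kt * dt

    n_saved = steps // save_stride + 1
    pos = np.empty((n_saved, n_walk, landscape.dim))
    v_tot = np.empty((n_saved, n_walk))
    v_dih = np.empty((n_saved, n_walk))
    dv = np.empty((n_saved, n_walk))

    def record(i, xx):
        v = landscape.potential(xx)
        vd = landscape.v_d(xx)
        d = total_boost(v, vd, params) if params is not None else np.zeros_like(v)
        if not (np.all(np.isfinite(v)) and np.all(np.isfinite(d))):
            raise FloatingPointError(
                f"non-finite energy at save index {i}; reduce dt or fix the landscape"
            )
        pos[i], v_tot[i], v_dih[i], dv[i] = xx, v, vd, d

    record(0, x)
    si = 1
    for step in range(1, steps + 1):
        v = landscape.potential(x)
        vd = landscape.v_d(x)
        grad = landscape.gradient(x)
        if params is not None:
            pref_p = 1.0 + boost_derivative(v, params.e_p, params.alpha_p)
            pref_d = boost_derivative(vd, params.e_d, params.alpha_d)
            force = pref_p[..., None] * grad + pref_d[..., None] * landscape.grad_d(x)
        else:
            force = grad
        x = x - mob * force + sigma * rng.standard_normal(x.shape)
        if step % save_stride == 0:
            record(si, x)
            si += 1
    return ToyTrajectory(
        times=np.arange(n_saved) * (dt * save_stride),
        positions=pos[:si],
        v_total=v_tot[:si],
        v_dihedral=v_dih[:si],
        delta_v=dv[:si],
    )


def count_well_transitions(x: np.ndarray, commit: float = 0.5) -> int:
    """Hysteresis count of sign transitions of a 1D coordinate series."""
    committed = np.where(x > commit, 1, np.where(x < -commit, -1, 0))
    nz = committed[committed != 0]
    if len(nz) < 2:
        return 0
    return int(np.sum(np.diff(nz) != 0))


# ---------------------------------------------------------------------------
# exploration scheduler


@dataclass
class WalkerState:
    """One walker's bookkeeping: current configuration and elapsed segments."""

    walker_id: int
    configuration: np.ndarray
    segment_index: int
    segment_length: float  # ns

    @property
    def accumulated_time(self) -> float:
        """ns of dynamics this walker has run: segment index × length."""
        return self.segment_index * self.segment_length

    def to_dict(self) -> dict:
        return {
            "walker_id": self.walker_id,
            "configuration": np.asarray(self.configuration).tolist(),
            "segment_index": self.segment_index,
            "accumulated_time_ns": self.accumulated_time,
        }


@dataclass
class ExplorationLog:
    """Full bookkeeping of a multi-walker cluster-restart exploration."""

    n_walkers: int
    segment_length: float      # ns
    n_rounds: int
    save_interval: float       # ns
    rounds: list[dict] = field(default_factory=list)
    totals: dict = field(default_factory=dict)

    def finalize(self) -> None:
        n_done = len(self.rounds)
        sim_time = self.n_walkers * self.segment_length * n_done
        self.totals = {
            "rounds_completed": n_done,
            "simulated_time_ns": sim_time,
            "frames_saved": int(round(sim_time / self.save_interval)),
        }

    def to_dict(self) -> dict:
        return {
            "n_walkers": self.n_walkers,
            "segment_length_ns": self.segment_length,
            "n_rounds": self.n_rounds,
            "save_interval_ns": self.save_interval,
            "rounds": self.rounds,
            "totals": self.totals,
        }


def kmeans_medoids(pool: np.ndarray, n_clusters: int, seed: int = 0) -> np.ndarray:
    """Seeded k-means medoid indices (the large-pool restart fallback).

    Scales to cumulative pools where hierarchical all-pairs clustering
    (quadratic in pool size) does not. Medoid = pool member nearest its
    centroid; deterministic for a fixed seed.
    """
    from sklearn.cluster import KMeans

    n = len(pool)
    if n_clusters > n:
        raise ValidationError("more clusters than pool members")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # duplicate points may empty a cluster
        km = KMeans(n_clusters=n_clusters, n_init=4, random_state=seed)
        labels = km.fit_predict(pool)
    reps = np.empty(n_clusters, dtype=int)
    empty = []
    for lab in range(n_clusters):
        members = np.flatnonzero(labels == lab)
        if len(members) == 0:
            empty.append(lab)
            continue
        d = np.linalg.norm(pool[members] - km.cluster_centers_[lab], axis=-1)
        reps[lab] = members[int(np.argmin(d))]
    # degenerate pools can leave clusters empty; fill deterministically with
    # the lowest-index points not already chosen
    if empty:
        taken = set(int(reps[lab]) for lab in range(n_clusters) if lab not in empty)
        spare = (i for i in range(n) if i not in taken)
        for lab in empty:
            reps[lab] = next(spare, 0)
            taken.add(int(reps[lab]))
    # deterministic ordering: by cluster size desc, then lowest member index
    sizes = np.bincount(labels, minlength=n_clusters)

    def sort_key(lab):
        members = np.flatnonzero(labels == lab)
        first = int(members[0]) if len(members) else n + lab
        return (-int(sizes[lab]), first)

    order = sorted(range(n_clusters), key=sort_key)
    return reps[order]


def hierarchical_medoids(pool: np.ndarray, n_clusters: int, seed: int = 0) -> np.ndarray:
    """Average-linkage medoid indices (small pools only; O(n²) memory)."""
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import pdist, squareform

    n = len(pool)
    if n_clusters > n:
        raise ValidationError("more clusters than pool members")
    if n_clusters == n:
        return np.arange(n)
    d = pdist(pool)
    labels = fcluster(linkage(d, method="average"), t=n_clusters, criterion="maxclust") - 1
    dm = squareform(d)
    reps = np.empty(n_clusters, dtype=int)
    empty = []
    for lab in range(n_clusters):
        members = np.flatnonzero(labels == lab)
        if len(members) == 0:  # duplicate points can merge clusters
            empty.append(lab)
            continue
        reps[lab] = members[int(np.argmin(dm[np.ix_(members, members)].sum(axis=1)))]
    if empty:
        taken = set(int(reps[lab]) for lab in range(n_clusters) if lab not in empty)
        spare = (i for i in range(n) if i not in taken)
        for lab in empty:
            reps[lab] = next(spare, 0)
            taken.add(int(reps[lab]))
    sizes = np.bincount(labels, minlength=n_clusters)

    def sort_key(lab):
        members = np.flatnonzero(labels == lab)
        first = int(members[0]) if len(members) else n + lab
        return (-int(sizes[lab]), first)

    order = sorted(range(n_clusters), key=sort_key)
    return reps[order]


#: pools at most this large are clustered hierarchically (O(n²) distances)
HIERARCHICAL_POOL_LIMIT = 6000


def default_restart_clustering(pool: np.ndarray, n_clusters: int, seed: int = 0) -> np.ndarray:
    """Average-linkage medoids for modest pools, seeded k-means beyond.

    Hierarchical clustering isolates rarely-visited frontier states into
    small clusters, which is what makes cluster restarts explore faster
    than free walkers; it is used whenever the pool fits the quadratic
    distance matrix, with k-means as the large-pool fallback.
    """
    if len(pool) <= HIERARCHICAL_POOL_LIMIT:
        return hierarchical_medoids(pool, n_clusters, seed)
    return kmeans_medoids(pool, n_clusters, seed)


def run_exploration(
    n_walkers: int,
    segment_length: float,
    n_rounds: int,
    save_interval: float,
    propagate_fn: Callable[[np.ndarray, float, int], np.ndarray],
    cluster_fn: Callable[[np.ndarray, int, int], np.ndarray] = default_restart_clustering,
    seed: int = 0,
    x0: np.ndarray | None = None,
    pool_stride: int = 1,
) -> tuple[ExplorationLog, np.ndarray]:
    """Multi-walker exploration with cluster restarts.

    Each round: propagate all walkers for one segment
    (``propagate_fn(starts, segment_length, seed) -> (n_frames, n_walkers,
    dim)`` saved frames), pool every conformer generated so far, cluster
    the pool into ``n_walkers`` clusters, and restart walker k from
    representative k (clusters ordered by size, then lowest member index).
    ``pool_stride`` optionally subsamples the cumulative pool fed to the
    cluster function. Returns the log and the full frame pool.

    On a propagation failure the round is aborted and the partial log (with
    totals for the completed rounds) is returned inside the raised
    exception's ``args[1]``.
    """
    if n_walkers < 1 or n_rounds < 1:
        raise ValidationError("need at least one walker and one round")
    if save_interval <= 0 or segment_length <= 0:
        raise ValidationError("segment_length and save_interval must be > 0")
    frames_per_segment = int(round(segment_length / save_interval))
    if frames_per_segment < 1:
        raise ValidationError("save_interval larger than segment_length")

    ss = np.random.SeedSequence(seed)
    round_seeds = ss.generate_state(2 * n_rounds) % (2**31)
    log = ExplorationLog(n_walkers, segment_length, n_rounds, save_interval)
    starts = np.zeros((n_walkers, 1)) if x0 is None else np.array(x0, dtype=float)
    pool_blocks: list[np.ndarray] = []

    for rnd in range(n_rounds):
        try:
            frames = propagate_fn(starts, segment_length, int(round_seeds[2 * rnd]))
        except Exception as exc:  # noqa: BLE001 - preserve the partial log
            log.finalize()
            raise RuntimeError(f"propagation failed in round {rnd}", log) from exc
        frames = np.asarray(frames, dtype=float)
        if frames.shape[0] != frames_per_segment or frames.shape[1] != n_walkers:
            raise ValidationError(
                "propagate_fn must return (frames_per_segment, n_walkers, dim)"
            )
        # pool is walker-major within the round: (n_walkers*frames, dim)
        pool_blocks.append(frames.transpose(1, 0, 2).reshape(-1, frames.shape[2]))
        pool = np.vstack(pool_blocks)
        reps = np.asarray(
            cluster_fn(pool[::pool_stride], n_walkers, int(round_seeds[2 * rnd + 1]))
        )
        if reps.shape != (n_walkers,):
            raise ValidationError("cluster_fn must return exactly n_walkers representatives")
        reps_global = reps * pool_stride
        new_starts = pool[reps_global]
        walker_states = [
            WalkerState(k, new_starts[k], rnd + 1, segment_length).to_dict()
            for k in range(n_walkers)
        ]
        log.rounds.append(
            {
                "round": rnd,
                "segment_seeds": int(round_seeds[2 * rnd]),
                "frames_saved": int(frames_per_segment * n_walkers),
                "pool_size": int(len(pool)),
                "restart_indices": reps_global.tolist(),
                "restart_structures": new_starts.tolist(),
                "walker_states": walker_states,
            }
        )
        starts = new_starts
    log.finalize()
    return log, np.vstack(pool_blocks)
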