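"""Conformational analytics for barrel/N-tail ensembles.

Superposition and RMSD, barrel ellipticity, charged-residue z statistics,
PCA conformational landscapes with cross-condition overlap, RMSD-based
agglomerative clustering with medoid representatives, coordinate-average
structures, and Henderson–Hasselbalch apparent sequence charge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform
from sklearn.decomposition import PCA

from .conformations import (
    ConformationEnsemble,
    ConformationFrame,
    select_atoms,
)
from .specs import ValidationError


# ---------------------------------------------------------------------------
# superposition / RMSD


def _kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Optimal rotation R and translation t mapping mobile onto target."""
    mc, tc = mobile.mean(axis=0), target.mean(axis=0)
    h = (mobile - mc).T @ (target - tc)
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    return rot, tc - rot @ mc


def rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """Plain coordinate RMSD in Å (no fitting)."""
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=-1))))


def superpose(
    ensemble: ConformationEnsemble,
    reference: ConformationFrame,
    selection: np.ndarray | None = None,
    scoring_selection: np.ndarray | None = None,
) -> tuple[ConformationEnsemble, np.ndarray]:
    """Least-squares rigid-body superposition of every frame onto a reference.

    The optimal rotation/translation is fit on ``selection`` (default: all
    non-hydrogen atoms); the per-frame RMSD is scored on
    ``scoring_selection`` (default: the fit selection). Returns the aligned
    ensemble and the RMSD array in Å.
    """
    if selection is None:
        selection = ensemble.select()
    selection = np.asarray(selection, dtype=bool)
    if not selection.any():
        raise ValidationError("empty fit selection")
    if reference.coords.shape[0] != ensemble.n_atoms:
        raise ValidationError("reference and ensemble atom rosters differ")
    score_sel = selection if scoring_selection is None else np.asarray(
        scoring_selection, dtype=bool
    )
    ref_sel = reference.coords[selection]
    aligned = np.empty_like(ensemble.coords)
    out = np.empty(ensemble.n_frames)
    for i, frame in enumerate(ensemble.coords):
        rot, trans = _kabsch(frame[selection], ref_sel)
        aligned[i] = frame @ rot.T + trans
        out[i] = rmsd(aligned[i][score_sel], reference.coords[score_sel])
    new = ConformationEnsemble(
        ensemble.atoms, aligned, condition=ensemble.condition,
        provenance={**ensemble.provenance, "superposed": True},
    )
    return new, out


# ---------------------------------------------------------------------------
# per-frame geometry


def ellipticity(points_xy: np.ndarray) -> float:
    """√(λ₁/λ₂) of the 2D covariance of projected points (λ₁ ≥ λ₂)."""
    if len(points_xy) < 3:
        raise ValidationError("need at least 3 points")
    cov = np.cov(points_xy.T, bias=True)
    lam = np.linalg.eigvalsh(cov)
    if lam[0] <= 1e-12 * max(lam[1], 1.0):
        raise ValidationError("degenerate (colinear) point set")
    return float(math.sqrt(lam[1] / lam[0]))


def ellipticity_series(
    ensemble: ConformationEnsemble,
    barrel_selection: np.ndarray | None = None,
    axis: np.ndarray = (0.0, 0.0, 1.0),
) -> np.ndarray:
    """Per-frame barrel ellipticity (dimensionless, ≥ 1).

    Barrel Cα positions are projected onto the plane normal to the pore
    axis; the ellipticity is the square root of the ratio of the principal
    variances of the projected cloud. 1.0 is a perfectly circular barrel.
    """
    if barrel_selection is None:
        barrel_selection = ensemble.select(segment="barrel", role="Cα")
    barrel_selection = np.asarray(barrel_selection, dtype=bool)
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    # orthonormal basis of the projection plane
    seed = np.array([1.0, 0.0, 0.0])
    if abs(axis @ seed) > 0.9:
        seed = np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, seed)
    u /= np.linalg.norm(u)
    v = np.cross(axis, u)
    out = np.empty(ensemble.n_frames)
    for i in range(ensemble.n_frames):
        pts = ensemble.coords[i][barrel_selection]
        out[i] = ellipticity(np.column_stack([pts @ u, pts @ v]))
    return out


def residue_z_stats(
    ensemble: ConformationEnsemble,
    residues: list[int],
    origin_z: float = 0.0,
) -> pd.DataFrame:
    """Mean ± SD of Cα z-positions (Å, relative to ``origin_z``) per residue.

    The SD convention is population (divide by n frames), matching error
    bars computed over the frames of one trajectory.
    """
    rows = []
    atoms = ensemble.atoms
    ca = (atoms["atom_name"] == "CA").to_numpy()
    for rid in residues:
        mask = ca & (atoms["res_id"].to_numpy() == rid)
        if mask.sum() != 1:
            raise ValidationError(f"residue {rid} has no unique Cα atom")
        z = ensemble.coords[:, mask, 2].ravel() - origin_z
        rows.append(
            {
                "res_id": rid,
                "mean_z": float(z.mean()),
                "sd_z": float(z.std()),  # population SD
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PCA landscape


@dataclass
class LandscapeModel:
    """PCA landscape over pooled conformations.

    ``projections`` maps each condition label to an (n_frames, n_pc) array
    of scores on the orthonormal principal axes of the pooled, flattened
    selection coordinates.
    """

    mean: np.ndarray
    components: np.ndarray            # (n_pc, n_features), unit rows
    explained_variance_ratio: np.ndarray
    projections: dict[str, np.ndarray] = field(default_factory=dict)
    selection: np.ndarray | None = None
    degenerate: bool = False

    def project(self, coords_flat: np.ndarray) -> np.ndarray:
        return (coords_flat - self.mean) @ self.components.T


def pca_landscape(
    ensembles: list[ConformationEnsemble],
    selection: np.ndarray | None = None,
    n_components: int = 2,
) -> LandscapeModel:
    """PCA of flattened selection coordinates pooled across conditions.

    Frames are assumed pre-superposed on a common reference (barrel
    backbone by convention). Identical frames everywhere yield a flagged
    degenerate model rather than an error.
    """
    if not ensembles:
        raise ValidationError("no ensembles given")
    if selection is None:
        selection = ensembles[0].select(segment="n-domain")
        if not selection.any():
            selection = ensembles[0].select()
    selection = np.asarray(selection, dtype=bool)
    blocks, labels = [], []
    for ens in ensembles:
        blocks.append(ens.coords[:, selection, :].reshape(ens.n_frames, -1))
        labels.append(ens.condition or f"ensemble{len(labels)}")
    pooled = np.vstack(blocks)
    if len(pooled) < 3:
        raise ValidationError("need at least 3 frames in total")

    total_var = float(np.var(pooled, axis=0).sum())
    if total_var < 1e-12:
        n_feat = pooled.shape[1]
        comps = np.zeros((n_components, n_feat))
        comps[:, :n_components] = np.eye(n_components)
        model = LandscapeModel(
            mean=pooled.mean(axis=0),
            components=comps,
            explained_variance_ratio=np.zeros(n_components),
            selection=selection,
            degenerate=True,
        )
    else:
        k = min(n_components, len(pooled) - 1, pooled.shape[1])
        pca = PCA(n_components=k, svd_solver="full")
        pca.fit(pooled)
        model = LandscapeModel(
            mean=pca.mean_,
            components=pca.components_,
            explained_variance_ratio=pca.explained_variance_ratio_,
            selection=selection,
            degenerate=False,
        )
    for ens, block, label in zip(ensembles, blocks, labels):
        model.projections[label] = model.project(block)
    return model


def ensemble_overlap(
    model: LandscapeModel,
    condition_a: str,
    condition_b: str,
    grid_bins: int = 40,
    density_floor: float = 1e-12,
) -> tuple[float, np.ndarray]:
    """Overlap between two condition clouds on the (PC1, PC2) plane.

    Both point sets are histogrammed on a common 2D grid and normalized to
    probability mass; the overlap fraction is ``Σ min(p_A, p_B)`` over the
    bins (1 for identical distributions, 0 for disjoint ones). The returned
    mask marks bins where both densities exceed ``density_floor``.
    """
    for cond in (condition_a, condition_b):
        if cond not in model.projections or len(model.projections[cond]) == 0:
            raise ValidationError(f"condition {cond!r} absent from the landscape")
    pa = model.projections[condition_a][:, :2]
    pb = model.projections[condition_b][:, :2]
    both = np.vstack([pa, pb])
    lo = both.min(axis=0)
    hi = both.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    edges = [
        np.linspace(lo[d] - 1e-9 * span[d], hi[d] + 1e-9 * span[d], grid_bins + 1)
        for d in range(2)
    ]
    ha, _, _ = np.histogram2d(pa[:, 0], pa[:, 1], bins=edges)
    hb, _, _ = np.histogram2d(pb[:, 0], pb[:, 1], bins=edges)
    ha /= ha.sum()
    hb /= hb.sum()
    overlap = float(np.minimum(ha, hb).sum())
    mask = (ha > density_floor) & (hb > density_floor)
    return overlap, mask


# ---------------------------------------------------------------------------
# clustering


@dataclass
class ClusterResult:
    """Frame partition with medoid representatives."""

    assignment: np.ndarray     # cluster label per frame, 0..n_clusters-1
    n_clusters: int
    representatives: np.ndarray  # frame index of each cluster's medoid
    linkage: str = "average"


def pairwise_rmsd_matrix(
    ensemble: ConformationEnsemble, selection: np.ndarray
) -> np.ndarray:
    coords = ensemble.coords[:, selection, :]
    n = len(coords)
    out = np.zeros((n, n))
    for i in range(n - 1):
        d = coords[i + 1 :] - coords[i]
        out[i, i + 1 :] = np.sqrt(np.mean(np.sum(d**2, axis=-1), axis=-1))
    return out + out.T


def cluster_frames(
    ensemble: ConformationEnsemble,
    n_clusters: int,
    selection: np.ndarray | None = None,
) -> ClusterResult:
    """Agglomerative (average-linkage) clustering on pairwise RMSD.

    Frames are assumed pre-superposed; hydrogens are excluded from the
    default selection. The tree is cut to exactly ``n_clusters``; each
    cluster's representative is its medoid (minimum summed RMSD to the
    other members, ties broken by lowest frame index). Output clusters are
    relabelled deterministically: descending size, then lowest member index.
    """
    if n_clusters <= 0:
        raise ValidationError("n_clusters must be positive")
    if n_clusters > ensemble.n_frames:
        raise ValidationError("more clusters than frames")
    if selection is None:
        selection = ensemble.select()
    selection = np.asarray(selection, dtype=bool)
    dm = pairwise_rmsd_matrix(ensemble, selection)

    if n_clusters == ensemble.n_frames:
        labels = np.arange(ensemble.n_frames)
    else:
        z = linkage(squareform(dm, checks=False), method="average")
        labels = fcluster(z, t=n_clusters, criterion="maxclust") - 1

    # deterministic relabelling: by (descending size, lowest member index)
    order = sorted(
        np.unique(labels),
        key=lambda lab: (-int(np.sum(labels == lab)), int(np.flatnonzero(labels == lab)[0])),
    )
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[lab] for lab in labels])

    reps = np.empty(n_clusters, dtype=int)
    for lab in range(n_clusters):
        members = np.flatnonzero(labels == lab)
        sums = dm[np.ix_(members, members)].sum(axis=1)
        reps[lab] = members[int(np.argmin(sums))]
    return ClusterResult(
        assignment=labels, n_clusters=n_clusters, representatives=reps
    )


def average_structure(
    ensemble: ConformationEnsemble, frame_indices=None
) -> tuple[ConformationFrame, np.ndarray]:
    """Coordinate-wise mean structure plus a per-atom RMSF sidecar (Å).

    Frames must be superposed beforehand. The RMSF column is reported
    because coordinate means of disordered segments can be unphysical; a
    large RMSF flags atoms whose average position is not representative.
    """
    coords = ensemble.coords
    if frame_indices is not None:
        idx = np.asarray(frame_indices, dtype=int)
        if len(idx) == 0:
            raise ValidationError("empty frame subset")
        coords = coords[idx]
    mean = coords.mean(axis=0)
    rmsf = np.sqrt(np.mean(np.sum((coords - mean) ** 2, axis=-1), axis=0))
    return ConformationFrame(ensemble.atoms, mean), rmsf


# ---------------------------------------------------------------------------
# sequence charge

#: default side-chain and termini pKa values (EMBOSS-style table)
DEFAULT_PKA = {
    "D": 3.9,
    "E": 4.1,
    "C": 8.5,
    "Y": 10.1,
    "H": 6.5,
    "K": 10.8,
    "R": 12.5,
    "N-term": 8.6,
    "C-term": 3.6,
}

_ACIDIC = {"D", "E", "C", "Y", "C-term"}
_BASIC = {"H", "K", "R", "N-term"}

_VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")


def sequence_apparent_charge(
    sequence: str,
    ph: float = 7.0,
    pka_table: dict | None = None,
    include_nterm: bool = True,
    include_cterm: bool = True,
) -> float:
    """Henderson–Hasselbalch net charge of a one-letter sequence at given pH.

    Basic groups contribute ``+1/(1+10^(pH−pKa))``, acidic groups
    ``−1/(1+10^(pKa−pH))``; termini are included when flagged. The pKa
    table is an explicit input — model-dependent corrections (ionic
    strength, structure-based shifts) are the caller's responsibility.
    """
    table = dict(DEFAULT_PKA if pka_table is None else pka_table)
    charge = 0.0
    for res in sequence.upper():
        if res not in _VALID_RESIDUES:
            raise ValidationError(f"unknown residue {res!r}")
        if res in table:
            pka = table[res]
            if res in _BASIC:
                charge += 1.0 / (1.0 + 10.0 ** (ph - pka))
            else:
                charge -= 1.0 / (1.0 + 10.0 ** (pka - ph))
    if include_nterm and "N-term" in table:
        charge += 1.0 / (1.0 + 10.0 ** (ph - table["N-term"]))
    if include_cterm and "C-term" in table:
        charge -= 1.0 / (1.0 + 10.0 ** (table["C-term"] - ph))
    return charge
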