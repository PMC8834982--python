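"""Unit tests for superposition, ellipticity, PCA landscapes and clustering."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.transform import Rotation
from scipy.stats import multivariate_normal

from poregate import (
    ConformationEnsemble,
    ConformationFrame,
    ToyEnsembleSpec,
    ValidationError,
    average_structure,
    cluster_frames,
    ellipticity,
    ellipticity_series,
    ensemble_overlap,
    make_toy_ensemble,
    pca_landscape,
    residue_z_stats,
    sequence_apparent_charge,
    superpose,
)
from poregate.structmet import pairwise_rmsd_matrix, rmsd


def atoms_table(n: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "res_id": np.arange(1, n + 1),
            "res_name": ["ALA"] * n,
            "atom_name": ["CA"] * n,
            "element": ["C"] * n,
            "segment": [""] * n,
        }
    )


def ensemble_from_coords(coords: np.ndarray, condition: str = "") -> ConformationEnsemble:
    return ConformationEnsemble(atoms_table(coords.shape[1]), coords, condition)


class TestSuperpose:
    def test_frame_vs_itself_is_zero(self):
        rng = np.random.default_rng(0)
        coords = rng.normal(size=(10, 3))
        ens = ensemble_from_coords(coords[None])
        ref = ConformationFrame(atoms_table(10), coords)
        _aligned, rmsds = superpose(ens, ref)
        assert rmsds[0] == pytest.approx(0.0, abs=1e-12)

    def test_rigid_transform_is_removed(self):
        rng = np.random.default_rng(1)
        coords = rng.normal(size=(20, 3)) * 5
        rot = Rotation.from_euler("xyz", [30, -45, 60], degrees=True).as_matrix()
        moved = coords @ rot.T + np.array([5.0, -3.0, 12.0])
        ens = ensemble_from_coords(moved[None])
        ref = ConformationFrame(atoms_table(20), coords)
        _aligned, rmsds = superpose(ens, ref)
        assert rmsds[0] <= 1e-6

    def test_four_point_deformation_rmsd_is_one(self):
        # square in the xy-plane with a ±1 Å z-deformation proportional to
        # x·y: orthogonal to all rigid-body modes, so the optimal fit leaves
        # exactly 1 Å per atom
        ref_coords = np.array(
            [[1.0, 1.0, 0.0], [1.0, -1.0, 0.0], [-1.0, 1.0, 0.0], [-1.0, -1.0, 0.0]]
        )
        moved = ref_coords.copy()
        moved[:, 2] = [1.0, -1.0, -1.0, 1.0]
        ens = ensemble_from_coords(moved[None])
        ref = ConformationFrame(atoms_table(4), ref_coords)
        _aligned, rmsds = superpose(ens, ref)
        assert rmsds[0] == pytest.approx(1.0, abs=1e-9)

    def test_empty_selection_rejected(self):
        coords = np.zeros((1, 4, 3))
        ens = ensemble_from_coords(coords)
        ref = ConformationFrame(atoms_table(4), coords[0])
        with pytest.raises(ValidationError):
            superpose(ens, ref, selection=np.zeros(4, dtype=bool))


class TestEllipticity:
    def test_perfect_circle_is_one(self):
        spec = ToyEnsembleSpec(radius_a=15, radius_b=15, jitter_sd=0.0, n_frames=2)
        ens = make_toy_ensemble(spec)
        values = ellipticity_series(ens)
        assert np.allclose(values, 1.0, atol=1e-12)

    def test_exact_ellipse_ratio(self):
        spec = ToyEnsembleSpec(radius_a=20, radius_b=10, jitter_sd=0.0, n_frames=1)
        values = ellipticity_series(make_toy_ensemble(spec))
        assert values[0] == pytest.approx(2.0, abs=1e-12)

    def test_small_jitter_stays_near_one(self):
        spec = ToyEnsembleSpec(
            radius_a=15, radius_b=15, jitter_sd=0.1, n_frames=50, seed=4
        )
        values = ellipticity_series(make_toy_ensemble(spec))
        assert np.all(np.abs(values - 1.0) < 0.02)

    def test_invariance_under_rotation_translation_scaling(self):
        angles = np.linspace(0, 2 * np.pi, 24, endpoint=False)
        pts = np.column_stack(
            [20 * np.cos(angles), 10 * np.sin(angles), np.zeros_like(angles)]
        )
        base = ellipticity(pts[:, :2])
        theta = 0.7
        rot_z = np.array(
            [[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]]
        )
        assert ellipticity(pts[:, :2] @ rot_z.T) == pytest.approx(base, rel=1e-12)
        assert ellipticity(pts[:, :2] + [7.0, -3.0]) == pytest.approx(base, rel=1e-12)
        assert ellipticity(2.5 * pts[:, :2]) == pytest.approx(base, rel=1e-12)

    def test_colinear_points_rejected(self):
        pts = np.column_stack([np.linspace(0, 1, 10), np.zeros(10)])
        with pytest.raises(ValidationError):
            ellipticity(pts)


class TestResidueZStats:
    def test_static_ensemble_has_zero_sd(self):
        coords = np.tile(np.arange(5)[None, :, None] * [0.0, 0.0, 2.0], (3, 1, 1))
        ens = ensemble_from_coords(coords)
        stats = residue_z_stats(ens, [1, 3, 5])
        assert np.all(stats["sd_z"] == 0.0)
        assert stats.loc[stats.res_id == 3, "mean_z"].item() == pytest.approx(4.0)

    def test_two_frame_population_sd(self):
        coords = np.zeros((2, 1, 3))
        coords[0, 0, 2] = 5.0
        coords[1, 0, 2] = -5.0
        stats = residue_z_stats(ensemble_from_coords(coords), [1])
        assert stats["mean_z"].item() == pytest.approx(0.0)
        assert stats["sd_z"].item() == pytest.approx(5.0)  # population convention

    def test_mid_pore_tail_sits_near_origin(self):
        ens = make_toy_ensemble(
            ToyEnsembleSpec(tail_placement="horizontal-mid-pore", jitter_sd=0.05,
                            n_frames=20, seed=2)
        )
        stats = residue_z_stats(ens, list(range(1, 12)))
        assert np.all(np.abs(stats["mean_z"]) <= 2.0)

    def test_missing_residue_named_in_error(self):
        coords = np.zeros((2, 3, 3))
        with pytest.raises(ValidationError, match="99"):
            residue_z_stats(ensemble_from_coords(coords), [99])


class TestPCALandscape:
    def test_identical_frames_flagged_degenerate(self):
        coords = np.tile(np.random.default_rng(0).normal(size=(1, 8, 3)), (5, 1, 1))
        model = pca_landscape([ensemble_from_coords(coords)])
        assert model.degenerate
        assert np.all(model.explained_variance_ratio == 0.0)

    def test_two_point_closed_form(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(6, 3))
        b = a + rng.normal(size=(6, 3))
        coords = np.array([a, b, a, b, a, b])
        model = pca_landscape([ensemble_from_coords(coords)])
        assert model.explained_variance_ratio[0] == pytest.approx(1.0)
        # PC1 must be colinear with the difference vector
        diff = (b - a).ravel()
        cosine = abs(model.components[0] @ diff) / np.linalg.norm(diff)
        assert cosine == pytest.approx(1.0, abs=1e-9)

    def test_reconstruction_and_variances_match_covariance(self):
        rng = np.random.default_rng(9)
        coords = rng.normal(size=(30, 5, 3))
        ens = ensemble_from_coords(coords)
        flat = coords.reshape(30, -1)
        model = pca_landscape([ens], n_components=15)  # full basis: 5 atoms × 3
        centered = flat - model.mean
        back = model.project(flat) @ model.components
        assert np.allclose(back, centered, atol=1e-8)
        # orthonormal basis
        gram = model.components @ model.components.T
        assert np.allclose(gram, np.eye(len(gram)), atol=1e-10)
        # explained variances equal eigenvalue ratios of the covariance
        eig = np.sort(np.linalg.eigvalsh(np.cov(flat.T, bias=True)))[::-1]
        expected = eig[: len(model.explained_variance_ratio)] / eig.sum()
        assert np.allclose(model.explained_variance_ratio, expected, atol=1e-8)

    def test_tail_placements_separate_along_pc1(self):
        from sklearn.metrics import silhouette_score

        up = make_toy_ensemble(
            ToyEnsembleSpec(tail_placement="vertical", n_frames=30, seed=1,
                            jitter_sd=0.3)
        )
        mid = make_toy_ensemble(
            ToyEnsembleSpec(tail_placement="horizontal-mid-pore", n_frames=30,
                            seed=2, jitter_sd=0.3)
        )
        model = pca_landscape([up, mid], selection=up.select(segment="tail"))
        x = np.vstack(
            [model.projections["vertical"][:, :1],
             model.projections["horizontal-mid-pore"][:, :1]]
        )
        labels = np.repeat([0, 1], 30)
        assert silhouette_score(x, labels) > 0.5


class TestEnsembleOverlap:
    @staticmethod
    def landscape_from_points(pa: np.ndarray, pb: np.ndarray):
        from poregate.structmet import LandscapeModel

        return LandscapeModel(
            mean=np.zeros(2),
            components=np.eye(2),
            explained_variance_ratio=np.array([0.5, 0.5]),
            projections={"A": pa, "B": pb},
        )

    def test_identical_sets_overlap_fully(self):
        pts = np.random.default_rng(0).normal(size=(500, 2))
        model = self.landscape_from_points(pts, pts.copy())
        overlap, _ = ensemble_overlap(model, "A", "B")
        assert overlap == pytest.approx(1.0)

    def test_disjoint_sets_do_not_overlap(self):
        rng = np.random.default_rng(1)
        model = self.landscape_from_points(
            rng.normal(size=(400, 2)), rng.normal(size=(400, 2)) + 50.0
        )
        overlap, mask = ensemble_overlap(model, "A", "B")
        assert overlap == 0.0
        assert not mask.any()

    def test_gaussian_clouds_match_numerical_integration(self):
        # two unit 2D Gaussians 2σ apart; oracle = grid integration of
        # min(p_A, p_B), which equals 2Φ(−1) ≈ 0.3173 analytically
        xs = np.linspace(-6, 8, 561)
        xx, yy = np.meshgrid(xs, xs, indexing="ij")
        grid = np.column_stack([xx.ravel(), yy.ravel()])
        pa = multivariate_normal([0, 0], np.eye(2)).pdf(grid)
        pb = multivariate_normal([2, 0], np.eye(2)).pdf(grid)
        cell = (xs[1] - xs[0]) ** 2
        oracle = float(np.minimum(pa, pb).sum() * cell)
        assert oracle == pytest.approx(0.3173, abs=0.001)

        rng = np.random.default_rng(11)
        n = 2000
        model = self.landscape_from_points(
            rng.normal(size=(n, 2)), rng.normal(size=(n, 2)) + [2.0, 0.0]
        )
        overlap, _ = ensemble_overlap(model, "A", "B", grid_bins=14)
        # binning + sampling error at n=2000, 14² bins stays within ~0.07
        assert overlap == pytest.approx(oracle, abs=0.07)

    def test_missing_condition_rejected(self):
        pts = np.zeros((5, 2))
        model = self.landscape_from_points(pts, pts)
        with pytest.raises(ValidationError):
            ensemble_overlap(model, "A", "C")


class TestClustering:
    @staticmethod
    def two_group_ensemble(n_per: int = 6, sep: float = 40.0, jitter: float = 0.3):
        rng = np.random.default_rng(5)
        base = rng.normal(size=(8, 3)) * 3
        frames = []
        for g in range(2):
            shift = np.array([g * sep, 0.0, 0.0])
            for _ in range(n_per):
                frames.append(base + shift + rng.normal(scale=jitter, size=(8, 3)))
        return ensemble_from_coords(np.array(frames)), np.repeat([0, 1], n_per)

    def test_singletons_when_clusters_equal_frames(self):
        ens, _ = self.two_group_ensemble(n_per=3)
        result = cluster_frames(ens, n_clusters=6)
        assert sorted(result.representatives.tolist()) == list(range(6))
        assert len(set(result.assignment.tolist())) == 6

    def test_ground_truth_partition_recovered(self):
        ens, truth = self.two_group_ensemble()
        result = cluster_frames(ens, n_clusters=2)
        # same partition up to label swap
        a = result.assignment
        assert (np.array_equal(a, truth) or np.array_equal(a, 1 - truth))
        for lab in (0, 1):
            members = np.flatnonzero(a == lab)
            assert result.representatives[lab] in members

    def test_repeat_run_is_identical(self):
        ens, _ = self.two_group_ensemble()
        r1 = cluster_frames(ens, 4)
        r2 = cluster_frames(ens, 4)
        assert np.array_equal(r1.assignment, r2.assignment)
        assert np.array_equal(r1.representatives, r2.representatives)

    def test_single_cluster_returns_global_medoid(self):
        ens, _ = self.two_group_ensemble(n_per=4)
        result = cluster_frames(ens, 1)
        dm = pairwise_rmsd_matrix(ens, ens.select())
        assert result.representatives[0] == int(np.argmin(dm.sum(axis=1)))

    def test_invalid_cluster_count_rejected(self):
        ens, _ = self.two_group_ensemble(n_per=2)
        with pytest.raises(ValidationError):
            cluster_frames(ens, 0)
        with pytest.raises(ValidationError):
            cluster_frames(ens, 99)


class TestAverageStructure:
    def test_single_frame_is_itself(self):
        coords = np.random.default_rng(0).normal(size=(1, 6, 3))
        mean, rmsf = average_structure(ensemble_from_coords(coords))
        assert np.allclose(mean.coords, coords[0])
        assert np.allclose(rmsf, 0.0)

    def test_mirrored_frames_average_onto_plane(self):
        coords = np.random.default_rng(1).normal(size=(1, 6, 3))
        mirrored = coords[0].copy()
        mirrored[:, 2] *= -1
        ens = ensemble_from_coords(np.array([coords[0], mirrored]))
        mean, _rmsf = average_structure(ens)
        assert np.allclose(mean.coords[:, 2], 0.0, atol=1e-12)

    def test_jittered_ensemble_mean_obeys_clt_bound(self):
        spec = ToyEnsembleSpec(jitter_sd=0.5, n_frames=400, seed=8)
        ens = make_toy_ensemble(spec)
        template = make_toy_ensemble(
            ToyEnsembleSpec(jitter_sd=0.0, n_frames=1)
        ).coords[0]
        mean, rmsf = average_structure(ens)
        per_atom = np.linalg.norm(mean.coords - template, axis=1)
        # 3D mean displacement: SE = jitter·sqrt(3/n); allow 5 SE
        bound = 5 * 0.5 * np.sqrt(3 / 400)
        assert np.percentile(per_atom, 99) < bound
        assert np.abs(rmsf - 0.5 * np.sqrt(3)).max() < 0.2

    def test_empty_subset_rejected(self):
        coords = np.zeros((2, 3, 3))
        with pytest.raises(ValidationError):
            average_structure(ensemble_from_coords(coords), frame_indices=[])


class TestSequenceCharge:
    def test_polyglycine_termini_cancel_at_neutral_ph(self):
        charge = sequence_apparent_charge(
            "GGGG", ph=7.0, pka_table={"N-term": 9.0, "C-term": 3.6}
        )
        assert charge == pytest.approx(-0.01, abs=0.005)

    def test_single_aspartate_without_termini(self):
        charge = sequence_apparent_charge(
            "D", ph=7.0, pka_table={"D": 3.67},
            include_nterm=False, include_cterm=False,
        )
        assert charge == pytest.approx(-0.9995, abs=1e-4)

    def test_half_titration_point(self):
        assert sequence_apparent_charge(
            "K", ph=10.8, pka_table={"K": 10.8},
            include_nterm=False, include_cterm=False,
        ) == pytest.approx(0.5)
        assert sequence_apparent_charge(
            "E", ph=4.1, pka_table={"E": 4.1},
            include_nterm=False, include_cterm=False,
        ) == pytest.approx(-0.5)

    def test_unknown_residue_rejected(self):
        with pytest.raises(ValidationError):
            sequence_apparent_charge("AXZ")


class TestPDBRoundTrip:
    def test_ensemble_survives_pdb_io(self, tmp_path):
        ens = make_toy_ensemble(ToyEnsembleSpec(n_frames=3, jitter_sd=0.1, seed=6))
        path = tmp_path / "ens.pdb"
        ens.to_pdb(path)
        back = ConformationEnsemble.from_pdb(path)
        assert back.n_frames == 3
        assert back.n_atoms == ens.n_atoms
        # PDB coordinates carry 3 decimals
        assert np.allclose(back.coords, ens.coords, atol=2e-3)
        assert (back.atoms["segment"] == ens.atoms["segment"]).all()


class TestRMSDPseudometric:
    def test_symmetry_identity_and_triangle_inequality(self):
        rng = np.random.default_rng(13)
        coords = rng.normal(size=(12, 9, 3)) * 2
        ens = ensemble_from_coords(coords)
        dm = pairwise_rmsd_matrix(ens, ens.select())
        assert np.allclose(dm, dm.T)
        assert np.allclose(np.diag(dm), 0.0)
        for i, j, k in [(0, 3, 7), (1, 5, 9), (2, 4, 11), (3, 8, 10)]:
            assert dm[i, k] <= dm[i, j] + dm[j, k] + 1e-12
        # rmsd helper agrees with the matrix
        assert rmsd(coords[0], coords[1]) == pytest.approx(dm[0, 1])
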