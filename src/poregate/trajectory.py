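"""The ion-trajectory container and its columnar serialization."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd


class TrajectoryError(ValueError):
    """Malformed trajectory data."""


@dataclass
class IonTrajectory:
    """Time-stamped positions of labelled charged particles in a periodic box.

    Attributes
    ----------
    times : ndarray, shape (n_frames,)
        Frame times in ns, strictly increasing with a constant step.
    positions : ndarray, shape (n_frames, n_particles, 3)
        Wrapped coordinates in Å (minimum-image box centred on the origin).
    ids : ndarray of int, shape (n_particles,)
    species : ndarray of str, shape (n_particles,)
    valence : ndarray of int, shape (n_particles,)
        Signed charge in e.
    box : ndarray, shape (3,)
        Box edge lengths in Å (constant over the trajectory).
    voltage : float
        Applied transmembrane voltage in mV (0 for field-free runs).
    axis : ndarray, shape (3,)
        Unit vector of the pore axis (conventionally z).
    origin_z : float
        Channel centre of mass along the axis, in Å.
    """

    times: np.ndarray
    positions: np.ndarray
    ids: np.ndarray
    species: np.ndarray
    valence: np.ndarray
    box: np.ndarray
    voltage: float = 0.0
    axis: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    origin_z: float = 0.0

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        self.ids = np.asarray(self.ids, dtype=int)
        self.species = np.asarray(self.species, dtype=object)
        self.valence = np.asarray(self.valence, dtype=int)
        self.box = np.asarray(self.box, dtype=float)
        self.axis = np.asarray(self.axis, dtype=float)
        self.validate()

    # -- invariants --------------------------------------------------------

    def validate(self) -> None:
        n_frames, n_particles = self.positions.shape[:2]
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise TrajectoryError("positions must have shape (frames, particles, 3)")
        if self.times.shape != (n_frames,):
            raise TrajectoryError("times length must match the number of frames")
        for arr, name in ((self.ids, "ids"), (self.species, "species"),
                          (self.valence, "valence")):
            if arr.shape != (n_particles,):
                raise TrajectoryError(f"{name} length must match particle count")
        if n_frames > 1:
            steps = np.diff(self.times)
            if np.any(steps <= 0):
                raise TrajectoryError("times must be strictly increasing")
            if not np.allclose(steps, steps[0], rtol=1e-6, atol=1e-9):
                raise TrajectoryError("times must be uniformly spaced")
        if not np.all(np.isfinite(self.positions)):
            raise TrajectoryError("positions must be finite")
        if len(set(self.ids.tolist())) != n_particles:
            raise TrajectoryError("particle ids must be unique")

    # -- convenience -------------------------------------------------------

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    @property
    def dt(self) -> float:
        if self.n_frames < 2:
            raise TrajectoryError("single-frame trajectory has no time step")
        return float(self.times[1] - self.times[0])

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def unwrapped_positions(self) -> np.ndarray:
        """Positions with periodic jumps removed (minimum-image unwrapping)."""
        deltas = np.diff(self.positions, axis=0)
        deltas -= self.box * np.round(deltas / self.box)
        out = np.empty_like(self.positions)
        out[0] = self.positions[0]
        np.cumsum(deltas, axis=0, out=out[1:])
        out[1:] += self.positions[0]
        return out

    # -- serialization -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format table: frame, time_ns, id, species, valence, x, y, z."""
        n_f, n_p = self.n_frames, self.n_particles
        return pd.DataFrame(
            {
                "frame": np.repeat(np.arange(n_f), n_p),
                "time_ns": np.repeat(self.times, n_p),
                "id": np.tile(self.ids, n_f),
                "species": np.tile(self.species, n_f),
                "valence": np.tile(self.valence, n_f),
                "x": self.positions[:, :, 0].ravel(),
                "y": self.positions[:, :, 1].ravel(),
                "z": self.positions[:, :, 2].ravel(),
            }
        )

    def metadata(self) -> dict:
        return {
            "box": self.box.tolist(),
            "voltage": self.voltage,
            "axis": self.axis.tolist(),
            "origin_z": self.origin_z,
        }

    def save(self, directory: str | Path, name: str = "traj") -> Path:
        """Write ``<name>.csv`` plus a ``<name>.meta.json`` sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        csv_path = directory / f"{name}.csv"
        self.to_frame().to_csv(csv_path, index=False, float_format="%.17g")
        (directory / f"{name}.meta.json").write_text(
            json.dumps(self.metadata(), indent=2)
        )
        return csv_path

    @classmethod
    def load(cls, csv_path: str | Path) -> "IonTrajectory":
        csv_path = Path(csv_path)
        meta_path = csv_path.with_suffix("").with_suffix(".meta.json")
        if not meta_path.exists():
            meta_path = csv_path.parent / (csv_path.stem + ".meta.json")
        meta = json.loads(meta_path.read_text())
        table = pd.read_csv(csv_path)
        frames = np.sort(table["frame"].unique())
        n_f = len(frames)
        first = table[table["frame"] == frames[0]].sort_values("id")
        ids = first["id"].to_numpy()
        n_p = len(ids)
        if len(table) != n_f * n_p:
            raise TrajectoryError("every id must be present in every frame")
        table = table.sort_values(["frame", "id"])
        positions = table[["x", "y", "z"]].to_numpy().reshape(n_f, n_p, 3)
        times = table["time_ns"].to_numpy().reshape(n_f, n_p)[:, 0]
        return cls(
            times=times,
            positions=positions,
            ids=ids,
            species=first["species"].to_numpy(),
            valence=first["valence"].to_numpy(),
            box=np.asarray(meta["box"]),
            voltage=float(meta["voltage"]),
            axis=np.asarray(meta["axis"]),
            origin_z=float(meta["origin_z"]),
        )
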