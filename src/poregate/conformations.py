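"""Containers for channel conformations: single frames and ensembles.

A frame is an atom table (residue index/name, atom name, element, segment
tag) plus an ``(n_atoms, 3)`` coordinate array in Å; an ensemble stacks
frames sharing one atom roster. Multi-model PDB I/O goes through biotite,
with segment tags carried in the chain-id field.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

#: default segment boundaries (residue ranges, inclusive) for the channel
DEFAULT_SEGMENTS = {
    "tail": (1, 11),
    "helix": (12, 19),
    "n-domain": (1, 25),
    "barrel": (26, 283),
}

_BACKBONE_NAMES = {"N", "CA", "C", "O"}

#: chain ids used to carry segment tags through PDB round trips
_SEGMENT_TO_CHAIN = {"tail": "T", "barrel": "B", "helix": "H", "": "A"}
_CHAIN_TO_SEGMENT = {v: k for k, v in _SEGMENT_TO_CHAIN.items()}


def atom_role(atom_name: str, element: str = "") -> str:
    """Classify an atom as Cα / backbone / sidechain / other."""
    if element == "H" or atom_name.startswith("H"):
        return "other"
    if atom_name == "CA":
        return "Cα"
    if atom_name in _BACKBONE_NAMES:
        return "backbone"
    return "sidechain"


def _check_atoms(atoms: pd.DataFrame) -> pd.DataFrame:
    required = {"res_id", "res_name", "atom_name", "element"}
    missing = required - set(atoms.columns)
    if missing:
        raise ValueError(f"atom table misses columns: {sorted(missing)}")
    if "segment" not in atoms.columns:
        atoms = atoms.assign(segment="")
    ca = atoms[atoms["atom_name"] == "CA"]
    if ca["res_id"].duplicated().any():
        raise ValueError("residue indices must be unique per Cα atom")
    return atoms.reset_index(drop=True)


@dataclass
class ConformationFrame:
    """One conformation: atom metadata plus coordinates in Å."""

    atoms: pd.DataFrame
    coords: np.ndarray

    def __post_init__(self):
        self.atoms = _check_atoms(self.atoms)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (len(self.atoms), 3):
            raise ValueError("coords must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def select(self, **kwargs) -> np.ndarray:
        return select_atoms(self.atoms, **kwargs)


@dataclass
class ConformationEnsemble:
    """An ordered stack of frames sharing one atom roster."""

    atoms: pd.DataFrame
    coords: np.ndarray  # (n_frames, n_atoms, 3)
    condition: str = ""
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.atoms = _check_atoms(self.atoms)
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 3 or self.coords.shape[1:] != (len(self.atoms), 3):
            raise ValueError("coords must have shape (n_frames, n_atoms, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.atoms)

    def frame(self, i: int) -> ConformationFrame:
        return ConformationFrame(self.atoms, self.coords[i])

    def select(self, **kwargs) -> np.ndarray:
        return select_atoms(self.atoms, **kwargs)

    def subset(self, frame_indices) -> "ConformationEnsemble":
        return ConformationEnsemble(
            self.atoms, self.coords[np.asarray(frame_indices)],
            condition=self.condition, provenance=dict(self.provenance),
        )

    # -- PDB I/O -----------------------------------------------------------

    def to_pdb(self, path: str | Path) -> Path:
        path = Path(path)
        n = self.n_atoms
        arrays = []
        for coords in self.coords:
            arr = struc.AtomArray(n)
            arr.coord = coords.astype(np.float32)
            arr.res_id = self.atoms["res_id"].to_numpy()
            arr.res_name = self.atoms["res_name"].to_numpy(dtype="U3")
            arr.atom_name = self.atoms["atom_name"].to_numpy(dtype="U4")
            arr.element = self.atoms["element"].to_numpy(dtype="U2")
            arr.chain_id = np.array(
                [_SEGMENT_TO_CHAIN.get(s, "A") for s in self.atoms["segment"]],
                dtype="U1",
            )
            arrays.append(arr)
        stack = struc.stack(arrays)
        f = pdb.PDBFile()
        f.set_structure(stack)
        f.write(str(path))
        return path

    @classmethod
    def from_pdb(cls, path: str | Path, chain_segments: dict | None = None,
                 condition: str = "") -> "ConformationEnsemble":
        chain_segments = chain_segments or _CHAIN_TO_SEGMENT
        f = pdb.PDBFile.read(str(path))
        stack = f.get_structure(model=None)
        if isinstance(stack, struc.AtomArray):
            stack = struc.stack([stack])
        first = stack[0]
        atoms = pd.DataFrame(
            {
                "res_id": first.res_id,
                "res_name": first.res_name,
                "atom_name": first.atom_name,
                "element": first.element,
                "segment": [chain_segments.get(c, "") for c in first.chain_id],
            }
        )
        return cls(atoms, stack.coord.astype(float), condition=condition)


def select_atoms(
    atoms: pd.DataFrame,
    segment: str | None = None,
    role: str | None = None,
    residues: tuple[int, int] | None = None,
    exclude_hydrogens: bool = True,
) -> np.ndarray:
    """Boolean atom mask by segment tag, role, and/or residue range.

    ``residues`` is an inclusive ``(first, last)`` residue-index range. If a
    ``segment`` tag is requested but the table carries no explicit tags, the
    :data:`DEFAULT_SEGMENTS` residue ranges are applied instead.
    """
    mask = np.ones(len(atoms), dtype=bool)
    if segment is not None:
        tagged = atoms["segment"].to_numpy() == segment
        if tagged.any():
            mask &= tagged
        elif segment in DEFAULT_SEGMENTS:
            lo, hi = DEFAULT_SEGMENTS[segment]
            mask &= (atoms["res_id"].to_numpy() >= lo) & (
                atoms["res_id"].to_numpy() <= hi
            )
        else:
            mask &= tagged
    if residues is not None:
        lo, hi = residues
        rid = atoms["res_id"].to_numpy()
        mask &= (rid >= lo) & (rid <= hi)
    if role is not None:
        roles = np.array(
            [atom_role(a, e) for a, e in zip(atoms["atom_name"], atoms["element"])]
        )
        mask &= roles == role
    if exclude_hydrogens:
        mask &= ~(
            (atoms["element"].to_numpy() == "H")
            | atoms["atom_name"].str.startswith("H").to_numpy()
        )
    return mask
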