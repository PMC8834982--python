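"""Input specifications for the synthetic generators.

These dataclasses define the study conditions of every simulation the
package can run: a cylindrical pore in an impermeable slab under an applied
transmembrane voltage (:class:`ChannelSpec`), a membrane-free dilute
electrolyte for diffusion estimation (:class:`ElectrolyteSpec`), and toy
barrel/N-tail coordinate ensembles (:class:`ToyEnsembleSpec`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict

from . import units


class ValidationError(ValueError):
    """A specification violates one of its physical invariants."""


@dataclass(frozen=True)
class SpeciesSpec:
    """One ionic species.

    Parameters
    ----------
    name : str
        Species label, e.g. ``"K+"`` or ``"Cl-"``.
    valence : int
        Charge in elementary charges (±1 for the KCl case).
    diffusion_coeff : float
        Bulk diffusion coefficient in cm²/s.
    concentration : float
        Bulk concentration in mol/L.
    """

    name: str
    valence: int
    diffusion_coeff: float
    concentration: float

    def validate(self) -> None:
        if self.diffusion_coeff <= 0:
            raise ValidationError(f"diffusion_coeff of {self.name} must be > 0")
        if self.concentration <= 0:
            raise ValidationError(f"concentration of {self.name} must be > 0")
        if self.valence == 0:
            raise ValidationError(f"valence of {self.name} must be non-zero")


#: Potassium and chloride at 1 M with standard infinite-dilution D values.
def kcl_species(concentration: float = 1.0) -> tuple[SpeciesSpec, SpeciesSpec]:
    return (
        SpeciesSpec("K+", +1, 1.96e-5, concentration),
        SpeciesSpec("Cl-", -1, 2.03e-5, concentration),
    )


@dataclass(frozen=True)
class ChannelSpec:
    """A cylindrical pore through an impermeable slab in a periodic box.

    The slab is centred on ``origin_z = 0`` and spans ``pore_length`` along z.
    An optional obstruction reduces the admissible pore cross-section to a
    fraction ``1 - obstruction_fraction`` inside ``obstruction_zrange``
    (default: the whole slab), emulating a partially occluding N-terminal
    tail.

    Units: Å for lengths, mV for voltage, K for temperature.
    """

    pore_radius: float = 5.0
    pore_length: float = 30.0
    box: tuple[float, float, float] = (49.2, 49.2, 40.0)
    voltage: float = 40.0
    temperature: float = 298.0
    species: tuple[SpeciesSpec, ...] = field(default_factory=kcl_species)
    obstruction_fraction: float = 0.0
    obstruction_zrange: tuple[float, float] | None = None

    def __post_init__(self):
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "box", tuple(float(b) for b in self.box))

    def validate(self) -> None:
        if self.pore_radius <= 0:
            raise ValidationError("pore_radius must be > 0")
        if self.pore_length <= 0:
            raise ValidationError("pore_length must be > 0")
        if any(b <= 0 for b in self.box):
            raise ValidationError("box lengths must be > 0")
        if self.pore_length >= self.box[2]:
            raise ValidationError("pore_length must be smaller than the box z-length")
        if not 0.0 <= self.obstruction_fraction <= 1.0:
            raise ValidationError("obstruction_fraction must lie in [0, 1]")
        if self.temperature <= 0:
            raise ValidationError("temperature must be > 0")
        if not self.species:
            raise ValidationError("at least one species is required")
        for sp in self.species:
            sp.validate()
        if self.obstruction_zrange is not None:
            lo, hi = self.obstruction_zrange
            if not lo < hi:
                raise ValidationError("obstruction_zrange must be an ordered interval")

    @property
    def open_area(self) -> float:
        """Open pore cross-section in Å², accounting for the obstruction."""
        return math.pi * self.pore_radius**2 * (1.0 - self.obstruction_fraction)

    def accessible_volume(self) -> float:
        """Volume in Å³ not excluded by the slab (pore lumen + reservoirs)."""
        ax, ay, az = self.box
        bulk = ax * ay * (az - self.pore_length)
        pore = math.pi * self.pore_radius**2 * self.pore_length
        return bulk + pore

    def matched_ion_count(self) -> int:
        """Per-species ion count reproducing the nominal concentration.

        Uses the accessible volume, so the simulated bulk density matches the
        concentration entering the analytic conductance oracle.
        """
        self.validate()
        counts = {
            sp.concentration for sp in self.species
        }
        c = max(counts)
        return max(1, round(c * units.MOL_PER_L_TO_PER_A3 * self.accessible_volume()))


@dataclass(frozen=True)
class ElectrolyteSpec:
    """A membrane-free periodic electrolyte box (for MSD-based D estimation)."""

    box: tuple[float, float, float] = (80.0, 80.0, 80.0)
    temperature: float = 298.0
    species: tuple[SpeciesSpec, ...] = field(
        default_factory=lambda: kcl_species(0.01)
    )

    def __post_init__(self):
        object.__setattr__(self, "species", tuple(self.species))
        object.__setattr__(self, "box", tuple(float(b) for b in self.box))

    def validate(self) -> None:
        if any(b <= 0 for b in self.box):
            raise ValidationError("box lengths must be > 0")
        if not self.species:
            raise ValidationError("at least one species is required")
        for sp in self.species:
            sp.validate()


@dataclass(frozen=True)
class ToyEnsembleSpec:
    """A toy β-barrel (elliptic rings of Cα-like points) plus an N-tail chain.

    ``tail_placement`` selects one of three geometries: ``"vertical"`` (tail
    running along the pore axis), ``"horizontal-mid-pore"`` (tail lying in the
    mid-pore xy-plane, the occluding arrangement), or ``"detached-below"``
    (tail dangling under the barrel). Gaussian jitter of SD ``jitter_sd`` Å is
    added independently per frame and coordinate.
    """

    n_frames: int = 50
    barrel_points_per_ring: int = 24
    barrel_rings: int = 8
    radius_a: float = 15.0
    radius_b: float = 15.0
    height: float = 30.0
    tail_residues: int = 11
    tail_placement: str = "vertical"
    jitter_sd: float = 0.2
    seed: int = 0

    _PLACEMENTS = ("vertical", "horizontal-mid-pore", "detached-below")

    def validate(self) -> None:
        if self.n_frames < 1:
            raise ValidationError("n_frames must be >= 1")
        if not self.radius_a >= self.radius_b > 0:
            raise ValidationError("require radius_a >= radius_b > 0")
        if self.jitter_sd < 0:
            raise ValidationError("jitter_sd must be >= 0")
        if self.tail_placement not in self._PLACEMENTS:
            raise ValidationError(
                f"tail_placement must be one of {self._PLACEMENTS}"
            )
        if self.barrel_points_per_ring < 3:
            raise ValidationError("need at least 3 points per ring")
        if self.height <= 0:
            raise ValidationError("height must be > 0")


def _species_from_dict(d: dict) -> SpeciesSpec:
    return SpeciesSpec(**d)


def channel_spec_from_dict(d: dict) -> ChannelSpec:
    d = dict(d)
    if "species" in d:
        d["species"] = tuple(_species_from_dict(s) for s in d["species"])
    if "box" in d:
        d["box"] = tuple(d["box"])
    if d.get("obstruction_zrange") is not None:
        d["obstruction_zrange"] = tuple(d["obstruction_zrange"])
    return ChannelSpec(**d)


def electrolyte_spec_from_dict(d: dict) -> ElectrolyteSpec:
    d = dict(d)
    if "species" in d:
        d["species"] = tuple(_species_from_dict(s) for s in d["species"])
    if "box" in d:
        d["box"] = tuple(d["box"])
    return ElectrolyteSpec(**d)


def spec_to_json(spec) -> str:
    """Serialize any spec dataclass to a JSON string."""
    return json.dumps(asdict(spec), indent=2, sort_keys=True)
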