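"""Polymorph phase data model and crystallographic geometry.

A :class:`CrystalPhase` bundles the bulk energetics of one polymorph
(intermolecular lattice energy ``E_latt_inter`` and intramolecular
conformational penalty ``dE_intra``, both per molecule in kJ/mol) with its
unit cell and a list of facet families ``{(hkl), E_att}``.  Attachment
energies are the energy released per molecule when a growth slice attaches
to the facet, so they must be stabilising (non-positive); ``-0.5 * E_att``
is the per-molecule surface penalty used by the particle-energy model.

Cell lengths and d-spacings are in angstroms; the Cartesian frame is the
standard crystallographic one (a along x, b in the xy-plane).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .errors import InputError, ValidationError

__all__ = [
    "UnitCell",
    "Facet",
    "CrystalPhase",
    "cell_basis",
    "cell_volume",
    "d_spacing",
    "facet_normal",
    "load_phase",
    "load_cell_from_cif",
]


@dataclass(frozen=True)
class UnitCell:
    """Unit-cell parameters: lengths in angstroms, angles in degrees."""

    a: float
    b: float
    c: float
    alpha: float
    beta: float
    gamma: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "c"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"cell length {name} must be > 0")
        for name in ("alpha", "beta", "gamma"):
            ang = getattr(self, name)
            if not 0.0 < ang < 180.0:
                raise ValidationError(f"cell angle {name} must be in (0, 180) degrees")
        if cell_volume(self) <= 0:
            raise ValidationError("cell parameters give a non-positive volume")

    @property
    def volume(self) -> float:
        """Cell volume in cubic angstroms."""
        return cell_volume(self)


def cell_basis(cell: UnitCell) -> np.ndarray:
    """Cartesian basis matrix with the cell vectors a, b, c as columns.

    Convention: a along x, b in the xy-plane.
    """
    ca, cb, cg = (math.cos(math.radians(x)) for x in (cell.alpha, cell.beta, cell.gamma))
    sg = math.sin(math.radians(cell.gamma))
    # squared fractional volume of the parallelepiped spanned by unit vectors
    v2 = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if v2 <= 0:
        raise ValidationError("cell angles do not define a valid 3D cell")
    v = math.sqrt(v2)
    a_vec = np.array([cell.a, 0.0, 0.0])
    b_vec = np.array([cell.b * cg, cell.b * sg, 0.0])
    c_vec = np.array([cell.c * cb, cell.c * (ca - cb * cg) / sg, cell.c * v / sg])
    return np.column_stack([a_vec, b_vec, c_vec])


def cell_volume(cell: UnitCell) -> float:
    ca, cb, cg = (math.cos(math.radians(x)) for x in (cell.alpha, cell.beta, cell.gamma))
    v2 = 1.0 - ca * ca - cb * cb - cg * cg + 2.0 * ca * cb * cg
    if v2 <= 0:
        return -1.0
    return cell.a * cell.b * cell.c * math.sqrt(v2)


def _reciprocal_vector(cell: UnitCell, hkl: Sequence[int]) -> np.ndarray:
    h, k, l = hkl
    if h == 0 and k == 0 and l == 0:
        raise ValidationError("hkl = (0,0,0) has no associated lattice plane")
    basis = cell_basis(cell)
    # reciprocal basis (crystallographic, no 2*pi): columns of inv(B).T
    recip = np.linalg.inv(basis).T
    return recip @ np.asarray([h, k, l], dtype=float)


def d_spacing(cell: UnitCell, hkl: Sequence[int]) -> float:
    """Interplanar spacing d_hkl in angstroms, from the reciprocal basis."""
    return 1.0 / float(np.linalg.norm(_reciprocal_vector(cell, hkl)))


def facet_normal(cell: UnitCell, hkl: Sequence[int]) -> np.ndarray:
    """Unit outward normal of the (hkl) plane in the fixed Cartesian frame."""
    g = _reciprocal_vector(cell, hkl)
    return g / np.linalg.norm(g)


@dataclass(frozen=True)
class Facet:
    """One facet family: Miller indices plus its attachment energy.

    The d-spacing and unit normal are derived from the owning phase's cell.
    Families are stored once and expanded to the +/-(hkl) Friedel pair when
    a hull is built.
    """

    hkl: tuple[int, int, int]
    E_att: float
    d_spacing: float
    unit_normal: np.ndarray = field(repr=False, compare=False)

    def __post_init__(self) -> None:
        if tuple(self.hkl) == (0, 0, 0):
            raise ValidationError("facet hkl must not be (0,0,0)")
        if self.E_att > 0:
            raise ValidationError(
                f"attachment energies must be stabilizing (<= 0); got {self.E_att} for {self.hkl}"
            )
        if self.d_spacing <= 0:
            raise ValidationError("d_spacing must be > 0")
        if abs(np.linalg.norm(self.unit_normal) - 1.0) > 1e-12:
            raise ValidationError("facet normal must be a unit vector")

    @property
    def label(self) -> str:
        return "(%d %d %d)" % self.hkl


@dataclass(frozen=True)
class CrystalPhase:
    """One polymorph: bulk energetics, unit cell and facet set."""

    name: str
    E_latt_inter: float
    dE_intra: float
    Z: int
    cell: UnitCell
    facets: tuple[Facet, ...]

    def __post_init__(self) -> None:
        if self.E_latt_inter > 0:
            raise ValidationError("E_latt_inter must be <= 0 (cohesive)")
        if self.dE_intra < 0:
            raise ValidationError("dE_intra must be >= 0 (a penalty)")
        if not (isinstance(self.Z, int) and self.Z > 0):
            raise ValidationError("Z must be a positive integer")
        if not math.isfinite(self.E_bulk) or self.E_bulk >= 0:
            raise ValidationError("bulk energy E_latt_inter + dE_intra must be finite and negative")
        if len(self.facets) < 3:
            raise ValidationError("at least 3 facet families are required")
        normals = np.array([f.unit_normal for f in self.facets])
        if np.linalg.matrix_rank(normals, tol=1e-9) < 3:
            raise ValidationError("facet normals must span 3-space (no bounded hull otherwise)")

    @property
    def E_bulk(self) -> float:
        """Bulk particle energy per molecule, kJ/mol."""
        return self.E_latt_inter + self.dE_intra

    @property
    def number_density(self) -> float:
        """Molecular number density Z / V_cell in molecules per cubic angstrom."""
        return self.Z / self.cell.volume

    def facet_by_label(self, label: str) -> Facet:
        for f in self.facets:
            if f.label == label:
                return f
        raise KeyError(label)


def make_phase(
    name: str,
    E_latt_inter: float,
    dE_intra: float,
    Z: int,
    cell: UnitCell,
    facet_specs: Sequence[tuple[Sequence[int], float]],
) -> CrystalPhase:
    """Assemble a validated phase, deriving per-facet d-spacings and normals."""
    facets = tuple(
        Facet(
            hkl=tuple(int(i) for i in hkl),
            E_att=float(e),
            d_spacing=d_spacing(cell, hkl),
            unit_normal=facet_normal(cell, hkl),
        )
        for hkl, e in facet_specs
    )
    return CrystalPhase(name=name, E_latt_inter=E_latt_inter, dE_intra=dE_intra, Z=Z, cell=cell, facets=facets)


_MANDATORY_KEYS = ("name", "E_latt_inter", "Z", "cell", "facets")
_CELL_KEYS = ("a", "b", "c", "alpha", "beta", "gamma")


def load_phase(path: str | Path) -> CrystalPhase:
    """Load and validate a phase file (JSON or YAML).

    Schema::

        name: str
        E_latt_inter: float    # kJ/mol, <= 0
        dE_intra: float        # kJ/mol, >= 0, optional (default 0)
        Z: int
        cell: {a, b, c, alpha, beta, gamma}
        facets: [{hkl: [h, k, l], E_att: float}, ...]
    """
    path = Path(path)
    if not path.exists():
        raise InputError(f"phase file not found: {path}")
    text = path.read_text()
    try:
        data = yaml.safe_load(text)  # YAML is a superset of JSON
    except yaml.YAMLError as exc:
        raise InputError(f"cannot parse phase file {path}: {exc}") from exc
    if not isinstance(data, dict):
        raise InputError(f"phase file {path} must contain a mapping")
    for key in _MANDATORY_KEYS:
        if key not in data:
            raise InputError(f"phase file {path} is missing mandatory key '{key}'")
    cell_data = data["cell"]
    for key in _CELL_KEYS:
        if key not in cell_data:
            raise InputError(f"phase file {path} cell block is missing key '{key}'")
    cell = UnitCell(**{k: float(cell_data[k]) for k in _CELL_KEYS})
    facet_specs = []
    for i, entry in enumerate(data["facets"]):
        for key in ("hkl", "E_att"):
            if key not in entry:
                raise InputError(f"phase file {path} facet #{i} is missing key '{key}'")
        facet_specs.append((entry["hkl"], float(entry["E_att"])))
    return make_phase(
        name=str(data["name"]),
        E_latt_inter=float(data["E_latt_inter"]),
        dE_intra=float(data.get("dE_intra", 0.0)),
        Z=int(data["Z"]),
        cell=cell,
        facet_specs=facet_specs,
    )


def save_phase(phase: CrystalPhase, path: str | Path) -> None:
    """Write a phase back to a phase file (JSON for .json, else YAML)."""
    data = {
        "name": phase.name,
        "E_latt_inter": phase.E_latt_inter,
        "dE_intra": phase.dE_intra,
        "Z": phase.Z,
        "cell": {
            "a": phase.cell.a,
            "b": phase.cell.b,
            "c": phase.cell.c,
            "alpha": phase.cell.alpha,
            "beta": phase.cell.beta,
            "gamma": phase.cell.gamma,
        },
        "facets": [{"hkl": list(f.hkl), "E_att": f.E_att} for f in phase.facets],
    }
    path = Path(path)
    if path.suffix == ".json":
        path.write_text(json.dumps(data, indent=2) + "\n")
    else:
        path.write_text(yaml.safe_dump(data, sort_keys=False))


def load_cell_from_cif(path: str | Path) -> tuple[UnitCell, int | None]:
    """Read cell parameters and Z from a CIF file (via gemmi).

    Energies never come from a CIF; only ``_cell_length_*``, ``_cell_angle_*``
    and ``_cell_formula_units_Z`` are consumed.
    """
    import gemmi

    path = Path(path)
    if not path.exists():
        raise InputError(f"CIF file not found: {path}")
    doc = gemmi.cif.read_file(str(path))
    block = doc.sole_block()

    def _num(tag: str) -> float | None:
        val = block.find_value(tag)
        if val is None:
            return None
        return gemmi.cif.as_number(val)

    vals = {
        "a": _num("_cell_length_a"),
        "b": _num("_cell_length_b"),
        "c": _num("_cell_length_c"),
        "alpha": _num("_cell_angle_alpha"),
        "beta": _num("_cell_angle_beta"),
        "gamma": _num("_cell_angle_gamma"),
    }
    missing = [k for k, v in vals.items() if v is None]
    if missing:
        raise InputError(f"CIF {path} is missing cell parameter(s): {', '.join(missing)}")
    z_raw = block.find_value("_cell_formula_units_Z")
    z = int(gemmi.cif.as_number(z_raw)) if z_raw is not None else None
    return UnitCell(**vals), z
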