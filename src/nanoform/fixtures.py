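"""Synthetic two-polymorph datasets and PBEM initial conditions.

The generated phase pair emulates the ritonavir situation: one form is
bulk-stable by a few kJ/mol (the printed lattice energies are -395 and
-400 kJ/mol), but the bulk-stable form carries the more expensive surfaces,
so the stability order can invert at the nanoscale.  Facet attachment
energies are drawn from a seeded uniform band around a per-form mean, with
the metastable form's mean reduced by the ``penalty_contrast`` factor.

A ritonavir template pair is also written with the printed bulk energies
and *placeholder* attachment energies: real DFT facet energies must be
transcribed by the user; they are never invented here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from .crystal import CrystalPhase, UnitCell, make_phase, save_phase
from .errors import ValidationError
from .morphology import attachment_energy_morphology
from .pbem import SizeGrid, lognormal_density

__all__ = [
    "FixtureSpec",
    "make_phase_pair",
    "write_phase_pair",
    "make_pbem_initial",
    "write_ritonavir_templates",
]

# Low-symmetry cells of the size class of a flexible drug molecule:
# a monoclinic cell for the metastable form, orthorhombic for the stable one.
_CELL_A = UnitCell(a=13.4, b=5.3, c=27.1, alpha=90.0, beta=103.0, gamma=90.0)
_CELL_B = UnitCell(a=10.0, b=18.7, c=20.5, alpha=90.0, beta=90.0, gamma=90.0)
# Families chosen so each form's d-spacings sit in a narrow band (~15%);
# with comparable slab thicknesses the attachment-energy habit is close to
# the optimum of the surface-penalty landscape, putting the penalty minimum
# at the most equant habit of the aspect-ratio sweep as in the drug-crystal
# case being emulated.
_HKL_A = [(2, 0, 0), (0, 1, 0), (2, 0, 2), (2, 0, -2), (0, 1, 1), (1, 1, 0)]
_HKL_B = [(1, 0, 0), (0, 2, 0), (0, 0, 2), (1, 1, 0), (0, 1, 2), (1, 1, 1)]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of the synthetic polymorph pair.

    ``bulk_gap`` is how much form B is bulk-stabler than form A (kJ/mol);
    ``penalty_contrast`` is the ratio of the two forms' surface-penalty
    coefficients for their attachment-energy habits (< 1 means the
    metastable form has cheaper surfaces, which is what makes a finite
    crossing size possible).
    """

    seed: int = 1
    bulk_gap: float = 5.0
    penalty_contrast: float = 0.68
    E_bulk_stable: float = -400.0
    mean_E_att_stable: float = 130.0  # |E_att| scale, kJ/mol
    band: float = 0.25  # relative half-width of the uniform |E_att| band
    n_facets: int = 6
    dE_intra_metastable: float = 0.0

    def __post_init__(self) -> None:
        if self.bulk_gap <= 0:
            raise ValidationError("bulk_gap must be > 0")
        if not 0 < self.penalty_contrast <= 1:
            raise ValidationError("penalty_contrast must be in (0, 1]")
        if not 3 <= self.n_facets <= 6:
            raise ValidationError("n_facets must be between 3 and 6")


def _draw_energies(rng: np.random.Generator, mean: float, band: float, n: int) -> np.ndarray:
    return -rng.uniform(mean * (1 - band), mean * (1 + band), size=n)


def make_phase_pair(spec: FixtureSpec = FixtureSpec()) -> tuple[CrystalPhase, CrystalPhase]:
    """Generate the (metastable, bulk-stable) synthetic phase pair.

    Form A ("alpha") sits ``bulk_gap`` above form B ("beta") in bulk energy
    but has uniformly cheaper surfaces; unless ``penalty_contrast`` is 1, a
    finite stability-crossing size exists for the attachment-energy habits
    (warned about otherwise, not raised).
    """
    from .energy import crossing_size, surface_penalty_coefficient  # deferred: energy imports morphology

    rng = np.random.default_rng(spec.seed)
    e_att_b = _draw_energies(rng, spec.mean_E_att_stable, spec.band, spec.n_facets)
    e_att_a = _draw_energies(rng, spec.mean_E_att_stable, spec.band, spec.n_facets)

    def _build(name, e_latt, de_intra, cell, hkls, e_att):
        return make_phase(name, e_latt, de_intra, 4, cell, list(zip(hkls, e_att)))

    e_latt_a = spec.E_bulk_stable + spec.bulk_gap - spec.dE_intra_metastable
    phase_a = _build("form-alpha", e_latt_a, spec.dE_intra_metastable, _CELL_A,
                     _HKL_A[: spec.n_facets], e_att_a)
    phase_b = _build("form-beta", spec.E_bulk_stable, 0.0, _CELL_B,
                     _HKL_B[: spec.n_facets], e_att_b)
    # The two cells carry different d-spacings and habits, so raw |E_att| ratios do
    # not control the penalty ratio.  Rescaling every |E_att| of form A leaves its
    # attachment-energy habit unchanged (plane distances are proportional to |E_att|
    # before volume normalisation) and scales its surface penalty exactly linearly,
    # so the contrast can be imposed on the penalty coefficients themselves.
    c_a = surface_penalty_coefficient(phase_a, attachment_energy_morphology(phase_a))
    c_b = surface_penalty_coefficient(phase_b, attachment_energy_morphology(phase_b))
    lam = spec.penalty_contrast * c_b / c_a
    phase_a = _build("form-alpha", e_latt_a, spec.dE_intra_metastable, _CELL_A,
                     _HKL_A[: spec.n_facets], e_att_a * lam)

    result = crossing_size(
        phase_a,
        attachment_energy_morphology(phase_a),
        phase_b,
        attachment_energy_morphology(phase_b),
        verify=False,
    )
    if not result.crosses:
        import warnings

        warnings.warn("no crossing possible for the generated pair", stacklevel=2)
    return phase_a, phase_b


def write_phase_pair(spec: FixtureSpec, out_dir: str | Path) -> tuple[Path, Path]:
    """Write the generated pair as YAML phase files; byte-identical per seed."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    phase_a, phase_b = make_phase_pair(spec)
    path_a = out_dir / "form_alpha.yaml"
    path_b = out_dir / "form_beta.yaml"
    save_phase(phase_a, path_a)
    save_phase(phase_b, path_b)
    return path_a, path_b


def make_pbem_initial(median: float, gsd: float, m0: float, grid: SizeGrid) -> np.ndarray:
    """Log-normal initial number density normalised to the requested m0."""
    return lognormal_density(grid, median=median, gsd=gsd, m0=m0)


def write_ritonavir_templates(out_dir: str | Path) -> tuple[Path, Path]:
    """Write SYNTHETIC ritonavir template phase files.

    Bulk lattice energies carry the printed values (-395 kJ/mol for form I,
    -400 kJ/mol for form II, dE_intra defaulted to 0).  Attachment energies
    are placeholders (null) marked for transcription from the publication's
    SI Appendix; the files fail validation until real values are filled in.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for name, e_latt, hkls in (
        ("ritonavir-form-I", -395.0, _HKL_A),
        ("ritonavir-form-II", -400.0, _HKL_B),
    ):
        data = {
            "name": name,
            "comment": "SYNTHETIC TEMPLATE: transcribe attachment energies from SI Appendix",
            "E_latt_inter": e_latt,
            "dE_intra": 0.0,
            "Z": 4,
            "cell": {"a": None, "b": None, "c": None, "alpha": None, "beta": None, "gamma": None},
            "facets": [{"hkl": list(hkl), "E_att": None} for hkl in hkls],
        }
        path = out_dir / (name.replace("-", "_") + "_template.yaml")
        path.write_text(yaml.safe_dump(data, sort_keys=False))
        paths.append(path)
    return tuple(paths)
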