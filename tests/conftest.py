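import numpy as np
import pytest

from nanoform import fixtures
from nanoform.crystal import UnitCell, make_phase
from nanoform.morphology import attachment_energy_morphology


def make_cubic_phase(e_bulk: float = -100.0, e_att: float = -10.0, a: float = 10.0):
    """Cubic toy phase with three orthogonal facet families of equal attachment energy.

    With a = 10 angstrom every d-spacing is 1 nm, so slab arithmetic is exact
    by hand: a cube of edge L nm has x_total = 6/L.
    """
    cell = UnitCell(a=a, b=a, c=a, alpha=90, beta=90, gamma=90)
    return make_phase(
        name="toy-cubic",
        E_latt_inter=e_bulk,
        dE_intra=0.0,
        Z=4,
        cell=cell,
        facet_specs=[((1, 0, 0), e_att), ((0, 1, 0), e_att), ((0, 0, 1), e_att)],
    )


@pytest.fixture(scope="session")
def cubic_phase():
    return make_cubic_phase()


@pytest.fixture(scope="session")
def phase_pair():
    """Default synthetic polymorph pair (metastable form-alpha, stable form-beta)."""
    return fixtures.make_phase_pair(fixtures.FixtureSpec(seed=1))


@pytest.fixture(scope="session")
def ae_morphologies(phase_pair):
    pa, pb = phase_pair
    return attachment_energy_morphology(pa), attachment_energy_morphology(pb)


def rejection_sample_volume(normals, distances, rng, box, n_points=1_000_000):
    """Monte-Carlo volume of the centrosymmetric half-space intersection.

    Samples the cube [-box, box]^3 (which must contain the body) and counts
    points satisfying |x . n_f| <= h_f for every family.
    """
    normals = np.asarray(normals, float)
    distances = np.asarray(distances, float)
    pts = rng.uniform(-box, box, size=(n_points, 3))
    inside = np.all(np.abs(pts @ normals.T) <= distances[None, :], axis=1)
    return (2 * box) ** 3 * inside.mean()


def layer_count_fractions(m, phase, rng, n_points=6_000_000):
    """Brute-force surface-fraction oracle: point-in-slab counting.

    Fills the hull's bounding box with uniform random points and, for each
    facet family, counts the interior points within one interplanar spacing
    (converted to nm) of either face of the +/- pair, divided by the total
    count inside.
    """
    lo = m.vertices.min(axis=0)
    hi = m.vertices.max(axis=0)
    pts = rng.uniform(lo, hi, size=(n_points, 3))
    proj = pts @ m.normals.T  # (P, F)
    inside = np.all(np.abs(proj) <= m.distances[None, :], axis=1)
    proj = proj[inside]
    total = len(proj)
    out = {}
    for i, fid in enumerate(m.facet_ids):
        d_nm = phase.facet_by_label(fid).d_spacing / 10.0
        in_slab = np.abs(proj[:, i]) > m.distances[i] - d_nm
        out[fid] = in_slab.sum() / total
    return out
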