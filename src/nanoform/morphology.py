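"""Convex crystal habits: construction, shape transforms and surface fractions.

A habit is a closed centrosymmetric convex polyhedron given in half-space
form: one unit normal and one perpendicular origin-plane distance per facet
*family*, expanded internally to the +/- Friedel pair.  Lengths here are in
nanometres.  scipy's half-space intersection and convex hull do the heavy
geometric lifting; per-family facet areas, the bounding box (L >= W >= T)
and the surface-molecule fractions x_(hkl) = A_(hkl) * d_(hkl) / V are
measured from the rebuilt hull.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
from scipy.spatial import ConvexHull, HalfspaceIntersection

from .crystal import CrystalPhase
from .errors import GeometryError, ValidationError

__all__ = [
    "Morphology",
    "AspectRatio",
    "SurfaceFractions",
    "build_hull",
    "attachment_energy_morphology",
    "apply_aspect_ratio",
    "scale_to_ped",
    "surface_fractions",
    "morphology_grid",
]

logger = logging.getLogger(__name__)

KV_SPHERE = np.pi / 6.0  # volume shape factor: V = (pi/6) * PED^3
ANGSTROM_PER_NM = 10.0

_GEOM_RTOL = 1e-9
_MIN_VOLUME = 1e-12  # nm^3


@dataclass(frozen=True)
class AspectRatio:
    """Canonical habit aspect ratios: L/T and W/T with 1 <= W/T <= L/T."""

    LT: float
    WT: float

    def __post_init__(self) -> None:
        if not (1.0 <= self.WT <= self.LT):
            raise ValidationError(f"aspect ratios must satisfy 1 <= WT <= LT; got LT={self.LT}, WT={self.WT}")


@dataclass(frozen=True)
class SurfaceFractions:
    """Per-family surface-molecule fractions and their sum.

    ``valid`` is False in the invalid regime (x_total > 1), where the
    one-slab surface model breaks down at extreme smallness; the numbers
    are still returned for inspection.
    """

    by_family: dict[str, float]
    x_total: float
    valid: bool


@dataclass(frozen=True)
class Morphology:
    """A centrosymmetric convex habit in half-space form plus measured geometry."""

    facet_ids: tuple[str, ...]
    normals: np.ndarray  # (F, 3), unit, one per family
    distances: np.ndarray  # (F,), nm, > 0
    vertices: np.ndarray = field(repr=False)  # (V, 3), nm
    facet_areas: np.ndarray = field(repr=False)  # (F,), nm^2, +/- pair summed
    volume: float = 0.0
    surface_area: float = 0.0
    bbox: tuple[float, float, float] = (0.0, 0.0, 0.0)  # L >= W >= T, nm
    bbox_axes: tuple[int, int, int] = (0, 1, 2)  # Cartesian axis carrying L, W, T

    @property
    def ped(self) -> float:
        """Particle equivalent diameter: diameter of the equal-volume sphere (nm)."""
        return float((self.volume / KV_SPHERE) ** (1.0 / 3.0))

    @property
    def aspect_ratio(self) -> AspectRatio:
        L, W, T = self.bbox
        return AspectRatio(LT=L / T, WT=W / T)

    def face_polygons(self) -> list[tuple[int, np.ndarray]]:
        """Vertex loops per face as (family_index, (k,3) array), +/- faces separately.

        Vertices of each face are ordered counter-clockwise seen from outside.
        """
        polys: list[tuple[int, np.ndarray]] = []
        for fam, sign in ((i, s) for i in range(len(self.facet_ids)) for s in (+1, -1)):
            n = sign * self.normals[fam]
            h = self.distances[fam]
            on = self.vertices[np.abs(self.vertices @ n - h) < 1e-9 * max(1.0, h)]
            if len(on) < 3:
                continue
            # order by angle in the face plane
            centroid = on.mean(axis=0)
            ref = on[0] - centroid
            ref = ref - np.dot(ref, n) * n
            ref /= np.linalg.norm(ref)
            other = np.cross(n, ref)
            ang = np.arctan2((on - centroid) @ other, (on - centroid) @ ref)
            polys.append((fam, on[np.argsort(ang)]))
        return polys


def build_hull(
    families: Sequence[tuple[np.ndarray, float]],
    facet_ids: Sequence[str] | None = None,
) -> Morphology:
    """Intersect centrosymmetric half-space pairs {x.n <= h} U {-x.n <= h}.

    Raises :class:`GeometryError` if the intersection is unbounded (normals
    do not span 3-space) or degenerate (volume below 1e-12 nm^3).
    """
    normals = np.array([np.asarray(n, dtype=float) for n, _ in families])
    distances = np.array([float(h) for _, h in families])
    if np.any(distances <= 0):
        raise GeometryError("all plane distances must be > 0")
    norms = np.linalg.norm(normals, axis=1)
    normals = normals / norms[:, None]
    if facet_ids is None:
        facet_ids = tuple(f"f{i}" for i in range(len(families)))
    if np.linalg.matrix_rank(normals, tol=1e-9) < 3:
        raise GeometryError("half-space intersection is unbounded: normals do not span 3-space")

    # scipy convention: rows [n_x, n_y, n_z, -h] meaning n.x - h <= 0
    halfspaces = np.vstack(
        [np.hstack([normals, -distances[:, None]]), np.hstack([-normals, -distances[:, None]])]
    )
    interior = np.zeros(3)  # origin is interior: all h > 0
    try:
        hs = HalfspaceIntersection(halfspaces, interior)
    except Exception as exc:  # scipy raises QhullError on unbounded input
        raise GeometryError(f"half-space intersection failed: {exc}") from exc
    verts = np.unique(np.round(hs.intersections, 12), axis=0)
    hull = ConvexHull(verts)
    if hull.volume < _MIN_VOLUME:
        raise GeometryError(f"degenerate hull: volume {hull.volume:.3e} nm^3 below {_MIN_VOLUME}")

    areas = _family_areas(hull, normals)
    extents = verts.max(axis=0) - verts.min(axis=0)
    order = tuple(int(i) for i in np.argsort(-extents, kind="stable"))
    bbox = tuple(float(extents[i]) for i in order)
    return Morphology(
        facet_ids=tuple(facet_ids),
        normals=normals,
        distances=distances,
        vertices=verts,
        facet_areas=areas,
        volume=float(hull.volume),
        surface_area=float(hull.area),
        bbox=bbox,
        bbox_axes=order,
    )


def _family_areas(hull: ConvexHull, normals: np.ndarray) -> np.ndarray:
    """Sum triangle areas of the vertex hull per facet family (+/- pair together)."""
    pts = hull.points
    areas = np.zeros(len(normals))
    unmatched = 0.0
    for simplex, eq in zip(hull.simplices, hull.equations):
        tri = pts[simplex]
        cross = np.cross(tri[1] - tri[0], tri[2] - tri[0])
        area = 0.5 * np.linalg.norm(cross)
        if area == 0.0:
            continue
        n_out = eq[:3]
        dots = np.abs(normals @ n_out)
        best = int(np.argmax(dots))
        if dots[best] > 1.0 - 1e-8:
            areas[best] += area
        else:
            unmatched += area
    if unmatched > 1e-9 * max(hull.area, 1.0):
        raise GeometryError("hull has faces not belonging to any declared family")
    return areas


def attachment_energy_morphology(phase: CrystalPhase, volume: float = 1.0) -> Morphology:
    """Attachment-energy habit: plane distances proportional to |E_att|.

    The proportionality constant is fixed by normalising the hull volume to
    ``volume`` (default 1 nm^3); callers rescale to the size they need.
    Facets too costly to appear on the hull keep zero area.
    """
    families = [(f.unit_normal, abs(f.E_att)) for f in phase.facets]
    ids = [f.label for f in phase.facets]
    m = build_hull(families, facet_ids=ids)
    scale = (volume / m.volume) ** (1.0 / 3.0)
    return _rescale(m, scale)


def _rescale(m: Morphology, factor: float) -> Morphology:
    """Uniform scaling of a measured morphology (no hull rebuild needed)."""
    extents = tuple(e * factor for e in m.bbox)
    return replace(
        m,
        distances=m.distances * factor,
        vertices=m.vertices * factor,
        facet_areas=m.facet_areas * factor**2,
        volume=m.volume * factor**3,
        surface_area=m.surface_area * factor**2,
        bbox=extents,
    )


def apply_aspect_ratio(
    m: Morphology,
    ar: AspectRatio,
    bounds: tuple[float, float] = (1.0, 14.0),
) -> Morphology:
    """Diagonally scale a habit so its bounding box hits the requested L/T, W/T.

    The scaling acts along the habit's canonical bounding-box axes; planes
    transform covariantly (n -> Lambda^{-1} n, renormalised) so each
    half-space keeps its facet identity, and the hull is rebuilt so areas
    are re-measured exactly.  The volume is left un-normalised.
    """
    lo, hi = bounds
    if not (lo <= ar.WT <= ar.LT <= hi):
        raise ValidationError(f"aspect ratios must lie within [{lo}, {hi}]; got {ar}")
    s = np.ones(3)
    eL, eW, eT = m.bbox
    axL, axW, axT = m.bbox_axes
    s[axT] = 1.0
    s[axL] = ar.LT * eT / eL
    s[axW] = ar.WT * eT / eW
    new_normals = m.normals / s[None, :]
    lengths = np.linalg.norm(new_normals, axis=1)
    new_normals /= lengths[:, None]
    new_distances = m.distances / lengths
    return build_hull(list(zip(new_normals, new_distances)), facet_ids=m.facet_ids)


def scale_to_ped(m: Morphology, ped: float) -> Morphology:
    """Uniformly scale so the volume equals that of a sphere of diameter ``ped`` nm."""
    if ped <= 0:
        raise ValidationError(f"PED must be > 0; got {ped}")
    target = KV_SPHERE * ped**3
    return _rescale(m, (target / m.volume) ** (1.0 / 3.0))


def surface_fractions(
    m: Morphology,
    phase: CrystalPhase,
    mode: str = "slab",
) -> SurfaceFractions:
    """Fraction of the particle's molecules in the surface layer of each facet.

    ``slab`` mode (default) counts the molecules within one interplanar
    spacing of each facet: x_(hkl) = A_(hkl) * d_(hkl) / V, with areas in
    nm^2, d converted from angstroms and V in nm^3 (the molecular number
    density cancels).  ``shell`` mode instead shrinks every plane by its own
    d-spacing, takes the volume difference between the outer and inner
    hulls, and apportions that shell among families by their A*d weights;
    the two agree as the particle grows.

    x_total > 1 marks the invalid regime (particle thinner than its own
    surface layer); the result is flagged, not raised.
    """
    d_nm = {}
    for fid in m.facet_ids:
        facet = phase.facet_by_label(fid)
        d_nm[fid] = facet.d_spacing / ANGSTROM_PER_NM

    weights = np.array([m.facet_areas[i] * d_nm[fid] for i, fid in enumerate(m.facet_ids)])
    if mode == "slab":
        x = weights / m.volume
    elif mode == "shell":
        inner_dist = m.distances - np.array([d_nm[fid] for fid in m.facet_ids])
        if np.any(inner_dist <= 0):
            x = np.full(len(m.facet_ids), np.inf)  # whole particle is surface
        else:
            inner = build_hull(list(zip(m.normals, inner_dist)), facet_ids=m.facet_ids)
            shell = m.volume - inner.volume
            x = shell * weights / weights.sum() / m.volume
    else:
        raise ValidationError(f"unknown surface-fraction mode '{mode}'")

    x_total = float(np.sum(x))
    valid = x_total <= 1.0
    if not valid:
        logger.warning("surface fractions in invalid regime: x_total = %.4f > 1", x_total)
    return SurfaceFractions(
        by_family=dict(zip(m.facet_ids, (float(v) for v in x))),
        x_total=x_total,
        valid=valid,
    )


def morphology_grid(levels: int = 24, lo: float = 1.0, hi: float = 14.0) -> list[AspectRatio]:
    """Canonical (L/T, W/T) sweep: all pairs with WT <= LT on an even grid.

    ``levels`` evenly spaced values in [lo, hi] give levels*(levels+1)/2
    habits; the default 24 levels on [1, 14] gives the standard 300-habit
    sweep.
    """
    if levels < 2:
        raise ValidationError(f"levels must be >= 2; got {levels}")
    if not lo < hi:
        raise ValidationError("lo must be < hi")
    vals = np.linspace(lo, hi, levels)
    return [AspectRatio(LT=float(lt), WT=float(wt)) for i, lt in enumerate(vals) for wt in vals[: i + 1]]


def to_off(m: Morphology) -> str:
    """Serialise the habit as an OFF polyhedron string for visualisation."""
    polys = m.face_polygons()
    vert_index: dict[tuple[float, ...], int] = {}
    verts: list[np.ndarray] = []
    faces: list[list[int]] = []
    for _, loop in polys:
        face = []
        for v in loop:
            key = tuple(np.round(v, 9))
            if key not in vert_index:
                vert_index[key] = len(verts)
                verts.append(v)
            face.append(vert_index[key])
        faces.append(face)
    lines = ["OFF", f"{len(verts)} {len(faces)} 0"]
    lines += [" ".join(f"{c:.9g}" for c in v) for v in verts]
    lines += [" ".join(str(i) for i in [len(f), *f]) for f in faces]
    return "\n".join(lines) + "\n"
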