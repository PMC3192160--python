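"""Cross-section hoops and segment lofting.

A fleshed body segment is reconstructed by placing planar cross-section
"hoops" (ellipses or octagons) on the skeletal boundary at stations along
the segment axis and lofting them into a closed triangle mesh.  Octagonal
hoops store eight radial control distances ordered from dorsal and
proceeding right-lateral, matching the section-hoop practice used when
fleshing out scanned skeletons; ellipses store two semi-axes.

Rings are discretized area-preservingly: the sampled radii are inflated by
``sqrt(true_area / polygon_area)`` so the polygonal ring has exactly the
profile's cross-sectional area.  A lofted cylinder, conical frustum or
octagonal prism then matches its closed-form volume at any ring resolution;
shape-dependent quantities (COM, inertia) still converge at O(n^-2) in the
ring vertex count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from shapely.geometry import Point, Polygon

from .mesh_core import (MassProperties, TriMesh, contains_points,
                        mass_properties, subtract_cavities)

__all__ = [
    "Hoop",
    "SegmentModel",
    "fit_hoop",
    "loft_segment",
    "scale_hoop",
    "diamondize",
    "add_cavity",
    "OCTAGON_ANGLES",
    "DIAMOND_FACTOR",
]

#: octagon control directions: angles from the dorsal axis toward right-lateral
OCTAGON_ANGLES = np.deg2rad(np.arange(8) * 45.0)
#: indices of the oblique (diagonal) octagon radii
DIAGONAL_INDICES = (1, 3, 5, 7)
#: radial factor approximating a diamond section from an octagon
DIAMOND_FACTOR = 0.853


def _polygon_area(radii: np.ndarray, angles: np.ndarray) -> float:
    """Shoelace area of the polygon with polar vertices (radii, angles)."""
    y = radii * np.cos(angles)
    z = radii * np.sin(angles)
    return 0.5 * abs(np.dot(y, np.roll(z, -1)) - np.dot(z, np.roll(y, -1)))


@dataclass(frozen=True)
class Hoop:
    """A planar cross-section profile at a station along a segment axis.

    Parameters
    ----------
    station : float
        Position along the segment axis (m).
    center : (3,) array
        Hoop centre in body coordinates.
    u, w : (3,) arrays
        Orthonormal in-plane axes (dorsal and right-lateral directions);
        both orthogonal to the segment axis.
    kind : {"octagon", "ellipse"}
    radii : array
        Eight radial distances (octagon, ordered from dorsal proceeding
        right-lateral) or two semi-axes ``(a, b)`` along ``u`` and ``w``.
    """

    station: float
    center: np.ndarray
    u: np.ndarray
    w: np.ndarray
    kind: Literal["octagon", "ellipse"]
    radii: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float).reshape(3))
        u = np.asarray(self.u, dtype=float).reshape(3)
        w = np.asarray(self.w, dtype=float).reshape(3)
        if abs(np.dot(u, w)) > 1e-9 or abs(np.linalg.norm(u) - 1) > 1e-9 \
                or abs(np.linalg.norm(w) - 1) > 1e-9:
            raise ValueError("hoop axes must be orthonormal")
        object.__setattr__(self, "u", u)
        object.__setattr__(self, "w", w)
        r = np.asarray(self.radii, dtype=float)
        n_expected = 8 if self.kind == "octagon" else 2
        if r.shape != (n_expected,):
            raise ValueError(f"{self.kind} hoop needs {n_expected} radii, got {r.shape}")
        if (r <= 0).any():
            raise ValueError("hoop radii must be positive")
        object.__setattr__(self, "radii", r)

    # -- profile geometry ----------------------------------------------
    def radius_at(self, theta: np.ndarray) -> np.ndarray:
        """Profile radius at in-plane angle theta (0 = dorsal, +pi/2 = right)."""
        theta = np.mod(np.asarray(theta, dtype=float), 2 * np.pi)
        if self.kind == "ellipse":
            a, b = self.radii
            return a * b / np.sqrt((b * np.cos(theta)) ** 2 + (a * np.sin(theta)) ** 2)
        # polar equation of the line segment between adjacent octagon vertices
        sector = (theta // (np.pi / 4)).astype(int) % 8
        t0 = sector * np.pi / 4
        r0 = self.radii[sector]
        r1 = self.radii[(sector + 1) % 8]
        s45 = np.sin(np.pi / 4)
        return r0 * r1 * s45 / (r1 * np.sin(t0 + np.pi / 4 - theta) + r0 * np.sin(theta - t0))

    def area(self) -> float:
        """Exact cross-sectional area of the profile."""
        if self.kind == "ellipse":
            return float(np.pi * self.radii[0] * self.radii[1])
        return _polygon_area(self.radii, OCTAGON_ANGLES)

    def resample(self, n: int) -> np.ndarray:
        """Area-preserving polygonal radii at ``n`` equally spaced angles.

        For octagons with ``n`` a multiple of 8 the sample angles include
        the control vertices, the sampled polygon coincides with the octagon
        and the correction factor is exactly 1.
        """
        if n < 3:
            raise ValueError("ring resolution must be >= 3")
        angles = 2 * np.pi * np.arange(n) / n
        r = self.radius_at(angles)
        poly_area = _polygon_area(r, angles)
        return r * np.sqrt(self.area() / poly_area)

    def ring_points(self, n: int) -> np.ndarray:
        """3D ring vertices of the resampled profile, shape (n, 3)."""
        angles = 2 * np.pi * np.arange(n) / n
        r = self.resample(n)
        return (self.center[None, :]
                + np.outer(r * np.cos(angles), self.u)
                + np.outer(r * np.sin(angles), self.w))

    def to_octagon(self) -> "Hoop":
        """Convert an elliptical profile to the octagon through its 8 control points."""
        if self.kind == "octagon":
            return self
        return replace(self, kind="octagon", radii=self.radius_at(OCTAGON_ANGLES))


def scale_hoop(hoop: Hoop, radial_factor: float) -> Hoop:
    """Multiply all radial dimensions; station and centre are never altered."""
    if radial_factor <= 0:
        raise ValueError("radial factor must be > 0")
    return replace(hoop, radii=hoop.radii * radial_factor)


def diamondize(hoop: Hoop, factor: float = DIAMOND_FACTOR) -> Hoop:
    """Shrink the four diagonal radii of an octagonal hoop toward a diamond.

    The dorsal/ventral and lateral control radii are unchanged; only the
    oblique radii are multiplied by ``factor``.  Elliptical hoops must be
    converted with :meth:`Hoop.to_octagon` first.
    """
    if hoop.kind != "octagon":
        raise ValueError("diamondize requires an octagonal hoop; convert with to_octagon()")
    if factor <= 0:
        raise ValueError("diamond factor must be > 0")
    radii = hoop.radii.copy()
    radii[list(DIAGONAL_INDICES)] *= factor
    return replace(hoop, radii=radii)


def fit_hoop(station: float,
             points: np.ndarray,
             u: np.ndarray,
             w: np.ndarray,
             center: np.ndarray | None = None,
             kind: Literal["octagon", "ellipse"] = "octagon",
             offset_fraction: float = 0.0) -> Hoop:
    """Fit a hoop around skeletal extreme points in a section plane.

    ``points`` are the per-direction outermost bone points of the section
    (3D, assumed to lie in the hoop plane).  With ``offset_fraction = 0`` the
    hoop hugs the bone: radii are chosen so every extreme point is contained,
    as small as the profile family allows.  Positive offsets inflate every
    radial dimension by ``1 + offset_fraction``.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if center is None:
        center = points.mean(axis=0)
    center = np.asarray(center, dtype=float).reshape(3)
    u = np.asarray(u, dtype=float).reshape(3)
    w = np.asarray(w, dtype=float).reshape(3)
    rel = points - center
    py, pz = rel @ u, rel @ w
    rad = np.hypot(py, pz)
    if len(points) < 3 or np.linalg.matrix_rank(np.column_stack([py, pz]), tol=1e-12) < 2:
        raise ValueError("need >= 3 non-collinear section points to fit a hoop")
    phi = np.arctan2(pz, py)  # angle from dorsal axis

    if kind == "ellipse":
        radii = np.array([np.abs(py).max(), np.abs(pz).max()])
    else:
        # skeletal extreme distance per control direction (nearest direction),
        # then inflate edges until every section point is contained
        phi_pos = np.mod(phi, 2 * np.pi)
        nearest = np.round(phi_pos / (np.pi / 4)).astype(int) % 8
        radii = np.zeros(8)
        for k in range(8):
            sel = nearest == k
            if sel.any():
                radii[k] = rad[sel].max()
        radii = np.maximum(radii, max(1e-9, 1e-3 * rad.max()))
        sector = (phi_pos // (np.pi / 4)).astype(int) % 8
        alpha = phi_pos - sector * (np.pi / 4)
        s45 = np.sin(np.pi / 4)
        for _ in range(100):
            r0, r1 = radii[sector], radii[(sector + 1) % 8]
            rho_max = r0 * r1 * s45 / (r1 * np.sin(np.pi / 4 - alpha) + r0 * np.sin(alpha))
            factor = rad / rho_max
            if (factor <= 1 + 1e-12).all():
                break
            # scaling both edge endpoints by f scales the edge clearance by f
            for k in range(8):
                sel = (sector == k) | ((sector + 1) % 8 == k)
                if sel.any() and factor[sel].max() > 1:
                    radii[k] *= factor[sel].max()

    hoop = Hoop(station, center, u, w, kind, radii)
    # guarantee containment against the exact polygonal boundary
    tol = 1e-9 * max(rad.max(), 1e-9)
    ang = 2 * np.pi * np.arange(64) / 64
    for _ in range(200):
        ring = hoop.resample(64)
        poly = Polygon(np.column_stack([ring * np.cos(ang), ring * np.sin(ang)]))
        if all(poly.distance(Point(py[i], pz[i])) <= tol for i in range(len(points))):
            break
        hoop = scale_hoop(hoop, 1.002)
    if offset_fraction:
        hoop = scale_hoop(hoop, 1.0 + offset_fraction)
    return hoop


def loft_segment(hoops: Sequence[Hoop], cap_ends: bool = True, ring_n: int = 32) -> TriMesh:
    """Loft ordered hoops into a (watertight, when capped) triangle mesh.

    Adjacent rings are joined by a ruled surface (linear interpolation of
    radii); end caps are triangle fans from the ring centroid, which
    guarantees watertightness.
    """
    hoops = list(hoops)
    if len(hoops) < 2:
        raise ValueError("loft requires at least 2 hoops")
    stations = np.array([h.station for h in hoops])
    if not (np.diff(stations) > 0).all():
        raise ValueError("hoops must be ordered by strictly increasing station")

    rings = [h.ring_points(ring_n) for h in hoops]
    vertices = np.vstack(rings)
    faces = []
    for k in range(len(rings) - 1):
        base0, base1 = k * ring_n, (k + 1) * ring_n
        for j in range(ring_n):
            j1 = (j + 1) % ring_n
            a, b = base0 + j, base0 + j1
            c, d = base1 + j1, base1 + j
            faces.append((a, b, c))
            faces.append((a, c, d))
    if cap_ends:
        c0 = rings[0].mean(axis=0)
        c1 = rings[-1].mean(axis=0)
        i0 = len(vertices)
        i1 = len(vertices) + 1
        vertices = np.vstack([vertices, c0[None, :], c1[None, :]])
        base_last = (len(rings) - 1) * ring_n
        for j in range(ring_n):
            j1 = (j + 1) % ring_n
            faces.append((i0, j1, j))                      # start cap
            faces.append((i1, base_last + j, base_last + j1))  # end cap
    mesh = TriMesh(vertices, np.asarray(faces, dtype=np.int64))
    if cap_ends and mesh.signed_volume() < 0:
        mesh = TriMesh(mesh.vertices, mesh.faces[:, ::-1])
    if _self_intersecting(rings):
        warnings.warn("loft may self-intersect: adjacent rings overlap along the axis",
                      stacklevel=2)
    return mesh


def _self_intersecting(rings: list[np.ndarray]) -> bool:
    # cheap diagnostic: consecutive ring centroids must advance monotonically
    centroids = np.array([r.mean(axis=0) for r in rings])
    axis = centroids[-1] - centroids[0]
    norm = np.linalg.norm(axis)
    if norm == 0:
        return True
    t = (centroids - centroids[0]) @ (axis / norm)
    return bool((np.diff(t) <= 0).any())


@dataclass
class SegmentModel:
    """A named body segment: flesh hoops, optional cavities, density.

    ``cavity_hoops`` holds one ordered hoop list per internal air space;
    cavity meshes are lofted on demand.  ``tight_hoops`` optionally records
    the bone-hugging (offset 0) hoops used by the tightly-fit sensitivity
    variant.  Limb segments represent the bilateral pair merged on the
    midline, matching the convention of the summary tables where whole-body
    mass is the sum of each listed segment once.
    """

    name: str
    hoops: list[Hoop]
    density: float = 1000.0
    cavity_hoops: list[list[Hoop]] = field(default_factory=list)
    cavity_meshes: list[TriMesh] = field(default_factory=list)
    tight_hoops: list[Hoop] | None = None
    ring_n: int = 32

    def __post_init__(self) -> None:
        if len(self.hoops) < 2:
            raise ValueError(f"segment '{self.name}' needs >= 2 hoops")
        st = [h.station for h in self.hoops]
        if not all(b > a for a, b in zip(st, st[1:])):
            raise ValueError(f"segment '{self.name}' hoops must have increasing stations")

    def build_mesh(self) -> TriMesh:
        return loft_segment(self.hoops, cap_ends=True, ring_n=self.ring_n)

    def build_cavity_meshes(self) -> list[TriMesh]:
        lofted = [loft_segment(hs, cap_ends=True, ring_n=self.ring_n)
                  for hs in self.cavity_hoops]
        return lofted + list(self.cavity_meshes)

    def mass_properties(self) -> MassProperties:
        """Net segment properties: flesh minus zero-density cavities.

        The external volume is unchanged by cavities, so the reported
        ``volume`` is the flesh volume and ``mass / volume`` is the bulk
        segment density (below the flesh density when air spaces exist).
        """
        flesh = mass_properties(self.build_mesh(), self.density)
        cavities = [mass_properties(m, self.density) for m in self.build_cavity_meshes()]
        if not cavities:
            return flesh
        return subtract_cavities(flesh, cavities)

    def check_cavity_containment(self, samples: int = 200, seed: int = 0) -> float:
        """Sampled fraction of cavity surface points inside the flesh mesh.

        Warns when below 1.0 (a cavity pokes outside the flesh surface).
        """
        cavities = self.build_cavity_meshes()
        if not cavities:
            return 1.0
        flesh = self.build_mesh()
        rng = np.random.default_rng(seed)
        inside = total = 0
        for cav in cavities:
            idx = rng.integers(0, len(cav.vertices), size=min(samples, len(cav.vertices)))
            pts = cav.vertices[idx]
            inside += int(contains_points(flesh, pts).sum())
            total += len(pts)
        frac = inside / total
        if frac < 1.0:
            warnings.warn(
                f"segment '{self.name}': only {100 * frac:.1f}% of sampled cavity points "
                "lie inside the flesh mesh", stacklevel=2)
        return frac


def add_cavity(segment: SegmentModel, cavity: TriMesh | Sequence[Hoop]) -> SegmentModel:
    """Register a zero-density air space inside a segment.

    The cavity must be watertight; its volume is subtracted from the segment
    mass at the flesh density while the external volume is unchanged.  A
    warning is emitted if sampled cavity points fall outside the flesh mesh.
    """
    if isinstance(cavity, TriMesh):
        cavity.validate()
        segment.cavity_meshes.append(cavity)
    else:
        segment.cavity_hoops.append(list(cavity))
    segment.check_cavity_containment()
    return segment
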