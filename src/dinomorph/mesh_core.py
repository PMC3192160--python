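"""Exact mass properties of closed triangle meshes.

Volume, centre of mass and inertia tensor are obtained by signed-tetrahedron
accumulation about the origin (an application of the divergence theorem).
For a watertight, consistently wound polyhedron the result is exact, with no
discretization error beyond the tessellation of the surface itself.  All
quantities are SI: metres, kilograms, kg m^2.

The convention throughout the package is a right-handed frame with
+x cranial, +y dorsal, +z right-lateral.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "TriMesh",
    "MassProperties",
    "DensityConfig",
    "MeshError",
    "WatertightError",
    "OrientationError",
    "mass_properties",
    "compose",
    "inertia_about",
    "subtract_cavities",
]

#: faces with area below this (m^2) are dropped as degenerate slivers
DEGENERATE_AREA = 1e-12


class MeshError(ValueError):
    """Base class for mesh validation failures."""


class WatertightError(MeshError):
    """Mesh is not closed: some edges are not shared by exactly two faces."""

    def __init__(self, open_edges: Sequence[tuple[int, int]]):
        self.open_edges = list(open_edges)
        shown = ", ".join(f"{a}-{b}" for a, b in self.open_edges[:10])
        more = "" if len(self.open_edges) <= 10 else f" (+{len(self.open_edges) - 10} more)"
        super().__init__(f"mesh is not watertight; open or inconsistent edges: {shown}{more}")


class OrientationError(MeshError):
    """Mesh winding encloses a non-positive signed volume."""


@dataclass(frozen=True)
class DensityConfig:
    """Densities (kg m^-3) used across a reconstruction.

    ``flesh`` is the homogeneous body density assigned to all fleshed
    segments; ``muscle`` is the density of vertebrate muscle used when
    correcting muscle-mass estimates; air ``cavity`` spaces carry zero
    density but full volume.
    """

    flesh: float = 1000.0
    muscle: float = 1060.0
    cavity: float = 0.0

    def __post_init__(self) -> None:
        for name in ("flesh", "muscle", "cavity"):
            if getattr(self, name) < 0:
                raise ValueError(f"density '{name}' must be >= 0")


@dataclass
class TriMesh:
    """A triangle surface mesh: vertices (n, 3) in metres, faces (m, 3) indices.

    Faces are wound counter-clockwise when viewed from outside, so the
    signed volume of a valid closed mesh is positive.  Degenerate faces
    (area below ``DEGENERATE_AREA``) are dropped at construction with a
    warning: lofted end caps can emit slivers.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError("vertices must have shape (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError("faces must have shape (m, 3)")
        areas = self._face_areas()
        bad = areas < DEGENERATE_AREA
        if bad.any():
            warnings.warn(
                f"dropping {int(bad.sum())} degenerate face(s) with area < {DEGENERATE_AREA} m^2",
                stacklevel=2,
            )
            self.faces = self.faces[~bad]

    # -- basic geometry -------------------------------------------------
    def _face_areas(self) -> np.ndarray:
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return 0.5 * np.linalg.norm(np.cross(b - a, c - a), axis=1)

    def signed_volume(self) -> float:
        v = self.vertices
        a, b, c = v[self.faces[:, 0]], v[self.faces[:, 1]], v[self.faces[:, 2]]
        return float(np.einsum("ij,ij->i", a, np.cross(b, c)).sum() / 6.0)

    def validate(self) -> None:
        """Raise unless the mesh is watertight, consistently wound and positive.

        Watertightness is checked on vertex indices (every directed edge must
        be matched by exactly one opposite directed edge); lofting always
        emits indexed closed meshes, so coordinate-proximity welding is not
        needed.
        """
        edges = np.concatenate(
            [self.faces[:, [0, 1]], self.faces[:, [1, 2]], self.faces[:, [2, 0]]]
        )
        directed = {}
        for a, b in edges:
            key = (int(a), int(b))
            directed[key] = directed.get(key, 0) + 1
        open_edges = []
        for (a, b), n in directed.items():
            if n != 1 or directed.get((b, a), 0) != 1:
                open_edges.append((a, b))
        if open_edges:
            raise WatertightError(sorted(set(tuple(sorted(e)) for e in open_edges)))
        if self.signed_volume() <= 0:
            raise OrientationError(
                f"signed volume {self.signed_volume():g} m^3 is not positive; "
                "faces are wound inward"
            )

    def is_watertight(self) -> bool:
        try:
            self.validate()
        except MeshError:
            return False
        return True

    # -- transforms -----------------------------------------------------
    def transformed(self, rotation: np.ndarray | None = None,
                    translation: np.ndarray | None = None) -> "TriMesh":
        """Return a rigidly moved copy (rotation applied before translation)."""
        v = self.vertices
        if rotation is not None:
            v = v @ np.asarray(rotation, dtype=float).T
        if translation is not None:
            v = v + np.asarray(translation, dtype=float)
        return TriMesh(v.copy(), self.faces.copy())

    def mirrored_z(self) -> "TriMesh":
        """Reflect across the midsagittal (z = 0) plane, fixing the winding."""
        v = self.vertices.copy()
        v[:, 2] *= -1.0
        return TriMesh(v, self.faces[:, ::-1].copy())

    @staticmethod
    def concatenate(meshes: Iterable["TriMesh"]) -> "TriMesh":
        """Disjoint union: stack vertex and (re-indexed) face arrays."""
        vs, fs, offset = [], [], 0
        for m in meshes:
            vs.append(m.vertices)
            fs.append(m.faces + offset)
            offset += len(m.vertices)
        if not vs:
            raise MeshError("cannot concatenate zero meshes")
        return TriMesh(np.vstack(vs), np.vstack(fs))

    # -- I/O --------------------------------------------------------------
    def to_trimesh(self):
        import trimesh

        return trimesh.Trimesh(self.vertices.copy(), self.faces.copy(), process=False)

    @classmethod
    def from_trimesh(cls, mesh) -> "TriMesh":
        return cls(np.asarray(mesh.vertices, dtype=float), np.asarray(mesh.faces))

    def save(self, path: str | Path) -> None:
        """Write ASCII OBJ or PLY (by extension), coordinates in metres."""
        path = Path(path)
        kind = path.suffix.lower().lstrip(".")
        if kind not in ("obj", "ply"):
            raise ValueError(f"unsupported mesh format '{kind}' (use .obj or .ply)")
        data = self.to_trimesh().export(file_type=kind, encoding="ascii") \
            if kind == "ply" else self.to_trimesh().export(file_type="obj")
        mode = "wb" if isinstance(data, bytes) else "w"
        with open(path, mode) as fh:
            fh.write(data)

    @classmethod
    def load(cls, path: str | Path) -> "TriMesh":
        import trimesh

        mesh = trimesh.load(str(path), force="mesh", process=False)
        return cls.from_trimesh(mesh)


@dataclass
class MassProperties:
    """Mass (kg), centre of mass (m), inertia about the COM (kg m^2), volume (m^3).

    For a homogeneous solid ``mass = density * volume``.  Composite bodies
    with internal zero-density cavities keep their external ``volume`` while
    ``mass`` reflects only the dense material, so ``mass / volume`` is the
    bulk (whole-body) density.
    """

    mass: float
    com: np.ndarray
    inertia: np.ndarray
    volume: float

    def __post_init__(self) -> None:
        self.com = np.asarray(self.com, dtype=float).reshape(3)
        self.inertia = np.asarray(self.inertia, dtype=float).reshape(3, 3)

    @property
    def density(self) -> float:
        return self.mass / self.volume

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "mass_kg": self.mass,
            "com_m": self.com.tolist(),
            "inertia_kg_m2": self.inertia.tolist(),
            "volume_m3": self.volume,
            "frame": "+x cranial, +y dorsal, +z right-lateral",
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "MassProperties":
        text = str(text_or_path)
        if not text.lstrip().startswith("{"):
            text = Path(text).read_text()
        d = json.loads(text)
        return cls(d["mass_kg"], np.array(d["com_m"]), np.array(d["inertia_kg_m2"]),
                   d["volume_m3"])


# -- divergence-theorem integrals ------------------------------------------

def _volume_integrals(mesh: TriMesh) -> tuple[float, np.ndarray, np.ndarray]:
    """Signed volume, first moment and second-moment matrix about the origin.

    Each face spans a signed tetrahedron with the origin.  For a tetrahedron
    with vertices p1..p4 (p4 = origin) and signed volume V:

        integral r dV      = V * (p1 + p2 + p3 + p4) / 4
        integral r r^T dV  = V / 20 * (sum_i p_i p_i^T + s s^T),  s = sum_i p_i
    """
    v = mesh.vertices
    a, b, c = v[mesh.faces[:, 0]], v[mesh.faces[:, 1]], v[mesh.faces[:, 2]]
    vols = np.einsum("ij,ij->i", a, np.cross(b, c)) / 6.0
    volume = vols.sum()
    first = (vols[:, None] * (a + b + c) / 4.0).sum(axis=0)
    s = a + b + c
    second = np.einsum("i,ijk->jk", vols / 20.0,
                       np.einsum("ij,ik->ijk", a, a)
                       + np.einsum("ij,ik->ijk", b, b)
                       + np.einsum("ij,ik->ijk", c, c)
                       + np.einsum("ij,ik->ijk", s, s))
    return float(volume), first, second


def mass_properties(mesh: TriMesh, density: float = 1000.0) -> MassProperties:
    """Exact mass, COM and central inertia tensor of a closed mesh.

    Parameters
    ----------
    mesh : TriMesh
        Watertight, consistently wound surface.
    density : float
        Homogeneous density in kg m^-3.  A zero density yields zero mass and
        inertia but the geometric volume and centroid are still reported.
    """
    if density < 0:
        raise ValueError("density must be >= 0")
    mesh.validate()
    volume, first, second = _volume_integrals(mesh)
    com = first / volume
    cov = second - volume * np.outer(com, com)  # central second moments
    inertia_geom = np.trace(cov) * np.eye(3) - cov
    return MassProperties(
        mass=density * volume,
        com=com,
        inertia=density * inertia_geom,
        volume=volume,
    )


def contains_points(mesh: TriMesh, points: np.ndarray, batch: int = 512) -> np.ndarray:
    """Point-in-solid test by the generalized winding number.

    The solid angle subtended by every face is accumulated per query point
    (van Oosterom & Strackee); for a watertight mesh the winding number is 1
    inside and 0 outside.  Robust to rays grazing edges, unlike ray casting.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    tri = mesh.vertices[mesh.faces]  # (F, 3, 3)
    result = np.empty(len(points), dtype=bool)
    for i in range(0, len(points), batch):
        p = points[i:i + batch]
        a = tri[None, :, 0, :] - p[:, None, :]
        b = tri[None, :, 1, :] - p[:, None, :]
        c = tri[None, :, 2, :] - p[:, None, :]
        la = np.linalg.norm(a, axis=-1)
        lb = np.linalg.norm(b, axis=-1)
        lc = np.linalg.norm(c, axis=-1)
        num = np.einsum("pfi,pfi->pf", a, np.cross(b, c))
        den = (la * lb * lc
               + np.einsum("pfi,pfi->pf", a, b) * lc
               + np.einsum("pfi,pfi->pf", b, c) * la
               + np.einsum("pfi,pfi->pf", c, a) * lb)
        omega = 2.0 * np.arctan2(num, den)
        result[i:i + len(p)] = omega.sum(axis=1) / (4.0 * np.pi) > 0.5
    return result


def _shift_inertia(inertia_com: np.ndarray, mass: float, d: np.ndarray) -> np.ndarray:
    """Parallel-axis shift of a central tensor by displacement ``d``."""
    d = np.asarray(d, dtype=float)
    return inertia_com + mass * (np.dot(d, d) * np.eye(3) - np.outer(d, d))


def inertia_about(props: MassProperties, point: np.ndarray) -> np.ndarray:
    """Inertia tensor of ``props`` about an arbitrary point.

    Shifting to ``props.com`` returns the central tensor unchanged; mass is
    invariant under the shift.
    """
    return _shift_inertia(props.inertia, props.mass, np.asarray(point) - props.com)


def compose(parts: Sequence[MassProperties]) -> MassProperties:
    """Combine rigidly connected parts into one body.

    Total mass and volume are sums; COM is the mass-weighted mean of the
    part COMs (zero-mass parts, e.g. air cavities, contribute volume only);
    inertia tensors are shifted to the composite COM by the parallel-axis
    theorem and summed.
    """
    parts = list(parts)
    if not parts:
        raise ValueError("compose() requires at least one part")
    total_mass = sum(p.mass for p in parts)
    total_volume = sum(p.volume for p in parts)
    if total_mass <= 0:
        raise ValueError("composite COM undefined: all parts have zero mass")
    com = sum(p.mass * p.com for p in parts) / total_mass
    inertia = np.zeros((3, 3))
    for p in parts:
        inertia += _shift_inertia(p.inertia, p.mass, com - p.com)
    return MassProperties(total_mass, com, inertia, total_volume)


def subtract_cavities(flesh: MassProperties,
                      cavities: Sequence[MassProperties]) -> MassProperties:
    """Net properties of a fleshed solid with internal zero-density cavities.

    ``cavities`` must be the mass properties of the cavity regions evaluated
    at the *flesh* density: the cavities lie wholly inside the flesh surface,
    so their volume stays part of the external volume, but the flesh mass
    they displace is removed along with the matching COM and inertia
    contributions.  The returned ``volume`` is therefore the external volume
    and ``mass / volume`` is the bulk density (< flesh density).
    """
    mass = flesh.mass - sum(c.mass for c in cavities)
    if mass <= 0:
        raise ValueError("cavities remove more mass than the flesh contains")
    moment = flesh.mass * flesh.com - sum(c.mass * c.com for c in cavities)
    com = moment / mass
    inertia = _shift_inertia(flesh.inertia, flesh.mass, com - flesh.com)
    for c in cavities:
        inertia -= _shift_inertia(c.inertia, c.mass, com - c.com)
    return MassProperties(mass, com, inertia, flesh.volume)
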