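"""Caudofemoral and limb extensor muscle-mass estimation.

Two complementary methods:

1. **M. caudofemoralis longus (CFL) reconstruction.**  For each caudal
   vertebra between the sacrum and the tail's transition point, a smooth
   closed loop is drawn from the lateral tip of the transverse process to
   the ventral tip of the chevron and back along the ventral and lateral
   borders of the chevron, centrum and transverse process.  The loops are
   lofted into a solid whose volume, at muscle-tissue density, yields the
   CFL mass.  A small, thin tendon extension connects the solid to the
   femur's fourth trochanter.  The region dorsolateral to the inner bone
   border (occupied by M. caudofemoralis brevis) is deliberately left
   unfilled and is not reconstructed.

2. **Segment-minus-bone extensor coefficients.**  Subtracting limb bone
   volumes from fleshed segment volumes leaves the soft-tissue volume; fixed
   fractions of that non-bony mass, taken from dissections of extant
   saurians, estimate the extensor (antigravity) muscle mass acting about
   each joint: hip = 54% of non-bone thigh mass plus the CFL mass, knee =
   34% of non-bone thigh mass, ankle = 47% of non-bone shank mass.

The "smooth curve" of the loop is realized as a periodic cubic spline
through the ordered landmark points, which passes *through* the transverse
process tip (so the small volume immediately below the process tip is
included) rather than truncating there.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.interpolate import CubicSpline

from .mesh_core import TriMesh, mass_properties

__all__ = [
    "CaudalVertebra",
    "CaudalSeries",
    "CflLoop",
    "CflResult",
    "ExtensorCoefficients",
    "ExtensorResult",
    "cfl_loops",
    "cfl_mass",
    "cfl_max",
    "cfl_fraction",
    "extensor_masses",
    "density_corrected_mass",
    "overestimate_pct",
]

#: landmark traversal order of a loop: outer smooth boundary first
#: (process tip to chevron tip), then back along the bone borders
LOOP_ORDER = ("transverse_process_tip", "chevron_tip", "chevron_lateral",
              "centrum_ventral", "centrum_lateral")
REQUIRED_LANDMARKS = set(LOOP_ORDER)


@dataclass
class CaudalVertebra:
    """Landmarks of one caudal vertebra, 3D points in the body frame.

    ``landmarks`` must contain the five named points of ``LOOP_ORDER``;
    ``outer`` optionally adds extra points on the smooth outer curve between
    the transverse process tip and the chevron tip.
    """

    station: float
    landmarks: dict[str, np.ndarray]
    outer: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.landmarks = {k: np.asarray(v, dtype=float).reshape(3)
                          for k, v in self.landmarks.items()}
        self.outer = [np.asarray(p, dtype=float).reshape(3) for p in self.outer]


@dataclass
class CaudalSeries:
    """Ordered caudal vertebrae (proximal to distal) plus femur attachment.

    ``transition_index`` is the first vertebra excluded distally (the tail's
    transition point, beyond which the CFL does not extend).
    """

    vertebrae: list[CaudalVertebra]
    transition_index: int
    fourth_trochanter: np.ndarray | None = None

    def __post_init__(self) -> None:
        if not 0 < self.transition_index <= len(self.vertebrae):
            raise ValueError("transition index must fall within the vertebral series")
        if self.fourth_trochanter is not None:
            self.fourth_trochanter = np.asarray(self.fourth_trochanter,
                                                dtype=float).reshape(3)

    # -- JSON landmark interchange --------------------------------------
    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "units": "m",
            "frame": "+x cranial, +y dorsal, +z right-lateral",
            "transition_index": self.transition_index,
            "fourth_trochanter": (None if self.fourth_trochanter is None
                                  else self.fourth_trochanter.tolist()),
            "vertebrae": [
                {"station": v.station,
                 "landmarks": {k: p.tolist() for k, p in v.landmarks.items()},
                 "outer": [p.tolist() for p in v.outer]}
                for v in self.vertebrae
            ],
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path: str | Path) -> "CaudalSeries":
        text = str(text_or_path)
        if not text.lstrip().startswith("{"):
            text = Path(text).read_text()
        d = json.loads(text)
        vertebrae = [CaudalVertebra(v["station"], v["landmarks"], v.get("outer", []))
                     for v in d["vertebrae"]]
        return cls(vertebrae, d["transition_index"], d.get("fourth_trochanter"))


@dataclass
class CflLoop:
    """One closed cross-section loop: sampled points (m, 3) in a vertebral plane."""

    station: float
    points: np.ndarray

    @property
    def centroid(self) -> np.ndarray:
        return self.points.mean(axis=0)

    def area(self) -> float:
        """Shoelace area of the loop in its section (y, z) plane."""
        y, z = self.points[:, 1], self.points[:, 2]
        return 0.5 * abs(np.dot(y, np.roll(z, -1)) - np.dot(z, np.roll(y, -1)))


@dataclass
class CflResult:
    """CFL reconstruction output: loops, lofted solid, volume and mass."""

    loops: list[CflLoop]
    volume: float
    mass: float
    density: float
    tendon_volume: float
    tendon_mass: float
    mesh: TriMesh

    @property
    def total_mass(self) -> float:
        return self.mass + self.tendon_mass


def _loop_spline(vertebra: CaudalVertebra, n_points: int, index: int) -> np.ndarray:
    missing = REQUIRED_LANDMARKS - set(vertebra.landmarks)
    if missing:
        raise ValueError(
            f"vertebra {index}: missing landmark(s) {sorted(missing)}")
    ordered = [vertebra.landmarks["transverse_process_tip"], *vertebra.outer]
    ordered += [vertebra.landmarks[k] for k in LOOP_ORDER[1:]]
    pts = np.asarray(ordered)[:, 1:]  # (y, z) in the section plane
    closed = np.vstack([pts, pts[:1]])
    chord = np.linalg.norm(np.diff(closed, axis=0), axis=1)
    t = np.concatenate([[0.0], np.cumsum(chord)])
    spline = CubicSpline(t, closed, bc_type="periodic")
    samples = spline(np.linspace(0.0, t[-1], n_points, endpoint=False))
    x = np.full(n_points, vertebra.station)
    return np.column_stack([x, samples])


def cfl_loops(series: CaudalSeries, n_points: int = 64) -> list[CflLoop]:
    """Closed planar muscle-boundary loops, one per pre-transition vertebra.

    Each loop is a periodic cubic spline through the ordered landmark points
    (process tip, optional outer points, chevron tip, then the chevron,
    centrum-ventral and centrum-lateral bone borders), sampled at ``n_points``
    equal parameter steps.  Loops pass through the transverse process tip
    and leave the brevis region (dorsal to the centrum-lateral border)
    unfilled.
    """
    active = series.vertebrae[:series.transition_index]
    if len(active) < 2:
        raise ValueError("need >= 2 vertebrae proximal to the transition point")
    return [CflLoop(v.station, _loop_spline(v, n_points, i))
            for i, v in enumerate(active)]


def _loft_loops(loops: Sequence[CflLoop]) -> TriMesh:
    rings = [lp.points for lp in loops]
    n = rings[0].shape[0]
    if any(r.shape[0] != n for r in rings):
        raise ValueError("all loops must be sampled with the same point count")
    # order rings by increasing x so the loft walks one way along the tail
    order = np.argsort([lp.station for lp in loops])
    rings = [rings[i] for i in order]
    vertices = np.vstack(rings)
    faces = []
    for k in range(len(rings) - 1):
        b0, b1 = k * n, (k + 1) * n
        for j in range(n):
            j1 = (j + 1) % n
            faces.append((b0 + j, b0 + j1, b1 + j1))
            faces.append((b0 + j, b1 + j1, b1 + j))
    i0 = len(vertices)
    i1 = i0 + 1
    vertices = np.vstack([vertices, rings[0].mean(axis=0), rings[-1].mean(axis=0)])
    last = (len(rings) - 1) * n
    for j in range(n):
        j1 = (j + 1) % n
        faces.append((i0, j1, j))
        faces.append((i1, last + j, last + j1))
    mesh = TriMesh(vertices, np.asarray(faces, dtype=np.int64))
    if mesh.signed_volume() < 0:
        mesh = TriMesh(mesh.vertices, mesh.faces[:, ::-1])
    return mesh


def _tendon_tube(start: np.ndarray, end: np.ndarray, radius: float,
                 n: int = 16) -> TriMesh:
    axis = end - start
    length = np.linalg.norm(axis)
    axis = axis / length
    ref = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(axis, ref)
    u /= np.linalg.norm(u)
    w = np.cross(axis, u)
    ang = 2 * np.pi * np.arange(n) / n
    ring = np.outer(np.cos(ang), u) + np.outer(np.sin(ang), w)
    verts = np.vstack([start + radius * ring, end + radius * ring,
                       start[None, :], end[None, :]])
    faces = []
    for j in range(n):
        j1 = (j + 1) % n
        faces.append((j, j1, n + j1))
        faces.append((j, n + j1, n + j))
        faces.append((2 * n, j1, j))
        faces.append((2 * n + 1, n + j, n + j1))
    mesh = TriMesh(verts, np.asarray(faces, dtype=np.int64))
    if mesh.signed_volume() < 0:
        mesh = TriMesh(mesh.vertices, mesh.faces[:, ::-1])
    return mesh


def cfl_mass(loops: Sequence[CflLoop],
             density: float = 1000.0,
             fourth_trochanter: np.ndarray | None = None,
             tendon_radius_fraction: float = 0.01) -> CflResult:
    """Loft the loops into a solid and report its volume and mass.

    ``density`` defaults to the homogeneous model density (1000 kg m^-3);
    mass is linear in density, so a muscle-density value (e.g. 1060) simply
    rescales it.  When ``fourth_trochanter`` is given, a thin tendon tube of
    radius ``tendon_radius_fraction`` x (mean radius of the proximal loop)
    runs from the proximal loop centroid to the trochanter; its small volume
    is reported separately and added to the total.
    """
    loops = list(loops)
    if len(loops) < 2:
        raise ValueError("need >= 2 loops to loft a volume")
    mesh = _loft_loops(loops)
    props = mass_properties(mesh, density)
    tendon_volume = tendon_mass = 0.0
    if fourth_trochanter is not None:
        proximal = max(loops, key=lambda lp: lp.station)
        mean_r = np.linalg.norm(proximal.points - proximal.centroid, axis=1).mean()
        tube = _tendon_tube(proximal.centroid, np.asarray(fourth_trochanter, float),
                            tendon_radius_fraction * mean_r)
        t_props = mass_properties(tube, density)
        tendon_volume, tendon_mass = t_props.volume, t_props.mass
    return CflResult(loops=loops, volume=props.volume, mass=props.mass,
                     density=density, tendon_volume=tendon_volume,
                     tendon_mass=tendon_mass, mesh=mesh)


def reconstruct_cfl(series: CaudalSeries, density: float = 1000.0,
                    n_points: int = 64) -> CflResult:
    """Landmarks-to-mass convenience wrapper: loops then loft."""
    loops = cfl_loops(series, n_points=n_points)
    return cfl_mass(loops, density=density,
                    fourth_trochanter=series.fourth_trochanter)


def cfl_max(cfl_min_mass: float, tail_max_mass: float, tail_min_mass: float) -> float:
    """Maximal-model CFL mass: scale by the tail-segment max/min mass ratio."""
    if cfl_min_mass <= 0 or tail_max_mass <= 0 or tail_min_mass <= 0:
        raise ValueError("masses must be > 0")
    return cfl_min_mass * (tail_max_mass / tail_min_mass)


def cfl_fraction(cfl_mass_kg: float, body_mass_kg: float) -> float:
    """CFL mass as a percentage of body mass."""
    if body_mass_kg <= 0:
        raise ValueError("body mass must be > 0")
    return 100.0 * cfl_mass_kg / body_mass_kg


@dataclass(frozen=True)
class ExtensorCoefficients:
    """Fractions of non-bone segment mass assigned to each joint's extensors."""

    hip: float = 0.54
    knee: float = 0.34
    ankle: float = 0.47

    def __post_init__(self) -> None:
        for name in ("hip", "knee", "ankle"):
            if not 0 < getattr(self, name) < 1:
                raise ValueError(f"coefficient '{name}' must lie in (0, 1)")


@dataclass(frozen=True)
class ExtensorResult:
    """Per-joint extensor masses (kg) and body-mass percentages."""

    hip_kg: float
    knee_kg: float
    ankle_kg: float
    body_mass_kg: float

    @property
    def total_kg(self) -> float:
        return self.hip_kg + self.knee_kg + self.ankle_kg

    @property
    def hip_pct(self) -> float:
        return 100.0 * self.hip_kg / self.body_mass_kg

    @property
    def knee_pct(self) -> float:
        return 100.0 * self.knee_kg / self.body_mass_kg

    @property
    def ankle_pct(self) -> float:
        return 100.0 * self.ankle_kg / self.body_mass_kg

    @property
    def total_pct(self) -> float:
        return 100.0 * self.total_kg / self.body_mass_kg

    def as_dict(self) -> dict[str, float]:
        return {"hip_kg": self.hip_kg, "knee_kg": self.knee_kg,
                "ankle_kg": self.ankle_kg, "total_kg": self.total_kg,
                "hip_pct": self.hip_pct, "knee_pct": self.knee_pct,
                "ankle_pct": self.ankle_pct, "total_pct": self.total_pct}


def extensor_masses(thigh_mass: float,
                    shank_mass: float,
                    femur_volume: float,
                    tibiotarsus_volume: float,
                    cfl_mass_kg: float,
                    body_mass: float,
                    coeffs: ExtensorCoefficients = ExtensorCoefficients(),
                    flesh_density: float = 1000.0) -> ExtensorResult:
    """Segment-minus-bone extensor estimates for one hindlimb.

    Bone mass is taken at the homogeneous model density (``flesh_density``),
    the convention under which the whole reconstruction is internally
    consistent.  Then::

        hip   = (thigh - femur_bone)      * coeffs.hip  + CFL
        knee  = (thigh - femur_bone)      * coeffs.knee
        ankle = (shank - tibiotarsus_bone) * coeffs.ankle
    """
    femur_bone = femur_volume * flesh_density
    tibio_bone = tibiotarsus_volume * flesh_density
    if femur_bone >= thigh_mass:
        raise ValueError("femur bone mass must be below the thigh segment mass")
    if tibio_bone >= shank_mass:
        raise ValueError("tibiotarsus bone mass must be below the shank segment mass")
    if body_mass <= 0:
        raise ValueError("body mass must be > 0")
    non_bone_thigh = thigh_mass - femur_bone
    non_bone_shank = shank_mass - tibio_bone
    return ExtensorResult(
        hip_kg=non_bone_thigh * coeffs.hip + cfl_mass_kg,
        knee_kg=non_bone_thigh * coeffs.knee,
        ankle_kg=non_bone_shank * coeffs.ankle,
        body_mass_kg=body_mass,
    )


def density_corrected_mass(mass: float, assumed_density: float,
                           actual_density: float) -> float:
    """Rescale a volume-derived mass from an assumed to an actual density."""
    if assumed_density <= 0 or actual_density <= 0:
        raise ValueError("densities must be > 0")
    return mass * actual_density / assumed_density


def overestimate_pct(estimate: float, actual: float) -> float:
    """Signed percent by which an estimate exceeds the measured value."""
    if actual <= 0:
        raise ValueError("actual value must be > 0")
    return 100.0 * (estimate / actual - 1.0)
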