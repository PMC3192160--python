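"""Synthetic skeletons, growth series and packaged table fixtures.

The original specimen scans are not available, so this module generates
every input the pipeline needs with analytic ground truth:

* parametric tyrannosaur-like (and crocodile-like) skeletons whose bones are
  unions of cylinders/frusta, so every bone volume has a closed form;
* octagonal body-section extreme points and hoop stations for the fleshing
  pipeline, with tapers kept *proportional* within a segment so the exact
  lofted volume follows the oblique pyramidal-frustum closed form
  ``(h/3)(A0 + A1 + sqrt(A0*A1))`` summed over hoop gaps;
* caudal vertebral landmark series for the caudofemoral muscle
  reconstruction, including a circle-based abstraction whose true muscle
  territory volume is analytic (the crocodile-like validation harness);
* growth observation series drawn from a known sigmoid plus seeded noise;
* the published summary tables of the reference tyrannosaur dataset,
  packaged bit-for-bit as CSV fixtures,
  with errata flagged (never silently corrected).
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .body_metrics import SkeletalMetrics
from .hoop_loft import Hoop, SegmentModel, fit_hoop, loft_segment, scale_hoop
from .mesh_core import TriMesh
from .muscle_recon import CaudalSeries, CaudalVertebra
from .variants import BodyModel
from .growth import generate_growth_series  # noqa: F401  (re-exported)

__all__ = [
    "SkeletonParams",
    "SyntheticSkeleton",
    "Fixture",
    "generate_skeleton",
    "build_initial_body",
    "synthetic_tyrannosaur",
    "prismatic_test_body",
    "crocodile_tail_series",
    "generate_random_solid",
    "generate_growth_series",
    "load_fixture",
    "tyrannosaur_params",
    "crocodile_params",
]

_Y = np.array([0.0, 1.0, 0.0])
_Z = np.array([0.0, 0.0, 1.0])
_X = np.array([1.0, 0.0, 0.0])
OCT = np.deg2rad(np.arange(8) * 45.0)


@dataclass(frozen=True)
class SkeletonParams:
    """Dimensions of a parametric archosaur skeleton (metres).

    Tapers are linear along each series and reach (near) zero at the tail
    tip.  ``seed`` controls the optional landmark jitter; with the default
    ``jitter = 0`` outputs are deterministic and byte-identical per seed.
    """

    presacral_count: int = 10
    caudal_count: int = 35
    centrum_radius: float = 0.09
    centrum_length: float = 0.19
    tp_span_base: float = 0.45       # transverse-process half-span at tail base
    chevron_depth_base: float = 0.40
    femur_length: float = 1.28
    femur_radius: float = 0.102
    tibiotarsus_length: float = 1.02
    tibiotarsus_radius: float = 0.10
    tarsometatarsus_length: float = 0.77
    tarsometatarsus_radius: float = 0.08
    gad: float = 2.5
    torso_length: float = 2.8
    neck_length: float = 1.1
    head_length: float = 1.1
    tail_length: float = 6.8
    jitter: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.presacral_count < 2 or self.caudal_count < 2:
            raise ValueError("vertebral counts must be >= 2")
        for name in ("centrum_radius", "centrum_length", "tp_span_base",
                     "chevron_depth_base", "femur_length", "femur_radius",
                     "tibiotarsus_length", "tibiotarsus_radius",
                     "tarsometatarsus_length", "tarsometatarsus_radius",
                     "gad", "torso_length", "neck_length", "head_length",
                     "tail_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")

    @property
    def body_length(self) -> float:
        return self.torso_length + self.neck_length + self.head_length + self.tail_length

    @property
    def leg_length(self) -> float:
        return (self.femur_length + self.tibiotarsus_length
                + self.tarsometatarsus_length)


def tyrannosaur_params(**overrides) -> SkeletonParams:
    """Adult tyrannosaur-like preset (femur ~1.3 m, body ~12 m)."""
    return SkeletonParams(**overrides)


def crocodile_params(**overrides) -> SkeletonParams:
    """Crocodile-like preset: long shallow tail, small process spans."""
    defaults = dict(
        caudal_count=24, centrum_radius=0.012, centrum_length=0.035,
        tp_span_base=0.045, chevron_depth_base=0.040,
        femur_length=0.12, femur_radius=0.009,
        tibiotarsus_length=0.10, tibiotarsus_radius=0.008,
        tarsometatarsus_length=0.08, tarsometatarsus_radius=0.006,
        gad=0.35, torso_length=0.40, neck_length=0.12, head_length=0.25,
        tail_length=0.85,
    )
    defaults.update(overrides)
    return SkeletonParams(**defaults)


# -- primitive solids -------------------------------------------------------

def _circular_hoop(station: float, center, radius: float, axis: str = "x") -> Hoop:
    if axis == "x":
        u, w = _Y, _Z
    elif axis == "-y":
        u, w = _X, _Z
    else:
        raise ValueError(f"unsupported axis '{axis}'")
    return Hoop(station, center, u, w, "ellipse", np.array([radius, radius]))


def cylinder_mesh(length: float, radius: float, origin, axis: str = "x",
                  ring_n: int = 32) -> TriMesh:
    """Closed cylinder along +x or -y; exact volume pi r^2 L by construction."""
    origin = np.asarray(origin, dtype=float)
    step = _X if axis == "x" else -_Y
    hoops = [_circular_hoop(0.0, origin, radius, axis),
             _circular_hoop(length, origin + length * step, radius, axis)]
    return loft_segment(hoops, cap_ends=True, ring_n=ring_n)


def _octagon_hoop(station, center, radii, axis="x") -> Hoop:
    u, w = (_Y, _Z) if axis == "x" else (_X, _Z)
    return Hoop(station, np.asarray(center, float), u, w, "octagon",
                np.asarray(radii, float))


def _frusta_volume(hoops: list[Hoop]) -> float:
    """Exact loft volume for hoops with proportional (similar) profiles."""
    total = 0.0
    for h0, h1 in zip(hoops, hoops[1:]):
        a0, a1 = h0.area(), h1.area()
        h = h1.station - h0.station
        total += h / 3.0 * (a0 + a1 + np.sqrt(a0 * a1))
    return total


def _inset_cavity(hoops: list[Hoop], radial: float, axial: float = 0.8) -> list[Hoop]:
    """Cavity hoops: radially shrunken and axially contracted toward mid-segment,
    so the air space sits strictly inside the flesh surface (clear of the caps)."""
    from dataclasses import replace

    mid_s = 0.5 * (hoops[0].station + hoops[-1].station)
    mid_c = 0.5 * (hoops[0].center + hoops[-1].center)
    out = []
    for h in hoops:
        shrunk = scale_hoop(h, radial)
        out.append(replace(shrunk,
                           station=mid_s + axial * (h.station - mid_s),
                           center=mid_c + axial * (h.center - mid_c)))
    return out


# -- caudal landmark series -------------------------------------------------

def _caudal_series(params: SkeletonParams, transition_fraction: float = 0.45
                   ) -> CaudalSeries:
    """Vertebral landmark loops for the caudofemoral reconstruction.

    Landmarks sit on per-vertebra circles of linearly tapering radius (a
    deliberate geometric abstraction: the loop spline through them
    approximates the circle, so the true muscle territory volume is the
    analytic circular frustum stack recorded in the ground truth).
    """
    n = params.caudal_count
    rng = np.random.default_rng(params.seed)
    transition = max(2, int(round(transition_fraction * n)))
    # angles (deg) of the ordered loop landmarks around the territory circle
    angle_map = {
        "transverse_process_tip": 30.0,
        "chevron_tip": 200.0,
        "chevron_lateral": 250.0,
        "centrum_ventral": 290.0,
        "centrum_lateral": 330.0,
    }
    outer_angles = (90.0, 150.0)
    vertebrae = []
    for k in range(n):
        s = (k + 0.5) * params.centrum_length
        x = -s
        frac = 1.0 - s / params.tail_length
        radius = max(0.3 * params.tp_span_base * frac, 0.02 * params.tp_span_base)
        center = np.array([x, -0.1 * params.chevron_depth_base, 0.3 * radius])
        jit = params.jitter * rng.normal(size=(len(angle_map) + 2, 2))

        def on_circle(deg, j):
            psi = np.deg2rad(deg)
            p = center + radius * (np.cos(psi) * _Y + np.sin(psi) * _Z)
            return p + np.array([0.0, jit[j, 0], jit[j, 1]])

        landmarks = {name: on_circle(deg, j)
                     for j, (name, deg) in enumerate(angle_map.items())}
        outer = [on_circle(deg, len(angle_map) + j)
                 for j, deg in enumerate(outer_angles)]
        vertebrae.append(CaudalVertebra(s, landmarks, outer))
    trochanter = np.array([0.0, -0.25 * params.femur_length, 0.05])
    return CaudalSeries(vertebrae, transition, trochanter)


def _cfl_territory_truth(series: CaudalSeries) -> float:
    """Analytic circular-frustum volume of the synthetic muscle territory."""
    active = series.vertebrae[:series.transition_index]
    radii, stations = [], []
    for v in active:
        pts = np.array([v.landmarks[k] for k in v.landmarks] + list(v.outer))
        center = pts.mean(axis=0)
        radii.append(np.linalg.norm((pts - center)[:, 1:], axis=1).mean())
        stations.append(v.station)
    total = 0.0
    for (r0, s0), (r1, s1) in zip(zip(radii, stations), zip(radii[1:], stations[1:])):
        total += np.pi * (s1 - s0) / 3.0 * (r0 ** 2 + r0 * r1 + r1 ** 2)
    return total


# -- skeleton ---------------------------------------------------------------

@dataclass
class SyntheticSkeleton:
    """Bone meshes, landmarks, section extremes and analytic ground truth."""

    params: SkeletonParams
    bone_meshes: dict[str, TriMesh]
    caudal_series: CaudalSeries
    torso_sections: list[tuple[float, np.ndarray]]
    metrics: SkeletalMetrics
    ground_truth: dict[str, float] = field(default_factory=dict)


#: torso skeletal boundary octagon radii (dorsal first, right-lateral next)
_TORSO_BASE_RADII = np.array([0.55, 0.60, 0.65, 0.55, 0.50, 0.55, 0.65, 0.60])
_TORSO_SCALES = (0.85, 0.95, 1.00, 0.95, 0.90)
_TORSO_AXIS_Y = -0.35


def generate_skeleton(params: SkeletonParams | None = None) -> SyntheticSkeleton:
    """Build the parametric skeleton with closed-form ground truth.

    Bones are cylinders, so e.g. the femur mesh volume equals
    ``pi * femur_radius^2 * femur_length`` up to the (area-preserving, hence
    vanishing) ring discretization.  Deterministic for a fixed seed.
    """
    p = params or tyrannosaur_params()
    scale = p.femur_length / 1.28  # limb bone placement scales with femur
    bones = {
        "femur": cylinder_mesh(p.femur_length, p.femur_radius,
                               (0.05, 0.0, 0.0), axis="-y"),
        "tibiotarsus": cylinder_mesh(p.tibiotarsus_length, p.tibiotarsus_radius,
                                     (0.05, -p.femur_length, 0.0), axis="-y"),
        "tarsometatarsus": cylinder_mesh(
            p.tarsometatarsus_length, p.tarsometatarsus_radius,
            (0.05, -(p.femur_length + p.tibiotarsus_length), 0.0), axis="-y"),
    }
    torso_scale = p.torso_length / 2.8
    sections = []
    stations = np.linspace(0.0, p.torso_length, len(_TORSO_SCALES))
    for s, sc in zip(stations, _TORSO_SCALES):
        radii = _TORSO_BASE_RADII * sc * torso_scale
        center = np.array([s, _TORSO_AXIS_Y * torso_scale, 0.0])
        pts = (center[None, :]
               + np.outer(radii * np.cos(OCT), _Y)
               + np.outer(radii * np.sin(OCT), _Z))
        sections.append((float(s), pts))
    series = _caudal_series(p)
    metrics = SkeletalMetrics(
        femur_length=p.femur_length, body_length=p.body_length, gad=p.gad,
        leg_length=p.leg_length, tail_length=p.tail_length)
    truth = {
        "femur_volume": np.pi * p.femur_radius ** 2 * p.femur_length,
        "tibiotarsus_volume": np.pi * p.tibiotarsus_radius ** 2 * p.tibiotarsus_length,
        "tarsometatarsus_volume": (np.pi * p.tarsometatarsus_radius ** 2
                                   * p.tarsometatarsus_length),
        "cfl_territory_volume": _cfl_territory_truth(series),
    }
    truth["femur_tibiotarsus_ratio"] = (truth["femur_volume"]
                                        / truth["tibiotarsus_volume"])
    return SyntheticSkeleton(p, bones, series, sections, metrics, truth)


# -- fleshed bodies ---------------------------------------------------------

def _tapered_segment(name, stations, base_radii, scales, centers, axis,
                     density=1000.0, cavity_scale: float | None = None,
                     ring_n: int = 32) -> SegmentModel:
    hoops = [_octagon_hoop(s, c, np.asarray(base_radii) * sc, axis)
             for s, sc, c in zip(stations, scales, centers)]
    seg = SegmentModel(name, hoops, density=density, ring_n=ring_n)
    if cavity_scale:
        seg.cavity_hoops.append(_inset_cavity(hoops, cavity_scale))
    return seg


def build_initial_body(skeleton: SyntheticSkeleton, torso_offset: float = 0.15,
                       ring_n: int = 32) -> BodyModel:
    """Flesh the synthetic skeleton into the initial ("preferred") body model.

    The torso is fitted to the skeletal section extremes with a radial
    offset (``torso_offset``; 0 would hug the bone), and the bone-hugging
    hoops are recorded for the tight minimal-model refit.  All other
    segments use proportional octagonal hoop tapers.  Limb segments sit in
    the midsagittal plane and stand for the bilateral pair merged, matching
    the summary-table convention of counting each roster segment once.
    """
    p = skeleton.params
    sc = p.torso_length / 2.8      # global axial scale
    lw = p.femur_length / 1.28     # limb/width scale

    torso_hoops, tight_hoops = [], []
    for s, pts in skeleton.torso_sections:
        center = np.array([s, _TORSO_AXIS_Y * sc, 0.0])
        torso_hoops.append(fit_hoop(s, pts, _Y, _Z, center=center,
                                    kind="octagon", offset_fraction=torso_offset))
        tight_hoops.append(fit_hoop(s, pts, _Y, _Z, center=center,
                                    kind="octagon", offset_fraction=0.0))
    torso = SegmentModel("body", torso_hoops, tight_hoops=tight_hoops, ring_n=ring_n)
    torso.cavity_hoops.append(_inset_cavity(torso_hoops, 0.36))

    def centers(x0, x1, n, y0, y1):
        xs = np.linspace(x0, x1, n)
        ys = np.linspace(y0, y1, n)
        return [np.array([x, y, 0.0]) for x, y in zip(xs, ys)]

    x_neck0 = p.torso_length
    x_neck1 = x_neck0 + p.neck_length
    x_head1 = x_neck1 + p.head_length
    neck = _tapered_segment(
        "neck", np.linspace(0, p.neck_length, 3), np.full(8, 0.30 * lw),
        (1.0, 0.92, 0.85), centers(x_neck0, x_neck1, 3, -0.10 * sc, 0.05 * sc),
        axis="x", cavity_scale=0.28, ring_n=ring_n)
    head = _tapered_segment(
        "head", np.linspace(0, p.head_length, 3), np.full(8, 0.34 * lw),
        (0.95, 1.0, 0.55), centers(x_neck1, x_head1, 3, 0.05 * sc, 0.10 * sc),
        axis="x", cavity_scale=0.45, ring_n=ring_n)

    n_tail = 7
    tail_scales = np.linspace(1.0, 0.045, n_tail)
    tail_stations = np.linspace(0.0, p.tail_length, n_tail)
    tail_centers = [np.array([-s, (-0.20 + 0.10 * s / p.tail_length) * sc, 0.0])
                    for s in tail_stations]
    tail = _tapered_segment("tail", tail_stations, np.full(8, 0.42 * lw),
                            tail_scales, tail_centers, axis="x", ring_n=ring_n)

    def limb(name, y0, length, r0, r1, x=0.05):
        sts = np.array([0.0, length])
        cts = [np.array([x, y0, 0.0]), np.array([x, y0 - length, 0.0])]
        return _tapered_segment(name, sts, np.full(8, r0), (1.0, r1 / r0),
                                cts, axis="-y", ring_n=ring_n)

    thigh = limb("thigh", 0.0, p.femur_length, 0.55 * lw, 0.35 * lw)
    shank = limb("shank", -p.femur_length, p.tibiotarsus_length,
                 0.38 * lw, 0.24 * lw)
    foot = limb("foot", -(p.femur_length + p.tibiotarsus_length),
                p.tarsometatarsus_length, 0.25 * lw, 0.15 * lw)
    forelimb = limb("forelimb", -0.1 * sc, 0.62 * lw, 0.07 * lw, 0.05 * lw,
                    x=0.85 * p.torso_length)

    segments = {s.name: s for s in
                (head, neck, torso, tail, forelimb, thigh, shank, foot)}
    body = BodyModel("synthetic", "initial", segments,
                     hip_origin=np.zeros(3), metrics=skeleton.metrics)
    # analytic flesh volumes: hoops within each segment are similar polygons
    skeleton.ground_truth.setdefault("initial_segment_volumes", {})
    for name, seg in segments.items():
        skeleton.ground_truth["initial_segment_volumes"][name] = \
            _frusta_volume(seg.hoops)
    return body


def synthetic_tyrannosaur(params: SkeletonParams | None = None,
                          ring_n: int = 32) -> BodyModel:
    """The packaged tyrannosaur-like test body (initial model)."""
    return build_initial_body(generate_skeleton(params or tyrannosaur_params()),
                              ring_n=ring_n)


def prismatic_test_body(ring_n: int = 32) -> BodyModel:
    """A body of straight prismatic segments with exact closed-form volumes.

    Segments are disjoint octagonal prisms, so radial scaling by f changes
    each volume by exactly f^2, composites equal the concatenated-mesh
    properties exactly, and every volume is analytic.
    """
    def prism(name, a, b, radii, y=0.0, axis="x", cavity=None):
        # axis "x": prism from x=a to x=b; axis "-y": length b at x=a, top y=y
        if axis == "x":
            cts = [np.array([a, y, 0.0]), np.array([b, y, 0.0])]
            sts = [0.0, b - a]
        else:
            cts = [np.array([a, y, 0.0]), np.array([a, y - b, 0.0])]
            sts = [0.0, b]
        hoops = [_octagon_hoop(s, c, radii, axis) for s, c in zip(sts, cts)]
        seg = SegmentModel(name, hoops, ring_n=ring_n)
        seg.tight_hoops = [scale_hoop(h, 0.85) for h in hoops]
        if cavity:
            seg.cavity_hoops.append(_inset_cavity(hoops, cavity))
        return seg

    r = np.full(8, 1.0)
    segments = {
        "body": prism("body", 0.0, 2.0, 0.8 * r, y=0.0, cavity=0.3),
        "neck": prism("neck", 2.5, 3.5, 0.35 * r, y=0.2),
        "head": prism("head", 4.0, 5.0, 0.4 * r, y=0.3),
        "tail": prism("tail", -3.0, -0.5, 0.45 * r, y=0.0),
        "forelimb": prism("forelimb", 1.8, 0.5, 0.08 * r, y=-1.0, axis="-y"),
        "thigh": prism("thigh", 0.1, 1.1, 0.5 * r, y=-1.2, axis="-y"),
        "shank": prism("shank", 0.1, 0.8, 0.3 * r, y=-2.5, axis="-y"),
        "foot": prism("foot", 0.1, 0.6, 0.2 * r, y=-3.6, axis="-y"),
    }
    metrics = SkeletalMetrics(femur_length=1.1, body_length=8.0, gad=2.0,
                              leg_length=2.8, tail_length=2.5)
    return BodyModel("prismatic", "initial", segments, metrics=metrics)


def crocodile_tail_series(params: SkeletonParams | None = None
                          ) -> tuple[CaudalSeries, float]:
    """Crocodile-like caudal landmark series plus the analytic territory volume.

    The blind-validation harness: landmarks lie on known tapering circles,
    so the true muscle volume is the circular frustum stack; the landmark
    reconstruction must recover it within a few percent.
    """
    skel = generate_skeleton(params or crocodile_params())
    return skel.caudal_series, skel.ground_truth["cfl_territory_volume"]


def generate_random_solid(seed: int, ring_n: int = 32) -> TriMesh:
    """A random watertight lofted solid (for oracle cross-checks)."""
    rng = np.random.default_rng(seed)
    n_hoops = int(rng.integers(3, 6))
    stations = np.sort(rng.uniform(0.0, 2.0, size=n_hoops))
    stations[1:] += 0.2 * np.arange(1, n_hoops)  # enforce separation
    hoops = []
    for s in stations:
        radii = rng.uniform(0.2, 1.0, size=8)
        center = np.array([s, rng.uniform(-0.1, 0.1), rng.uniform(-0.1, 0.1)])
        hoops.append(_octagon_hoop(s, center, radii, axis="x"))
    return loft_segment(hoops, cap_ends=True, ring_n=ring_n)


# -- packaged fixtures -------------------------------------------------------

_FIXTURE_ERRATA = {
    6: ["Carnegie printed average mass 9081 kg is not the mean of its "
        "printed min/max (7394, 14564)"],
    8: ["Stan printed maximal CFL mass 22 kg is inconsistent with its own "
        "scaling recipe (~192 x 1290/587)"],
}


@dataclass(frozen=True)
class Fixture:
    """One packaged summary table: printed rows, units and erratum flags."""

    table: int
    data: pd.DataFrame
    errata: tuple[str, ...] = ()

    def rows_flagged(self) -> pd.DataFrame:
        if "erratum" not in self.data.columns:
            return self.data.iloc[0:0]
        return self.data[self.data["erratum"].notna() & (self.data["erratum"] != "")]


def load_fixture(table_id: int) -> Fixture:
    """Load one of the packaged printed tables (ids 2-9).

    Values match the printed tables bit-for-bit; known inconsistencies are
    flagged in an ``erratum`` column and listed in ``Fixture.errata``, never
    silently corrected.
    """
    if table_id not in range(2, 10):
        raise ValueError(f"unknown fixture table id {table_id!r} (use 2-9)")
    ref = importlib.resources.files("dinomorph.data") / f"table{table_id}.csv"
    with importlib.resources.as_file(ref) as path:
        data = pd.read_csv(path, comment="#")
    return Fixture(table_id, data, tuple(_FIXTURE_ERRATA.get(table_id, ())))


def load_external_ages() -> pd.DataFrame:
    """Ages for the growth check; Stan/Sue/Carnegie rows are external estimates."""
    ref = importlib.resources.files("dinomorph.data") / "trex_growth_ages_external.csv"
    with importlib.resources.as_file(ref) as path:
        return pd.read_csv(path, comment="#")
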