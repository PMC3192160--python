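"""Sensitivity-analysis body models.

From an initial ("preferred") reconstruction, six variant bodies bracket the
uncertainty of fleshing out a skeleton:

* ``minimal`` — torso hoops refit tightly to the skeletal boundary; neck,
  limbs and tail radii x0.80 of the initial model; diagonal hoop radii
  x0.853 to approximate a diamond section; largest airspaces.
* ``maximal`` — all radial dimensions x1.2 (segment lengths never change);
  smallest airspaces.
* ``most_cranial`` / ``most_caudal`` / ``most_dorsal`` / ``most_ventral`` —
  per-segment compositions of the minimal/maximal rules that intentionally
  bias the centre of mass toward each extreme (e.g. most-cranial combines
  maximal neck+trunk with minimal tail+hindlimbs).

Head and forelimb dimensions are never varied: the head is well constrained
by anatomical landmarks and the forelimbs are a negligible mass fraction.
Airspace extremes reuse the flesh radial factors (largest x1.2, smallest
x0.8), applied per segment according to whether that segment takes its
minimal or maximal form.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .mesh_core import MassProperties, compose
from .hoop_loft import Hoop, SegmentModel, diamondize, scale_hoop, DIAMOND_FACTOR

__all__ = [
    "BodyModel",
    "VariantSpec",
    "VARIANT_NAMES",
    "variant_spec",
    "derive_variant",
    "com_extreme_suite",
]

SEGMENT_ROSTER = ("head", "neck", "body", "tail", "forelimb", "thigh", "shank", "foot")
FIXED_SEGMENTS = ("head", "forelimb")
AXIAL_VARIED = ("neck", "body", "tail")
HINDLIMB = ("thigh", "shank", "foot")

VARIANT_NAMES = ("initial", "minimal", "maximal",
                 "most_cranial", "most_caudal", "most_dorsal", "most_ventral")

# per-segment rules
RULE_UNCHANGED = "unchanged"
RULE_TIGHT = "tight_to_bone"
RULE_SHRINK = "radial_x0.80_diamond"
RULE_INFLATE = "radial_x1.2"


@dataclass
class BodyModel:
    """A complete fleshed body: named segments plus a hip-centred frame.

    ``hip_origin`` is the right hip joint centre; COM values are reported
    relative to it with cranial = +x and ventral = -y.  ``metrics`` holds the
    skeletal measurements used to normalize COM positions.
    """

    specimen: str
    variant: str
    segments: dict[str, SegmentModel]
    hip_origin: np.ndarray = field(default_factory=lambda: np.zeros(3))
    metrics: object | None = None  # SkeletalMetrics, kept loose to avoid a cycle

    def __post_init__(self) -> None:
        self.hip_origin = np.asarray(self.hip_origin, dtype=float).reshape(3)
        missing = [s for s in SEGMENT_ROSTER if s not in self.segments]
        if missing:
            raise ValueError(f"body model is missing segments: {missing}")

    def segment_properties(self) -> dict[str, MassProperties]:
        return {name: seg.mass_properties() for name, seg in self.segments.items()}

    def mass_properties(self) -> MassProperties:
        """Whole-body mass, COM and inertia (COM in absolute coordinates).

        Each roster segment contributes once, matching the summary-table
        convention in which whole-body mass is the sum of the listed segment
        masses.
        """
        return compose(list(self.segment_properties().values()))

    def com_hip_frame(self) -> np.ndarray:
        """Whole-body COM relative to the right hip joint centre."""
        return self.mass_properties().com - self.hip_origin


@dataclass(frozen=True)
class VariantSpec:
    """Per-segment scaling rules and airspace treatment for one variant."""

    name: str
    rules: Mapping[str, str]
    diamondize_torso: bool = True

    def __post_init__(self) -> None:
        unknown = set(self.rules) - set(SEGMENT_ROSTER)
        if unknown:
            raise ValueError(f"unknown segment name(s) in variant spec: {sorted(unknown)}")
        missing = set(SEGMENT_ROSTER) - set(self.rules)
        if missing:
            raise ValueError(f"variant spec missing rules for: {sorted(missing)}")
        for seg in FIXED_SEGMENTS:
            if self.rules[seg] != RULE_UNCHANGED:
                raise ValueError(f"{seg} dimensions are never varied")


def _rules(minimal_for: tuple[str, ...], maximal_for: tuple[str, ...]) -> dict[str, str]:
    rules = {seg: RULE_UNCHANGED for seg in SEGMENT_ROSTER}
    for seg in minimal_for:
        rules[seg] = RULE_TIGHT if seg == "body" else RULE_SHRINK
    for seg in maximal_for:
        rules[seg] = RULE_INFLATE
    return rules


def variant_spec(name: str, diamondize_torso: bool = True) -> VariantSpec:
    """Standard per-segment rule set for one of the seven model names."""
    varied = AXIAL_VARIED + HINDLIMB
    if name == "initial":
        rules = _rules((), ())
    elif name == "minimal":
        rules = _rules(varied, ())
    elif name == "maximal":
        rules = _rules((), varied)
    elif name == "most_dorsal":
        rules = _rules(HINDLIMB, AXIAL_VARIED)
    elif name == "most_ventral":
        rules = _rules(AXIAL_VARIED, HINDLIMB)
    elif name == "most_cranial":
        rules = _rules(("tail",) + HINDLIMB, ("neck", "body"))
    elif name == "most_caudal":
        rules = _rules(("neck", "body") + HINDLIMB, ("tail",))
    else:
        raise ValueError(f"unknown variant '{name}'")
    return VariantSpec(name, rules, diamondize_torso)


def _apply_rule(segment: SegmentModel, rule: str, diamondize_torso: bool) -> SegmentModel:
    seg = copy.deepcopy(segment)
    if rule == RULE_UNCHANGED:
        return seg

    def shrink(h: Hoop) -> Hoop:
        return diamondize(scale_hoop(h, 0.80).to_octagon(), DIAMOND_FACTOR)

    if rule == RULE_INFLATE:
        seg.hoops = [scale_hoop(h, 1.2) for h in seg.hoops]
        cavity_factor = 0.8  # smallest airspaces
    elif rule == RULE_SHRINK:
        seg.hoops = [shrink(h) for h in seg.hoops]
        cavity_factor = 1.2  # largest airspaces
    elif rule == RULE_TIGHT:
        if seg.tight_hoops is None:
            raise ValueError(
                f"segment '{seg.name}' has no bone-hugging hoops for the tight fit")
        hoops = [copy.deepcopy(h) for h in seg.tight_hoops]
        if diamondize_torso:
            hoops = [diamondize(h.to_octagon(), DIAMOND_FACTOR) for h in hoops]
        seg.hoops = hoops
        cavity_factor = 1.2
    else:
        raise ValueError(f"unknown rule '{rule}'")
    seg.cavity_hoops = [[scale_hoop(h, cavity_factor) for h in hs]
                        for hs in seg.cavity_hoops]
    return seg


def derive_variant(initial: BodyModel, spec: VariantSpec | str) -> BodyModel:
    """Apply per-segment scaling rules to an initial body model.

    Stations, hoop centres and therefore all segment lengths are bit-identical
    to the initial model; only radial dimensions change.
    """
    if isinstance(spec, str):
        spec = variant_spec(spec)
    segments = {name: _apply_rule(seg, spec.rules[name], spec.diamondize_torso)
                for name, seg in initial.segments.items()}
    return BodyModel(initial.specimen, spec.name, segments,
                     hip_origin=initial.hip_origin.copy(), metrics=initial.metrics)


def com_extreme_suite(initial: BodyModel,
                      diamondize_torso: bool = True
                      ) -> tuple[dict[str, BodyModel], pd.DataFrame]:
    """All six sensitivity variants with their mass properties.

    Returns the variant bodies plus a summary table (one row per variant:
    mass, COMx, COMy in the hip frame).  By construction the craniocaudal COM
    order satisfies most_caudal <= {minimal, maximal, dorsal, ventral} <=
    most_cranial on any body with nonzero neck and tail volume.
    """
    names = [n for n in VARIANT_NAMES if n != "initial"]
    bodies = {n: derive_variant(initial, variant_spec(n, diamondize_torso)) for n in names}
    rows = []
    for name, body in bodies.items():
        props = body.mass_properties()
        com = props.com - body.hip_origin
        rows.append({"model": name, "mass_kg": props.mass,
                     "comx_m": com[0], "comy_m": com[1], "comz_m": com[2],
                     "volume_m3": props.volume})
    return bodies, pd.DataFrame(rows).set_index("model")
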