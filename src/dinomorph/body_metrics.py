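"""Summary metrics: segment masses, COM normalization, ranges, densities.

These operations produce the tabular surface of a reconstruction study:
per-segment masses and body-mass fractions, whole-body mass and COM in the
hip-centred frame, COM positions normalized by four skeletal metrics (femur
length, total body length, gleno-acetabular distance and pelvic limb
length), maximal/minimal ranges, and whole-body bulk density.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variants import SEGMENT_ROSTER, BodyModel

__all__ = [
    "SkeletalMetrics",
    "ComSummary",
    "segment_table",
    "max_min_ratio",
    "normalize_com",
    "average_and_range",
    "whole_body_density",
    "round_sig",
]


@dataclass(frozen=True)
class SkeletalMetrics:
    """Skeleton-only measurements (metres) used for size normalization.

    ``gad`` is the gleno-acetabular distance (shoulder joint to hip joint), a
    torso-length proxy.  ``gad`` is stored directly rather than recovered
    from the GAD/body-length ratio, whose printed rounding is too coarse for
    normalization arithmetic.
    """

    femur_length: float
    body_length: float
    gad: float
    leg_length: float
    tail_length: float

    def __post_init__(self) -> None:
        for name in ("femur_length", "body_length", "gad", "leg_length", "tail_length"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        for name, value in (("gad_over_body", self.gad_over_body),
                            ("tail_over_body", self.tail_over_body)):
            if not 0 < value < 1:
                raise ValueError(f"{name} = {value:.3f} outside (0, 1)")

    @property
    def gad_over_body(self) -> float:
        return self.gad / self.body_length

    @property
    def tail_over_body(self) -> float:
        return self.tail_length / self.body_length


@dataclass(frozen=True)
class ComSummary:
    """COM position in the hip frame with its four normalizations (percent).

    Cranial is +x and ventral is -y; each normalized value is
    ``100 * COM / metric`` for the respective axis.
    """

    comx_m: float
    comy_m: float
    pct_femur: tuple[float, float]
    pct_body: tuple[float, float]
    pct_gad: tuple[float, float]
    pct_leg: tuple[float, float]

    def as_row(self) -> dict[str, float]:
        return {
            "comx_m": self.comx_m, "comy_m": self.comy_m,
            "comx_pct_femur": self.pct_femur[0], "comy_pct_femur": self.pct_femur[1],
            "comx_pct_body": self.pct_body[0], "comy_pct_body": self.pct_body[1],
            "comx_pct_gad": self.pct_gad[0], "comy_pct_gad": self.pct_gad[1],
            "comx_pct_leg": self.pct_leg[0], "comy_pct_leg": self.pct_leg[1],
        }


def segment_table(body: BodyModel) -> pd.DataFrame:
    """Per-segment masses and body-mass fractions.

    The fractions are relative to the whole-body mass (sum over the full
    roster, each listed segment once) and sum to 1.
    """
    props = body.segment_properties()
    missing = [s for s in SEGMENT_ROSTER if s not in props]
    if missing:
        raise ValueError(f"missing segments: {missing}")
    total = sum(p.mass for p in props.values())
    rows = [{"segment": name, "mass_kg": p.mass, "mass_fraction": p.mass / total}
            for name, p in props.items()]
    return pd.DataFrame(rows).set_index("segment")


def max_min_ratio(min_val: float, max_val: float) -> float:
    """Ratio of maximal to minimal model values (mass range)."""
    if min_val <= 0:
        raise ValueError("minimal value must be > 0")
    return max_val / min_val


def normalize_com(com: np.ndarray, metrics: SkeletalMetrics) -> ComSummary:
    """Normalize a hip-frame COM by the four skeletal metrics, in percent."""
    com = np.asarray(com, dtype=float).reshape(-1)
    x, y = float(com[0]), float(com[1])

    def pair(metric: float) -> tuple[float, float]:
        if metric <= 0:
            raise ValueError("normalizing metric must be > 0")
        return 100.0 * x / metric, 100.0 * y / metric

    return ComSummary(
        comx_m=x, comy_m=y,
        pct_femur=pair(metrics.femur_length),
        pct_body=pair(metrics.body_length),
        pct_gad=pair(metrics.gad),
        pct_leg=pair(metrics.leg_length),
    )


def average_and_range(min_mass: float, max_mass: float) -> tuple[float, float]:
    """Arithmetic mean of the minimal/maximal masses and their ratio."""
    return 0.5 * (min_mass + max_mass), max_min_ratio(min_mass, max_mass)


def whole_body_density(body: BodyModel) -> float:
    """Total mass over total external volume (kg m^-3).

    Air cavities inside the external surfaces contribute volume but no mass,
    so a reconstruction with realistic respiratory air spaces falls below
    the flesh density.
    """
    props = body.mass_properties()
    if props.volume <= 0:
        raise ValueError("body has zero external volume")
    return props.mass / props.volume


def round_sig(value: float, sig: int = 3) -> float:
    """Round to significant figures, as used when emitting display columns."""
    if value == 0:
        return 0.0
    from math import floor, log10

    return round(value, -int(floor(log10(abs(value)))) + (sig - 1))
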