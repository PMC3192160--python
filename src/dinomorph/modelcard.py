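"""Model cards and the end-to-end pipeline.

A model card is a YAML/JSON document declaring a specimen's segments (hoop
stations, profiles and radii), air cavities, densities and skeletal
metrics — everything needed to rebuild a body model reproducibly.  Units
are metres and kg throughout; the frame is +x cranial, +y dorsal,
+z right-lateral with the origin at the right hip joint centre.

``run_pipeline`` ties the stages together: build the initial model, derive
the six sensitivity variants, and emit summary CSVs (segment masses and
fractions, whole-body mass/COM per variant with the four normalizations),
plus the caudofemoral reconstruction when landmarks are available.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .body_metrics import SkeletalMetrics, normalize_com, segment_table, \
    whole_body_density
from .hoop_loft import Hoop, SegmentModel
from .muscle_recon import CaudalSeries, reconstruct_cfl
from .variants import SEGMENT_ROSTER, BodyModel, com_extreme_suite

logger = logging.getLogger("dinomorph")

__all__ = ["load_model_card", "body_from_card", "run_pipeline", "ModelCardError"]

_AXES = {
    "x": (np.array([0.0, 1.0, 0.0]), np.array([0.0, 0.0, 1.0])),
    "-y": (np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0])),
}


class ModelCardError(ValueError):
    """Schema violation in a model card (raised before any computation)."""


def load_model_card(path: str | Path) -> dict:
    """Parse and validate a YAML/JSON model card."""
    path = Path(path)
    text = path.read_text()
    card = json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    _validate_card(card)
    return card


def _validate_card(card: dict) -> None:
    if not isinstance(card, dict):
        raise ModelCardError("model card must be a mapping")
    for key in ("specimen", "segments"):
        if key not in card:
            raise ModelCardError(f"model card missing required key '{key}'")
    if card.get("units", "m") != "m":
        raise ModelCardError("model card units must be metres ('m')")
    names = {s.get("name") for s in card["segments"]}
    missing = set(SEGMENT_ROSTER) - names
    if missing:
        raise ModelCardError(f"model card missing segments: {sorted(missing)}")
    for seg in card["segments"]:
        hoops = seg.get("hoops", [])
        if len(hoops) < 2:
            raise ModelCardError(f"segment '{seg.get('name')}' needs >= 2 hoops")
        stations = [h["station"] for h in hoops]
        if not all(b > a for a, b in zip(stations, stations[1:])):
            raise ModelCardError(
                f"segment '{seg.get('name')}' hoop stations must strictly increase")


def _hoop_from_dict(d: dict, axis: str) -> Hoop:
    u, w = _AXES[axis]
    radii = np.asarray(d["radii"], dtype=float)
    kind = d.get("kind", "octagon" if radii.size == 8 else "ellipse")
    return Hoop(float(d["station"]), np.asarray(d["center"], dtype=float),
                u, w, kind, radii)


def body_from_card(card: dict | str | Path) -> BodyModel:
    """Instantiate a BodyModel from a (path to a) model card."""
    if not isinstance(card, dict):
        card = load_model_card(card)
    else:
        _validate_card(card)
    density = float(card.get("density_kg_m3", 1000.0))
    segments = {}
    for seg_d in card["segments"]:
        axis = seg_d.get("axis", "x")
        if axis not in _AXES:
            raise ModelCardError(f"unsupported segment axis '{axis}'")
        hoops = [_hoop_from_dict(h, axis) for h in seg_d["hoops"]]
        seg = SegmentModel(seg_d["name"], hoops, density=density)
        for cav in seg_d.get("cavities", []):
            seg.cavity_hoops.append([_hoop_from_dict(h, axis) for h in cav["hoops"]])
        if "tight_hoops" in seg_d:
            seg.tight_hoops = [_hoop_from_dict(h, axis) for h in seg_d["tight_hoops"]]
        segments[seg.name] = seg
    metrics = None
    if "metrics" in card:
        m = card["metrics"]
        metrics = SkeletalMetrics(m["femur_length_m"], m["body_length_m"],
                                  m["gad_m"], m["leg_length_m"], m["tail_length_m"])
    return BodyModel(card["specimen"], card.get("variant", "initial"), segments,
                     hip_origin=np.asarray(card.get("hip_origin", [0, 0, 0]), float),
                     metrics=metrics)


def _com_rows(bodies: dict) -> pd.DataFrame:
    rows = []
    for name, body in bodies.items():
        props = body.mass_properties()
        com = props.com - body.hip_origin
        row = {"model": name, "body_mass_kg": props.mass}
        if body.metrics is not None:
            row.update(normalize_com(com, body.metrics).as_row())
        else:
            row.update({"comx_m": com[0], "comy_m": com[1]})
        row["bulk_density_kg_m3"] = whole_body_density(body)
        rows.append(row)
    return pd.DataFrame(rows).set_index("model")


def run_pipeline(body_or_card, outdir: str | Path,
                 caudal_series: CaudalSeries | None = None,
                 write_meshes: bool = False, seed: int = 0) -> dict:
    """Run the full reconstruction chain and write its report directory.

    Accepts a BodyModel or a model-card path/dict.  Deterministic: the only
    random stage (cavity containment sampling) is driven by ``seed``, and
    the parameter choices are logged to stderr and echoed in the report.
    """
    body = body_or_card if isinstance(body_or_card, BodyModel) \
        else body_from_card(body_or_card)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline start: specimen=%s seed=%d outdir=%s",
                body.specimen, seed, outdir)

    bodies, summary = com_extreme_suite(body)
    bodies = {"initial": body, **bodies}

    seg_tables = {name: segment_table(b) for name, b in bodies.items()}
    seg_rows = []
    for name, table in seg_tables.items():
        t = table.reset_index()
        t.insert(0, "model", name)
        seg_rows.append(t)
    segments_csv = pd.concat(seg_rows, ignore_index=True)
    segments_csv.to_csv(outdir / "segment_masses.csv", index=False)

    com_csv = _com_rows(bodies)
    com_csv.to_csv(outdir / "body_mass_com.csv")

    report = {
        "specimen": body.specimen,
        "seed": seed,
        "models": list(bodies),
        "whole_body_mass_kg": {n: float(seg_tables[n]["mass_kg"].sum())
                               for n in bodies},
    }
    if caudal_series is not None:
        cfl = reconstruct_cfl(caudal_series)
        report["cfl_mass_kg"] = cfl.mass
        report["cfl_tendon_mass_kg"] = cfl.tendon_mass
        pd.DataFrame([{"cfl_mass_kg": cfl.mass,
                       "cfl_volume_m3": cfl.volume,
                       "tendon_mass_kg": cfl.tendon_mass}]
                     ).to_csv(outdir / "cfl.csv", index=False)
    if write_meshes:
        for name, b in bodies.items():
            for seg_name, seg in b.segments.items():
                seg.build_mesh().save(outdir / f"{name}_{seg_name}.obj")
    (outdir / "report.json").write_text(json.dumps(report, indent=2))
    logger.info("pipeline done: %d models, total initial mass %.0f kg",
                len(bodies), report["whole_body_mass_kg"]["initial"])
    return report
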