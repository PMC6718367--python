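"""Structured-text file formats: machine config, field files, parameter files.

Everything is plain YAML/CSV so a campaign is desk-inspectable; clinical
formats (DICOM-RT) are out of scope.  Output files carry a provenance block
(tool version, input hashes, seed) and are written deterministically, so
repeated runs with the same inputs are byte-identical.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .aperture import JawSetting, MLCBank
from .dsm import DSMFitResult, DSMParams, FieldSpec
from .geometry import MachineGeometry, scd_from_alpha
from .mlc_source import (APRatioModel, MLCScatterParams, MLCSourceModel, QuadCoeff)


def sha256_of(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]


def provenance_block(seed=None, inputs: dict | None = None) -> dict:
    prov = {"tool": "headscatter", "version": __version__}
    if seed is not None:
        prov["seed"] = int(seed)
    if inputs:
        prov["inputs"] = {str(k): sha256_of(v) for k, v in inputs.items()}
    return prov


def _dump(doc: dict, path) -> None:
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=False))


def _load(path) -> dict:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict):
        raise ValueError(f"{path}: expected a YAML mapping")
    return doc


# ----------------------------------------------------------------------------
# Machine config

def read_machine_config(path) -> MachineGeometry:
    """Keys: sad_cm, smd_cm, ff_dist_cm, and exactly one of scd_x_cm / alpha;
    optional scd_y_cm, cap_radius_cm."""
    doc = _load(path)
    has_scd = "scd_x_cm" in doc
    has_alpha = "alpha" in doc
    if has_scd == has_alpha:
        raise ValueError(f"{path}: exactly one of scd_x_cm / alpha is required")
    sad = float(doc.get("sad_cm", 100.0))
    smd = float(doc.get("smd_cm", 51.0))
    scd_x = float(doc["scd_x_cm"]) if has_scd else scd_from_alpha(float(doc["alpha"]), smd, sad)
    kw = {}
    if "scd_y_cm" in doc:
        kw["scd_y"] = float(doc["scd_y_cm"])
    if "cap_radius_cm" in doc:
        kw["cap_radius"] = float(doc["cap_radius_cm"])
    return MachineGeometry(sad=sad, smd=smd, scd_x=scd_x,
                           ff_dist=float(doc.get("ff_dist_cm", 12.5)), **kw)


def write_machine_config(geom: MachineGeometry, path, provenance=None) -> None:
    doc = {"sad_cm": geom.sad, "smd_cm": geom.smd, "scd_x_cm": geom.scd_x,
           "ff_dist_cm": geom.ff_dist, "cap_radius_cm": geom.cap_radius}
    if geom.scd_y is not None:
        doc["scd_y_cm"] = geom.scd_y
    if provenance:
        doc["provenance"] = provenance
    _dump(doc, path)


# ----------------------------------------------------------------------------
# Field files

def write_field_file(fs: FieldSpec, path, provenance=None) -> None:
    doc: dict = {"jaw": {"x1": fs.jaw.x1, "x2": fs.jaw.x2,
                         "y1": fs.jaw.y1, "y2": fs.jaw.y2}}
    if fs.bank is not None:
        doc["mlc"] = {"edges": [float(v) for v in fs.bank.edges],
                      "left": [float(v) for v in fs.bank.left],
                      "right": [float(v) for v in fs.bank.right]}
    if fs.field_id:
        doc["field_id"] = fs.field_id
    if provenance:
        doc["provenance"] = provenance
    _dump(doc, path)


def read_field_file(path) -> FieldSpec:
    doc = _load(path)
    j = doc["jaw"]
    jaw = JawSetting(float(j["x1"]), float(j["x2"]), float(j["y1"]), float(j["y2"]))
    bank = None
    if "mlc" in doc:
        m = doc["mlc"]
        if "mlc_square" in m:
            bank = MLCBank.square(float(m["mlc_square"]))
        else:
            edges = np.asarray(m["edges"], float) if "edges" in m else None
            kw = {"edges": edges} if edges is not None else {}
            bank = MLCBank(left=np.asarray(m["left"], float),
                           right=np.asarray(m["right"], float), **kw)
    return FieldSpec(jaw=jaw, bank=bank, field_id=str(doc.get("field_id", "")))


# ----------------------------------------------------------------------------
# Parameter files

def write_dsm_params(result: DSMFitResult | DSMParams, path, provenance=None) -> None:
    p = result.params if isinstance(result, DSMFitResult) else result
    doc = {"k_ff": float(p.k_ff), "sigma_ff": float(p.sigma_ff), "k_b": float(p.k_b)}
    if isinstance(result, DSMFitResult):
        doc["fit"] = {"objective": result.objective, "nfev": result.nfev,
                      "converged": result.converged, "message": result.message}
    if provenance:
        doc["provenance"] = provenance
    _dump(doc, path)


def read_dsm_params(path) -> DSMParams:
    doc = _load(path)
    return DSMParams(k_ff=float(doc["k_ff"]), sigma_ff=float(doc["sigma_ff"]),
                     k_b=float(doc["k_b"]))


def write_mlc_params(model: MLCSourceModel, path, provenance=None) -> None:
    doc: dict = {"provenance_class": model.provenance, "per_jaw": []}
    for (w, h), p in sorted(model.per_jaw.items()):
        doc["per_jaw"].append({"jaw_x_cm": float(w), "jaw_y_cm": float(h),
                               **{k: float(getattr(p, k))
                                  for k in MLCScatterParams.PARAM_NAMES}})
    if model.apratio_model is not None:
        am = model.apratio_model
        doc["apratio_model"] = {
            "fitted_range": [float(am.fitted_range[0]), float(am.fitted_range[1])],
            "coeffs": {k: {"c2": float(c.c2), "c1": float(c.c1), "c0": float(c.c0),
                           "scale": c.scale} for k, c in am.coeffs.items()},
        }
    # units are part of the file so fitted parameters are self-describing
    doc["conventions"] = {"fp_rp_plane": "mid-MLC", "length_unit": "cm",
                          "ma_ra_unit": "cm^2", "apratio_plane": "isocenter"}
    if provenance:
        doc["provenance"] = provenance
    _dump(doc, path)


def read_mlc_params(path) -> MLCSourceModel:
    doc = _load(path)
    per_jaw = {}
    for row in doc.get("per_jaw", []):
        key = (float(row["jaw_x_cm"]), float(row["jaw_y_cm"]))
        per_jaw[key] = MLCScatterParams(
            **{k: float(row[k]) for k in MLCScatterParams.PARAM_NAMES})
    ap = None
    if "apratio_model" in doc:
        am = doc["apratio_model"]
        coeffs = {k: QuadCoeff(float(c["c2"]), float(c["c1"]), float(c["c0"]),
                               scale=c.get("scale", "linear"))
                  for k, c in am["coeffs"].items()}
        ap = APRatioModel(coeffs, fitted_range=tuple(am.get("fitted_range",
                                                            (2.5, 7.5))))
    return MLCSourceModel(per_jaw=per_jaw, apratio_model=ap,
                          provenance=doc.get("provenance_class", "fitted"))
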