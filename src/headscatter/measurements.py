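"""Measured-Sc campaign tables.

A campaign is a CSV with one row per collimator setting: field_id, the four
jaw positions at isocenter, an MLC specification, the measured Sc and its
standard deviation.  ``mlc_spec`` is one of

* ``retracted``            -- MLC out of the beam (bank = None),
* ``square:<side>``        -- centered MLC square (cm at isocenter),
* ``template:<name>[:J]``  -- a named irregular leaf template (cross,
                              mirrored_e, maze) scaled to jaw size J,
* a path to a field definition file (YAML) with explicit leaf positions.

Lines starting with '#' are provenance comments; unknown columns are kept.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .aperture import JawSetting, MLCBank
from .dsm import FieldSpec

REQUIRED_COLUMNS = ("field_id", "jaw_x1", "jaw_x2", "jaw_y1", "jaw_y2",
                    "mlc_spec", "sc", "sd")


class SchemaError(ValueError):
    pass


def bank_from_spec(spec: str, jaw: JawSetting, base_dir: Path | None = None):
    """Materialize an MLC bank (or None) from an mlc_spec string."""
    spec = str(spec).strip()
    if spec == "retracted":
        return None
    if spec.startswith("square:"):
        return MLCBank.square(float(spec.split(":", 1)[1]))
    if spec.startswith("template:"):
        from .campaign import template_bank
        parts = spec.split(":")
        name = parts[1]
        size = float(parts[2]) if len(parts) > 2 else min(jaw.width, jaw.height)
        return template_bank(name, size)
    from .io import read_field_file
    path = Path(spec)
    if base_dir is not None and not path.is_absolute():
        path = base_dir / path
    return read_field_file(path).bank


@dataclass
class MeasurementTable:
    """Campaign rows backed by a DataFrame, with optional in-memory fields.

    When built programmatically (e.g. by the synthetic campaign) the
    originating FieldSpec objects ride along so fitting does not have to
    re-materialize them from the spec strings.
    """

    frame: pd.DataFrame
    fields: list[FieldSpec] | None = None
    base_dir: Path | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.frame.columns]
        if missing:
            raise SchemaError(f"measurement table is missing columns: {missing}")
        for col in ("sc", "sd"):
            vals = pd.to_numeric(self.frame[col], errors="coerce")
            if vals.isna().any():
                raise SchemaError(f"non-numeric values in column '{col}'")
            self.frame[col] = vals

    def __len__(self) -> int:
        return len(self.frame)

    @classmethod
    def from_fields(cls, fields: list[FieldSpec], sc, sd,
                    mlc_specs: list[str] | None = None,
                    provenance: dict | None = None) -> "MeasurementTable":
        if mlc_specs is None:
            mlc_specs = ["retracted" if f.bank is None else "explicit" for f in fields]
        frame = pd.DataFrame({
            "field_id": [f.field_id for f in fields],
            "jaw_x1": [f.jaw.x1 for f in fields],
            "jaw_x2": [f.jaw.x2 for f in fields],
            "jaw_y1": [f.jaw.y1 for f in fields],
            "jaw_y2": [f.jaw.y2 for f in fields],
            "mlc_spec": mlc_specs,
            "sc": np.asarray(sc, float),
            "sd": np.asarray(sd, float),
        })
        return cls(frame=frame, fields=list(fields), provenance=provenance or {})

    def field_specs(self) -> list[FieldSpec]:
        if self.fields is not None:
            return self.fields
        out = []
        for _, row in self.frame.iterrows():
            jaw = JawSetting(row["jaw_x1"], row["jaw_x2"], row["jaw_y1"], row["jaw_y2"])
            bank = bank_from_spec(row["mlc_spec"], jaw, self.base_dir)
            out.append(FieldSpec(jaw=jaw, bank=bank, field_id=str(row["field_id"])))
        self.fields = out
        return out

    def to_csv(self, path, provenance: dict | None = None) -> None:
        path = Path(path)
        prov = dict(self.provenance)
        prov.update(provenance or {})
        with open(path, "w") as fh:
            for k, v in prov.items():
                fh.write(f"# {k}: {v}\n")
            self.frame.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path) -> "MeasurementTable":
        path = Path(path)
        prov = {}
        with open(path) as fh:
            for line in fh:
                if not line.startswith("#"):
                    break
                key, _, val = line[1:].strip().partition(":")
                prov[key.strip()] = val.strip()
        frame = pd.read_csv(path, comment="#")
        return cls(frame=frame, base_dir=path.parent, provenance=prov)
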