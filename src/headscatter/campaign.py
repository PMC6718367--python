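"""Synthetic measured-Sc campaign generator.

Reproduces the layout of a full modeling/evaluation measurement campaign so
the fitting and evaluation pipeline runs with no external data:

* jaw-only fields for the dual-source fit: squares 4x4 .. 40x40 in 1 cm
  steps plus rectangles with one jaw pair fixed at 4, 10 or 40 cm while the
  other sweeps 4 .. 40 cm;
* per-jaw MLC-square series for the MLC scatter fit: squares from 4x4 up to
  the jaw size, 1 cm steps, at fixed jaws 10/15/20/25/30 cm;
* irregular MLC shapes (cross, mirrored E, maze) at jaws 15/20/25 cm for
  evaluation.

Readings carry multiplicative Gaussian noise with a relative SD of 0.2% by
default, the repeat-reading spread quoted for miniphantom Sc campaigns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .aperture import JawSetting, MLCBank, millennium120_edges
from .dsm import DSMParams, FieldSpec
from .geometry import MachineGeometry
from .measurements import MeasurementTable
from .mlc_source import MLCSourceModel, sc_total

DEFAULT_NOISE_SD = 0.002  # relative; repeat readings spread within 0.2%


# ----------------------------------------------------------------------------
# Irregular leaf templates.  The evaluation shapes are published only as
# drawings, so these are declared approximations: parameterized leaf-position
# functions of the jaw size J, one open interval per leaf pair.

def _bank_from_bands(size: float, interval_of_y) -> MLCBank:
    edges = millennium120_edges()
    centers = 0.5 * (edges[:-1] + edges[1:])
    n = centers.size
    left = np.zeros(n)
    right = np.zeros(n)
    for i, y in enumerate(centers):
        iv = interval_of_y(y) if abs(y) < size / 2.0 else None
        if iv is not None:
            left[i], right[i] = iv
    return MLCBank(left=left, right=right, edges=edges)


def cross_bank(size: float) -> MLCBank:
    """Cross: full-width horizontal bar, one-third-width vertical bar."""
    def iv(y):
        if abs(y) <= size / 6.0:
            return (-size / 2.0, size / 2.0)
        return (-size / 6.0, size / 6.0)
    return _bank_from_bands(size, iv)


def mirrored_e_bank(size: float) -> MLCBank:
    """Opposed-E fingers: three full-width bars joined by a narrow central
    channel."""
    def iv(y):
        a = abs(y)
        if a <= size / 10.0 or a >= 3.0 * size / 10.0:
            return (-size / 2.0, size / 2.0)
        return (-size / 10.0, size / 10.0)
    return _bank_from_bands(size, iv)


def maze_bank(size: float) -> MLCBank:
    """Serpentine channel: alternating off-center corridors."""
    def iv(y):
        if y > size / 6.0:
            return (-size / 2.0, size / 8.0)
        if y < -size / 6.0:
            return (-size / 8.0, size / 2.0)
        return (-size / 2.0, size / 2.0)
    return _bank_from_bands(size, iv)


_TEMPLATES = {"cross": cross_bank, "mirrored_e": mirrored_e_bank, "maze": maze_bank}


def template_bank(name: str, size: float) -> MLCBank:
    try:
        builder = _TEMPLATES[name]
    except KeyError:
        raise ValueError(f"unknown irregular template '{name}'; "
                         f"choose from {sorted(_TEMPLATES)}") from None
    return builder(size)


# ----------------------------------------------------------------------------
# Design enumeration

@dataclass(frozen=True)
class CampaignDesign:
    """The measurement design: which fields the campaign contains."""

    jaw_square_sides: tuple = tuple(range(4, 41))
    jaw_fixed_pairs: tuple = (4, 10, 40)
    jaw_swept_sides: tuple = tuple(range(4, 41))
    mlc_series_jaws: tuple = (10, 15, 20, 25, 30)
    mlc_min_square: int = 4
    mlc_square_sides: tuple | None = None  # explicit override of the per-jaw sweep
    irregular_jaws: tuple = (15, 20, 25)
    irregular_shapes: tuple = ("cross", "mirrored_e", "maze")
    noise_sd: float = DEFAULT_NOISE_SD
    include_jaw_fields: bool = True
    include_mlc_squares: bool = True
    include_irregular: bool = True

    def __post_init__(self):
        if not (0.0 <= self.noise_sd <= 0.005):
            raise ValueError("noise_sd must lie in [0, 0.005]")


def build_design(design: CampaignDesign) -> tuple[list[FieldSpec], list[str]]:
    """Deterministic field enumeration; returns (fields, mlc_spec strings).

    The 10x10 jaw-only reference appears exactly once.  MLC squares are
    centered leaf patterns; an MLC square larger than its jaw is an error.
    """
    fields: list[FieldSpec] = []
    specs: list[str] = []
    seen_jaw: set[tuple[float, float]] = set()

    def add_jaw(w, h):
        key = (float(w), float(h))
        if key in seen_jaw:
            return
        seen_jaw.add(key)
        fields.append(FieldSpec(jaw=JawSetting.rectangle(w, h), bank=None,
                                field_id=f"jaw{w:g}x{h:g}_open"))
        specs.append("retracted")

    if design.include_jaw_fields:
        for s in design.jaw_square_sides:
            add_jaw(s, s)
        for fixed in design.jaw_fixed_pairs:
            for v in design.jaw_swept_sides:
                add_jaw(fixed, v)
                add_jaw(v, fixed)
    if design.include_mlc_squares:
        for j in design.mlc_series_jaws:
            sides = (design.mlc_square_sides if design.mlc_square_sides is not None
                     else range(design.mlc_min_square, j + 1))
            for s in sides:
                if s > j:
                    raise ValueError(f"MLC square {s} exceeds jaw {j}")
                fields.append(FieldSpec(jaw=JawSetting.square(j),
                                        bank=MLCBank.square(s),
                                        field_id=f"jaw{j:g}_mlc{s:02d}"))
                specs.append(f"square:{s}")
    if design.include_irregular:
        for j in design.irregular_jaws:
            for shape in design.irregular_shapes:
                fields.append(FieldSpec(jaw=JawSetting.square(j),
                                        bank=template_bank(shape, float(j)),
                                        field_id=f"jaw{j:g}_{shape}"))
                specs.append(f"template:{shape}:{j}")
    return fields, specs


def simulate_campaign(design: CampaignDesign, dsm_truth: DSMParams,
                      mlc_truth: MLCSourceModel, geom: MachineGeometry,
                      seed: int = 0, noise_sd: float | None = None) -> MeasurementTable:
    """Forward-model Sc for every design field and add reading noise.

    Noise is multiplicative Gaussian with relative SD ``noise_sd`` (default:
    the design's); the quoted SD column is noise_sd times the reported
    reading.  The same seed reproduces the table bit-for-bit.
    """
    noise_sd = design.noise_sd if noise_sd is None else noise_sd
    fields, specs = build_design(design)
    sc_true = np.array([sc_total(f, dsm_truth, mlc_truth, geom) for f in fields])
    rng = np.random.default_rng(seed)
    sc_read = sc_true * (1.0 + rng.normal(0.0, noise_sd, sc_true.size)) \
        if noise_sd > 0 else sc_true.copy()
    sd = noise_sd * sc_read
    prov = {"generator": "headscatter.campaign.simulate_campaign",
            "seed": seed, "noise_sd": noise_sd}
    return MeasurementTable.from_fields(fields, sc_read, sd, mlc_specs=specs,
                                        provenance=prov)
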