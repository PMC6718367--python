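"""Rectilinear aperture polygons from jaw + MLC settings, and their metrics.

The MLC scatter model needs, per field, the perimeter of the MLC-defined
aperture and the radiation-exposed leaf area at the mid-MLC plane, each split
by the scatter interface into an "in" and an "out" part.  This module builds
the aperture polygon (union of open leaf gaps clipped to the jaw rectangle),
computes those metrics with shapely, and classifies fields into the three
jaw/MLC configurations the model distinguishes:

1. leaves strictly retracted out of the jaw-defined beam's-eye view,
2. leaves inside the BEV but the aperture boundary outside the interface,
3. aperture boundary entering the interface (leaves clip the on-axis DEV).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely import affinity
from shapely.geometry import box as shapely_box
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from .geometry import MachineGeometry, Rect

GAP_TOL = 0.05  # closed-pair gap tolerance, cm at isocenter
_EPS = 1e-9


@dataclass(frozen=True)
class JawSetting:
    """Jaw positions at the isocenter plane (cm, signed)."""

    x1: float
    x2: float
    y1: float
    y2: float

    def __post_init__(self):
        if self.x1 > self.x2 or self.y1 > self.y2:
            raise ValueError("jaw setting requires x1 <= x2 and y1 <= y2")

    @classmethod
    def square(cls, side: float) -> "JawSetting":
        h = side / 2.0
        return cls(-h, h, -h, h)

    @classmethod
    def rectangle(cls, width: float, height: float) -> "JawSetting":
        return cls(-width / 2, width / 2, -height / 2, height / 2)

    @property
    def width(self) -> float:
        return self.x2 - self.x1

    @property
    def height(self) -> float:
        return self.y2 - self.y1

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def perimeter(self) -> float:
        return 2.0 * (self.width + self.height)

    @property
    def apratio(self) -> float:
        """Area-to-perimeter ratio (cm) at isocenter scale."""
        return self.area / self.perimeter

    def rect(self, plane_dist: float = 100.0, sad: float = 100.0) -> Rect:
        f = plane_dist / sad
        return Rect(self.x1 * f, self.x2 * f, self.y1 * f, self.y2 * f, plane_dist)


def millennium120_edges() -> np.ndarray:
    """Leaf-boundary y coordinates of a Millennium-120 bank at isocenter.

    60 pairs spanning y in [-20, 20]: 10 outer 1.0 cm pairs per side and 40
    central 0.5 cm pairs.
    """
    e = np.concatenate([
        np.arange(-20.0, -10.0, 1.0),
        np.arange(-10.0, 10.0, 0.5),
        np.arange(10.0, 20.0 + 0.5, 1.0),
    ])
    assert e.size == 61
    return e


@dataclass
class MLCBank:
    """Leaf-pair tip positions at the isocenter plane.

    ``left[i] <= right[i]`` are the x positions of the opposing tips of pair
    i, which spans y in [edges[i], edges[i+1]].  A pair with
    ``right - left <= gap_tol`` is closed and contributes no aperture.
    """

    left: np.ndarray
    right: np.ndarray
    edges: np.ndarray = field(default_factory=millennium120_edges)
    gap_tol: float = GAP_TOL

    def __post_init__(self):
        self.left = np.asarray(self.left, dtype=float)
        self.right = np.asarray(self.right, dtype=float)
        self.edges = np.asarray(self.edges, dtype=float)
        if self.edges.ndim != 1 or np.any(np.diff(self.edges) <= 0):
            raise ValueError("leaf edges must be strictly increasing")
        n = self.edges.size - 1
        if self.left.shape != (n,) or self.right.shape != (n,):
            raise ValueError(f"need {n} left/right tip positions")
        if np.any(self.left > self.right + _EPS):
            raise ValueError("leaf tips require left <= right")

    @property
    def n_pairs(self) -> int:
        return self.edges.size - 1

    def is_open(self) -> np.ndarray:
        return (self.right - self.left) > self.gap_tol

    @classmethod
    def retracted(cls, park: float = 20.0, edges: np.ndarray | None = None) -> "MLCBank":
        """All pairs withdrawn to +-``park`` cm."""
        edges = millennium120_edges() if edges is None else np.asarray(edges, float)
        n = edges.size - 1
        return cls(left=np.full(n, -park), right=np.full(n, park), edges=edges)

    @classmethod
    def square(cls, side: float, closed_at: float = 0.0,
               edges: np.ndarray | None = None) -> "MLCBank":
        """Centered square field of the given side (cm at isocenter).

        Pairs whose center lies inside the square's y extent open to
        +-side/2; all other pairs are closed (abutted at ``closed_at``).
        When the square edge falls between leaf boundaries the opened rows
        are the ones with majority overlap, as on a real bank.
        """
        if side <= 0:
            raise ValueError("side must be positive")
        edges = millennium120_edges() if edges is None else np.asarray(edges, float)
        centers = 0.5 * (edges[:-1] + edges[1:])
        n = edges.size - 1
        left = np.full(n, closed_at)
        right = np.full(n, closed_at)
        sel = np.abs(centers) < side / 2.0
        left[sel] = -side / 2.0
        right[sel] = side / 2.0
        return cls(left=left, right=right, edges=edges)


@dataclass(frozen=True)
class AperturePolygon:
    """Rectilinear (possibly multi-part or empty) aperture at a named plane."""

    geom: BaseGeometry
    plane_dist: float

    @property
    def area(self) -> float:
        return self.geom.area

    @property
    def perimeter(self) -> float:
        return self.geom.length

    @property
    def is_empty(self) -> bool:
        return self.geom.is_empty or self.geom.area <= 0

    def projected(self, d2: float) -> "AperturePolygon":
        f = d2 / self.plane_dist
        return AperturePolygon(affinity.scale(self.geom, f, f, origin=(0, 0)), d2)


def mlc_polygon(bank: MLCBank | None, jaw: JawSetting,
                plane_dist: float = 100.0, sad: float = 100.0) -> AperturePolygon:
    """Aperture polygon: open leaf gaps united, clipped to the jaw rectangle.

    Leaf/jaw positions are at isocenter scale; the result is projected to
    ``plane_dist``.  A bank of ``None`` means the MLC is out of the beam.
    Closed pairs are excluded, so their abutment line never contributes
    perimeter.  An empty aperture is returned as a zero-area polygon.
    """
    jaw_box = shapely_box(jaw.x1, jaw.y1, jaw.x2, jaw.y2)
    if bank is None:
        geom = jaw_box
    else:
        open_idx = np.nonzero(bank.is_open())[0]
        rects = [shapely_box(bank.left[i], bank.edges[i], bank.right[i], bank.edges[i + 1])
                 for i in open_idx]
        geom = unary_union(rects).intersection(jaw_box) if rects else shapely.Polygon()
    f = plane_dist / sad
    if f != 1.0:
        geom = affinity.scale(geom, f, f, origin=(0, 0))
    return AperturePolygon(geom, plane_dist)


def exposed_mlc_area(jaw: JawSetting, mlc_field: AperturePolygon,
                     plane_dist: float | None = None, sad: float = 100.0) -> float:
    """Radiation-exposed leaf area: jaw-defined minus MLC-defined field area.

    Evaluated at ``plane_dist`` (default: the plane of ``mlc_field``).  The
    MLC field must already be clipped to the jaw rectangle.
    """
    plane_dist = mlc_field.plane_dist if plane_dist is None else plane_dist
    f = plane_dist / sad
    jaw_area = jaw.area * f * f
    field_area = mlc_field.projected(plane_dist).area
    ma = jaw_area - field_area
    if ma < -1e-6 * max(jaw_area, 1.0):
        raise ValueError("MLC field exceeds the jaw rectangle; clip it first")
    return max(ma, 0.0)


@dataclass(frozen=True)
class RegionMetrics:
    """Perimeter/area split of one field by the scatter interface.

    All lengths/areas at the mid-MLC plane: fp_* perimeter of the MLC-defined
    field inside/outside the interface, ma_* exposed leaf area, rp the
    interface perimeter, ra_out the interface area and ra_in a fixed 3x3 cm^2
    (isocenter) reference projected to the plane.
    """

    fp_in: float
    fp_out: float
    ma_in: float
    ma_out: float
    rp: float
    ra_in: float
    ra_out: float
    plane_dist: float

    @property
    def fp(self) -> float:
        return self.fp_in + self.fp_out

    @property
    def ma(self) -> float:
        return self.ma_in + self.ma_out


RA_IN_ISO_AREA = 9.0  # 3 x 3 cm^2 at the isocenter


def split_by_interface(poly: AperturePolygon, jaw: JawSetting, interface: Rect,
                       geom: MachineGeometry | None = None) -> RegionMetrics:
    """Split perimeter and exposed area of ``poly`` by the interface rectangle.

    ``poly`` and ``interface`` must live in the same plane.  Boundary
    segments lying exactly on the interface edge count as "in" (ties broken
    inward, which a closed-set intersection gives for free).
    """
    if abs(poly.plane_dist - interface.plane_dist) > 1e-9:
        raise ValueError("aperture and interface are in different planes")
    sad = geom.sad if geom is not None else 100.0
    plane = poly.plane_dist
    ibox = shapely_box(interface.x_lo, interface.y_lo, interface.x_hi, interface.y_hi)

    boundary = poly.geom.boundary
    fp_in = boundary.intersection(ibox).length
    fp_out = boundary.difference(ibox).length

    jaw_box = shapely_box(*(v * plane / sad for v in (jaw.x1, jaw.y1, jaw.x2, jaw.y2)))
    exposed = jaw_box.difference(poly.geom)
    ma_in = exposed.intersection(ibox).area
    ma_out = exposed.difference(ibox).area

    ra_in = RA_IN_ISO_AREA * (plane / sad) ** 2
    return RegionMetrics(fp_in=fp_in, fp_out=fp_out, ma_in=ma_in, ma_out=ma_out,
                         rp=interface.perimeter, ra_in=ra_in, ra_out=interface.area,
                         plane_dist=plane)


def classify_category(jaw: JawSetting, bank: MLCBank | None, interface: Rect,
                      geom: MachineGeometry | None = None, tol: float = 1e-9) -> int:
    """Classify the jaw/MLC configuration (1, 2 or 3).

    Category 1 requires every leaf pair overlapping the open jaw y-range to
    be strictly retracted past both jaw x-edges (or no bank at all): a tip
    parked exactly at the jaw edge still presents its rounded end to the
    aperture and is treated as category 2.  Category 3 is any field whose
    aperture boundary reaches the scatter interface (fp_in > 0).
    """
    if bank is None:
        return 1
    overlaps = (np.minimum(bank.edges[1:], jaw.y2)
                - np.maximum(bank.edges[:-1], jaw.y1)) > tol
    clear = (bank.left < jaw.x1 - tol) & (bank.right > jaw.x2 + tol)
    if np.all(clear[overlaps]) if overlaps.any() else True:
        return 1
    sad = geom.sad if geom is not None else 100.0
    poly = mlc_polygon(bank, jaw, plane_dist=interface.plane_dist, sad=sad)
    metrics = split_by_interface(poly, jaw, interface, geom)
    return 3 if metrics.fp_in > tol else 2
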