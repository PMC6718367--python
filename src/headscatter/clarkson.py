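"""Clarkson sector integration of radial dosimetric tables for irregular fields.

Scatter-dependent factors (phantom scatter Sp, tissue-maximum ratio TMR) of
an irregular aperture are obtained by averaging their radial-table values
over angular sectors about the calculation point: for each sector (default
width 1 degree, 360 sectors) the distance from the point to the aperture
boundary along the sector's central ray picks the table entry, and the
factors enter a standard MU-style point dose

    dose = MU * k_cal * Sc * Sp * TMR.

Non-convex apertures are handled with the first boundary crossing per ray
only (primary-aperture Clarkson); re-entrant contributions beyond the first
crossing are ignored, a documented limitation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from shapely.geometry import LineString, Point

from .aperture import AperturePolygon


class TableRangeError(ValueError):
    """A requested radius or depth lies outside the tabulated range."""


@dataclass(frozen=True)
class RadialTable:
    """Sp(radius) and TMR(depth, radius) lookup with linear interpolation.

    Radii (and depths) must be strictly increasing; lookups outside the
    tabulated range raise ``TableRangeError`` rather than extrapolate.
    """

    sp_radii: np.ndarray
    sp_values: np.ndarray
    tmr_depths: np.ndarray | None = None
    tmr_radii: np.ndarray | None = None
    tmr_values: np.ndarray | None = None  # (n_depths, n_radii)

    def __post_init__(self):
        object.__setattr__(self, "sp_radii", np.asarray(self.sp_radii, float))
        object.__setattr__(self, "sp_values", np.asarray(self.sp_values, float))
        if np.any(np.diff(self.sp_radii) <= 0):
            raise ValueError("Sp radii must be strictly increasing")
        if self.tmr_values is not None:
            for name in ("tmr_depths", "tmr_radii", "tmr_values"):
                object.__setattr__(self, name, np.asarray(getattr(self, name), float))
            if np.any(np.diff(self.tmr_radii) <= 0) or np.any(np.diff(self.tmr_depths) <= 0):
                raise ValueError("TMR axes must be strictly increasing")

    def sp(self, radius) -> np.ndarray:
        r = np.asarray(radius, float)
        if np.any(r < self.sp_radii[0]) or np.any(r > self.sp_radii[-1]):
            raise TableRangeError("radius outside the Sp table range")
        return np.interp(r, self.sp_radii, self.sp_values)

    def tmr(self, depth: float, radius) -> np.ndarray:
        if self.tmr_values is None:
            raise ValueError("table carries no TMR grid")
        r = np.atleast_1d(np.asarray(radius, float))
        interp = RegularGridInterpolator((self.tmr_depths, self.tmr_radii),
                                         self.tmr_values, bounds_error=True)
        try:
            out = interp(np.column_stack([np.full(r.size, depth), r]))
        except ValueError as exc:
            raise TableRangeError(str(exc)) from None
        return out if np.ndim(radius) else float(out[0])

    @classmethod
    def from_csv(cls, sp_path, tmr_path=None) -> "RadialTable":
        """Sp CSV: columns radius_cm, sp.  TMR CSV (long format): columns
        depth_cm, radius_cm, tmr."""
        sp = pd.read_csv(sp_path, comment="#")
        kw = {"sp_radii": sp["radius_cm"].to_numpy(), "sp_values": sp["sp"].to_numpy()}
        if tmr_path is not None:
            tmr = pd.read_csv(tmr_path, comment="#")
            grid = tmr.pivot(index="depth_cm", columns="radius_cm", values="tmr")
            kw.update(tmr_depths=grid.index.to_numpy(),
                      tmr_radii=grid.columns.to_numpy(),
                      tmr_values=grid.to_numpy())
        return cls(**kw)


def synthetic_radial_table(r_max: float = 30.0, n_r: int = 121,
                           depths=(1.5, 5.0, 10.0, 15.0, 20.0)) -> RadialTable:
    """Smooth, monotone, physically plausible synthetic Sp/TMR tables.

    Shapes mimic a flattened 6 MV beam (Sp rising ~10% from small to large
    circles; TMR falling quasi-exponentially with depth, shallower for large
    radii).  Synthetic stand-ins for machine-measured tables: no claim of
    matching any particular beam.
    """
    r = np.linspace(0.25, r_max, n_r)
    sp = 0.92 + 0.16 * r / (r + 5.0)
    depths = np.asarray(depths, float)
    mu_eff = 0.060 - 0.012 * r / (r + 10.0)
    tmr = np.exp(-np.subtract.outer(depths, 1.5 * np.ones(n_r)).clip(0)
                 * mu_eff[None, :] / 1.0)
    return RadialTable(sp_radii=r, sp_values=sp, tmr_depths=depths,
                       tmr_radii=r, tmr_values=tmr)


def sector_radii(poly: AperturePolygon, point=(0.0, 0.0),
                 sector_deg: float = 1.0) -> np.ndarray:
    """Distance from ``point`` to the aperture boundary along each sector's
    central ray (first crossing).  ``point`` must lie strictly inside."""
    if sector_deg <= 0 or not float(360.0 / sector_deg).is_integer():
        raise ValueError("360 must be divisible by the sector width")
    g = poly.geom
    pt = Point(point)
    if not g.contains(pt) or g.boundary.distance(pt) < 1e-12:
        raise ValueError("calculation point must lie strictly inside the aperture")
    xmin, ymin, xmax, ymax = g.bounds
    reach = 2.0 * math.hypot(xmax - xmin, ymax - ymin) + 1.0
    n = int(round(360.0 / sector_deg))
    angles = (np.arange(n) + 0.5) * math.radians(sector_deg)
    radii = np.empty(n)
    px, py = point
    boundary = g.boundary
    for k, th in enumerate(angles):
        ray = LineString([(px, py), (px + reach * math.cos(th), py + reach * math.sin(th))])
        hit = ray.intersection(boundary)
        if hit.is_empty:
            raise ValueError("ray missed the aperture boundary (degenerate aperture)")
        pts = []
        for part in getattr(hit, "geoms", [hit]):
            pts.extend(part.coords)
        d = np.hypot(np.array([p[0] for p in pts]) - px,
                     np.array([p[1] for p in pts]) - py)
        radii[k] = d[d > 1e-12].min()
    return radii


def clarkson_value(radii: np.ndarray, table: RadialTable,
                   depth: float | None = None) -> float:
    """Sector average of the radial table: Sp if ``depth`` is None, else TMR."""
    radii = np.asarray(radii, float)
    vals = table.sp(radii) if depth is None else table.tmr(depth, radii)
    return float(np.mean(vals))


@dataclass(frozen=True)
class DoseContext:
    """mu: monitor units; k_cal: reference calibration (cGy/MU); depth in cm;
    calculation point at the isocenter plane."""

    mu: float
    k_cal: float
    depth: float
    point: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        if self.mu < 0 or self.k_cal <= 0:
            raise ValueError("require mu >= 0 and k_cal > 0")


def dose_at_point(ctx: DoseContext, sc: float, sp: float, tmr: float) -> float:
    """Factor-based MU formalism: dose = MU * k_cal * Sc * Sp * TMR (cGy)."""
    if min(sc, sp, tmr) <= 0:
        raise ValueError("all dosimetric factors must be positive")
    return ctx.mu * ctx.k_cal * sc * sp * tmr


def dose_for_field(fs, dsm_params, mlc_model, geom, table: RadialTable,
                   ctx: DoseContext, sector_deg: float = 1.0) -> dict:
    """Convenience pipeline: Sc (dual-source x MLC scatter) plus Clarkson Sp
    and TMR of the aperture, combined into a point dose."""
    from .aperture import mlc_polygon
    from .mlc_source import sc_breakdown

    bd = sc_breakdown(fs, dsm_params, mlc_model, geom)
    poly = mlc_polygon(fs.bank, fs.jaw, plane_dist=geom.sad, sad=geom.sad)
    radii = sector_radii(poly, ctx.point, sector_deg)
    sp = clarkson_value(radii, table)
    tmr = clarkson_value(radii, table, depth=ctx.depth)
    dose = dose_at_point(ctx, bd.sc, sp, tmr)
    return {"dose_cgy": dose, "sc": bd.sc, "sp": sp, "tmr": tmr,
            "category": bd.category, "sc_dsm": bd.sc_dsm, "sc_mlc": bd.sc_mlc}
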