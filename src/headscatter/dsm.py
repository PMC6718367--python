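"""Dual-source model (DSM) for the in-air output ratio Sc.

Two effective sources: the focal spot and an extra-focal, radially symmetric
Gaussian source at the flattening-filter plane.  For a collimator setting fs
measured by an on-axis detector,

    Sc_DSM(fs) = (1 + F_efs(fs)) (1 - F_mbs(fs))
                 / [(1 + F_efs(fs_ref)) (1 - F_mbs(fs_ref))],

where F_efs is the extra-focal scatter fraction -- the Gaussian source mass
visible through the detector's-eye view (DEV) back-projection of all
collimator openings -- and F_mbs the monitor-backscatter reduction, taken
linear in the jaw-blocked area.  fs_ref is the 10 x 10 cm^2 jaw field with
the MLC retracted.

Model parameters (Gaussian amplitude k_ff and width sigma_ff, backscatter
slope k_b) are free and are re-fit to each measured-Sc campaign of jaw-only
fields with a trust-region-reflective least-squares solver.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.special import ndtr
from shapely.geometry import Point, box as shapely_box

from .aperture import AperturePolygon, JawSetting, MLCBank, mlc_polygon
from .geometry import MachineGeometry

A_MAX = 1600.0  # largest jaw opening, 40 x 40 cm^2 at isocenter


@dataclass(frozen=True)
class DSMParams:
    """k_ff: extra-focal amplitude; sigma_ff: Gaussian width at the ff plane
    (cm); k_b: monitor-backscatter slope per cm^2 of blocked jaw area."""

    k_ff: float
    sigma_ff: float
    k_b: float

    def __post_init__(self):
        if self.k_ff < 0 or self.k_b < 0 or self.sigma_ff <= 0:
            raise ValueError("require k_ff >= 0, sigma_ff > 0, k_b >= 0")


@dataclass(frozen=True)
class FieldSpec:
    """A collimator setting: jaws plus an optional MLC bank (None = out of
    the beam).  The detector sits on the beam axis at SCD = SAD."""

    jaw: JawSetting
    bank: MLCBank | None = None
    field_id: str = ""

    @property
    def is_jaw_only(self) -> bool:
        return self.bank is None


def reference_field() -> FieldSpec:
    return FieldSpec(jaw=JawSetting.square(10.0), bank=None, field_id="reference")


def _dev_factor(geom: MachineGeometry, plane: float) -> float:
    """Back-projection magnification: an isocenter-scale edge of a collimator
    at ``plane``, seen from the on-axis detector at SAD, lands on the
    extra-focal plane scaled by this factor."""
    return (plane / geom.sad) * (geom.sad - geom.ff_dist) / (geom.sad - plane)


def dev_region(field: FieldSpec, geom: MachineGeometry) -> AperturePolygon:
    """Detector's-eye-view region on the extra-focal source plane.

    Each collimator opening (jaw rectangle; open leaf gaps if a bank is
    present) is back-projected from the on-axis detector point to the
    flattening-filter plane and the projections are intersected, then capped
    by the primary-collimator field of view.
    """
    gx = _dev_factor(geom, geom.scd_x)
    gy = _dev_factor(geom, geom.scd_y if geom.scd_y is not None else geom.scd_x)
    jaw = field.jaw
    region = shapely_box(jaw.x1 * gx, jaw.y1 * gy, jaw.x2 * gx, jaw.y2 * gy)
    if field.bank is not None:
        gm = _dev_factor(geom, geom.smd)
        gaps = mlc_polygon(field.bank, JawSetting(-1e3, 1e3, -1e3, 1e3),
                           plane_dist=100.0 * gm, sad=100.0)
        region = region.intersection(gaps.geom)
    if not region.is_empty and geom.cap_radius > 0:
        xmin, ymin, xmax, ymax = region.bounds
        corner = math.hypot(max(abs(xmin), abs(xmax)), max(abs(ymin), abs(ymax)))
        if corner > geom.cap_radius:  # cap only bites for very large openings
            cap = Point(0, 0).buffer(geom.cap_radius, quad_segs=64)
            region = region.intersection(cap)
    return AperturePolygon(region, geom.ff_dist)


def _is_rectilinear(geom) -> bool:
    polys = getattr(geom, "geoms", [geom])
    for p in polys:
        for ring in [p.exterior, *p.interiors]:
            c = np.asarray(ring.coords)
            dx, dy = np.diff(c[:, 0]), np.diff(c[:, 1])
            if np.any((np.abs(dx) > 1e-12) & (np.abs(dy) > 1e-12)):
                return False
    return True


def gaussian_mass(poly: AperturePolygon, sigma: float) -> float:
    """Mass of an axis-centered isotropic 2-D Gaussian N(0, sigma^2 I) over
    the region.

    Rectilinear regions are decomposed into y-strips of rectangles whose mass
    is an exact product of one-dimensional normal-CDF differences.  A region
    with oblique edges (possible only when the primary cap clips) is handled
    by the same strip sweep on a fine sub-grid.
    """
    g = poly.geom
    if g.is_empty or g.area == 0:
        return 0.0
    ys = np.unique([c[1] for part in getattr(g, "geoms", [g])
                    for ring in [part.exterior, *part.interiors]
                    for c in ring.coords])
    if not _is_rectilinear(g):
        fine = np.linspace(ys[0], ys[-1], max(2000, ys.size))
        ys = np.unique(np.concatenate([ys, fine]))
    xmin, _, xmax, _ = g.bounds
    total = 0.0
    for y0, y1 in zip(ys[:-1], ys[1:]):
        strip = g.intersection(shapely_box(xmin - 1.0, y0, xmax + 1.0, y1))
        if strip.is_empty:
            continue
        wy = ndtr(y1 / sigma) - ndtr(y0 / sigma)
        for part in getattr(strip, "geoms", [strip]):
            if part.area <= 0:
                continue
            x0, _, x1, _ = part.bounds
            total += (ndtr(x1 / sigma) - ndtr(x0 / sigma)) * wy
    return total


def f_efs(field: FieldSpec, params: DSMParams, geom: MachineGeometry) -> float:
    """Extra-focal scatter fraction: k_ff x Gaussian mass over the DEV."""
    return params.k_ff * gaussian_mass(dev_region(field, geom), params.sigma_ff)


def f_mbs(jaw: JawSetting, params: DSMParams) -> float:
    """Monitor-backscatter fraction, linear in the jaw-blocked area."""
    return min(max(params.k_b * (A_MAX - jaw.area), 0.0), 1.0 - 1e-12)


def sc_from_factors(fe: float, fm: float, fe_ref: float, fm_ref: float) -> float:
    return ((1.0 + fe) * (1.0 - fm)) / ((1.0 + fe_ref) * (1.0 - fm_ref))


def sc_dsm(field: FieldSpec, params: DSMParams, geom: MachineGeometry) -> float:
    """Dual-source-model Sc of a field, normalized to the reference field."""
    ref = reference_field()
    return sc_from_factors(f_efs(field, params, geom), f_mbs(field.jaw, params),
                           f_efs(ref, params, geom), f_mbs(ref.jaw, params))


# ----------------------------------------------------------------------------
# Fitting

@dataclass(frozen=True)
class DSMFitResult:
    params: DSMParams
    objective: float  # final chi-square
    nfev: int
    converged: bool
    message: str


class FitError(ValueError):
    pass


def _strip_rects(poly: AperturePolygon) -> np.ndarray:
    """(n, 4) rectangle decomposition [x0, x1, y0, y1] of a rectilinear region."""
    g = poly.geom
    if g.is_empty or g.area == 0:
        return np.zeros((0, 4))
    ys = np.unique([c[1] for part in getattr(g, "geoms", [g])
                    for c in part.exterior.coords])
    xmin, _, xmax, _ = g.bounds
    rects = []
    for y0, y1 in zip(ys[:-1], ys[1:]):
        strip = g.intersection(shapely_box(xmin - 1.0, y0, xmax + 1.0, y1))
        for part in getattr(strip, "geoms", [strip]):
            if getattr(part, "area", 0) > 0:
                x0, _, x1, _ = part.bounds
                rects.append((x0, x1, y0, y1))
    return np.asarray(rects)


def _masses(rect_sets: list[np.ndarray], idx: np.ndarray, sigma: float,
            n_fields: int) -> np.ndarray:
    """Gaussian masses per field from concatenated rectangle sets."""
    all_rects = np.concatenate([r for r in rect_sets if r.size], axis=0) \
        if any(r.size for r in rect_sets) else np.zeros((0, 4))
    out = np.zeros(n_fields)
    if all_rects.size:
        m = ((ndtr(all_rects[:, 1] / sigma) - ndtr(all_rects[:, 0] / sigma))
             * (ndtr(all_rects[:, 3] / sigma) - ndtr(all_rects[:, 2] / sigma)))
        np.add.at(out, idx, m)
    return out


def fit_dsm(measurements, geom: MachineGeometry,
            max_iter: int = 400, tol: float = 1e-6) -> DSMFitResult:
    """Fit (k_ff, sigma_ff, k_b) to a table of jaw-only Sc measurements.

    Minimizes the chi-square sum((Sc_calc - Sc_meas)/SD)^2 with the
    trust-region-reflective algorithm under the parameter bound constraints,
    capped at ``max_iter`` iterations.  ``converged`` reports whether the
    solver terminated on its tolerance criteria; the final objective is
    returned so a campaign-level threshold (e.g. chi-square < ``tol`` for a
    noise-free table) can be checked by the caller.

    ``measurements`` is a MeasurementTable; only rows with the MLC retracted
    (no bank) enter the fit, and the 10 x 10 reference must be present.
    """
    fields = measurements.field_specs()
    sc = measurements.frame["sc"].to_numpy(float)
    sd = measurements.frame["sd"].to_numpy(float)
    mask = np.array([f.is_jaw_only for f in fields])
    if mask.sum() < 3:
        raise FitError("need at least 3 jaw-only fields (MLC retracted) to fit the DSM")
    fields = [f for f, m in zip(fields, mask) if m]
    sc, sd = sc[mask], sd[mask]
    jaws = {(round(f.jaw.width, 6), round(f.jaw.height, 6)) for f in fields}
    if len(jaws) < 3:
        raise FitError("need at least 3 distinct jaw settings to identify 3 parameters")
    if (10.0, 10.0) not in jaws:
        raise FitError("reference jaw field 10 x 10 (MLC retracted) is required")
    w = np.where(sd > 0, sd, 1.0)

    rect_sets = [_strip_rects(dev_region(f, geom)) for f in fields]
    idx = np.concatenate([np.full(len(r), i) for i, r in enumerate(rect_sets) if r.size]) \
        if any(r.size for r in rect_sets) else np.zeros(0, int)
    ref_rects = [_strip_rects(dev_region(reference_field(), geom))]
    blocked = np.array([A_MAX - f.jaw.area for f in fields])
    blocked_ref = A_MAX - 100.0
    n = len(fields)

    def model(theta):
        k_ff, sigma, k_b = theta
        fe = k_ff * _masses(rect_sets, idx, sigma, n)
        fe_ref = k_ff * _masses(ref_rects, np.zeros(len(ref_rects[0]), int), sigma, 1)[0]
        fm = np.clip(k_b * blocked, 0.0, 1.0 - 1e-12)
        fm_ref = min(k_b * blocked_ref, 1.0 - 1e-12)
        return ((1.0 + fe) * (1.0 - fm)) / ((1.0 + fe_ref) * (1.0 - fm_ref))

    def residuals(theta):
        return (model(theta) - sc) / w

    x0 = np.array([0.03, 1.0, 5e-6])
    bounds = (np.array([0.0, 0.05, 0.0]), np.array([1.0, 10.0, 1e-3]))
    res = least_squares(residuals, x0, bounds=bounds, method="trf",
                        x_scale=np.array([0.05, 1.0, 1e-5]),
                        ftol=1e-14, xtol=1e-14, gtol=1e-14,
                        max_nfev=max_iter * (len(x0) + 1))
    chi2 = float(2.0 * res.cost)
    params = DSMParams(*res.x)
    # solver tolerance termination, or the campaign-level objective threshold
    converged = bool(res.status > 0) or chi2 < tol
    if not converged:
        res.message += " (iteration cap reached; fit not converged)"
    return DSMFitResult(params=params, objective=chi2, nfev=res.nfev,
                        converged=converged, message=res.message)
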