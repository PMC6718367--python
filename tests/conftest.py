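"""Shared fixtures and independent oracles for the test suite.

The oracles here deliberately avoid the library's own computational paths:
area by the shoelace formula on ring coordinates, perimeter by summed edge
lengths, Gaussian mass by dense midpoint rasterization, and the
interface split by per-segment clipping against the rectangle's edge lines.
"""

from __future__ import annotations

import numpy as np
import pytest
import shapely
from shapely.geometry import box as shapely_box
from shapely.ops import unary_union

from headscatter import MachineGeometry, AperturePolygon, JawSetting, MLCBank
from headscatter import defaults


@pytest.fixture(scope="session")
def geom() -> MachineGeometry:
    return MachineGeometry()


@pytest.fixture(scope="session")
def dsm_truth():
    return defaults.plausible_dsm_params()


@pytest.fixture(scope="session")
def mlc_truth():
    return defaults.published_source_model()


# ----------------------------------------------------------------------------
# Random rectilinear apertures (leaf-gap style: one x-interval per row)

def random_aperture(rng: np.random.Generator, lattice: float = 0.0,
                    plane_dist: float = 51.0, y0_range=(-8.0, -4.0)):
    """Random rectilinear polygon built like an MLC aperture: contiguous rows
    of x-intervals, united.  With ``lattice`` > 0 all coordinates snap to
    that grid (useful for exact rasterization oracles)."""
    n_rows = rng.integers(3, 12)
    y0 = rng.uniform(*y0_range)
    heights = rng.uniform(0.4, 1.5, n_rows)
    heights *= min(1.0, 12.0 / heights.sum())  # keep |y| <= 8
    rects = []
    y = y0
    for h in heights:
        cx = rng.uniform(-4.0, 4.0)
        w = rng.uniform(1.0, 8.0)
        lo, hi, yy0, yy1 = cx - w / 2, cx + w / 2, y, y + h
        if lattice > 0:
            lo, hi = np.round(lo / lattice) * lattice, np.round(hi / lattice) * lattice
            yy0, yy1 = np.round(yy0 / lattice) * lattice, np.round(yy1 / lattice) * lattice
        if hi > lo and yy1 > yy0:
            rects.append(shapely_box(lo, yy0, hi, yy1))
        y += h
    g = unary_union(rects)
    if g.is_empty:
        g = shapely_box(-1, -1, 1, 1)
    return AperturePolygon(g, plane_dist)


def random_field(rng: np.random.Generator):
    """Random jaw + MLC-square field within the modeled range."""
    jaw = int(rng.integers(8, 31))
    s = int(rng.integers(4, jaw + 1))
    from headscatter import FieldSpec
    return FieldSpec(jaw=JawSetting.square(jaw), bank=MLCBank.square(s),
                     field_id=f"rand_j{jaw}_s{s}")


# ----------------------------------------------------------------------------
# Oracles

def _rings(g):
    for part in getattr(g, "geoms", [g]):
        yield part.exterior
        yield from part.interiors


def shoelace_area(g) -> float:
    total = 0.0
    for part in getattr(g, "geoms", [g]):
        for ring, sign in [(part.exterior, 1.0), *[(r, -1.0) for r in part.interiors]]:
            c = np.asarray(ring.coords)
            x, y = c[:, 0], c[:, 1]
            total += sign * 0.5 * abs(np.sum(x[:-1] * y[1:] - x[1:] * y[:-1]))
    return total


def edge_sum_perimeter(g) -> float:
    total = 0.0
    for ring in _rings(g):
        c = np.asarray(ring.coords)
        total += np.sum(np.hypot(np.diff(c[:, 0]), np.diff(c[:, 1])))
    return float(total)


def segment_clip_fp_split(g, rect) -> tuple[float, float]:
    """Perimeter split by a rectangle via per-segment subdivision at edge-line
    crossings; a sub-segment whose midpoint lies in the closed rectangle
    counts as 'in' (ties inward)."""
    eps = 1e-12
    fp_in = fp_out = 0.0
    for ring in _rings(g):
        c = np.asarray(ring.coords)
        for (x0, y0), (x1, y1) in zip(c[:-1], c[1:]):
            ts = {0.0, 1.0}
            if x1 != x0:
                for xc in (rect.x_lo, rect.x_hi):
                    t = (xc - x0) / (x1 - x0)
                    if 0.0 < t < 1.0:
                        ts.add(t)
            if y1 != y0:
                for yc in (rect.y_lo, rect.y_hi):
                    t = (yc - y0) / (y1 - y0)
                    if 0.0 < t < 1.0:
                        ts.add(t)
            ts = sorted(ts)
            seg_len = np.hypot(x1 - x0, y1 - y0)
            for a, b in zip(ts[:-1], ts[1:]):
                mx, my = x0 + (x1 - x0) * (a + b) / 2, y0 + (y1 - y0) * (a + b) / 2
                piece = seg_len * (b - a)
                inside = (rect.x_lo - eps <= mx <= rect.x_hi + eps
                          and rect.y_lo - eps <= my <= rect.y_hi + eps)
                if inside:
                    fp_in += piece
                else:
                    fp_out += piece
    return fp_in, fp_out


def grid_gaussian_mass(g, sigma: float, h: float = 0.025) -> float:
    """Dense midpoint rasterization of the N(0, sigma^2 I) mass over ``g``.

    Exact cell classification requires the polygon's edges to lie on
    multiples of 2h (use lattice-snapped apertures)."""
    xmin, ymin, xmax, ymax = g.bounds
    lim = 8.0 * sigma
    xmin, xmax = max(xmin, -lim), min(xmax, lim)
    ymin, ymax = max(ymin, -lim), min(ymax, lim)
    if xmin >= xmax or ymin >= ymax:
        return 0.0
    xs = np.arange(xmin + h / 2, xmax, h)
    ys = np.arange(ymin + h / 2, ymax, h)
    xx, yy = np.meshgrid(xs, ys)
    inside = shapely.contains_xy(g, xx.ravel(), yy.ravel())
    pdf = np.exp(-(xx.ravel() ** 2 + yy.ravel() ** 2) / (2 * sigma * sigma))
    return float(np.sum(pdf[inside]) * h * h / (2 * np.pi * sigma * sigma))
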