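"""The MLC scatter source: line- and area-based components of Sc_MLC.

The multiplicative correction to the dual-source Sc for leaf scatter is

    Sc = Sc_DSM * Sc_MLC,        Sc_MLC = Sc_line * Sc_area,

with, per region (out = between interface and jaw edge, in = inside the
scatter interface),

    ES_line = a (FP^b - RP^b) + 1        (leaf rounded-edge scatter)
    ES_area = exp(-(MA - RA) / (2 sigma^2))   (exposed leaf-face scatter)

and the general irregular-field combination

    Sc_MLC = ES_line,out(FP_out) * ES_line,in(FP_in)
             * ES_area,out(MA_out - RA_out) * ES_area,in(MA_in - RA_in).

FP/MA are the aperture perimeter and exposed leaf area at the mid-MLC plane
split by the scatter interface; RP is the interface perimeter (one reference
for both line factors); RA_out the interface area and RA_in 3 x 3 cm^2 at
isocenter projected to the mid-MLC plane.  Category-1 fields (leaves
retracted out of the jaw BEV) short-circuit to Sc_MLC = 1.

The six parameters (a, b, sigma per region) depend on the jaw setting and are
fit per jaw, then interpolated across jaw settings as quadratics in the jaw
field's area-to-perimeter (AP) ratio; sigma is interpolated on a log scale
because its fitted values span more than an order of magnitude and a
linear-space quadratic through them goes negative inside the fitted range.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from .aperture import (JawSetting, RegionMetrics, classify_category, mlc_polygon,
                       split_by_interface)
from .dsm import DSMParams, FieldSpec, FitError, sc_dsm
from .geometry import MachineGeometry, scatter_interface


class ModelValidityError(ValueError):
    """An AP-ratio parameter function produced a non-positive b or sigma."""


@dataclass(frozen=True)
class MLCScatterParams:
    """Per-jaw-setting parameters: (a, b, sigma) for the out and in regions."""

    a_out: float
    b_out: float
    sigma_out: float
    a_in: float
    b_in: float
    sigma_in: float

    PARAM_NAMES = ("a_out", "b_out", "sigma_out", "a_in", "b_in", "sigma_in")

    def __post_init__(self):
        if self.a_out < 0 or self.a_in < 0:
            raise ValueError("amplitudes a_* must be non-negative")
        if self.b_out <= 0 or self.b_in <= 0 or self.sigma_out <= 0 or self.sigma_in <= 0:
            raise ValueError("exponents b_* and widths sigma_* must be positive")

    @property
    def out_triple(self) -> tuple[float, float, float]:
        return (self.a_out, self.b_out, self.sigma_out)

    @property
    def in_triple(self) -> tuple[float, float, float]:
        return (self.a_in, self.b_in, self.sigma_in)

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in self.PARAM_NAMES])


def es_line(fp: float, rp: float, a: float, b: float) -> float:
    """Line-source factor a(FP^b - RP^b) + 1; FP = 0 contributes 0^b = 0."""
    if fp < 0 or rp < 0:
        raise ValueError("perimeters must be non-negative")
    fpb = fp ** b if fp > 0 else 0.0
    rpb = rp ** b if rp > 0 else 0.0
    return a * (fpb - rpb) + 1.0


def es_area(ma_minus_ra: float, sigma: float) -> float:
    """Area-source factor exp(-(MA - RA)/(2 sigma^2)); exceeds 1 when MA < RA."""
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    return float(np.exp(-ma_minus_ra / (2.0 * sigma * sigma)))


# ----------------------------------------------------------------------------
# AP-ratio parameter functions

@dataclass(frozen=True)
class QuadCoeff:
    """Quadratic c2*x^2 + c1*x + c0 in the AP ratio; with ``scale='log'`` the
    quadratic models ln(parameter)."""

    c2: float
    c1: float
    c0: float
    scale: str = "linear"

    def __call__(self, x: float) -> float:
        v = self.c2 * x * x + self.c1 * x + self.c0
        return float(np.exp(v)) if self.scale == "log" else float(v)


APRATIO_FITTED_RANGE = (2.5, 7.5)  # AP ratios of 10x10 .. 30x30 jaw squares


@dataclass(frozen=True)
class APRatioModel:
    """Parameter functions of the jaw field's area-to-perimeter ratio."""

    coeffs: dict[str, QuadCoeff]
    fitted_range: tuple[float, float] = APRATIO_FITTED_RANGE

    def __post_init__(self):
        missing = set(MLCScatterParams.PARAM_NAMES) - set(self.coeffs)
        if missing:
            raise ValueError(f"missing coefficient blocks: {sorted(missing)}")

    def evaluate(self, apratio: float) -> MLCScatterParams:
        if apratio <= 0:
            raise ValueError("AP ratio must be positive")
        lo, hi = self.fitted_range
        if not (lo <= apratio <= hi):
            warnings.warn(
                f"AP ratio {apratio:.3g} outside the fitted range [{lo}, {hi}]; "
                "parameters are extrapolated", stacklevel=2)
        vals = {k: self.coeffs[k](apratio) for k in MLCScatterParams.PARAM_NAMES}
        bad = [k for k in ("b_out", "b_in", "sigma_out", "sigma_in") if vals[k] <= 0]
        if bad:
            raise ModelValidityError(
                f"AP-ratio model yields non-positive {bad} at AP ratio {apratio:.3g}")
        return MLCScatterParams(**vals)


def params_from_apratio(apratio: float, region: str,
                        model: APRatioModel) -> tuple[float, float, float]:
    """(a, b, sigma) of one region ('in'/'out') at the given AP ratio."""
    if region not in ("in", "out"):
        raise ValueError("region must be 'in' or 'out'")
    p = model.evaluate(apratio)
    return p.out_triple if region == "out" else p.in_triple


# ----------------------------------------------------------------------------
# Sc_MLC and total Sc

@dataclass(frozen=True)
class ScatterComponents:
    sc_line: float
    sc_area: float

    @property
    def sc_mlc(self) -> float:
        return self.sc_line * self.sc_area


def sc_mlc(metrics: RegionMetrics, params_out: tuple[float, float, float],
           params_in: tuple[float, float, float], category: int | None = None,
           zero_fp_identity: bool = False) -> ScatterComponents:
    """Combine region metrics and (a, b, sigma) triples into Sc_MLC.

    ``category=1`` short-circuits to exactly 1.  ``zero_fp_identity`` forces
    a region's line factor to 1 when that region holds no perimeter, instead
    of the as-printed value a(0 - RP^b) + 1.
    """
    if category == 1:
        return ScatterComponents(1.0, 1.0)
    a_o, b_o, s_o = params_out
    a_i, b_i, s_i = params_in
    if zero_fp_identity and metrics.fp_out == 0:
        line_out = 1.0
    else:
        line_out = es_line(metrics.fp_out, metrics.rp, a_o, b_o)
    if zero_fp_identity and metrics.fp_in == 0:
        line_in = 1.0
    else:
        line_in = es_line(metrics.fp_in, metrics.rp, a_i, b_i)
    area_out = es_area(metrics.ma_out - metrics.ra_out, s_o)
    area_in = es_area(metrics.ma_in - metrics.ra_in, s_i)
    return ScatterComponents(line_out * line_in, area_out * area_in)


@dataclass(frozen=True)
class MLCSourceModel:
    """Resolvable MLC-scatter parameter set.

    Per-jaw fitted parameters (keyed by jaw width x height at isocenter) take
    precedence; the AP-ratio model is the interpolation fallback for unseen
    jaw settings.
    """

    per_jaw: dict[tuple[float, float], MLCScatterParams] = field(default_factory=dict)
    apratio_model: APRatioModel | None = None
    provenance: str = "fitted"
    zero_fp_identity: bool = False

    def resolve(self, jaw: JawSetting) -> MLCScatterParams:
        key = (round(jaw.width, 6), round(jaw.height, 6))
        if key in self.per_jaw:
            return self.per_jaw[key]
        if self.apratio_model is not None:
            return self.apratio_model.evaluate(jaw.apratio)
        raise KeyError(f"no MLC scatter parameters for jaw {key} and no AP-ratio model")


@dataclass(frozen=True)
class ScBreakdown:
    sc: float
    sc_dsm: float
    sc_line: float
    sc_area: float
    category: int

    @property
    def sc_mlc(self) -> float:
        return self.sc_line * self.sc_area


def field_metrics(fs: FieldSpec, geom: MachineGeometry) -> tuple[RegionMetrics, int]:
    """Region metrics at the mid-MLC plane and the field's category."""
    interface = scatter_interface(geom, fs.jaw.rect(geom.sad, geom.sad))
    category = classify_category(fs.jaw, fs.bank, interface, geom)
    poly = mlc_polygon(fs.bank, fs.jaw, plane_dist=geom.smd, sad=geom.sad)
    metrics = split_by_interface(poly, fs.jaw, interface, geom)
    return metrics, category


def sc_breakdown(fs: FieldSpec, dsm_params: DSMParams, mlc_model: MLCSourceModel,
                 geom: MachineGeometry) -> ScBreakdown:
    """Total Sc with its factors: Sc = Sc_DSM x Sc_line x Sc_area."""
    s_dsm = sc_dsm(fs, dsm_params, geom)
    metrics, category = field_metrics(fs, geom)
    if category == 1:
        comp = ScatterComponents(1.0, 1.0)
    else:
        p = mlc_model.resolve(fs.jaw)
        comp = sc_mlc(metrics, p.out_triple, p.in_triple, category=category,
                      zero_fp_identity=mlc_model.zero_fp_identity)
    return ScBreakdown(sc=s_dsm * comp.sc_mlc, sc_dsm=s_dsm,
                       sc_line=comp.sc_line, sc_area=comp.sc_area, category=category)


def sc_total(fs: FieldSpec, dsm_params: DSMParams, mlc_model: MLCSourceModel,
             geom: MachineGeometry) -> float:
    return sc_breakdown(fs, dsm_params, mlc_model, geom).sc


# ----------------------------------------------------------------------------
# Fitting

@dataclass(frozen=True)
class JawFit:
    params: MLCScatterParams
    apratio: float
    objective: float
    nfev: int
    converged: bool
    n_points: int


@dataclass(frozen=True)
class MLCFitResult:
    model: MLCSourceModel
    per_jaw_fits: dict[tuple[float, float], JawFit]

    @property
    def converged(self) -> bool:
        return all(f.converged for f in self.per_jaw_fits.values())


def _residual_pieces(metrics_list: list[RegionMetrics]):
    fo = np.array([m.fp_out for m in metrics_list])
    fi = np.array([m.fp_in for m in metrics_list])
    rp = np.array([m.rp for m in metrics_list])
    xo = np.array([m.ma_out - m.ra_out for m in metrics_list])
    xi = np.array([m.ma_in - m.ra_in for m in metrics_list])
    return fo, fi, rp, xo, xi


def _powb(base: np.ndarray, b: float) -> tuple[np.ndarray, np.ndarray]:
    """base**b and its derivative w.r.t. b, with 0**b = 0."""
    pos = base > 0
    p = np.zeros_like(base)
    dp = np.zeros_like(base)
    p[pos] = base[pos] ** b
    dp[pos] = p[pos] * np.log(base[pos])
    return p, dp


def _fit_one_jaw(metrics_list, y, w, max_iter, starts):
    """Fit the six (a, b, ln sigma) parameters of one jaw setting.

    Internal parameterization uses ln sigma for conditioning; the analytic
    Jacobian keeps the noise-free recovery sharp.
    """
    fo, fi, rp, xo, xi = _residual_pieces(metrics_list)

    def unpack(theta):
        a_o, b_o, ls_o, a_i, b_i, ls_i = theta
        return a_o, b_o, np.exp(ls_o), a_i, b_i, np.exp(ls_i)

    def factors(theta):
        a_o, b_o, s_o, a_i, b_i, s_i = unpack(theta)
        fob, _ = _powb(fo, b_o)
        rpob, _ = _powb(rp, b_o)
        fib, _ = _powb(fi, b_i)
        rpib, _ = _powb(rp, b_i)
        Lo = a_o * (fob - rpob) + 1.0
        Li = a_i * (fib - rpib) + 1.0
        Ao = np.exp(-xo / (2.0 * s_o * s_o))
        Ai = np.exp(-xi / (2.0 * s_i * s_i))
        return Lo, Li, Ao, Ai

    def residuals(theta):
        Lo, Li, Ao, Ai = factors(theta)
        return (Lo * Li * Ao * Ai - y) / w

    def jac(theta):
        a_o, b_o, s_o, a_i, b_i, s_i = unpack(theta)
        fob, dfob = _powb(fo, b_o)
        rpob, drpob = _powb(rp, b_o)
        fib, dfib = _powb(fi, b_i)
        rpib, drpib = _powb(rp, b_i)
        Lo = a_o * (fob - rpob) + 1.0
        Li = a_i * (fib - rpib) + 1.0
        Ao = np.exp(-xo / (2.0 * s_o * s_o))
        Ai = np.exp(-xi / (2.0 * s_i * s_i))
        m = Lo * Li * Ao * Ai
        J = np.empty((y.size, 6))
        J[:, 0] = (fob - rpob) * Li * Ao * Ai
        J[:, 1] = a_o * (dfob - drpob) * Li * Ao * Ai
        J[:, 2] = m * (xo / (s_o * s_o))          # d/d(ln sigma_o)
        J[:, 3] = Lo * (fib - rpib) * Ao * Ai
        J[:, 4] = Lo * a_i * (dfib - drpib) * Ao * Ai
        J[:, 5] = m * (xi / (s_i * s_i))
        return J / w[:, None]

    lb = np.array([0.0, 0.05, np.log(0.5), 0.0, 0.05, np.log(0.5)])
    ub = np.array([0.5, 3.0, np.log(5000.0), 0.5, 3.0, np.log(5000.0)])
    best = None
    for x0 in starts:
        res = least_squares(residuals, x0, jac=jac, bounds=(lb, ub), method="trf",
                            ftol=1e-15, xtol=1e-15, gtol=1e-15,
                            max_nfev=max_iter * 7)
        if best is None or res.cost < best.cost:
            best = res
    a_o, b_o, s_o, a_i, b_i, s_i = unpack(best.x)
    params = MLCScatterParams(a_o, b_o, s_o, a_i, b_i, s_i)
    return params, float(2.0 * best.cost), int(best.nfev), bool(best.status > 0)


_DEFAULT_STARTS = (
    np.array([0.015, 0.8, np.log(50.0), 0.010, 0.5, np.log(50.0)]),
    np.array([0.015, 0.8, np.log(400.0), 0.008, 0.4, np.log(400.0)]),
    np.array([0.030, 1.2, np.log(20.0), 0.020, 0.8, np.log(20.0)]),
)


def fit_mlc_params(measurements, dsm_params: DSMParams, geom: MachineGeometry,
                   max_iter: int = 400) -> MLCFitResult:
    """Two-stage fit of the MLC scatter source to a measured-Sc campaign.

    Stage 1: per jaw setting, fit (a, b, sigma) for the out and in regions to
    the residual ratio Sc_meas / Sc_DSM over that jaw's MLC-defined fields
    (chi-square objective, trust-region-reflective, iteration cap).  Each jaw
    series must contain both category-2 and category-3 fields.

    Stage 2: quadratics in the jaw AP ratio through the per-jaw parameters
    (log scale for sigma) give the interpolating AP-ratio model; it needs at
    least three jaw settings and is omitted otherwise.
    """
    fields = measurements.field_specs()
    sc = measurements.frame["sc"].to_numpy(float)
    sd = measurements.frame["sd"].to_numpy(float)

    groups: dict[tuple[float, float], list[int]] = {}
    cats: dict[int, int] = {}
    metrics_cache: dict[int, RegionMetrics] = {}
    for i, f in enumerate(fields):
        if f.bank is None:
            continue
        metrics, cat = field_metrics(f, geom)
        if cat == 1:
            continue
        cats[i] = cat
        metrics_cache[i] = metrics
        key = (round(f.jaw.width, 6), round(f.jaw.height, 6))
        groups.setdefault(key, []).append(i)
    if not groups:
        raise FitError("campaign contains no MLC-defined category-2/3 fields to fit")

    per_jaw: dict[tuple[float, float], JawFit] = {}
    for key, idxs in sorted(groups.items()):
        got = {cats[i] for i in idxs}
        if got != {2, 3}:
            raise FitError(
                f"jaw {key[0]:g} x {key[1]:g}: MLC series must span categories 2 and 3, "
                f"found only {sorted(got)}")
        y = np.array([sc[i] / sc_dsm(fields[i], dsm_params, geom) for i in idxs])
        w = np.array([sd[i] if sd[i] > 0 else 1.0 for i in idxs])
        mets = [metrics_cache[i] for i in idxs]
        params, obj, nfev, conv = _fit_one_jaw(mets, y, w, max_iter, _DEFAULT_STARTS)
        apr = fields[idxs[0]].jaw.apratio
        per_jaw[key] = JawFit(params=params, apratio=apr, objective=obj,
                              nfev=nfev, converged=conv, n_points=len(idxs))

    ap_model = None
    if len(per_jaw) >= 3:
        x = np.array([f.apratio for f in per_jaw.values()])
        coeffs = {}
        for k in MLCScatterParams.PARAM_NAMES:
            v = np.array([getattr(f.params, k) for f in per_jaw.values()])
            if k.startswith("sigma"):
                c = np.polyfit(x, np.log(v), 2)
                coeffs[k] = QuadCoeff(c[0], c[1], c[2], scale="log")
            else:
                c = np.polyfit(x, v, 2)
                coeffs[k] = QuadCoeff(c[0], c[1], c[2])
        ap_model = APRatioModel(coeffs, fitted_range=(float(x.min()), float(x.max())))

    model = MLCSourceModel(per_jaw={k: f.params for k, f in per_jaw.items()},
                           apratio_model=ap_model, provenance="fitted")
    return MLCFitResult(model=model, per_jaw_fits=per_jaw)
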