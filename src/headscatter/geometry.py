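"""Machine geometry, plane-to-plane projection and the scatter interface.

All transverse coordinates are beam-axis-centered centimeters: x cross-plane,
y in-plane.  Apertures are specified at the isocenter plane and projected to
other planes by similar-triangle magnification from the focal source.

The *scatter interface* is the rectangle at the mid-MLC plane obtained by
scaling the jaw-projected field by the coefficient

    alpha = SCD_x * (SAD - SMD) / (SMD * (SAD - SCD_x)),

where SCD_x is the source-to-X-jaw distance, SMD the source-to-mid-MLC
distance and SAD the source-to-axis distance.  Geometrically it is the
boundary of the jaw-defined detector's-eye view (DEV) at the mid-MLC plane:
leaves whose field edge lies inside it clip the on-axis DEV, leaves outside
it only add scatter.
"""

from __future__ import annotations

from dataclasses import dataclass, replace


def project(value, d1: float, d2: float):
    """Scale a transverse length/coordinate from plane ``d1`` to plane ``d2``.

    Both distances are measured from the focal source along the beam axis and
    must be positive.  Works on scalars and numpy arrays.
    """
    if d1 <= 0 or d2 <= 0:
        raise ValueError(f"plane distances must be positive, got {d1}, {d2}")
    return value * (d2 / d1)


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle in a named transverse plane."""

    x_lo: float
    x_hi: float
    y_lo: float
    y_hi: float
    plane_dist: float

    def __post_init__(self):
        if self.x_lo > self.x_hi or self.y_lo > self.y_hi:
            raise ValueError("degenerate rectangle: lo > hi")
        if self.plane_dist <= 0:
            raise ValueError("plane_dist must be positive")

    @property
    def width(self) -> float:
        return self.x_hi - self.x_lo

    @property
    def height(self) -> float:
        return self.y_hi - self.y_lo

    @property
    def area(self) -> float:
        return self.width * self.height

    @property
    def perimeter(self) -> float:
        return 2.0 * (self.width + self.height)

    def projected(self, d2: float) -> "Rect":
        f = d2 / self.plane_dist
        if d2 <= 0:
            raise ValueError("plane_dist must be positive")
        return Rect(self.x_lo * f, self.x_hi * f, self.y_lo * f, self.y_hi * f, d2)

    def scaled(self, fx: float, fy: float | None = None) -> "Rect":
        """Scale about the beam axis (origin), keeping the plane."""
        fy = fx if fy is None else fy
        return replace(self, x_lo=self.x_lo * fx, x_hi=self.x_hi * fx,
                       y_lo=self.y_lo * fy, y_hi=self.y_hi * fy)

    def contains(self, other: "Rect", tol: float = 1e-12) -> bool:
        return (self.x_lo - tol <= other.x_lo and other.x_hi <= self.x_hi + tol
                and self.y_lo - tol <= other.y_lo and other.y_hi <= self.y_hi + tol)


def alpha_from_scd(scd: float, smd: float, sad: float) -> float:
    """Scatter-interface coefficient alpha for a jaw plane at distance ``scd``."""
    if not (0 < scd < smd < sad):
        raise ValueError("require 0 < SCD < SMD < SAD")
    return scd * (sad - smd) / (smd * (sad - scd))


def scd_from_alpha(alpha: float, smd: float, sad: float) -> float:
    """Invert the alpha relation for the jaw distance SCD.

    alpha = SCD(SAD-SMD)/(SMD(SAD-SCD))  =>  SCD = alpha*SMD*SAD/(SAD-SMD+alpha*SMD)
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    scd = alpha * smd * sad / (sad - smd + alpha * smd)
    if not (0 < scd < smd):
        raise ValueError(f"alpha={alpha} implies SCD={scd:.3f}, outside (0, SMD)")
    return scd


# Defaults: SAD and SMD are standard Varian-type values; alpha = 0.577 fixes
# SCD_x because the jaw distance itself is a machine constant that is rarely
# quoted, while alpha is the quantity the interface construction needs.
DEFAULT_SAD = 100.0
DEFAULT_SMD = 51.0
DEFAULT_ALPHA = 0.577
DEFAULT_FF_DIST = 12.5  # flattening-filter (extra-focal) source plane
DEFAULT_CAP_RADIUS = 20.0  # primary-collimator field of view at the ff plane


@dataclass(frozen=True)
class MachineGeometry:
    """Axial distances (cm from the focal source) of the collimating stack.

    Exactly one of ``scd_x``/``alpha`` is needed to place the X jaw; the
    default machine derives ``scd_x`` from alpha = 0.577.  ``scd_y`` is
    optional and only used when ``per_axis_alpha`` is set: by default a
    single alpha (from the X jaw) scales both interface dimensions.
    """

    sad: float = DEFAULT_SAD
    smd: float = DEFAULT_SMD
    scd_x: float | None = None
    scd_y: float | None = None
    ff_dist: float = DEFAULT_FF_DIST
    cap_radius: float = DEFAULT_CAP_RADIUS
    per_axis_alpha: bool = False

    def __post_init__(self):
        if self.scd_x is None:
            object.__setattr__(self, "scd_x",
                               scd_from_alpha(DEFAULT_ALPHA, self.smd, self.sad))
        if not (0 < self.scd_x < self.smd < self.sad):
            raise ValueError("require 0 < SCD_x < SMD < SAD")
        if not (0 < self.ff_dist < self.scd_x):
            raise ValueError("require 0 < ff_dist < SCD_x")
        if self.scd_y is not None and not (0 < self.scd_y < self.smd):
            raise ValueError("require 0 < SCD_y < SMD")

    @classmethod
    def from_alpha(cls, alpha: float, sad: float = DEFAULT_SAD,
                   smd: float = DEFAULT_SMD, **kw) -> "MachineGeometry":
        return cls(sad=sad, smd=smd, scd_x=scd_from_alpha(alpha, smd, sad), **kw)

    @property
    def alpha(self) -> float:
        return alpha_from_scd(self.scd_x, self.smd, self.sad)

    @property
    def alpha_y(self) -> float:
        if self.per_axis_alpha and self.scd_y is not None:
            return alpha_from_scd(self.scd_y, self.smd, self.sad)
        return self.alpha


def compute_alpha(geom: MachineGeometry) -> float:
    """Interface scaling coefficient of the machine (see module docstring)."""
    return geom.alpha


def scatter_interface(geom: MachineGeometry, jaw_rect: Rect) -> Rect:
    """Scatter-interface rectangle at the mid-MLC plane.

    ``jaw_rect`` is the jaw-defined field at the isocenter plane (or any
    plane; it is projected).  The jaw field is projected to the mid-MLC plane
    and both dimensions are scaled by alpha about the beam axis.
    """
    at_mid = jaw_rect.projected(geom.smd)
    return at_mid.scaled(geom.alpha, geom.alpha_y)
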