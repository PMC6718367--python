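"""Published default parameters of the MLC scatter source (6 MV, Millennium-120).

Two parameter sets are shipped:

* ``published_source_model()`` -- the published per-jaw optimum (a, b, sigma)
  values for 10x10, 20x20 and 30x30 cm^2 jaw squares, with an AP-ratio
  interpolation through them (sigma on a log scale) for other jaw settings.
  This is the model used as simulation truth by the synthetic campaign.

* ``published_apratio_model()`` -- the quadratic AP-ratio coefficient set as
  published.  Only the a_out quadratic is numerically consistent with the
  per-jaw table; the published sigma quadratics go negative inside the fitted
  range, so evaluating this model raises ``ModelValidityError`` for most AP
  ratios.  It is kept verbatim for reference and for the a_out consistency
  check.

``plausible_dsm_params()`` is a synthetic-but-realistic 6 MV dual-source
parameter set (the published study re-fits the DSM to each machine and does
not print its values); it drives the synthetic campaign's forward model.
"""

from __future__ import annotations

import numpy as np

from .dsm import DSMParams
from .mlc_source import APRatioModel, MLCScatterParams, MLCSourceModel, QuadCoeff

# Published optimum per-jaw parameters (6 MV): jaw side -> (a_out, b_out,
# sigma_out, a_in, b_in, sigma_in).
PUBLISHED_PER_JAW_PARAMS: dict[float, MLCScatterParams] = {
    10.0: MLCScatterParams(0.016, 0.820, 17.891, 0.014, 0.503, 32.418),
    20.0: MLCScatterParams(0.016, 0.797, 45.942, 0.009, 0.456, 57.543),
    30.0: MLCScatterParams(0.017, 0.751, 403.412, 0.007, 0.404, 450.124),
}

# Published quadratic AP-ratio coefficient set (c2, c1, c0), verbatim.
PUBLISHED_APRATIO_COEFFS: dict[str, tuple[float, float, float]] = {
    "a_out": (3.067e-5, 5.333e-5, 0.015),
    "b_out": (7.810e-4, -6.042e-3, 0.840),
    "sigma_out": (-1.762e-4, 26.360e-5, -37.103),
    "a_in": (3.724e-4, 5.120e-5, 0.025),
    "b_in": (3.303e-4, -4.135e-3, 1.648),
    "sigma_in": (-14.072e-4, 224.207e-3, -440.218),
}


def published_apratio_model() -> APRatioModel:
    return APRatioModel({k: QuadCoeff(*c) for k, c in PUBLISHED_APRATIO_COEFFS.items()})


def _apratio_of_square(side: float) -> float:
    return side / 4.0


def published_anchored_apratio_model() -> APRatioModel:
    """Quadratics through the per-jaw table at AP ratios 2.5, 5.0, 7.5.

    a and b interpolate in linear space; sigma in log space (the only
    positive-valued quadratic interpolation through values spanning
    17.9 .. 450).
    """
    x = np.array([_apratio_of_square(s) for s in sorted(PUBLISHED_PER_JAW_PARAMS)])
    coeffs = {}
    for k in MLCScatterParams.PARAM_NAMES:
        v = np.array([getattr(PUBLISHED_PER_JAW_PARAMS[s], k) for s in sorted(PUBLISHED_PER_JAW_PARAMS)])
        if k.startswith("sigma"):
            c = np.polyfit(x, np.log(v), 2)
            coeffs[k] = QuadCoeff(c[0], c[1], c[2], scale="log")
        else:
            c = np.polyfit(x, v, 2)
            coeffs[k] = QuadCoeff(c[0], c[1], c[2])
    return APRatioModel(coeffs)


def published_source_model() -> MLCSourceModel:
    per_jaw = {(s, s): p for s, p in PUBLISHED_PER_JAW_PARAMS.items()}
    return MLCSourceModel(per_jaw=per_jaw, apratio_model=published_anchored_apratio_model(),
                          provenance="paper_default")


def plausible_dsm_params() -> DSMParams:
    """Synthetic 6 MV dual-source parameters for simulation truth.

    k_ff = 0.05 and sigma_ff = 1.5 cm give an Sc span of roughly 0.97--1.02
    over 4x4 to 40x40 jaw squares, the magnitude typical of flattened 6 MV
    beams; k_b = 1e-5 per cm^2 yields a ~1.5% monitor-backscatter swing.
    """
    return DSMParams(k_ff=0.05, sigma_ff=1.5, k_b=1.0e-5)
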