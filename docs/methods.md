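# Methods

`headscatter` computes the in-air output ratio S_c of a flattened linac
photon beam — the collimator-setting dependence of the output measured in a
miniphantom on the beam axis, normalized to a 10 × 10 cm² jaw field — for
fields shaped by jaws and a 60-pair multi-leaf collimator (MLC). It combines
a conventional dual-source head-scatter model with an explicit MLC scatter
source, fits both from measured-S_c tables, and evaluates Clarkson
sector-integrated point dose for irregular MLC apertures.

## Geometry and conventions

All transverse coordinates are beam-axis-centered centimeters (x cross-plane,
y in-plane); apertures are specified at the isocenter plane and projected to
other planes by similar-triangle magnification from the focal source.
Default axial distances: SAD = 100 cm, mid-MLC plane SMD = 51 cm,
flattening-filter (extra-focal) plane at 12.5 cm. The X-jaw plane SCD_x is
derived by algebraically inverting

    alpha = SCD_x (SAD − SMD) / (SMD (SAD − SCD_x))

for alpha = 0.577, giving SCD_x ≈ 37.52 cm; machine configs may instead give
SCD_x directly (exactly one of the two). A single alpha scales both interface
dimensions by default; a per-axis alpha from an explicit Y-jaw distance is
supported but off by default. The flattening-filter distance is a
conventional value for this machine class, not a fitted quantity; it only
rescales the DEV geometry and is absorbed by the fitted Gaussian width.

The **scatter interface** is the jaw field projected to the mid-MLC plane and
shrunk by alpha about the axis. It is exactly the footprint of the
jaw-defined detector's-eye view (DEV) at the mid-MLC plane: a leaf edge
inside it clips the on-axis DEV, a leaf edge outside it only adds scatter.
Field categories: (1) leaves strictly retracted out of the jaw beam's-eye
view, (2) leaves in the BEV with the aperture boundary outside the
interface, (3) aperture boundary reaching the interface.

Tie-breaks, chosen once for determinism:

* Perimeter lying exactly on the interface boundary counts as "in" (the
  closed-set intersection shapely computes).
* Leaf tips parked exactly at the jaw edge are category 2, not 1 — the last
  point of an MLC-square series (square = jaw) is then modeled by the
  general formula rather than short-circuited, which keeps the series
  monotone. Category 1 requires strictly retracted tips or no bank; jaw-only
  fields carry no bank and are category 1 by construction.
* Closed leaf pairs (gap ≤ 0.05 cm at isocenter) contribute no aperture and
  their abutment line contributes no perimeter.

Leaf geometry defaults to the Millennium-120 layout (40 central 0.5 cm pairs,
20 outer 1.0 cm pairs at isocenter); the edge list is configurable. MLC
squares whose half-side falls between outer-leaf boundaries are realized by
opening the majority-overlap rows, as on a real bank, so such "squares" are
leaf-quantized; the forward model and the fit see the same polygon, so this
introduces no inconsistency.

## Dual-source model

    S_c,DSM(fs) = (1 + F_efs(fs)) (1 − F_mbs(fs))
                  / [(1 + F_efs(fs_ref)) (1 − F_mbs(fs_ref))]

F_efs is k_ff times the mass of an isotropic Gaussian (width sigma_ff, at the
flattening-filter plane) over the DEV — each collimator opening
back-projected from the on-axis detector at SAD and intersected, capped by a
primary-collimator field of view (default radius 20 cm at the ff plane,
which never clips jaw fields up to 40 × 40). F_mbs = k_b × (1600 − A_jaw)
cm² is monitor backscatter, linear in the jaw-blocked area relative to the
fully open 40 × 40 setting — the minimal parameterization identifiable from
a jaw-only campaign. Because DEV regions are rectilinear, the Gaussian mass
is computed exactly as products of one-dimensional normal-CDF differences
over a y-strip rectangle decomposition; only a clipped (non-rectilinear)
primary cap falls back to a fine-strip approximation.

Fitting minimizes the chi-square Σ((S_c,calc − S_c,meas)/SD)² over
(k_ff, sigma_ff, k_b) with scipy's trust-region-reflective solver under
bound constraints, an iteration cap of 400, and convergence reported rather
than silently accepted; a noise-free campaign ends with chi-square below
1e-6. Rows with zero/absent SD are weighted 1. Fits use jaw-only
(MLC-retracted) rows; predictions for MLC-defined fields include the leaves
in the DEV blocking.

## MLC scatter source

The correction S_c = S_c,DSM × S_c,MLC uses an extra-focal source at the
mid-MLC plane with a line-based component (rounded leaf ends along the
aperture perimeter) and an area-based component (exposed leaf faces):

    ES_line = a (FP^b − RP^b) + 1
    ES_area = exp(−(MA − RA) / 2σ²)

    S_c,MLC = ES_line,out(FP_out) · ES_line,in(FP_in)
              · ES_area,out(MA_out − RA_out) · ES_area,in(MA_in − RA_in)

FP is the aperture perimeter and MA the exposed leaf area at the mid-MLC
plane, each split by the scatter interface; RP is the interface perimeter
(one reference for both line factors); RA_out is the interface area and
RA_in is 3 × 3 cm² at isocenter projected to the mid-MLC plane by
(SMD/SAD)², so that every area in the formula lives in one plane. All six
parameters (a, b, σ per region) are per-jaw-setting. Category-1 fields
short-circuit to S_c,MLC = 1 exactly.

Numerical conventions where the formulas are silent:

* A region holding no perimeter is evaluated at FP = 0 as written
  (0^b = 0, so the factor is 1 − a·RP^b). This is the continuous limit of
  the formula; a `zero_fp_identity` switch forces the factor to 1 instead,
  off by default. Consequence: when an entire perimeter segment switches
  region (a leaf tip crossing the interface edge, or a concentric square
  outgrowing the interface) S_c,MLC steps by a finite amount set by the
  segment length; within a regime it varies smoothly.
* ES_area may exceed 1 when MA < RA (large MLC openings); values are allowed
  as written.
* The exponent uses the first power of MA (σ² carries cm² units), matching
  the magnitudes of the shipped per-jaw σ values.

**Parameter files.** The shipped defaults are the published per-jaw optima
for 10 × 10, 20 × 20 and 30 × 30 cm² jaws, plus two AP-ratio models
(quadratics in the jaw field's area-to-perimeter ratio, fitted range
2.5–7.5 cm): the published coefficient set, kept verbatim for reference —
only its a_out line is numerically consistent with the per-jaw table, and
its σ quadratics go negative inside the fitted range, so evaluating it
raises a model-validity error — and a usable interpolation anchored on the
per-jaw table, quadratic in AP ratio for a and b and quadratic in ln σ for
σ (the only positive-valued choice through σ values spanning 17.9–450).
Per-jaw parameters take precedence; the AP-ratio model is the fallback for
unseen jaw settings. Parameter files record plane/unit conventions so fitted
values are self-describing.

**Fitting** is two-stage: per jaw setting, the six parameters are fit to the
residual ratio S_c,meas / S_c,DSM over that jaw's MLC series (weighted
least squares, trust-region-reflective, iteration cap 400, small
multi-start, analytic Jacobian, σ parameterized internally as ln σ for
conditioning); each series must span categories 2 and 3. Then AP-ratio
quadratics are fit through the per-jaw values (log scale for σ) when at
least three jaw settings are present. Region metrics are geometry-only and
precomputed once per field, so fits take milliseconds.

**Identifiability.** On a noise-free campaign the fit recovers every
generating parameter essentially exactly (the suite checks 1e-2 relative;
observed ~1e-6). Under realistic 0.2% reading noise the *curve* is well
determined but individual parameters are strongly correlated — σ_out in
particular becomes nearly flat once the area factor saturates — so fitted
parameter values should be read as a set, not term by term. Held-out
prediction is the meaningful noise-level check: with interior squares of
the 20 and 30 cm series held out, predicted S_c agrees with the noise-free
truth to ≈0.1% RMS (pooled over replicate campaigns). The 7-point 10 × 10
series is never thinned: six parameters against six training points would
leave no residual degrees of freedom. Interpolating *parameters* across jaw
settings through the AP-ratio model amplifies these correlated errors, so
AP-ratio interpolation from noisy fits predicts unseen jaws at only the
~1% level; per-jaw fits should be used wherever the jaw setting was
measured.

## Synthetic campaign

The generator reproduces the standard measurement design: jaw squares
4–40 cm (1 cm steps) and rectangles with one pair fixed at 4/10/40 cm for
the dual-source fit; MLC squares from 4 × 4 up to the jaw size at jaws
10/15/20/25/30 cm; cross / mirrored-E / maze leaf templates at jaws
15/20/25 cm for evaluation. The 10 × 10 reference appears exactly once.
Truth parameters: the published per-jaw MLC values (log-σ AP-ratio
interpolation for jaws 15/25) and a plausible 6 MV dual-source set
(k_ff = 0.05, sigma_ff = 1.5 cm, k_b = 1e-5 cm⁻², giving an S_c span of
roughly 0.97–1.02 over 4–40 cm jaw squares). Noise is multiplicative
Gaussian with 0.2% relative SD (bounded at 0.5%), matching how
repeat-reading spread is quoted; the SD column is noise_sd times the
reported reading. Same seed, same table, byte for byte.

What the generator does *not* emulate: detector volume averaging,
miniphantom scatter, source occlusion for very small fields, output drift,
and the true (unpublished) S_c magnitudes of any physical beam — with the
shipped defaults the MLC correction for deeply blocked category-3 fields is
larger than the sub-percent corrections seen clinically, because the
published line/area parameters are used outside the normalization their
original measurements imposed. Passing tests therefore demonstrate internal
consistency and recoverability of the model, not agreement with any
particular linac. The irregular leaf templates are parameterized
approximations of the published drawings (exact leaf coordinates were never
printed).

## Clarkson dose

Sp and TMR for an aperture are sector averages of user-supplied radial
tables: 1° sectors by default (360 contributions), table value taken at the
distance from the calculation point to the aperture boundary along each
sector's central ray. Multi-crossing rays in non-convex apertures use the
first crossing only (primary-aperture Clarkson) — re-entrant scatter beyond
the first wall is ignored, a documented limitation. Tables interpolate
linearly and refuse to extrapolate. Point dose is the factor-based MU
formalism dose = MU × k_cal × S_c × Sp × TMR. A synthetic monotone Sp/TMR
generator ships for tests and demos; it makes no claim of matching measured
beam data.

## Problem sizes used in the test suite

Oracle comparisons run on 50 random rectilinear regions (Gaussian
quadrature vs dense rasterization, 1e-4 relative) and 200 random apertures
(perimeter/area splits vs segment-clipping and shoelace oracles, 1e-9
relative). Recovery tests simulate the three-jaw modeling campaign
(298 fields); the held-out check pools 12 held-out squares over three
replicate noisy campaigns. The full suite runs in well under a minute on
one CPU.
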