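"""In-air output ratio across an MLC-square series at a fixed jaw.

Evaluates Sc = Sc_DSM x Sc_MLC for MLC squares 4..20 cm inside a 20 x 20
jaw, using the published per-jaw MLC scatter parameters and a plausible
dual-source parameter set.  Sc_line grows with the aperture perimeter,
Sc_area shrinks with the exposed leaf area, and their product rises
monotonically with the MLC opening — the qualitative signature the MLC
scatter source was built to reproduce.
"""

from headscatter import FieldSpec, JawSetting, MachineGeometry, MLCBank, sc_breakdown
from headscatter import defaults

geom = MachineGeometry()
dsm = defaults.plausible_dsm_params()
mlc = defaults.published_source_model()

print("side  cat  Sc_DSM   Sc_line  Sc_area  Sc_MLC   Sc")
for side in range(4, 21, 2):
    fs = FieldSpec(jaw=JawSetting.square(20.0), bank=MLCBank.square(float(side)))
    bd = sc_breakdown(fs, dsm, mlc, geom)
    print(f"{side:4d}  {bd.category}   {bd.sc_dsm:.5f}  {bd.sc_line:.5f}  "
          f"{bd.sc_area:.5f}  {bd.sc_mlc:.5f}  {bd.sc:.5f}")
print("\nReference field (jaw 10x10, MLC retracted) normalizes Sc to 1:")
from headscatter import reference_field, sc_total
print("Sc(reference) =", sc_total(reference_field(), dsm, mlc, geom))
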