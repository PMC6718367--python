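"""Scatter-interface geometry and jaw/MLC field classification.

Builds the default machine (SAD 100 cm, mid-MLC plane at 51 cm, alpha =
0.577), computes the scatter interface for a 20 x 20 cm^2 jaw field, and
classifies MLC squares of growing size: small squares sit inside the
interface (category 3, they clip the detector's-eye view), large ones sit
between interface and jaw (category 2, pure scatter contributors), and a
retracted bank is category 1 (no MLC effect at all).
"""

from headscatter import (FieldSpec, JawSetting, MachineGeometry, MLCBank,
                         compute_alpha, scatter_interface)
from headscatter.mlc_source import field_metrics

geom = MachineGeometry()
print(f"alpha = {compute_alpha(geom):.3f}  (jaw plane at {geom.scd_x:.2f} cm)")

jaw = JawSetting.square(20.0)
iface = scatter_interface(geom, jaw.rect(geom.sad, geom.sad))
print(f"20x20 jaw -> interface {iface.width:.3f} x {iface.height:.3f} cm^2 "
      f"at the {iface.plane_dist:g} cm plane")
# The interface edge maps back to an MLC square of side width/(0.51*alpha)
# ~ 11.5 cm at isocenter: squares below that clip the DEV.

for side in (4, 8, 12, 16, 20):
    fs = FieldSpec(jaw=jaw, bank=MLCBank.square(float(side)))
    metrics, category = field_metrics(fs, geom)
    print(f"MLC square {side:2d} cm: category {category}, "
          f"FP_in={metrics.fp_in:6.2f} FP_out={metrics.fp_out:6.2f} cm, "
          f"MA_in={metrics.ma_in:6.2f} MA_out={metrics.ma_out:6.2f} cm^2")

fs = FieldSpec(jaw=jaw, bank=MLCBank.retracted())
print("retracted bank: category", field_metrics(fs, geom)[1])
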