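"""Reconstruct the two-layer vessel phantom end to end.

Renders the canonical four-tube phantom (two tubes 7.5 mm below the
phantom top, two at 8.5 mm) through the stereo optics and the 1300-LP
scattering model, runs enhancement + semi-global matching + triangulation,
and reports the recovered per-layer depths.  The printed separation is the
quantity that tells the two layers apart; with the 40 mm baseline it should
land within a fraction of the system's 0.6 mm depth resolution of the true
1 mm gap.
"""

import warnings

warnings.filterwarnings("ignore")

from stereonir.analysis import two_layer_recovery

rec = two_layer_recovery(seed=1, band="LP1300")

print("per-vessel reconstruction (depths below the phantom top, mm):")
for vid, v in rec.metrics["per_vessel"].items():
    print(f"  vessel {vid}: measured {-v['mean_mm']:.2f}  true {-v['truth_mm']:.1f}  "
          f"({v['n']} px)")
print(f"upper layer mean: {rec.per_layer_mean[7.5]:.2f} mm (true 7.5)")
print(f"lower layer mean: {rec.per_layer_mean[8.5]:.2f} mm (true 8.5)")
print(f"layer separation: {rec.separation_mm:.2f} mm (true 1.0)")
print(f"pixelwise depth RMSE: {rec.metrics['rmse_mm']:.2f} mm")
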