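"""Render a synthetic retina pair and inspect its ground truth.

The generator draws a paired angiogram + color fundus image with a bright
vessel-crossed optic disc, a branching vessel tree with Gaussian profile, a
vessel-free foveal avascular zone, microaneurysm dots and exudate blobs —
all recorded in a truth object so detectors can be scored against it.
"""

from curvegrade.phantom import grade_presets, render_pair

spec = grade_presets(2, seed=7)  # mild/moderate retinopathy preset
ffa, color, truth = render_pair(spec)

print(f"FFA shape {ffa.shape}, color shape {color.shape}")
print(f"optic disc at {truth.od_center}, radius {truth.od_radius} px")
print(f"FAZ center {truth.faz_center}, radius {truth.faz_radius} px "
      f"(area {truth.faz_area:.0f} px²)")
print(f"planted vessel pixels: {truth.vessel_mask.sum()}")
print(f"planted microaneurysms: {len(truth.ma_centers)}")
print(f"planted exudate area: {truth.ex_area} px")
# Everything above is exact by construction; the rendered images add only
# mild Gaussian noise on top, so each object is recoverable by a detector.
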