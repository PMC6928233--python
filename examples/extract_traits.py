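"""Extract the 44-trait table from a phantom, in pixels and millimetres.

Renders a three-root soil phantom, measures its ground-truth mask and
prints the headline traits.  A conversion factor of 0.1 mm/px (a 10 mm
reference bar spanning 100 px) converts lengths to mm, areas to mm^2
and volumes to mm^3.
"""

import rootpheno as rp

scene = rp.render_scene(seed=1)
cf = rp.ConversionFactor(reference_len_mm=10.0, reference_len_px=100.0)

t_px = rp.compute_traits(scene.truth_mask, scene.image)
t_mm = rp.compute_traits(scene.truth_mask, scene.image, cf=cf)

print(f"trait count: {len(t_px)}")
print(f"root objects:     {t_px['object_count']:.0f}")
print(f"total length:     {t_px['total_length_px']:.1f} px = "
      f"{t_mm['total_length_mm']:.2f} mm")
print(f"mean local width: {t_px['width_mean_px']:.2f} px = "
      f"{t_mm['width_mean_mm']:.3f} mm")
print(f"tube volume:      {t_px['volume_px3']:.0f} px^3 = "
      f"{t_mm['volume_mm3']:.2f} mm^3")
print(f"branch points:    {t_px['branch_count']:.0f}, "
      f"end points: {t_px['end_count']:.0f}")
print(f"mean tangent angle (vs horizontal): {t_px['angle_mean_deg']:.1f} deg")
# Lengths scale by CF, areas by CF^2, volumes by CF^3; counts and angles
# are unit-free.  The generator recorded a total centerline length of
print(f"generator ground truth length: {scene.total_centerline_length:.0f} px")
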