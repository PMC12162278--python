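"""Measure airway structural metrics on a synthetic tube phantom.

Builds a circular airway of inner radius 5 mm with a 1 mm wall at 0.25 mm
voxel spacing, measures the mid-branch cross-section, and compares against
the analytic ground truth (LA = pi r^2 = 78.54 mm^2, P_e = 2 pi r =
31.42 mm, D_h = 2r = 10 mm, Cr = 1).
"""

from lungqct import (
    TubePhantomSpec,
    circularity,
    hydraulic_diameter,
    make_tube_phantom,
    measure_cross_section,
    tube_masks,
)

spec = TubePhantomSpec(inner_radius=5.0, wall_thickness_true=1.0, voxel_spacing=0.25)
vol, skeleton, truth = make_tube_phantom(spec)
lumen, wall = tube_masks(vol, spec)

m = measure_cross_section(lumen, wall, vol.grid, skeleton, "Trachea")
print(f"luminal area  LA  = {m.LA:7.3f} mm^2   (analytic {truth.LA:7.3f})")
print(f"perimeter     P_e = {m.P_e:7.3f} mm     (analytic {truth.P_e:7.3f})")
print(f"hydraulic D_h     = {hydraulic_diameter(m.LA, m.P_e):7.3f} mm     (analytic 10.000)")
print(f"circularity   Cr  = {circularity(m.D_inner, m.P_e):7.4f}        (1 for a circle)")
print(f"wall thickness WT = {m.WT:7.3f} mm     (analytic {truth.WT:7.3f}, diameter-difference)")
print()
print("Sub-percent agreement shows the sub-pixel contour measurement recovers")
print("the analytic cylinder; WT is the equivalent-diameter difference, i.e.")
print("twice the physical wall.")
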