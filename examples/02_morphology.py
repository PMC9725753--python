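"""Mitochondrial morphology: Otsu mask, particle counts, mean area, skeleton.

Reproduces the mean-area-per-mitochondrion readout: threshold the matrix
channel in a 15x15 µm ROI, count particles, divide total area by the count.
An elongated network gives a large mean area; a fragmented one a small mean.
"""

from mitonode import ROI, build_scene, mean_area_per_mitochondrion, otsu_mask, render_movie, skeletonize_mask
from mitonode.simulate import SceneParams

scene = build_scene(SceneParams.constriction_stack(), seed=2)
stack = render_movie(scene, seed=102)

plane = stack.pixels[0, :, stack.channel("mito")].max(axis=0)  # max z-projection
mask = otsu_mask(plane, calibration=stack.calibration)
mean, count, total = mean_area_per_mitochondrion(mask, roi=ROI.preset("15x15"))
print(f"{count} mitochondria in the ROI, total {total:.2f} µm², "
      f"mean area per mitochondrion {mean:.2f} µm²")

skel = skeletonize_mask(mask)
print(f"skeleton: {skel.total_length_um:.1f} µm of centreline, "
      f"{len(skel.endpoints())} tips, {len(skel.junctions())} branch points")
true_len = sum(f.length_um for f in scene.filaments)
print(f"(ground-truth filament length: {true_len:.1f} µm)")
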