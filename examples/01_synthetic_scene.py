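"""Build a ground-truthed synthetic FTIR tissue scene and render it.

The scene is a 32 x 32 acquisition grid with three contiguous tissue
classes (protein-, lipid- and nucleic-acid-rich), ~2% sample holes, ~2%
scattering-artifact pixels, mild affine baselines, a variable atmospheric
CO2 band and Gaussian channel noise.  Everything about it is known, so it
serves as an oracle for the rest of the workflow.
"""

import numpy as np

import specmap as sm

scene = sm.make_default_scene(nx=32, ny=32, seed=0)
smap = sm.render(scene)

print(f"spectral map: {smap.n_pixels} pixels x {smap.n_wavenumbers} wavenumbers")
print(f"axis: {smap.axis[0]:.0f}-{smap.axis[-1]:.0f} cm^-1, "
      f"spacing {smap.axis[1] - smap.axis[0]:.0f} cm^-1")
counts = {int(c): int(n) for c, n in zip(*np.unique(scene.region_map, return_counts=True))}
print(f"region sizes (class -> pixels): {counts}")
print(f"seeded holes: {len(scene.holes)}, scatter pixels: {len(scene.scatter_pixels)}")
# The three classes differ in their band signatures; the amide I band at
# 1654 cm^-1 is present everywhere (all tissue contains protein).
j = int(np.argmin(np.abs(smap.axis - 1654)))
for c in range(3):
    mean_a = smap.absorbance[scene.region_map == c, j].mean()
    print(f"class {c}: mean absorbance at 1654 cm^-1 = {mean_a:.3f}")
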