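"""Quality control and spectral preprocessing.

Holes (no-sample pixels) are detected from the mean amide I absorbance,
scattering artifacts from the baseline slope over the 1800-2600 cm^-1
silent region; excluded positions are saved for later spatial
repopulation.  Retained spectra then lose the atmospheric CO2 region, are
scaled to unit Euclidean norm, and are transformed to their Savitzky-Golay
second derivative (which removes constant and linear baseline drift).
"""

import numpy as np

import specmap as sm

scene = sm.make_default_scene(32, 32, seed=0)
smap = sm.render(scene)
params = sm.PreprocessParams()  # all thresholds/windows overridable

empty = sm.detect_empty(smap, params)
scatter = sm.detect_scatter(smap, params)
mask = empty & scatter
print(f"flagged empty: {len(empty.excluded_indices)} "
      f"(seeded holes: {len(scene.holes)})")
print(f"flagged scatter: {len(scatter.excluded_indices)} "
      f"(seeded artifacts: {len(scene.scatter_pixels)})")
print(f"retained {mask.n_retained}/{mask.original_n} pixels")

x = sm.apply_mask(smap, mask)
x = sm.exclude_co2(x, params)
print(f"CO2 excision: {smap.n_wavenumbers} -> {x.n_wavenumbers} wavenumbers")
x = sm.vector_normalize(x)
norms = np.linalg.norm(x.absorbance, axis=1)
print(f"row norms after normalization: max |norm - 1| = {np.abs(norms - 1).max():.2e}")
x = sm.second_derivative(x, params)
print(f"second derivative: values in [{x.absorbance.min():.2e}, {x.absorbance.max():.2e}] "
      "absorbance*cm^2")
for entry in x.log[-4:]:
    print("  log:", entry)
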