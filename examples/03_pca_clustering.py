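"""Eigen-spectra PCA and graph-based clustering of pixel spectra.

PCA summarizes each preprocessed spectrum by its scores on the top
eigen-spectra; a k-nearest-neighbor graph on the scores is partitioned
with the Leiden algorithm.  On the synthetic scene the recovered clusters
can be compared against the generative region labels.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

import specmap as sm

scene = sm.make_default_scene(32, 32, seed=0)
smap = sm.render(scene)
params = sm.PreprocessParams()
mask = sm.detect_empty(smap, params) & sm.detect_scatter(smap, params)
x = sm.second_derivative(
    sm.vector_normalize(sm.exclude_co2(sm.apply_mask(smap, mask), params)), params
)

pca = sm.fit_pca(x, n_components=15)
cum = sm.cumulative_variance(pca)
print("explained variance ratio (top 5):",
      np.round(pca.explained_variance_ratio[:5], 4))
print(f"cumulative variance after 2 components: {cum[1]:.4f}")

assignment = sm.cluster(pca.scores, n_neighbors=15, resolution=0.5, seed=0)
truth = scene.region_map[mask.keep]
ari = adjusted_rand_score(truth, assignment.labels)
print(f"clusters found: {assignment.n_clusters} (ground truth: 3 regions)")
print(f"adjusted Rand index vs ground truth: {ari:.3f}")
sizes = [int((assignment.labels == k).sum()) for k in range(assignment.n_clusters)]
print(f"cluster sizes (largest first): {sizes}")
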