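"""Build a PCA morphospace from per-cell shape features.

Redundant features (|r| >= 0.95) are screened out, the rest are z-scored
and decomposed.  The variance fractions say how much cell-shape variability
each component explains; the significant contributors of a component are the
features whose contribution exceeds the mean (100/p %) — together they give
each axis of morphospace a geometric interpretation.
"""

from notomorph import (
    embed,
    extract_cells,
    feature_table,
    fit_morphospace,
    generate_notochord,
    significant_contributors,
    trunk_config,
)

data = generate_notochord(trunk_config(seed=0))
cells = extract_cells(data.volume, data.voxel_size_um, data.nucleus_table)
feats = feature_table(cells, data.annotations)

model = fit_morphospace(feats, n_components=5)
print("retained features:", ", ".join(model.features))
print()
for k, frac in enumerate(model.variance_fraction, start=1):
    names = ", ".join(significant_contributors(model, k))
    print(f"PC{k}: {100 * frac:5.1f}% of variance  <- {names}")
print(f"first five components: {100 * model.variance_fraction.sum():.1f}%")
print()
coords = embed(model, feats)
print(coords.groupby("stage")[["PC1", "PC2"]].mean().round(2))
print("Per-stage mean coordinates: cells drift through morphospace as the "
      "shape programme advances.")
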