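"""Infer a principal-curve trajectory and pseudotime for trunk cells.

Somite stage guides a minimum spanning tree over cluster centres in the
first three principal components; an iterated principal curve through the
cells defines pseudotime as normalised arc length.  A high stage-pseudotime
Pearson r means the inferred shape trajectory recapitulates developmental
time; the per-stage means should increase monotonically.
"""

import numpy as np
from scipy.stats import pearsonr

from notomorph import (
    cluster_inputs,
    embed,
    extract_cells,
    feature_table,
    fit_morphospace,
    generate_notochord,
    infer_trajectory,
    stage_pseudotime_correlation,
    trunk_config,
)

data = generate_notochord(trunk_config(seed=0))
cells = extract_cells(data.volume, data.voxel_size_um, data.nucleus_table)
feats = feature_table(cells, data.annotations)
coords = embed(fit_morphospace(feats, n_components=5), feats)

labels = cluster_inputs(coords, mode="stage")
model = infer_trajectory(coords, labels, start=6, ends=14)
corr = stage_pseudotime_correlation(model, coords["stage"].to_numpy())
print(f"stage-pseudotime Pearson r = {corr['pearson_r']:.3f}")
print(corr["per_stage"].round(3).to_string(index=False))

truth = data.ground_truth.set_index("cell_id")
maturity = truth.loc[coords["cell_id"], "maturity"].to_numpy()
r = pearsonr(model.pseudotime, maturity)[0]
print(f"pseudotime vs ground-truth maturity: r = {r:.3f}")
print("Pseudotime (arc length along the fitted curve, scaled to [0, 1]) "
      "recovers each cell's true maturation state.")
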