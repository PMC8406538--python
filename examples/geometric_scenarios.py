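"""Decompose neighbourhood elongation into shape, growth and intercalation.

A mean cell per stage is summarised by AP length l, volume V and transverse
area A (l ~= V/A).  Counterfactual scenarios re-run development letting one
transformation act alone on the starting-stage cell, then couple it to the
measured 10-cell intercalation index beta(s).  Comparing the predicted
percentage elongation of a 10-cell neighbourhood across scenarios shows
which transformations carry tissue lengthening — shape change without
growth actually shortens the group.
"""

import pandas as pd

from notomorph import (
    IntercalationSeries,
    generate_notochord,
    mean_cell_params,
    neighbourhood_lengths,
    scenario_neighborhood,
    trunk_config,
)
from notomorph.geomodel import SCENARIOS

gt = generate_notochord(trunk_config(seed=0)).ground_truth
gt = gt.rename(columns={"area_um2": "area_transverse_um2"})
params = mean_cell_params(gt)
series = IntercalationSeries(
    n=10,
    table=neighbourhood_lengths(gt, x_left_col="x_left_um",
                                x_right_col="x_right_um"),
)

rows = []
for scen in SCENARIOS:
    out = scenario_neighborhood(params, series, scen)
    rows.append({"scenario": scen,
                 "final_length_um": out["neighborhood_length_um"].iloc[-1],
                 "pct_change_6_to_14ss": out["pct_change"].iloc[-1]})
print(pd.DataFrame(rows).round(1).to_string(index=False))
print()
print("'full' reproduces the measured neighbourhood lengths by construction;"
      " growth-only and intercalation-only each fall short of it, and the"
      " growth-free shape scenario shrinks the group — growth and"
      " intercalation must act together to elongate the tissue.")
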