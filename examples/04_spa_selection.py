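"""Successive-projections feature selection on the VI family.

Screens the 30 vegetation indices against ground-truth LAI, runs SPA
from every candidate start column and reports the cross-validated RMSE
path and the chosen minimally-collinear subset.
"""

import numpy as np

from canopylai import (build_spectral_features, correlation_screen,
                      make_layout, plot_mean_spectrum, simulate_cube,
                      simulate_lai, spa_select)

layout = make_layout(seed=0)
truth = simulate_lai(layout, "BBCH41", seed=0)
cube = simulate_cube(layout, truth, "BBCH41", seed=0)
records = plot_mean_spectrum(cube, layout, "BBCH41")
table = build_spectral_features(records)
vi = table.subset(table.columns_of("VI"))
lai = np.array([t.lai for t in truth])

screen = correlation_screen(vi, lai)
top = screen.table["r"].abs().sort_values(ascending=False).head(3)
print("strongest single indices:", ", ".join(
    f"{n} (|r|={v:.2f})" for n, v in top.items()))

res = spa_select(vi, lai, folds=5, seed=0)
print(f"SPA chain from column {res.start_column}: {res.chain}")
print("RMSECV path:", np.round(res.rmsecv_path, 3))
print(f"chosen {res.chosen_k} features: {res.chosen_columns}")
# The chosen subset minimizes cross-validated RMSE; unselected indices
# are either uninformative for LAI or collinear with the chosen ones.
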