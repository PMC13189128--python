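"""Fit the 12-predictor lasso encoding model to a peripheral unit.

Each fixation is coded by which stimulus types occupy the unit's receptive
field, crossed with whether the monkey is fixating a target or a
distractor; the split-half-averaged lasso coefficients estimate the
response strength of each stimulus-by-state combination and are compared
to the unit's planted generative coefficients.
"""

import numpy as np

from popdyn import SimConfig, simulate_session
from popdyn.encoding import build_design, fit_lasso_splits
from popdyn.simulate import STIMULUS_TYPES, rf_locations

session = simulate_session(SimConfig(
    n_units={"V4": 20, "IT": 0, "OFC": 0, "LPFC": 0},
    n_trials=250, seed=5, lfp_enabled=False,
    rf_fractions={"focal_foveal": 0.0, "broad_foveal": 0.0,
                  "peripheral_localized": 1.0,
                  "peripheral_unlocalized": 0.0, "nonresponsive": 0.0},
))

unit = session.units[0]
truth = session.ground_truth.units[unit.unit_id]
locs = rf_locations(truth, session.array_geometry)
X, y, fixations = build_design(session, unit, locs)
fit = fit_lasso_splits(X, y, n_splits=25, seed=0, unit_id=unit.unit_id)

print(f"unit {unit.unit_id}: RF covers locations {sorted(locs)}, "
      f"{len(y)} fixations, lasso alpha = {fit.alpha:.3f}")
print(f"{'predictor':<28}{'fitted':>8}{'planted':>9}")
for block, state in ((0, "on-target"), (6, "on-distractor")):
    for k, stype in enumerate(STIMULUS_TYPES):
        j = block + k
        if X[:, j].any():
            print(f"{state + ' ' + stype:<28}{fit.coefficients[j]:8.2f}"
                  f"{truth.encoding_coefficients[j]:9.2f}")
seen = np.array([X[:, j].any() for j in range(12)])
r = np.corrcoef(fit.coefficients[seen], truth.encoding_coefficients[seen])[0, 1]
print(f"correlation with planted coefficients (observed predictors): {r:.2f}")
print("fitted response strengths track the generative ones, dissociating")
print("stimulus identity in the periphery from the foveal attentional state.")
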