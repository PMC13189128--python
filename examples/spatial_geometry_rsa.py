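"""Does population activity preserve the search array's spatial layout?

Compares the neural dissimilarity structure over the 20 array locations
(1 - Pearson r between per-location population vectors, four post-fixation
windows) with the physical distances between locations, using Spearman
correlation and a location-shuffle permutation null.
"""

import numpy as np

from popdyn import SimConfig, simulate_session
from popdyn.rsa import RSA_WINDOWS, neural_dm, physical_dm, rsa_correlation_test

session = simulate_session(SimConfig(
    n_units={"V4": 40, "IT": 0, "OFC": 0, "LPFC": 0},
    n_trials=220, seed=21, lfp_enabled=False,
    rf_fractions={"focal_foveal": 1.0, "broad_foveal": 0.0,
                  "peripheral_localized": 0.0,
                  "peripheral_unlocalized": 0.0, "nonresponsive": 0.0},
    position_gain_amp=1.5, position_sigma_deg=3.0,
    p_category_tuned_foveal=0.0, p_attention_tuned=0.0,
))
ids = [u.unit_id for u in session.units]

print("window (ms)   Spearman rho   perm p    significant (Bonferroni x4)")
for wi, window in enumerate(RSA_WINDOWS):
    ndm = neural_dm(session, ids, window)
    pdm = physical_dm(session.array_geometry, ndm.labels)
    rho, p, _, sig = rsa_correlation_test(ndm, pdm, n_perm=1000,
                                          rng=np.random.default_rng(wi))
    print(f"{int(window[0]):>3}-{int(window[1]):<10}{rho:11.3f}{p:11.4f}"
          f"{'yes' if sig else 'no':>12}")
print("a positive rho emerging after ~50 ms and absent in the first window")
print("(before the planted 50-ms latency) shows the population carries a map")
print("of the array whose geometry matches the physical layout.")
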