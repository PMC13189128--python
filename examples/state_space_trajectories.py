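"""dPCA state-space trajectories with shuffle statistics.

Projects cue-epoch population activity of foveal units onto demixed
components and tests, bin by bin, whether the face- and house-cue
trajectories separate more than label-shuffled surrogates allow.
"""

import numpy as np

from popdyn import SimConfig, simulate_session
from popdyn.dpca import binned_samples, trajectory_separation_test
from popdyn.selection import classify_units

session = simulate_session(SimConfig(
    n_units={"V4": 24, "IT": 12, "OFC": 0, "LPFC": 0},
    n_trials=200, seed=3, p_category_tuned_foveal=0.5, lfp_enabled=False,
))
classify_units(session)
foveal = [u.unit_id for u in session.units if u.rf_class.endswith("foveal")]

samples, labels, times, kept = binned_samples(session, foveal, "cue", "category")
traj = trajectory_separation_test(samples, labels, times, kept,
                                  n_perm=200, rng=np.random.default_rng(0))

sig = traj.significant
first = times[np.argmax(sig)] if sig.any() else None
print(f"{len(kept)} foveal units, {len(samples)} trials, "
      f"{len(times)} x 10-ms bins after cue onset")
print(f"bins with significant face/house separation (FDR 0.05): "
      f"{sig.sum()}/{len(sig)}")
print(f"first significant bin: {first} ms")
print("a long run of significant bins through the cue epoch means the")
print("population trajectory carries the cue category even when single-unit")
print("rate differences are modest (isolated early bins are the FDR's")
print("tolerated false-discovery share).")
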