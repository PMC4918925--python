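"""Small-worldness of one synthetic connectome via null-model normalization.

Takes a single control-group connectome, builds an ensemble of
degree-preserving Maslov-Sneppen surrogates and prints the raw and
normalized segregation/integration measures.
"""

import numpy as np

from glyconnect.metrics import compute_metrics
from glyconnect.nulls import NullEnsembleConfig, normalize_metrics
from glyconnect.synthetic import SyntheticCohortConfig, gen_cohort

mats, recs = gen_cohort(SyntheticCohortConfig(n_per_group=1, seed=4, cov_corr={}))
w = mats[0].weights
m = compute_metrics(w, n_restarts=20, rng=4)
m = normalize_metrics(w, NullEnsembleConfig(n_null=200, seed=4), metrics=m)

print(f"raw clustering C      = {m.C_raw:.4f}")
print(f"raw path length L     = {m.L_raw:.1f}  (1/fiber-density units)")
print(f"modularity Q          = {m.Q:.3f}")
print(f"global efficiency E   = {m.E:.3e}")
print(f"normalized gamma      = {m.gamma:.2f}")
print(f"normalized lambda     = {m.lam:.3f}")
print(f"small-worldness sigma = {m.sigma:.2f}")
print(
    "\ngamma >> 1 with lambda ~ 1.4 says the network is far more clustered"
    "\nthan degree-matched random graphs at only moderately longer paths -"
    "\nthe small-world architecture (sigma > 1) expected of a healthy brain."
)
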