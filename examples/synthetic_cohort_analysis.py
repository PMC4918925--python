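"""Full cohort analysis: generate, measure, normalize, test.

Generates the default calibrated two-group cohort (20 controls, 20
poorly-controlled-diabetes-like patients; 144-node fiber-density
connectomes), computes the five global network measures per subject with
degree-preserving null normalization, and runs the group permutation
tests and glycemia partial correlations.

A small null ensemble and few Louvain restarts keep this demo around a
minute; a production run would use n_null=1000 and 100 restarts.
"""

import numpy as np
import pandas as pd

from glyconnect.nulls import NullEnsembleConfig
from glyconnect.pipeline import metrics_table
from glyconnect.stats import analyze_cohort, comparisons_frame, correlations_frame
from glyconnect.synthetic import SyntheticCohortConfig, gen_cohort, records_frame

cfg = SyntheticCohortConfig(seed=11)
matrices, records = gen_cohort(cfg)
rec_df = records_frame(records)
print(f"cohort: {len(matrices)} subjects, {cfg.n_nodes}-node connectomes")

mdf, _ = metrics_table(
    matrices,
    list(rec_df.subject_id),
    NullEnsembleConfig(n_null=50, seed=11),
    cohort_seed=11,
    n_restarts=20,
)
pd.set_option("display.float_format", lambda v: f"{v:.4g}")
print("\nper-group metric means (gamma/Q segregation, lambda/E integration):")
print(mdf.merge(rec_df).groupby("group")[["gamma", "Q", "lambda", "E", "sigma"]].mean())

comps, corrs = analyze_cohort(mdf, rec_df, n_perm=10_000, rng=11)
print("\ngroup comparisons (difference = patient - control; q = BH-FDR):")
print(comparisons_frame(comps)[["measure", "observed_diff", "p", "q"]])
print("\nglycemia partial correlations (controls: age, sex, edges, strength):")
cdf = correlations_frame(corrs)
print(cdf[["measure", "covariate", "r", "p", "q"]])

sig = cdf[cdf.q < 0.05]
print(
    "\nReading: integration is impaired in the patient group (lower E, longer"
    "\nlambda, q<0.05) and HbA1c tracks efficiency at r ~ -0.5. Because fewer"
    "\nshortcuts also raise clustering, the lattice-based generator shows a"
    "\nsmall opposite-sign segregation difference (gamma, Q) that can reach"
    "\nsignificance - see docs/methods.md; sigma, their ratio, does not."
    "\nSignificant correlation rows (q<0.05) above:",
    len(sig),
)
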