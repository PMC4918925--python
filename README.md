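# glyconnect

Structural brain-network analysis of glycemic control in type 2 diabetes,
as a tested, reusable Python library.

Chronic hyperglycemia damages cerebral white matter; because cortical
regions communicate through white-matter tracts, that damage should show up
in the *topology* of the structural connectome. `glyconnect` implements the
whole analysis chain used to ask that question with diffusion MRI:

1. **Diffusion tensors** — log-linear least-squares fit of the single-tensor
   model S = S₀·exp(−b·gᵀDg), and the scalar maps FA, MD, AD, RD.
2. **Deterministic tractography** — FACT-style streamline tracking with the
   standard stopping rules (FA > 0.2, turn < 30°, 20 seeds per voxel).
3. **Connectome construction** — streamline endpoints × a 144-region
   parcellation, a ≥3-streamline edge filter against false positives, and
   fiber-density weights (pair count / total streamline count) in a
   144×144 symmetric matrix.
4. **Graph measures** — segregation: Onnela weighted clustering C and
   Louvain modularity Q; integration: characteristic path length L and
   global efficiency E over reciprocal-weight distances d = 1/w.
5. **Null-model normalization** — γ = C/⟨C_null⟩ and λ = L/⟨L_null⟩ over
   1000 degree-preserving Maslov–Sneppen surrogates; small-worldness
   σ = γ/λ (σ > 1: clustered *and* well-integrated).
6. **Statistics** — 10,000-permutation two-sample tests with
   Benjamini–Hochberg FDR, and glycemia–network partial correlations
   (HbA1c, fasting plasma glucose) controlling age, sex, and the number and
   strength of connections.

No imaging data ship with the package. A first-class synthetic module
generates tensor phantoms (for the tractography path) and statistically
calibrated cohorts: two groups of 20 subjects whose connectomes are
weighted small-world graphs tuned so the *control* group matches published
healthy means (E ≈ 0.63×10⁻³, λ ≈ 1.41) and the *patient* group shows the
impaired-integration signature (E ≈ 0.59×10⁻³, λ ≈ 1.52) with glucose
covariates injected at stated partial-correlation strengths. See
`docs/methods.md` for the models, calibration, and what the synthetic world
does and does not emulate.

## Worked example

```bash
python examples/synthetic_cohort_analysis.py
```

generates the default calibrated cohort and prints (seed 11, 50-null
normalization):

```
per-group metric means (gamma/Q segregation, lambda/E integration):
         gamma      Q  lambda         E  sigma
group
control  8.253 0.7058   1.391 0.0006416  5.935
patient  8.652 0.7147   1.487 0.0006068  5.834

group comparisons (difference = patient - control; q = BH-FDR):
  measure  observed_diff         p        q
0   gamma         0.3982    0.0002   0.0005
1       Q       0.008889  0.007499 0.009374
2  lambda        0.09559    0.0003   0.0005
3       E     -3.484e-05 9.999e-05   0.0005
4   sigma        -0.1005    0.1909   0.1909

glycemia partial correlations (controls: age, sex, edges, strength):
  measure covariate       r        p       q
...
3       E     hba1c -0.4072   0.0137 0.06852
8       E       fpg -0.4232  0.01013 0.01688
```

Reading: the patient group has longer normalized path length (λ 1.49 vs
1.39) and lower global efficiency (0.61 vs 0.64 ×10⁻³) — impaired network
integration, each significant after FDR — while higher glucose tracks lower
efficiency at r ≈ −0.4 in this realization (the injected population value
is −0.53; single cohorts of n = 40 scatter around it with sd ≈ 0.12, which
is why the recovery tests average 200 replicates). The small opposite-sign
segregation difference (γ, Q) is a known side-effect of
lattice-plus-shortcut generators (fewer shortcuts ⇒ more clustering)
discussed in `docs/methods.md`; σ, the ratio, does not separate the groups.

Other examples, one per capability: `tensor_scalars_demo.py` (tensor fit →
FA/MD/AD/RD), `phantom_tractography.py` (phantom → tracking → connectome),
`null_normalization.py` (γ, λ, σ for one subject),
`calibration_demo.py` (the two calibration knobs).

There is no command-line tool; the library API plus
`glyconnect.pipeline.run(RunConfig(...))` (YAML-configurable, writes
metrics/results CSVs and a run manifest) is the interface.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes the pipeline's headline quantities from scratch (~8–12 minutes
on one CPU): it recalibrates the cohort generator to the published group
means, then measures (t5–t7) the mean recovered partial correlation between
synthetic glucose covariates and network integration measures over 200
cohort replicates of 40 subjects (HbA1c–efficiency, HbA1c–path-length,
FPG–efficiency), and (t8) the minimum small-worldness σ across the
calibrated 20-subject control ensemble with 100-null normalization. Results
are written as JSON, one entry per target.
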