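# Methods

`glyconnect` implements a structural brain-network analysis of poorly
controlled type 2 diabetes: from diffusion tensors and deterministic
tractography, through weighted connectome construction, to graph-theoretic
segregation/integration measures with null-model normalization, permutation
group tests and glycemia–network partial correlations. Because no imaging
data are distributed, a synthetic-cohort generator provides inputs carrying
the statistical structure the analysis assumes; this note documents the
models, the parameters that matter, and the limits of what a passing test
establishes.

## Diffusion model and scalar maps

The single-tensor model relates the diffusion-weighted signal along unit
gradient g at b-value b to the symmetric 3×3 tensor D (mm²/s):
S = S₀·exp(−b·gᵀDg). Tensors are fitted per voxel by ordinary log-linear
least squares — the conventional baseline estimator; no weighting or
positivity constraint is applied. Voxels with non-positive signals are
flagged invalid, get a zero tensor, and are excluded downstream. From the
sorted eigenvalues λ₁ ≥ λ₂ ≥ λ₃:

- MD = (λ₁+λ₂+λ₃)/3, AD = λ₁, RD = (λ₂+λ₃)/2
- FA = √(3/2)·‖λ − MD‖ / ‖λ‖ ∈ [0, 1]

Negative eigenvalues from noisy fits are clamped to 0 before the scalar
formulas (keeping FA in range); the all-zero tensor has FA = 0 by
convention. Phantom signals use a deterministic 30-direction Fibonacci
gradient scheme plus one b = 0 at b = 1000 s/mm²; noise, when requested, is
additive Gaussian (no Rician bias is modeled).

## Tractography

FACT-style deterministic tracking: bidirectional Euler integration along
the principal eigenvector of the nearest-neighbor voxel tensor, eigenvector
sign chosen to continue the previous heading. Defaults follow the study's
stopping rules: seed FA threshold and per-step stopping at FA ≤ 0.2, turn
angle ≥ 30° (measured between successive step directions), or volume exit;
20 uniformly random seeds per masked voxel. The step size is 0.5 × the
smallest voxel edge and streamlines shorter than 3 points (2 steps) are
discarded — both implementation choices, since the reference tool does not
state them. No tensor interpolation is performed; whether the turn
criterion should be per-step or cumulative is ambiguous in the source
tooling, and per-step is implemented.

## Connectome construction

Nodes are the regions of an integer parcellation (144 in the emulated
design); a streamline contributes one count to the unordered pair of labels
containing its two terminal points (terminal voxel only, no dilation;
background or same-region terminals are discarded). Pairs with fewer than
3 streamlines are zeroed to suppress false-positive connections. Surviving
counts are divided by the total streamline count of the whole-brain set —
counted before any thresholding or endpoint filtering, a literal reading of
"number of whole fiber tracts" — giving the fiber-density weight matrix:
symmetric, zero-diagonal, non-negative.

## Graph measures

Edge length is reciprocal weight, d = 1/w (the Brain Connectivity Toolbox
convention for fiber-density weights; weights are not rescaled first, which
is why efficiencies come out at the 10⁻³ scale). Per-source Dijkstra gives
the distance matrix; then

- characteristic path length L: mean finite off-diagonal distance
  (disconnected pairs excluded and counted);
- global efficiency E: mean of 1/d over ordered pairs with 1/∞ = 0 —
  defined even on disconnected graphs, which is why it is the more robust
  integration measure;
- clustering C: Onnela weighted clustering (geometric-mean triangle
  intensity, weights normalized by the matrix maximum, degree-<2 nodes
  contribute 0), averaged over nodes — the weighted generalization used by
  the BCT; scale-invariant by construction;
- modularity Q: weighted Newman modularity maximized by Louvain with 100
  seeded restarts, best-of, first-found tie-break; the returned Q is always
  re-evaluated with an independent closed-form evaluator.

Two scaling identities used throughout testing and calibration:
E(s·W) = s·E(W) and L(s·W) = L(W)/s for any s > 0.

## Null models and normalized measures

γ = C/⟨C_null⟩ and λ = L/⟨L_null⟩ over an ensemble of Maslov–Sneppen
surrogates (default 1000; degree sequence preserved exactly, weights travel
with swapped edges so the weight multiset is conserved; 10 swap attempts
per edge). Small-worldness is σ = γ/λ, an exact identity in the code.
Each subject gets an independent null ensemble seeded from
(cohort seed, subject id), so results do not depend on evaluation order.
Whether the original analysis used per-subject or shared ensembles is
unstated; per-subject is implemented. The ensemble path length uses a
jitted Dijkstra that is tested for exact agreement with the public
scipy-based route.

## Statistics

Group differences: two-sample permutation test on the difference of group
means, two-sided, 10,000 uniform label permutations, with +1 smoothing so
p is never 0. Benjamini–Hochberg FDR is applied across the family of five
global measures {γ, Q, λ, E, σ}; the correlation analyses form one
five-measure family per glucose variable (HbA1c, FPG). Families follow the
sets reported together; two-sided tests are used throughout even where the
findings are directional.

Associations are partial correlations: both the measure and the glucose
variable are residualized by least squares on an intercept plus age, sex
(0/1), connection count and total connection strength; r is the Pearson
correlation of residuals and p comes from t = r·√((n−2−k)/(1−r²)) on
n−2−k df. Rank-deficient control matrices are rejected naming the
collinear columns, except that the cohort-level driver drops zero-variance
control columns with a warning (identical matrices would otherwise make the
analysis un-runnable). Correlations default to all 40 subjects (the study's
wording suggests the whole population), switchable to patients only.

## Synthetic cohort: the stated world

Two groups of 20 subjects, matched in age (uniform 50–59 y, mirroring
54.3 ± 2.4 / 54.6 ± 2.3) and sex (9 males per 20, coded 0/1). Each
connectome is a Watts–Strogatz-style weighted graph on 144 nodes: a ring
lattice of degree 12, each edge rewired to a random shortcut with a
group-specific probability. Per-edge synthetic streamline counts are
log-normal integers (median 20, σ = 1.0 — the count distribution is a
modeling choice; the study states none) converted to fiber densities
(count/total) after the ≥3-count rule, then multiplied by a group weight
scale. About 3% of edges fall below the count threshold, so the edge filter
is exercised and per-subject connection counts vary naturally.

Group structure enters through exactly two knobs, both calibrated to the
printed group means rather than chosen freely:

- shortcut probability → normalized path length λ. Bisection against a
  coarse independent oracle (Floyd–Warshall distances, naive edge-swap
  nulls) to the targets λ = 1.41 (control) and 1.52 (patient).
- weight scale → global efficiency E. Since E is linear in the scale, the
  scale is solved analytically from a probe ensemble to the targets
  E = 0.63×10⁻³ (control) and 0.59×10⁻³ (patient).

The packaged defaults are the frozen output of this calibration
(`calibrated_config(seed=7)`): shortcut probabilities 0.0459/0.0312 and
weight scales 1.161/1.140. Re-running the calibrator reproduces them up to
probe sampling noise. Segregation parameters (lattice degree, count
distribution) are shared between groups, so γ and Q group differences are
approximately centered; note, however, that the lower patient shortcut
probability slightly *raises* patient clustering, a small segregation
side-effect opposite in sign to the (non-significant) trend in the
emulated study.

Glucose covariates: HbA1c (pooled 8.3 ± 2.5 %) and FPG (pooled 7.6 ± 2.6
mmol/L) are generated as r·z(metric) + √(1−r²)·noise, rescaled to the
stated mean/sd. Because the reported association strengths are *partial*
correlations (adjusted for age, sex, connection number and strength — and
total strength correlates ~0.6 with efficiency in this generator), the
metric is residualized on those controls before mixing, so the target is
injected on the scale on which it is reported. A finite-sample correction
scales the injected noise by 1/√(1−(k+1)/n): the recovery step
residualizes the covariate on the same k controls in-sample, removing
(k+1)/n of the noise variance and otherwise inflating the recovered
partial correlation by ≈5% at n = 40, k = 4 (closed form
r/√(r²+(1−r²)(1−(k+1)/n)), confirmed empirically). Default targets:
HbA1c–E −0.53 and FPG–E −0.41. The covariates are unimodal across the cohort; the
study's strong group separation in glucose values (5.9 vs 10.7 % HbA1c) is
not emulated — only the correlation structure the statistics consume.

What a green test does *not* establish: the generator has no spatial
embedding, no hemispheric or lobar organization, no distance-dependent
connection probability, no measurement noise model, and covariates with
purely linear dependence — so passing tests validate the computational
pipeline and its statistical calibration, not any neurobiological claim.

## Tensor phantoms

Piecewise-constant tensor fields on a voxel grid (regions as axis-aligned
boxes with a principal direction and eigenvalues; isotropic background),
simulated signals from the forward model, and an integer label volume for
terminal regions. These drive the end-to-end integration path
(phantom → fit → track → connectome), kept deliberately small; the
statistics-level tests run on directly generated connectomes for speed.

## Numerical choices and degenerate inputs

- Distances: explicit zeros are absent edges; unreachable pairs are +∞.
- L on a graph with no finite pair is an error; E is 0 on an edgeless graph.
- Permutation test returns p = 1 for constant inputs; BH on an empty list
  returns an empty list.
- Rewiring a graph with <2 edges returns it unchanged with a warning.
- γ is undefined (error) if the null-mean clustering is 0.
- All randomness flows from explicit numpy Generators; identical seeds give
  bit-identical cohorts, metrics and result files (CSV floats are written
  as %.17g and parsed round-trip).

## Known limitations

- Deterministic tracking with nearest-neighbor lookup only; no
  interpolation, no probabilistic variant.
- No eddy-current/motion preprocessing, coregistration or parcellation
  machinery: label volumes are inputs.
- Louvain is a heuristic; on ≤8-node graphs it reaches the exhaustive
  optimum in ≥95% of seeded runs (tested), but global optimality is not
  guaranteed at 144 nodes.
- The voxelwise skeleton-based (TBSS/TFCE) analyses of the emulated study
  are out of scope.
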