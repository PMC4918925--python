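"""Synthetic cohorts, covariates and tensor phantoms.

No imaging data ship with this package; instead the generator emulates
the statistical world the analysis assumes: two groups of 20 subjects,
144-node weighted connectomes with small-world topology (ring lattice
plus random shortcuts, Watts–Strogatz style), integer per-edge
streamline counts converted to fiber-density weights, and glucose
covariates correlated with integration measures at chosen strengths.

Group structure is injected through two knobs only:

- ``shortcut_prob``: fewer shortcuts -> longer normalized path length
  (lower integration); calibrated per group by bisection against a
  coarse Floyd–Warshall oracle.
- ``weight_scale``: global efficiency is linear in the weight scale
  (distances are reciprocal weights), so the scale is calibrated
  analytically to the target group mean efficiency.

Segregation parameters (lattice degree, count distribution) are shared
between groups, so clustering and modularity differences are centered at
zero by construction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import floyd_warshall

from .connectome import ConnectivityMatrix, density_from_counts
from .diffusion import TensorVolume
from .connectome import LabelVolume
from .metrics import global_efficiency
from .stats import SubjectRecord

# Group mean targets used by the default calibration: control/patient
# global efficiency (weight units) and normalized path length.
TARGET_E = {"control": 0.63e-3, "patient": 0.59e-3}
TARGET_LAMBDA = {"control": 1.41, "patient": 1.52}


@dataclass
class SyntheticCohortConfig:
    """Stated world of the synthetic cohort.

    Defaults reproduce the study design: two groups of 20, 144 regions,
    small-world topology whose shortcut probabilities and weight scales
    were set by the packaged calibrators (`calibrated_config`) to the
    target group means above. Covariates: HbA1c in %, FPG in mmol/L at
    pooled cohort means; target correlations against global efficiency.
    """

    n_per_group: int = 20
    n_nodes: int = 144
    lattice_degree: int = 12
    # shortcut probabilities / weight scales below are the output of
    # calibrated_config(seed=7): bisection to the target normalized path
    # lengths, then analytic scaling to the target efficiencies.
    shortcut_prob_control: float = 0.0459
    shortcut_prob_patient: float = 0.0312
    weight_scale_control: float = 1.161
    weight_scale_patient: float = 1.140
    weight_dispersion: float = 1.0  # log-normal sigma of streamline counts
    median_streamlines: float = 20.0  # log-normal median of per-edge counts
    min_streamlines: int = 3
    cov_corr: dict = field(
        default_factory=lambda: {"E": {"hba1c": -0.53, "fpg": -0.41}}
    )
    hba1c_mean: float = 8.3
    hba1c_sd: float = 2.5
    fpg_mean: float = 7.6
    fpg_sd: float = 2.6
    age_range: tuple[float, float] = (50.0, 59.0)
    seed: int = 0

    def __post_init__(self):
        if self.lattice_degree % 2 or self.lattice_degree <= 0:
            raise ValueError("lattice_degree must be a positive even count")
        if self.n_nodes < self.lattice_degree + 1:
            raise ValueError(
                f"n_nodes={self.n_nodes} too small for lattice_degree="
                f"{self.lattice_degree}; need n_nodes >= lattice_degree + 1"
            )
        for p in (self.shortcut_prob_control, self.shortcut_prob_patient):
            if not 0.0 <= p <= 1.0:
                raise ValueError("shortcut probabilities must lie in [0, 1]")
        if min(self.weight_scale_control, self.weight_scale_patient) <= 0:
            raise ValueError("weight scales must be positive")
        if self.weight_dispersion < 0:
            raise ValueError("weight_dispersion must be >= 0")


def _ws_adjacency(n: int, k: int, p: float, rng: np.random.Generator) -> np.ndarray:
    """Watts–Strogatz topology: ring lattice, each edge rewired with prob p."""
    adj = np.zeros((n, n), dtype=bool)
    for off in range(1, k // 2 + 1):
        for i in range(n):
            j = (i + off) % n
            adj[i, j] = adj[j, i] = True
    for off in range(1, k // 2 + 1):
        for i in range(n):
            j = (i + off) % n
            if rng.random() < p and adj[i, j]:
                choices = np.flatnonzero(~adj[i] & (np.arange(n) != i))
                if choices.size == 0:
                    continue
                new_j = int(rng.choice(choices))
                adj[i, j] = adj[j, i] = False
                adj[i, new_j] = adj[new_j, i] = True
    return adj


def _subject_matrix(
    cfg: SyntheticCohortConfig, group: str, rng: np.random.Generator
) -> ConnectivityMatrix:
    p = cfg.shortcut_prob_control if group == "control" else cfg.shortcut_prob_patient
    scale = (
        cfg.weight_scale_control if group == "control" else cfg.weight_scale_patient
    )
    adj = _ws_adjacency(cfg.n_nodes, cfg.lattice_degree, p, rng)
    iu, ju = np.nonzero(np.triu(adj, 1))
    if cfg.weight_dispersion > 0:
        counts = np.rint(
            np.exp(rng.normal(np.log(cfg.median_streamlines), cfg.weight_dispersion, iu.size))
        ).astype(int)
    else:
        counts = np.full(iu.size, int(round(cfg.median_streamlines)))
    counts = np.maximum(counts, 0)
    cmat = np.zeros((cfg.n_nodes, cfg.n_nodes), dtype=int)
    cmat[iu, ju] = counts
    cmat = cmat + cmat.T
    total = int(counts.sum())
    w = density_from_counts(cmat, total, cfg.min_streamlines) * scale
    names = [f"region_{i + 1}" for i in range(cfg.n_nodes)]
    return ConnectivityMatrix(weights=w, region_names=names, total_streamlines=total)


def gen_covariates(
    metric_values: np.ndarray,
    target_r: float,
    rng: np.random.Generator | int | None = None,
    mean: float = 0.0,
    sd: float = 1.0,
    controls: np.ndarray | None = None,
) -> np.ndarray:
    """Covariate with population correlation ``target_r`` to a metric.

    covariate = r * z(metric) + sqrt(1-r^2) * noise, rescaled to the given
    mean and sd; noise is independent standard normal.

    The study's association strengths are partial correlations, adjusted
    for age, sex and connection number/strength.  When ``controls`` is
    given (n x k), the metric is residualized on [1, controls] before the
    mixing, so ``target_r`` is injected as the *partial* correlation given
    those controls.  The noise is scaled up by 1/sqrt(1-(k+1)/n) to offset
    the variance the recovery step removes when it residualizes the
    covariate on the same controls in-sample; without the correction the
    recovered partial correlation is inflated by ~5% at n=40, k=4.
    Without ``controls`` the marginal correlation is targeted.
    """
    v = np.asarray(metric_values, dtype=float)
    if v.size < 3:
        raise ValueError("need >= 3 subjects")
    if not abs(target_r) < 1:
        raise ValueError("|target_r| must be < 1")
    if v.std() == 0:
        raise ValueError("metric values have zero variance")
    noise_var = 1.0 - target_r**2
    if controls is not None:
        z = np.atleast_2d(np.asarray(controls, dtype=float))
        if z.shape[0] != v.size:
            z = z.T
        design = np.column_stack([np.ones(v.size), z])
        if v.size <= design.shape[1] + 1:
            raise ValueError("need n > k+2 subjects to inject a partial correlation")
        beta, *_ = np.linalg.lstsq(design, v, rcond=None)
        v = v - design @ beta
        if v.std() == 0:
            raise ValueError("metric values fully explained by controls")
        noise_var /= 1.0 - design.shape[1] / v.size
    rng = np.random.default_rng(rng)
    z = (v - v.mean()) / v.std()
    raw = target_r * z + np.sqrt(noise_var) * rng.standard_normal(v.size)
    return mean + sd * (raw - raw.mean()) / raw.std()


def gen_cohort(
    config: SyntheticCohortConfig,
) -> tuple[list[ConnectivityMatrix], list[SubjectRecord]]:
    """Generate the two-group cohort: connectomes plus subject records.

    Deterministic in ``config.seed``; all randomness flows from one
    generator.  Glucose covariates are generated cohort-wide against the
    per-subject metric named in ``config.cov_corr`` (global efficiency
    "E" or raw path length "L") at the configured target correlations.
    """
    rng = np.random.default_rng(config.seed)
    matrices: list[ConnectivityMatrix] = []
    groups: list[str] = []
    ids: list[str] = []
    for group, tag in (("control", "c"), ("patient", "p")):
        for i in range(config.n_per_group):
            matrices.append(_subject_matrix(config, group, rng))
            groups.append(group)
            ids.append(f"{tag}{i + 1:02d}")

    n_total = 2 * config.n_per_group
    ages = rng.uniform(*config.age_range, size=n_total)
    # sex balanced within group: 9 males per 20 subjects, as in the cohort
    n_male = int(round(config.n_per_group * 9 / 20))
    sexes = np.concatenate(
        [
            rng.permutation(
                np.r_[np.ones(n_male, dtype=int),
                      np.zeros(config.n_per_group - n_male, dtype=int)]
            )
            for _ in range(2)
        ]
    )

    metric_cache: dict[str, np.ndarray] = {}

    def metric_vector(name: str) -> np.ndarray:
        if name not in metric_cache:
            if name == "E":
                metric_cache[name] = np.array(
                    [global_efficiency(m.weights) for m in matrices]
                )
            elif name == "L":
                from .metrics import char_path_length

                metric_cache[name] = np.array(
                    [char_path_length(m.weights) for m in matrices]
                )
            else:
                raise ValueError(f"unsupported covariate-driving metric {name!r}")
        return metric_cache[name]

    # the targets are partial correlations: inject them given the same
    # controls the statistics adjust for
    controls = np.column_stack(
        [
            ages,
            sexes,
            [(m.weights > 0).sum() // 2 for m in matrices],
            [m.weights.sum() / 2.0 for m in matrices],
        ]
    )
    cov_values = {
        "hba1c": rng.normal(config.hba1c_mean, config.hba1c_sd, n_total),
        "fpg": rng.normal(config.fpg_mean, config.fpg_sd, n_total),
    }
    seen: set[str] = set()
    for measure, targets in config.cov_corr.items():
        mv = metric_vector(measure)
        for cov_name, r in targets.items():
            if cov_name in seen:
                raise ValueError(f"covariate {cov_name!r} driven by two measures")
            seen.add(cov_name)
            mean, sd = (
                (config.hba1c_mean, config.hba1c_sd)
                if cov_name == "hba1c"
                else (config.fpg_mean, config.fpg_sd)
            )
            try:
                cov_values[cov_name] = gen_covariates(
                    mv, r, rng, mean=mean, sd=sd, controls=controls
                )
            except ValueError as exc:
                # degenerate world (e.g. all subjects identical): keep the
                # baseline uncorrelated covariate
                warnings.warn(
                    f"covariate {cov_name!r} left uncorrelated with {measure}: {exc}"
                )

    records = [
        SubjectRecord(
            subject_id=ids[i],
            group=groups[i],
            age=float(ages[i]),
            sex=int(sexes[i]),
            hba1c=float(cov_values["hba1c"][i]),
            fpg=float(cov_values["fpg"][i]),
        )
        for i in range(n_total)
    ]
    return matrices, records


# ---------------------------------------------------------------------------
# Calibration against target group means
# ---------------------------------------------------------------------------

def calibrate_weight_scale(base_matrix: ConnectivityMatrix, target_E: float) -> float:
    """Scale factor s with E(s * W) = target_E, using E(sW) = s E(W)."""
    if target_E <= 0:
        raise ValueError("target_E must be positive")
    e = global_efficiency(base_matrix.weights)
    if e == 0:
        raise ValueError("base matrix has zero efficiency (disconnected)")
    return target_E / e


def _oracle_L(w: np.ndarray) -> float:
    """Coarse oracle path length: Floyd–Warshall mean finite distance."""
    i, j = np.nonzero(w)
    d = floyd_warshall(csr_matrix((1.0 / w[i, j], (i, j)), shape=w.shape),
                       directed=False)
    off = ~np.eye(w.shape[0], dtype=bool)
    finite = np.isfinite(d) & off
    return float(d[finite].mean())


def _oracle_null_L(w: np.ndarray, rng: np.random.Generator, swaps_per_edge: int = 5) -> float:
    """Coarse oracle null: naive double-edge swaps, then Floyd–Warshall L."""
    iu, ju = np.nonzero(np.triu(w, 1))
    edges = list(zip(iu.tolist(), ju.tolist()))
    weights = list(w[iu, ju])
    present = {frozenset(e) for e in edges}
    n_edges = len(edges)
    for _ in range(swaps_per_edge * n_edges):
        i1, i2 = rng.integers(0, n_edges, size=2)
        if i1 == i2:
            continue
        a, b = edges[i1]
        c, d = edges[i2]
        if rng.random() < 0.5:
            c, d = d, c
        if len({a, b, c, d}) < 4:
            continue
        if frozenset((a, d)) in present or frozenset((c, b)) in present:
            continue
        present -= {frozenset((a, b)), frozenset((c, d))}
        present |= {frozenset((a, d)), frozenset((c, b))}
        edges[i1], edges[i2] = (a, d), (c, b)
    wn = np.zeros_like(w)
    for (a, b), wt in zip(edges, weights):
        wn[a, b] = wn[b, a] = wt
    return _oracle_L(wn)


def _probe_lambda(
    cfg: SyntheticCohortConfig,
    p: float,
    n_null: int,
    n_probe: int,
    rng: np.random.Generator,
) -> float:
    """Mean normalized path length of a probe ensemble, by the coarse oracle."""
    probe_cfg = replace(cfg, shortcut_prob_control=p)
    lams = []
    for _ in range(n_probe):
        m = _subject_matrix(probe_cfg, "control", rng)
        L = _oracle_L(m.weights)
        null_L = np.mean([_oracle_null_L(m.weights, rng) for _ in range(n_null)])
        lams.append(L / null_L)
    return float(np.mean(lams))


def calibrate_shortcut_prob(
    target_lambda: float,
    config: SyntheticCohortConfig,
    n_null: int = 20,
    n_probe: int = 8,
    tol: float = 0.02,
    max_iter: int = 12,
    rng: np.random.Generator | int | None = None,
) -> float:
    """Shortcut probability whose ensemble-mean normalized path length
    matches ``target_lambda``, by bisection against the coarse oracle.

    lambda decreases monotonically in the shortcut probability: p = 1 is a
    fully randomized graph (lambda ~ 1) and p = 0 the bare ring lattice
    (maximal lambda).  Raises when the target is outside the achievable
    range for the configured lattice.
    """
    if target_lambda < 1.0 - tol:
        raise ValueError("target_lambda must be >= 1")
    rng = np.random.default_rng(config.seed if rng is None else rng)
    lam_hi = _probe_lambda(config, 1.0, n_null, n_probe, rng)
    lam_lo = _probe_lambda(config, 0.0, n_null, n_probe, rng)
    if not (lam_hi - tol <= target_lambda <= lam_lo + tol):
        raise ValueError(
            f"target lambda {target_lambda} outside achievable range "
            f"[{lam_hi:.3f}, {lam_lo:.3f}] for this lattice"
        )
    lo_p, hi_p = 0.0, 1.0  # lambda(lo_p) >= target >= lambda(hi_p)
    p = 0.5
    for _ in range(max_iter):
        p = 0.5 * (lo_p + hi_p)
        lam = _probe_lambda(config, p, n_null, n_probe, rng)
        if abs(lam - target_lambda) <= tol:
            return p
        if lam > target_lambda:
            lo_p = p
        else:
            hi_p = p
    return p


def calibrated_config(
    seed: int = 0,
    n_null: int = 10,
    n_probe: int = 6,
    n_scale_probe: int = 16,
    base: SyntheticCohortConfig | None = None,
) -> SyntheticCohortConfig:
    """Recalibrate shortcut probabilities and weight scales at run time.

    Bisection sets each group's shortcut probability to its target
    normalized path length; the weight scale is then set analytically so
    the probe-ensemble mean efficiency hits the target group mean.
    """
    cfg = base or SyntheticCohortConfig(seed=seed)
    cfg = replace(cfg, seed=seed)
    rng = np.random.default_rng(seed)
    probs = {}
    scales = {}
    for group in ("control", "patient"):
        p = calibrate_shortcut_prob(
            TARGET_LAMBDA[group], cfg, n_null=n_null, n_probe=n_probe, rng=rng
        )
        probs[group] = p
        probe_cfg = replace(cfg, shortcut_prob_control=p, weight_scale_control=1.0)
        es = [
            global_efficiency(_subject_matrix(probe_cfg, "control", rng).weights)
            for _ in range(n_scale_probe)
        ]
        scales[group] = TARGET_E[group] / float(np.mean(es))
    return replace(
        cfg,
        shortcut_prob_control=probs["control"],
        shortcut_prob_patient=probs["patient"],
        weight_scale_control=scales["control"],
        weight_scale_patient=scales["patient"],
    )


# ---------------------------------------------------------------------------
# Tensor phantom
# ---------------------------------------------------------------------------

@dataclass
class PhantomRegion:
    """One block of the piecewise tensor field, in voxel index ranges."""

    bbox: tuple  # ((x0, x1), (y0, y1), (z0, z1)), half-open voxel ranges
    direction: tuple = (1.0, 0.0, 0.0)
    eigvals: tuple = (1.7e-3, 0.3e-3, 0.2e-3)
    label: int = 0  # nonzero marks a terminal region in the label volume


@dataclass
class TensorPhantomConfig:
    grid_shape: tuple = (20, 10, 10)
    voxel_size: tuple = (2.0, 2.0, 2.0)
    field_spec: list = field(default_factory=list)
    background_eigvals: tuple = (0.7e-3, 0.7e-3, 0.7e-3)
    noise_sd: float = 0.0
    s0: float = 1000.0
    b_value: float = 1000.0
    n_directions: int = 30
    seed: int = 0

    def __post_init__(self):
        if min(self.grid_shape) <= 0:
            raise ValueError("grid_shape must be positive")
        specs = list(self.field_spec) + [
            PhantomRegion(bbox=None, eigvals=self.background_eigvals)
        ]
        for s in specs:
            if min(s.eigvals) < 0:
                raise ValueError("requested tensor eigenvalues must be non-negative")


@dataclass
class Phantom:
    tensors: TensorVolume
    labels: LabelVolume
    signals: np.ndarray  # grid + (n_measurements,)
    b_values: np.ndarray
    b_vectors: np.ndarray


def fibonacci_directions(n: int) -> np.ndarray:
    """n roughly uniform unit vectors on the sphere (deterministic)."""
    i = np.arange(n) + 0.5
    phi = np.arccos(1 - 2 * i / n)
    theta = np.pi * (1 + 5**0.5) * i
    return np.column_stack(
        [np.sin(phi) * np.cos(theta), np.sin(phi) * np.sin(theta), np.cos(phi)]
    )


def _rotation_to(direction: np.ndarray) -> np.ndarray:
    """Rotation matrix taking the x-axis to ``direction``."""
    d = np.asarray(direction, dtype=float)
    d = d / np.linalg.norm(d)
    helper = np.array([0.0, 0.0, 1.0]) if abs(d[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(d, helper)
    u /= np.linalg.norm(u)
    v = np.cross(d, u)
    return np.column_stack([d, u, v])


def gen_tensor_phantom(config: TensorPhantomConfig) -> Phantom:
    """Piecewise-constant tensor field, labels, and simulated DW signals.

    Signals follow the single-tensor model S_k = S0 exp(-b g_k^T D g_k)
    on a b=0 plus n-direction gradient table, with optional additive
    Gaussian noise.
    """
    rng = np.random.default_rng(config.seed)
    shape = tuple(config.grid_shape)
    d6 = np.empty(shape + (6,))
    labels = np.zeros(shape, dtype=int)

    def tensor6(direction, eigvals) -> np.ndarray:
        r = _rotation_to(direction)
        m = r @ np.diag(eigvals) @ r.T
        return np.array([m[0, 0], m[1, 1], m[2, 2], m[0, 1], m[0, 2], m[1, 2]])

    d6[...] = tensor6((1, 0, 0), config.background_eigvals)
    for region in config.field_spec:
        (x0, x1), (y0, y1), (z0, z1) = region.bbox
        sl = (slice(x0, x1), slice(y0, y1), slice(z0, z1))
        d6[sl] = tensor6(region.direction, region.eigvals)
        if region.label:
            labels[sl] = region.label

    tensors = TensorVolume(data=d6, voxel_size=tuple(config.voxel_size))
    g = np.vstack([[0.0, 0.0, 0.0], fibonacci_directions(config.n_directions)])
    b = np.r_[0.0, np.full(config.n_directions, config.b_value)]
    # g^T D g for each voxel and direction
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    quad = (
        d6[..., 0][..., None] * gx**2
        + d6[..., 1][..., None] * gy**2
        + d6[..., 2][..., None] * gz**2
        + 2 * d6[..., 3][..., None] * gx * gy
        + 2 * d6[..., 4][..., None] * gx * gz
        + 2 * d6[..., 5][..., None] * gy * gz
    )
    signals = config.s0 * np.exp(-b * quad)
    if config.noise_sd > 0:
        signals = signals + rng.normal(0.0, config.noise_sd, signals.shape)
        signals = np.clip(signals, 1e-6, None)
    label_vol = LabelVolume(data=labels, voxel_size=tuple(config.voxel_size))
    return Phantom(tensors, label_vol, signals, b, g)


# ---------------------------------------------------------------------------
# Cohort file contracts
# ---------------------------------------------------------------------------

def records_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "subject_id": r.subject_id,
                "group": r.group,
                "age": r.age,
                "sex": r.sex,
                "hba1c": r.hba1c,
                "fpg": r.fpg,
            }
            for r in records
        ]
    )


def write_cohort(matrices, records, outdir) -> None:
    """One CSV per subject matrix plus a cohort covariates CSV."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for m, r in zip(matrices, records):
        m.to_csv(outdir / f"{r.subject_id}_connectome.csv")
    records_frame(records).to_csv(outdir / "covariates.csv", index=False)


def load_cohort(indir) -> tuple[list[ConnectivityMatrix], pd.DataFrame]:
    from pathlib import Path

    indir = Path(indir)
    records = pd.read_csv(indir / "covariates.csv", float_precision="round_trip")
    matrices = [
        ConnectivityMatrix.from_csv(indir / f"{sid}_connectome.csv")
        for sid in records["subject_id"]
    ]
    return matrices, records
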