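"""Group comparison and glycemia–network association statistics.

Two-sample permutation tests (difference of group means, two-sided,
10,000 label permutations) compare each global network measure between
patients and controls, with Benjamini–Hochberg FDR correction across the
family of five measures.  Associations between network measures and
glucose variables (HbA1c, FPG) are covariate-adjusted partial
correlations: both variables are residualized on age, sex, and the number
and strength of network connections before computing Pearson r.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
import warnings

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

GLOBAL_MEASURES = ("gamma", "Q", "lambda", "E", "sigma")
GLUCOSE_VARS = ("hba1c", "fpg")
CONTROL_VARS = ("age", "sex", "n_edges", "total_strength")


@dataclass
class SubjectRecord:
    """Group label and covariates of one participant."""

    subject_id: str
    group: str  # "control" or "patient"
    age: float
    sex: int  # 0/1
    hba1c: float  # %
    fpg: float  # mmol/L


@dataclass
class GroupComparisonResult:
    measure: str
    mean_control: float
    sd_control: float
    mean_patient: float
    sd_patient: float
    observed_diff: float  # patient - control
    p: float
    q: float = np.nan


@dataclass
class CorrelationResult:
    measure: str
    covariate: str
    r: float
    p: float
    n: int
    controlled: tuple
    q: float = np.nan


def permutation_test(
    values: np.ndarray,
    groups: np.ndarray,
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float]:
    """Two-sided two-sample permutation test on the difference of means.

    Returns (observed difference second-group-minus-first, p).  p uses the
    +1 smoothing convention, p = (1 + #{|diff*| >= |diff|}) / (1 + n_perm),
    so it is never exactly 0.  Constant inputs give p = 1.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    labels = pd.unique(groups)
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 groups, got {list(labels)}")
    mask = groups == labels[1]
    n1, n0 = int(mask.sum()), int((~mask).sum())
    if min(n0, n1) < 2:
        raise ValueError("each group needs >= 2 subjects")
    obs = values[mask].mean() - values[~mask].mean()
    if np.ptp(values) == 0:
        return float(obs), 1.0
    rng = np.random.default_rng(rng)
    # vectorized label permutations: choose n1 indices per permutation
    perm_idx = np.argsort(rng.random((n_perm, values.size)), axis=1)[:, :n1]
    perm_sum1 = values[perm_idx].sum(axis=1)
    total = values.sum()
    diffs = perm_sum1 / n1 - (total - perm_sum1) / n0
    p = (1.0 + np.count_nonzero(np.abs(diffs) >= abs(obs) - 1e-12)) / (1.0 + n_perm)
    return float(obs), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini–Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def partial_correlation(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None = None
) -> tuple[float, float]:
    """Partial Pearson correlation of x and y given covariates.

    Both variables are residualized on [1, covariates] by least squares;
    r is the Pearson correlation of the residuals and p comes from
    t = r*sqrt((n-2-k)/(1-r^2)) on n-2-k degrees of freedom (two-sided),
    k the number of covariates.  With no covariates this reduces to the
    plain Pearson correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if covariates is None:
        z = np.empty((n, 0))
    else:
        z = np.atleast_2d(np.asarray(covariates, dtype=float))
        if z.shape[0] != n:
            z = z.T
    k = z.shape[1]
    if n <= k + 2:
        raise ValueError(f"need n > k+2 subjects (n={n}, k={k})")
    design = np.column_stack([np.ones(n), z])
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        bad = [
            str(j - 1)
            for j in range(1, design.shape[1])
            if np.linalg.matrix_rank(np.delete(design, j, axis=1)) == rank
        ]
        raise ValueError(f"rank-deficient covariates (collinear columns: {bad})")
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    r = float(np.corrcoef(rx, ry)[0, 1])
    dof = n - 2 - k
    r_ = np.clip(r, -1 + 1e-15, 1 - 1e-15)
    t = r_ * np.sqrt(dof / (1.0 - r_**2))
    p = float(2 * sps.t.sf(abs(t), dof))
    return r, p


def analyze_cohort(
    metrics: pd.DataFrame,
    records: pd.DataFrame,
    n_perm: int = 10_000,
    rng: np.random.Generator | int | None = None,
    correlation_subjects: str = "all",
) -> tuple[list[GroupComparisonResult], list[CorrelationResult]]:
    """Full statistical analysis of a cohort.

    ``metrics`` has one row per subject (subject_id, gamma, Q, lambda, E,
    sigma, n_edges, total_strength); ``records`` carries subject_id,
    group, age, sex, hba1c, fpg.  Group permutation tests run on the five
    global measures with BH-FDR across that family; partial correlations
    of each measure with HbA1c and FPG control for age, sex, edge count
    and total strength, BH-FDR within each glucose variable's family of
    five.  ``correlation_subjects`` is "all" (default) or "patient".
    """
    rng = np.random.default_rng(rng)
    missing = set(metrics["subject_id"]).symmetric_difference(records["subject_id"])
    if missing:
        raise ValueError(f"subject ids do not match between tables: {sorted(missing)}")
    df = metrics.merge(records, on="subject_id", validate="1:1")

    comparisons: list[GroupComparisonResult] = []
    is_patient = df["group"].to_numpy() == "patient"
    for m in GLOBAL_MEASURES:
        v = df[m].to_numpy(dtype=float)
        obs, p = permutation_test(
            v, np.where(is_patient, "patient", "control"), n_perm=n_perm, rng=rng
        )
        comparisons.append(
            GroupComparisonResult(
                measure=m,
                mean_control=v[~is_patient].mean(),
                sd_control=v[~is_patient].std(ddof=1),
                mean_patient=v[is_patient].mean(),
                sd_patient=v[is_patient].std(ddof=1),
                observed_diff=v[is_patient].mean() - v[~is_patient].mean(),
                p=p,
            )
        )
    qs = bh_fdr([c.p for c in comparisons])
    for c, q in zip(comparisons, qs):
        c.q = float(q)

    sub = df[df["group"] == "patient"] if correlation_subjects == "patient" else df
    controls = list(CONTROL_VARS)
    zvar = sub[controls].to_numpy(dtype=float)
    keep = [i for i in range(zvar.shape[1]) if np.ptp(zvar[:, i]) > 0]
    if len(keep) < len(controls):
        dropped = [controls[i] for i in range(len(controls)) if i not in keep]
        warnings.warn(f"dropping zero-variance control columns: {dropped}")
        controls = [controls[i] for i in keep]
        zvar = zvar[:, keep]

    correlations: list[CorrelationResult] = []
    for g in GLUCOSE_VARS:
        fam: list[CorrelationResult] = []
        for m in GLOBAL_MEASURES:
            r, p = partial_correlation(
                sub[m].to_numpy(dtype=float), sub[g].to_numpy(dtype=float), zvar
            )
            fam.append(
                CorrelationResult(
                    measure=m, covariate=g, r=r, p=p, n=len(sub),
                    controlled=tuple(controls),
                )
            )
        for res, q in zip(fam, bh_fdr([f.p for f in fam])):
            res.q = float(q)
        correlations.extend(fam)
    return comparisons, correlations


def comparisons_frame(results: list[GroupComparisonResult]) -> pd.DataFrame:
    return pd.DataFrame([asdict(r) for r in results])


def correlations_frame(results: list[CorrelationResult]) -> pd.DataFrame:
    df = pd.DataFrame([asdict(r) for r in results])
    df["controlled"] = df["controlled"].map(lambda t: ";".join(t))
    return df
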