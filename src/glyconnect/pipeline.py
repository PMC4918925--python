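"""End-to-end orchestration: stage graph, file contracts, run manifest.

Four modes tie the stages together:

- ``synthetic-cohort``: generate a calibrated cohort, compute raw and
  null-normalized metrics per subject, run the group and correlation
  statistics, write all result files.
- ``from-matrices``: same, starting from connectome CSVs + covariates CSV.
- ``from-streamlines``: build a connectome from a streamline file and a
  label volume, then metrics.
- ``phantom-e2e``: tensor phantom -> tensor fit -> tracking -> connectome,
  the small integration path.

Every run writes a manifest (config echo, seed, package versions, stage
timings, warnings); identical config + seed gives byte-identical outputs.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .connectome import ConnectivityMatrix, LabelVolume, build_matrix
from .diffusion import fit_tensor, tensor_scalars
from .metrics import compute_metrics
from .nulls import NullEnsembleConfig, normalize_metrics
from .stats import analyze_cohort, comparisons_frame, correlations_frame
from .synthetic import (
    SyntheticCohortConfig,
    TensorPhantomConfig,
    gen_cohort,
    gen_tensor_phantom,
    records_frame,
    write_cohort,
)
from .tractography import TrackingConfig, load_streamlines_tsv, load_trk, track_all

MODES = ("synthetic-cohort", "from-matrices", "from-streamlines", "phantom-e2e")


@dataclass
class RunConfig:
    mode: str = "synthetic-cohort"
    output_dir: str = "glyconnect_run"
    seed: int = 0
    n_perm: int = 10_000
    modularity_restarts: int = 100
    null: NullEnsembleConfig = field(default_factory=NullEnsembleConfig)
    cohort: SyntheticCohortConfig = field(default_factory=SyntheticCohortConfig)
    tracking: TrackingConfig = field(default_factory=TrackingConfig)
    phantom: TensorPhantomConfig = field(default_factory=TensorPhantomConfig)
    # inputs for file-driven modes
    matrices_dir: str | None = None
    streamlines_path: str | None = None
    labels_path: str | None = None

    def __post_init__(self):
        if self.mode not in MODES:
            raise ValueError(f"mode must be one of {MODES}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if None in raw:  # YAML parses the bare key `null:` as None
            raw["null"] = raw.pop(None)
        for key, typ in (
            ("null", NullEnsembleConfig),
            ("cohort", SyntheticCohortConfig),
            ("tracking", TrackingConfig),
            ("phantom", TensorPhantomConfig),
        ):
            if key in raw and isinstance(raw[key], dict):
                sub = raw[key]
                if "cov_corr" not in sub and typ is SyntheticCohortConfig:
                    pass
                if "age_range" in sub:
                    sub["age_range"] = tuple(sub["age_range"])
                raw[key] = typ(**sub)
        return cls(**raw)


def _check_inputs(config: RunConfig) -> None:
    missing = []
    if config.mode == "from-matrices":
        d = config.matrices_dir
        if d is None or not Path(d).is_dir():
            missing.append(f"matrices_dir: {d}")
        elif not (Path(d) / "covariates.csv").exists():
            missing.append(f"{d}/covariates.csv")
    if config.mode == "from-streamlines":
        for label, p in (
            ("streamlines_path", config.streamlines_path),
            ("labels_path", config.labels_path),
        ):
            if p is None or not Path(p).exists():
                missing.append(f"{label}: {p}")
    if missing:
        raise FileNotFoundError("missing inputs: " + "; ".join(missing))


def _subject_null_seed(cohort_seed: int, subject_id: str) -> int:
    """Stable per-subject null seed; independent of evaluation order."""
    h = 0
    for ch in f"{cohort_seed}:{subject_id}":
        h = (h * 131 + ord(ch)) % (2**31 - 1)
    return h


def metrics_table(
    matrices: list[ConnectivityMatrix],
    subject_ids: list[str],
    null_cfg: NullEnsembleConfig,
    cohort_seed: int = 0,
    n_restarts: int = 100,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-subject raw + normalized metrics, and the null-ensemble summary."""
    from .nulls import null_distribution

    rows, null_rows = [], []
    for m, sid in zip(matrices, subject_ids):
        met = compute_metrics(m.weights, n_restarts=n_restarts)
        cfg = NullEnsembleConfig(
            n_null=null_cfg.n_null,
            swaps_per_edge=null_cfg.swaps_per_edge,
            seed=_subject_null_seed(cohort_seed, sid),
        )
        c_null, l_null = null_distribution(m.weights, cfg)
        met.gamma = met.C_raw / c_null.mean()
        met.lam = met.L_raw / l_null.mean()
        met.sigma = met.gamma / met.lam
        rows.append({"subject_id": sid, **met.as_dict()})
        null_rows.append(
            {
                "subject_id": sid,
                "C_null_mean": c_null.mean(),
                "C_null_sd": c_null.std(ddof=1) if len(c_null) > 1 else 0.0,
                "L_null_mean": l_null.mean(),
                "L_null_sd": l_null.std(ddof=1) if len(l_null) > 1 else 0.0,
                "n_null": cfg.n_null,
            }
        )
    return pd.DataFrame(rows), pd.DataFrame(null_rows)


def run(config: RunConfig) -> dict:
    """Execute the configured stage graph; returns the run manifest."""
    _check_inputs(config)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "mode": config.mode,
        "seed": config.seed,
        "glyconnect_version": __version__,
        "numpy_version": np.__version__,
        "stages": {},
        "warnings": [],
    }
    t0 = time.time()

    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")

        if config.mode in ("synthetic-cohort", "from-matrices"):
            if config.mode == "synthetic-cohort":
                t = time.time()
                cohort_cfg = config.cohort
                matrices, records = gen_cohort(cohort_cfg)
                rec_df = records_frame(records)
                write_cohort(matrices, records, out / "cohort")
                manifest["stages"]["generate"] = round(time.time() - t, 3)
            else:
                from .synthetic import load_cohort

                matrices, rec_df = load_cohort(config.matrices_dir)

            t = time.time()
            mdf, ndf = metrics_table(
                matrices,
                list(rec_df["subject_id"]),
                config.null,
                cohort_seed=config.seed,
                n_restarts=config.modularity_restarts,
            )
            mdf.to_csv(out / "metrics.csv", index=False)
            ndf.to_csv(out / "null_summary.csv", index=False)
            manifest["stages"]["metrics"] = round(time.time() - t, 3)

            t = time.time()
            comps, corrs = analyze_cohort(
                mdf, rec_df, n_perm=config.n_perm, rng=config.seed
            )
            comparisons_frame(comps).to_csv(out / "group_comparisons.csv", index=False)
            correlations_frame(corrs).to_csv(out / "correlations.csv", index=False)
            manifest["stages"]["statistics"] = round(time.time() - t, 3)
            manifest["significance_threshold"] = "FDR q < 0.05"

        elif config.mode == "from-streamlines":
            t = time.time()
            path = str(config.streamlines_path)
            ss = load_trk(path) if path.endswith(".trk") else load_streamlines_tsv(path)
            labels = LabelVolume.from_nifti(config.labels_path)
            cm = build_matrix(ss, labels)
            cm.to_csv(out / "connectome.csv")
            met = compute_metrics(cm.weights)
            pd.DataFrame([{"subject_id": "s01", **met.as_dict()}]).to_csv(
                out / "metrics.csv", index=False
            )
            manifest["stages"]["connectome"] = round(time.time() - t, 3)

        elif config.mode == "phantom-e2e":
            t = time.time()
            phantom = gen_tensor_phantom(config.phantom)
            tensors = fit_tensor(
                phantom.signals, phantom.b_values, phantom.b_vectors,
                voxel_size=phantom.tensors.voxel_size,
            )
            scalars = tensor_scalars(tensors)
            mask = scalars["FA"].data > config.tracking.fa_stop
            ss = track_all(tensors, scalars["FA"], mask, config.tracking)
            manifest["n_streamlines"] = len(ss)
            if len(ss) and phantom.labels.n_regions >= 2:
                cm = build_matrix(ss, phantom.labels)
                cm.to_csv(out / "connectome.csv")
            manifest["stages"]["phantom_e2e"] = round(time.time() - t, 3)

        manifest["warnings"] = sorted({str(w.message) for w in caught})

    manifest["total_seconds"] = round(time.time() - t0, 3)
    manifest["config"] = json.loads(json.dumps(asdict(config), default=str))
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
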