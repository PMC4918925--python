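"""Weighted connectome assembly from streamline endpoints and a parcellation.

Each streamline contributes one count to the unordered pair of parcel
labels containing its two terminal points; streamlines ending in
background or with both ends in the same parcel are discarded.  Pairs
with fewer than three streamlines are zeroed (false-positive control),
and surviving counts are divided by the total streamline count of the
whole set — the fiber density — giving an N x N symmetric, zero-diagonal,
non-negative weight matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

from .tractography import Streamline, StreamlineSet


@dataclass
class LabelVolume:
    """Integer parcellation: 0 = background, 1..N = regions."""

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    region_names: dict[int, str] = field(default=None)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if (self.data < 0).any():
            raise ValueError("labels must be non-negative")
        present = set(np.unique(self.data)) - {0}
        if self.region_names is None:
            self.region_names = {int(r): f"region_{int(r)}" for r in present}
        missing = present - set(self.region_names)
        if missing:
            raise ValueError(f"region name table misses labels {sorted(missing)}")

    @property
    def n_regions(self) -> int:
        return max(self.region_names, default=0)

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag(list(self.voxel_size) + [1.0])
        return nib.Nifti1Image(self.data.astype(np.int32), affine)

    @classmethod
    def from_nifti(cls, path) -> "LabelVolume":
        img = nib.load(str(path))
        vs = tuple(float(z) for z in img.header.get_zooms()[:3])
        return cls(np.asarray(img.dataobj).astype(int), vs)


@dataclass
class ConnectivityMatrix:
    """Symmetric fiber-density weight matrix with region labels."""

    weights: np.ndarray
    region_names: list[str]
    total_streamlines: int = 0

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be a square matrix")
        if len(self.region_names) != w.shape[0]:
            raise ValueError("region_names length must match matrix size")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
        if not np.allclose(w, w.T):
            raise ValueError("weights must be symmetric")
        if np.abs(np.diagonal(w)).max(initial=0.0) > 0:
            raise ValueError("diagonal must be zero")
        self.weights = w

    @property
    def n_nodes(self) -> int:
        return self.weights.shape[0]

    def to_csv(self, path) -> None:
        # %.17g guarantees exact float64 round trips through the CSV
        pd.DataFrame(self.weights, columns=self.region_names).to_csv(
            path, index=False, float_format="%.17g"
        )

    @classmethod
    def from_csv(cls, path, total_streamlines: int = 0) -> "ConnectivityMatrix":
        df = pd.read_csv(path, float_precision="round_trip")
        return cls(df.to_numpy(dtype=float), list(df.columns), total_streamlines)


def endpoint_labels(s: Streamline, labels: LabelVolume) -> tuple[int, int] | None:
    """Region labels of a streamline's two terminal points, or None.

    None when either terminal voxel is background (0), out of bounds, or
    both terminals share the same region (self-connections excluded).
    The returned pair is canonically ordered (low, high).
    """
    vs = np.asarray(labels.voxel_size, dtype=float)
    shape = np.asarray(labels.data.shape)
    out = []
    for p in (s.points[0], s.points[-1]):
        ijk = np.floor(p / vs).astype(int)
        if (ijk < 0).any() or (ijk >= shape).any():
            return None
        out.append(int(labels.data[tuple(ijk)]))
    a, b = out
    if a == 0 or b == 0 or a == b:
        return None
    return (a, b) if a < b else (b, a)


def build_matrix(
    ss: StreamlineSet, labels: LabelVolume, min_streamlines: int = 3
) -> ConnectivityMatrix:
    """Fiber-density connectivity matrix from a whole-brain streamline set.

    Pair counts below ``min_streamlines`` are zeroed; surviving counts are
    normalized by the total number of streamlines in the set (counted
    before any thresholding or endpoint filtering).
    """
    if len(ss) == 0:
        raise ValueError("streamline set is empty")
    n = labels.n_regions
    counts = np.zeros((n, n), dtype=int)
    for s in ss.streamlines:
        pair = endpoint_labels(s, labels)
        if pair is not None:
            counts[pair[0] - 1, pair[1] - 1] += 1
    counts = counts + counts.T
    total = len(ss)
    return ConnectivityMatrix(
        weights=density_from_counts(counts, total, min_streamlines),
        region_names=[labels.region_names.get(r + 1, f"region_{r + 1}") for r in range(n)],
        total_streamlines=total,
    )


def density_from_counts(
    counts: np.ndarray, total: int, min_streamlines: int = 3
) -> np.ndarray:
    """Apply the >= min_streamlines edge rule, then divide by the total count."""
    counts = np.asarray(counts)
    if total <= 0:
        raise ValueError("total streamline count must be positive")
    kept = np.where(counts >= min_streamlines, counts, 0)
    np.fill_diagonal(kept, 0)
    return kept / float(total)
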