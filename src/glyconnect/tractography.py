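"""Deterministic streamline tractography with FA and turn-angle stopping.

FACT-style tracking: from each seed point, step bidirectionally along the
principal eigenvector of the tensor in the current (nearest-neighbor)
voxel.  Propagation stops when the local FA drops to the threshold
(default 0.2), the turn between successive steps reaches the angle
threshold (default 30 degrees), or the path leaves the volume.  Twenty
random seeds per masked voxel give whole-volume coverage.

Coordinates are in mm in the volume frame; voxel (i,j,k) spans
[i*dx, (i+1)*dx) x [j*dy, (j+1)*dy) x [k*dz, (k+1)*dz).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .diffusion import ScalarMap, TensorVolume, principal_directions


@dataclass
class Streamline:
    """Ordered 3-D polyline in mm; consecutive points one step apart."""

    points: np.ndarray

    def __post_init__(self):
        self.points = np.asarray(self.points, dtype=float)
        if self.points.ndim != 2 or self.points.shape[1] != 3 or len(self.points) < 2:
            raise ValueError("streamline needs >= 2 three-dimensional points")

    def __len__(self) -> int:
        return len(self.points)


@dataclass
class StreamlineSet:
    """Tracking output plus the provenance needed for fiber-density weights."""

    streamlines: list[Streamline]
    n_seeds: int = 0
    fa_stop: float = 0.2
    angle_stop_deg: float = 30.0

    def __len__(self) -> int:
        return len(self.streamlines)


@dataclass
class TrackingConfig:
    seeds_per_voxel: int = 20
    step_mm: float | None = None  # default 0.5 * smallest voxel edge
    fa_stop: float = 0.2
    angle_stop_deg: float = 30.0
    min_points: int = 3  # >= 2 steps retained
    seed: int = 0


def seed_points(
    mask: np.ndarray,
    voxel_size: tuple[float, float, float],
    seeds_per_voxel: int = 20,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Uniform random seed points inside each masked voxel, in mm.

    Returns shape (n_masked_voxels * seeds_per_voxel, 3); empty masks are
    rejected.  Reproducible for a given rng seed.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise ValueError("seed mask is empty")
    if seeds_per_voxel == 0:
        return np.empty((0, 3))
    rng = np.random.default_rng(rng)
    idx = np.argwhere(mask)  # (m, 3) voxel indices
    offsets = rng.random((len(idx), seeds_per_voxel, 3))
    pts = (idx[:, None, :] + offsets) * np.asarray(voxel_size)
    return pts.reshape(-1, 3)


def _voxel_of(point: np.ndarray, voxel_size: np.ndarray, shape: tuple) -> tuple | None:
    ijk = np.floor(point / voxel_size).astype(int)
    if (ijk < 0).any() or (ijk >= np.asarray(shape)).any():
        return None
    return tuple(ijk)


def track(
    tensors: TensorVolume,
    fa: ScalarMap,
    seed: np.ndarray,
    step_mm: float | None = None,
    fa_stop: float = 0.2,
    angle_stop_deg: float = 30.0,
    max_steps: int = 10_000,
) -> Streamline | None:
    """Track one streamline bidirectionally from a seed point.

    Euler integration along the (sign-continuous) principal eigenvector of
    the nearest-neighbor voxel tensor.  Returns None when the seed voxel
    itself fails the FA threshold, lies outside the volume, or the tensor
    there is not finite.
    """
    vs = np.asarray(tensors.voxel_size, dtype=float)
    shape = tensors.grid_shape
    if step_mm is None:
        step_mm = 0.5 * float(vs.min())
    cos_stop = np.cos(np.radians(angle_stop_deg))
    _, e1 = principal_directions(tensors)

    seed = np.asarray(seed, dtype=float)
    v0 = _voxel_of(seed, vs, shape)
    if v0 is None or fa.data[v0] <= fa_stop or not np.isfinite(tensors.data[v0]).all():
        return None
    if not tensors.valid[v0]:
        return None

    def march(direction: np.ndarray) -> list[np.ndarray]:
        pts = []
        pos = seed.copy()
        d = direction.copy()
        for _ in range(max_steps):
            nxt = pos + step_mm * d
            vox = _voxel_of(nxt, vs, shape)
            if vox is None:
                break
            if fa.data[vox] <= fa_stop or not tensors.valid[vox]:
                break
            e = e1[vox]
            if not np.isfinite(e).all():
                break
            if np.dot(e, d) < 0:
                e = -e
            if np.dot(e, d) < cos_stop:  # turn >= angle threshold
                break
            pts.append(nxt)
            pos, d = nxt, e
        return pts

    d0 = e1[v0]
    fwd = march(d0)
    bwd = march(-d0)
    points = bwd[::-1] + [seed] + fwd
    if len(points) < 2:
        return None
    return Streamline(np.asarray(points))


def track_all(
    tensors: TensorVolume,
    fa: ScalarMap,
    mask: np.ndarray,
    config: TrackingConfig | None = None,
) -> StreamlineSet:
    """Whole-volume tracking from random per-voxel seeds.

    Streamlines shorter than ``config.min_points`` points are discarded;
    the total seed count is recorded for provenance.
    """
    config = config or TrackingConfig()
    seeds = seed_points(
        mask, tensors.voxel_size, config.seeds_per_voxel, rng=config.seed
    )
    kept = []
    for s in seeds:
        sl = track(
            tensors,
            fa,
            s,
            step_mm=config.step_mm,
            fa_stop=config.fa_stop,
            angle_stop_deg=config.angle_stop_deg,
        )
        if sl is not None and len(sl) >= config.min_points:
            kept.append(sl)
    return StreamlineSet(
        streamlines=kept,
        n_seeds=len(seeds),
        fa_stop=config.fa_stop,
        angle_stop_deg=config.angle_stop_deg,
    )


# ---------------------------------------------------------------------------
# I/O: TrackVis TRK (via nibabel) and a plain TSV dialect
# ---------------------------------------------------------------------------

def save_trk(path, ss: StreamlineSet, voxel_size, grid_shape) -> None:
    """Write streamlines in TrackVis TRK format with the volume header."""
    affine = np.diag(list(voxel_size) + [1.0])
    # points are already in mm of the volume frame: identity rasmm mapping
    tractogram = nib.streamlines.Tractogram(
        [s.points for s in ss.streamlines], affine_to_rasmm=np.eye(4)
    )
    header = nib.streamlines.trk.TrkFile.create_empty_header()
    header["voxel_sizes"] = np.asarray(voxel_size, dtype=np.float32)
    header["dimensions"] = np.asarray(grid_shape, dtype=np.int16)
    header["voxel_to_rasmm"] = affine.astype(np.float32)
    nib.streamlines.save(tractogram, str(path), header=header)


def load_trk(path) -> StreamlineSet:
    trk = nib.streamlines.load(str(path))
    return StreamlineSet([Streamline(np.asarray(s)) for s in trk.streamlines])


def save_streamlines_tsv(path, ss: StreamlineSet) -> None:
    """Plain-text dialect: streamline_id, point_index, x, y, z (tab-separated)."""
    with open(path, "w") as fh:
        fh.write("streamline_id\tpoint_index\tx\ty\tz\n")
        for i, s in enumerate(ss.streamlines):
            for j, (x, y, z) in enumerate(s.points):
                fh.write(f"{i}\t{j}\t{x:.6f}\t{y:.6f}\t{z:.6f}\n")


def load_streamlines_tsv(path) -> StreamlineSet:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    sls = [
        Streamline(g.sort_values("point_index")[["x", "y", "z"]].to_numpy())
        for _, g in df.groupby("streamline_id", sort=True)
    ]
    return StreamlineSet(sls)
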