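"""Diffusion tensor estimation and scalar maps (FA, MD, AD, RD).

The single-tensor model relates the diffusion-weighted signal along unit
gradient g with b-value b to the 3x3 symmetric tensor D:

    S = S0 * exp(-b * g^T D g)

Taking logs gives a linear system in the six unique tensor components,
solved per voxel by ordinary least squares (the conventional log-linear
fit).  Scalar maps are functions of the sorted eigenvalues l1 >= l2 >= l3:

    MD = (l1+l2+l3)/3          mean diffusivity
    AD = l1                    axial diffusivity
    RD = (l2+l3)/2             radial diffusivity
    FA = sqrt(3/2) * ||l - MD|| / ||l||   fractional anisotropy in [0, 1]
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

# order of unique tensor components in the flattened representation
TENSOR_COMPONENTS = ("Dxx", "Dyy", "Dzz", "Dxy", "Dxz", "Dyz")
SCALAR_KINDS = ("FA", "MD", "AD", "RD")


@dataclass
class TensorVolume:
    """Per-voxel symmetric diffusion tensors.

    ``data`` has shape grid + (6,) storing (Dxx, Dyy, Dzz, Dxy, Dxz, Dyz)
    in mm^2/s; ``valid`` flags voxels with a usable fit.
    """

    data: np.ndarray
    voxel_size: tuple[float, float, float]
    valid: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.data.shape[-1] != 6:
            raise ValueError("tensor volume needs 6 components per voxel")
        if self.valid is None:
            self.valid = np.ones(self.data.shape[:-1], dtype=bool)

    @property
    def grid_shape(self) -> tuple:
        return self.data.shape[:-1]

    def as_matrices(self) -> np.ndarray:
        """Full 3x3 symmetric matrices, shape grid + (3, 3)."""
        xx, yy, zz, xy, xz, yz = np.moveaxis(self.data, -1, 0)
        m = np.empty(self.grid_shape + (3, 3))
        m[..., 0, 0], m[..., 1, 1], m[..., 2, 2] = xx, yy, zz
        m[..., 0, 1] = m[..., 1, 0] = xy
        m[..., 0, 2] = m[..., 2, 0] = xz
        m[..., 1, 2] = m[..., 2, 1] = yz
        return m

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag(list(self.voxel_size) + [1.0])
        return nib.Nifti1Image(self.data.astype(np.float64), affine)


@dataclass
class ScalarMap:
    """One scalar diffusion measure on the tensor grid."""

    data: np.ndarray
    kind: str
    voxel_size: tuple[float, float, float]

    def __post_init__(self):
        if self.kind not in SCALAR_KINDS:
            raise ValueError(f"kind must be one of {SCALAR_KINDS}")

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag(list(self.voxel_size) + [1.0])
        return nib.Nifti1Image(self.data.astype(np.float64), affine)


def design_matrix(b_values: np.ndarray, b_vectors: np.ndarray) -> np.ndarray:
    """Rows b * (gx^2, gy^2, gz^2, 2 gx gy, 2 gx gz, 2 gy gz)."""
    b = np.asarray(b_values, dtype=float)
    g = np.asarray(b_vectors, dtype=float)
    if g.shape[0] != b.size:
        g = g.T
    gx, gy, gz = g[:, 0], g[:, 1], g[:, 2]
    return b[:, None] * np.column_stack(
        [gx**2, gy**2, gz**2, 2 * gx * gy, 2 * gx * gz, 2 * gy * gz]
    )


def fit_tensor(
    signals: np.ndarray,
    b_values: np.ndarray,
    b_vectors: np.ndarray,
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
) -> TensorVolume:
    """Log-linear least-squares tensor fit per voxel.

    ``signals`` has shape grid + (n_measurements,).  Requires at least 7
    measurements including one with b = 0 (S0 is the mean of the b = 0
    signals).  Voxels with any non-positive signal are flagged invalid
    and get a zero tensor.
    """
    signals = np.asarray(signals, dtype=float)
    b = np.asarray(b_values, dtype=float)
    g = np.asarray(b_vectors, dtype=float)
    if g.shape != (b.size, 3):
        g = g.T
    if g.shape != (b.size, 3):
        raise ValueError("b_vectors must have shape (n, 3) matching b_values")
    if signals.shape[-1] != b.size:
        raise ValueError("signal count does not match gradient table")
    b0 = b == 0
    if not b0.any():
        raise ValueError("need at least one b=0 measurement")
    if (~b0).sum() < 6:
        raise ValueError("need >= 6 diffusion-weighted measurements (underdetermined)")
    grid = signals.shape[:-1]
    flat = signals.reshape(-1, b.size)
    valid = (flat > 0).all(axis=1)
    s0 = np.where(valid, flat[:, b0].mean(axis=1), 1.0)
    dw = ~b0
    X = design_matrix(b[dw], g[dw])
    with np.errstate(divide="ignore", invalid="ignore"):
        y = -np.log(flat[:, dw] / s0[:, None])
    y[~valid] = 0.0
    coeffs, *_ = np.linalg.lstsq(X, y.T, rcond=None)
    d = coeffs.T.reshape(grid + (6,))
    d[~valid.reshape(grid)] = 0.0
    return TensorVolume(data=d, voxel_size=tuple(voxel_size), valid=valid.reshape(grid))


def principal_directions(t: TensorVolume) -> tuple[np.ndarray, np.ndarray]:
    """Sorted eigenvalues (descending) and principal eigenvectors.

    Returns (eigvals grid+(3,), e1 grid+(3,)).
    """
    m = t.as_matrices()
    vals, vecs = np.linalg.eigh(m)  # ascending
    vals = vals[..., ::-1]
    e1 = vecs[..., :, ::-1][..., :, 0]
    return vals, e1


def tensor_scalars(t: TensorVolume) -> dict[str, ScalarMap]:
    """FA, MD, AD and RD maps from a tensor volume.

    Negative eigenvalues (noisy fits) are clamped to 0 before the scalar
    formulas, keeping FA in [0, 1]; the all-zero tensor has FA = 0 by
    convention.
    """
    vals, _ = principal_directions(t)
    vals = np.clip(vals, 0.0, None)
    l1, l2, l3 = vals[..., 0], vals[..., 1], vals[..., 2]
    md = (l1 + l2 + l3) / 3.0
    num = np.sqrt((l1 - md) ** 2 + (l2 - md) ** 2 + (l3 - md) ** 2)
    den = np.sqrt(l1**2 + l2**2 + l3**2)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.sqrt(1.5) * num / den
    fa = np.where(den > 0, fa, 0.0)
    vs = t.voxel_size
    return {
        "FA": ScalarMap(np.clip(fa, 0.0, 1.0), "FA", vs),
        "MD": ScalarMap(md, "MD", vs),
        "AD": ScalarMap(l1, "AD", vs),
        "RD": ScalarMap((l2 + l3) / 2.0, "RD", vs),
    }


def save_gradient_table(path_prefix, b_values, b_vectors) -> None:
    """Write FSL-style .bval / .bvec text files (one row per axis)."""
    b = np.atleast_2d(np.asarray(b_values, dtype=float))
    g = np.asarray(b_vectors, dtype=float)
    if g.shape[0] != 3:
        g = g.T
    np.savetxt(f"{path_prefix}.bval", b, fmt="%.1f")
    np.savetxt(f"{path_prefix}.bvec", g, fmt="%.8f")


def load_gradient_table(path_prefix) -> tuple[np.ndarray, np.ndarray]:
    """Read FSL-style .bval / .bvec; returns (b_values (k,), b_vectors (k,3))."""
    b = np.loadtxt(f"{path_prefix}.bval").ravel()
    g = np.loadtxt(f"{path_prefix}.bvec")
    if g.shape[0] == 3:
        g = g.T
    return b, g
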