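"""Diffusion tensor fitting and scalar maps on a two-compartment phantom.

Builds a phantom with an anisotropic x-oriented bar inside an isotropic
background, simulates 30-direction diffusion-weighted signals, refits the
tensors by log-linear least squares and prints the FA/MD/AD/RD values of
both compartments.
"""

import numpy as np

from glyconnect.diffusion import fit_tensor, tensor_scalars
from glyconnect.synthetic import PhantomRegion, TensorPhantomConfig, gen_tensor_phantom

bar = PhantomRegion(
    bbox=((0, 12), (3, 6), (3, 6)),
    direction=(1, 0, 0),
    eigvals=(1.7e-3, 0.3e-3, 0.2e-3),  # white-matter-like prolate tensor
)
cfg = TensorPhantomConfig(
    grid_shape=(12, 9, 9),
    voxel_size=(2.0, 2.0, 2.0),
    field_spec=[bar],
    background_eigvals=(0.7e-3, 0.7e-3, 0.7e-3),  # gray-matter-like isotropic
    noise_sd=0.0,
    seed=0,
)
phantom = gen_tensor_phantom(cfg)
fitted = fit_tensor(phantom.signals, phantom.b_values, phantom.b_vectors)
scalars = tensor_scalars(fitted)

inside = (slice(0, 12), slice(3, 6), slice(3, 6))
outside = (0, 0, 0)
print("compartment   FA      MD [mm^2/s]  AD [mm^2/s]  RD [mm^2/s]")
for name, vox in (("bar (WM)", (5, 4, 4)), ("background", outside)):
    vals = [scalars[k].data[vox] for k in ("FA", "MD", "AD", "RD")]
    print(f"{name:12s} {vals[0]:.4f}  {vals[1]:.3e}   {vals[2]:.3e}   {vals[3]:.3e}")

print(
    "\nThe bar shows high FA (directionally coherent diffusion, the substrate"
    "\nof tractography) with AD >> RD; the isotropic background has FA = 0 and"
    "\nequal diffusivities. Noiseless refits recover the generating tensors to"
    f"\nmachine precision (max abs error {np.abs(fitted.data - phantom.tensors.data).max():.2e})."
)
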