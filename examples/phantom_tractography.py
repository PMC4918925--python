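"""Phantom-to-connectome integration path.

Builds a tensor phantom with two labelled terminal regions joined by an
anisotropic bar, fits tensors from the simulated signals, runs
deterministic tracking (FA > 0.2, turns < 30 degrees, 20 seeds/voxel) and
assembles the fiber-density connectivity matrix with the >=3-streamline
edge rule.
"""

import numpy as np

from glyconnect.connectome import build_matrix
from glyconnect.diffusion import fit_tensor, tensor_scalars
from glyconnect.synthetic import PhantomRegion, TensorPhantomConfig, gen_tensor_phantom
from glyconnect.tractography import TrackingConfig, track_all

regions = [
    PhantomRegion(bbox=((0, 20), (3, 7), (3, 7)), direction=(1, 0, 0),
                  eigvals=(1.7e-3, 0.2e-3, 0.2e-3)),
    PhantomRegion(bbox=((0, 3), (3, 7), (3, 7)), direction=(1, 0, 0),
                  eigvals=(1.7e-3, 0.2e-3, 0.2e-3), label=1),
    PhantomRegion(bbox=((17, 20), (3, 7), (3, 7)), direction=(1, 0, 0),
                  eigvals=(1.7e-3, 0.2e-3, 0.2e-3), label=2),
]
cfg = TensorPhantomConfig(
    grid_shape=(20, 10, 10), voxel_size=(2.0, 2.0, 2.0), field_spec=regions, seed=3
)
phantom = gen_tensor_phantom(cfg)
tensors = fit_tensor(
    phantom.signals, phantom.b_values, phantom.b_vectors, voxel_size=cfg.voxel_size
)
fa = tensor_scalars(tensors)["FA"]

mask = fa.data > 0.2
ss = track_all(tensors, fa, mask, TrackingConfig(seeds_per_voxel=20, seed=3))
print(f"seeds: {ss.n_seeds}, retained streamlines: {len(ss)}")

conn = build_matrix(ss, phantom.labels)
print("fiber-density connectivity matrix (rows/cols = terminal regions):")
print(np.array_str(conn.weights, precision=3))
print(
    "\nAll streamlines follow the bar, so nearly every retained streamline"
    "\nlinks region 1 to region 2; the single edge weight is the fraction of"
    "\nall streamlines connecting the pair (fiber density)."
)
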