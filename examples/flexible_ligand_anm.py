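"""Backbone flexibility through anisotropic-network-model (ANM) modes.

Computes the low-frequency elastic-network modes of the toy ligand and
shows how mode amplitudes deform the posed structure: a pose is no longer
just a rigid placement but carries a small vector of collective-motion
amplitudes.
"""

import numpy as np

import glowdock as gd
from glowdock.pose import compute_anm_basis

_, ligand, _, _ = gd.make_toy_complex(seed=0)
basis = compute_anm_basis(ligand, M=4, cutoff=10.0)
print(f"ANM basis: {basis.n_modes} modes over {basis.n_ca} residues, "
      f"scale {basis.scale} A per unit amplitude")
print(f"mode eigenvalues (stiffness): {np.round(basis.eigenvalues, 3)}")

rigid = gd.Pose(ligand.centroid())
flexed = gd.Pose(ligand.centroid(), mode_amplitudes=np.array([1.0, 0.0, 0.0, 0.0]))
displacement = np.linalg.norm(
    gd.apply_pose(ligand, flexed, basis) - gd.apply_pose(ligand, rigid, basis), axis=1)
print(f"softest-mode deformation at amplitude 1: per-atom displacement "
      f"{displacement.min():.2f}-{displacement.max():.2f} A")
# low eigenvalues = soft collective motions; during docking the optimizer
# searches these amplitudes alongside translation and rotation.
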