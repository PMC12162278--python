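"""Deformation indices J, ADI and SRI from a displacement field.

Samples the affine map x -> A x on a grid, runs the tensor pipeline
(F = I + grad u, J = det F, principal stretches from F^T F), and checks the
voxel values against the closed forms from A. J measures local volume
change, ADI the magnitude of directional preference, SRI (0 = slab-like,
1 = rod-like) its character.
"""

import numpy as np

from lungqct import AffineFieldSpec, compute_tensors, make_affine_displacement

A = np.diag([1.2, 1.1, 1.0])  # 20%/10%/0% principal stretches
field, closed = make_affine_displacement(AffineFieldSpec(A=A, grid_shape=(24, 24, 24)))
tensors = compute_tensors(field)

c = (12, 12, 12)
print(f"closed-form:  J = {closed['J']:.4f}  ADI = {closed['ADI']:.5f}  "
      f"SRI = {closed['SRI']:.4f}")
print(f"field-based:  J = {tensors.J[c]:.4f}  ADI = {tensors.ADI[c]:.5f}  "
      f"SRI = {tensors.SRI[c]:.4f}")
print()
print("J = 1.32 means 32% local volume gain; ADI = 0.135 a moderate")
print("directional preference; SRI = 0.47 a deformation between slab-like")
print("and rod-like. Central differences are exact on affine fields, so the")
print("interior voxels match the closed form to machine precision.")
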