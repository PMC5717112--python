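"""Measurement corruption and its inverse.

Corrupts a clean phantom with an eddy-current offset plane and phase
wrapping (velocities beyond venc alias into [-venc, venc)), then runs the
preprocessing chain — eddy-current correction from static tissue, then
neighborhood-median phase unwrapping — and reports the recovery error.
"""

import numpy as np

from flow4d import PhantomConfig, corrupt_phantom, correct_eddy_currents, generate_phantom, unwrap_velocity

eddy = np.array([[0.05, 0.001, 0.0, 0.0], [0.02, 0.0, 0.0005, 0.0], [-0.03, 0.0, 0.0, 0.0008]])
config = PhantomConfig(
    grid_shape=(64, 74, 40), n_frames=6, v_max=1.0,
    venc=(0.95, 0.95, 0.95), wrap_enabled=True, eddy_plane_coeffs=eddy, seed=5,
)
field, magnitude, truth = generate_phantom(config)
measured = corrupt_phantom(field, config)

wrapped = np.abs(measured.data - truth.clean_velocity.data) > 1.0
print(f"corrupted voxels beyond venc (wrapped): {int(wrapped.sum())}")

recovered = unwrap_velocity(correct_eddy_currents(measured, magnitude))
err = np.abs(recovered.data - truth.clean_velocity.data).max()
print(f"max |recovered - clean| : {err:.2e} m/s")
print(
    "With noise-free data and isolated single wraps the preprocessing chain"
    " inverts the corruption to machine precision."
)
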