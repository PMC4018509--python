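"""Preset-recovery experiment: accuracy of both registration modes.

Applies three known rigid motions to a phantom, registers each floating
image with the fused-measure method and with intensity-only NMI, and
tabulates recovered parameters, errors and RMS gray-level error before
and after registration.
"""

from swtreg import PhantomSpec, RigidTransform, make_phantom, run_recovery_experiment

ref = make_phantom(PhantomSpec(shape=(128, 128), n_regions=6, seed=3))
# stay within the capture range documented for this phantom size
presets = [RigidTransform(10, 15, -3), RigidTransform(12, -6, -2), RigidTransform(5, 8, 2)]

table = run_recovery_experiment(ref, presets)
cols = ["preset_dx", "preset_dy", "preset_theta",
        "err_dx_proposed", "err_dy_proposed", "err_theta_proposed",
        "mse_pre", "mse_proposed", "mse_mi_only"]
print(table[cols].round(3).to_string(index=False))
print()
print("err_* columns are recovered-minus-preset parameter errors (px / deg);")
print("mse_pre is the misalignment's RMS gray error, mse_proposed/mse_mi_only")
print("what remains after registering with each mode.")
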