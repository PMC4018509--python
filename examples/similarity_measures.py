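"""Entropy, mutual information and NMI of aligned vs. misaligned pairs.

Shows how the joint histogram of an image with itself collapses onto the
diagonal (NMI = 2) and how misalignment disperses it (NMI toward 1),
and evaluates the logistic-weighted fusion of intensity and gradient
NMI that serves as the registration objective.
"""

from swtreg import (
    MeasureConfig,
    PhantomSpec,
    RigidTransform,
    apply_rigid,
    combined_measure,
    joint_histogram,
    logistic_weight,
    make_phantom,
    mutual_information,
    normalized_mutual_information,
)
from swtreg.similarity import entropy

img = make_phantom(PhantomSpec(shape=(128, 128), n_regions=6, seed=3))
cfg = MeasureConfig(bins=64, T=0.04)

for label, t in [("aligned", RigidTransform()), ("shifted 10 px", RigidTransform(10, 0, 0))]:
    moved = apply_rigid(img, t)
    h = joint_histogram(img, moved, cfg)
    print(f"{label:14s}: H(A) = {entropy(h.marginal_a):.3f} bits, "
          f"I = {mutual_information(h):.3f} bits, "
          f"NMI = {normalized_mutual_information(h):.4f}")

print()
for nmi_i, nmi_g, note in [
    (2.0, 2.0, "perfect alignment"),
    (1.5, 1.5, "logistic midpoint (f = 0.5)"),
    (1.2, 1.1, "far from alignment"),
]:
    v = ((nmi_i - 1) + (nmi_g - 1)) / 2
    f = logistic_weight(v, cfg.T)
    c = combined_measure(nmi_i, nmi_g, cfg)
    print(f"NMI_i={nmi_i:.2f} NMI_g={nmi_g:.2f}: f(v)={f:.4f}, combined={c:.4f}  ({note})")

print()
print("Far from alignment the weight f saturates toward 0 and the fused")
print("measure follows the gradient NMI; near alignment it hands over to")
print("the intensity NMI.")
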