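"""Histogram-based similarity measures for registration.

Gray-value co-occurrence between a reference image ``A`` and a floating
image ``B`` is estimated with a ``B x B`` joint histogram; from it come
the marginal entropies ``H(A)``, ``H(B)``, the joint entropy ``H(A,B)``,
mutual information ``I = H(A) + H(B) - H(A,B)`` and the overlap-robust
normalized mutual information ``NMI = (H(A) + H(B)) / H(A,B)`` with
range [1, 2].  All entropies use log base 2 (bits).

The registration measure fuses the intensity-image NMI with the
gradient-image NMI through a logistic weight

    f(v) = 1 / (1 + exp(-(v - 0.5) / T)),   v = (x + y) / 2

so that the intensity term dominates once both component measures are
high (near alignment) and the edge-driven gradient term dominates far
from alignment.  Because raw NMI lives in [1, 2] while the logistic is
centered at 0.5, the default maps both components through ``NMI - 1``
when computing ``v`` (``nmi_rescale``); the combination itself always
mixes the raw values.  A literal mode (raw NMI inside ``v``) is kept as
an option — there f saturates and the fusion collapses to the intensity
term.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateEntropyError, DegenerateOverlapError
from .image_io import Image2D

__all__ = [
    "HistogramModel",
    "MeasureConfig",
    "joint_histogram",
    "entropy",
    "joint_entropy",
    "mutual_information",
    "normalized_mutual_information",
    "logistic_weight",
    "combined_measure",
]


@dataclass
class MeasureConfig:
    """Knobs of the similarity measure.

    bins : joint-histogram size per axis (default 64, the usual
        bias/variance compromise for ~512^2 samples).
    T : logistic temperature controlling how sharply the fusion switches
        between gradient- and intensity-dominated regimes (default 0.04).
    """

    bins: int = 64
    T: float = 0.04
    interpolation: str = "bilinear"
    nmi_rescale: bool = True

    def __post_init__(self):
        if self.bins < 2:
            raise ValueError("bins must be >= 2")
        if self.T <= 0:
            raise ValueError("T must be > 0")


@dataclass
class HistogramModel:
    """Normalized joint histogram with its marginals."""

    joint: np.ndarray
    marginal_a: np.ndarray
    marginal_b: np.ndarray
    bins: int
    range_a: tuple[float, float]
    range_b: tuple[float, float]
    n_samples: int = 0


def _gray_range(arr: np.ndarray) -> tuple[float, float]:
    lo, hi = float(np.nanmin(arr)), float(np.nanmax(arr))
    if hi <= lo:
        hi = lo + 1.0  # constant image: a single occupied bin
    return lo, hi


def joint_histogram(
    ref,
    flt,
    cfg: MeasureConfig | None = None,
    range_a: tuple[float, float] | None = None,
    range_b: tuple[float, float] | None = None,
) -> HistogramModel:
    """Joint gray-value histogram of two spatially aligned images.

    Pixels where either image is NaN (out-of-bounds samples from a
    transformed floating image) are excluded, so the estimate uses the
    overlap region only.  Bin ranges default to each image's own
    (min, max); a registration loop should pass fixed ranges captured at
    the start so the objective stays smooth across iterations.
    """
    cfg = cfg or MeasureConfig()
    a = ref.pixels if isinstance(ref, Image2D) else np.asarray(ref, dtype=np.float64)
    b = flt.pixels if isinstance(flt, Image2D) else np.asarray(flt, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"image shapes differ: {a.shape} vs {b.shape}")
    valid = np.isfinite(a) & np.isfinite(b)
    n = int(valid.sum())
    if n == 0:
        raise DegenerateOverlapError("no valid overlapping pixels")
    ra = range_a or _gray_range(a[valid])
    rb = range_b or _gray_range(b[valid])
    # histogram2d drops samples outside the fixed ranges; clip instead so
    # every overlap pixel contributes.
    av = np.clip(a[valid], ra[0], ra[1])
    bv = np.clip(b[valid], rb[0], rb[1])
    joint, _, _ = np.histogram2d(av, bv, bins=cfg.bins, range=[ra, rb])
    joint /= joint.sum()
    return HistogramModel(
        joint=joint,
        marginal_a=joint.sum(axis=1),
        marginal_b=joint.sum(axis=0),
        bins=cfg.bins,
        range_a=ra,
        range_b=rb,
        n_samples=n,
    )


def entropy(marginal) -> float:
    """Shannon entropy in bits, with 0 log 0 = 0."""
    p = np.asarray(marginal, dtype=np.float64).ravel()
    if np.any(p < 0):
        raise ValueError("probabilities must be nonnegative")
    s = p.sum()
    if not np.isclose(s, 1.0, atol=1e-8):
        raise ValueError(f"probabilities must sum to 1, got {s}")
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def joint_entropy(hist: HistogramModel) -> float:
    return entropy(hist.joint)


def mutual_information(hist: HistogramModel) -> float:
    """I(A,B) = H(A) + H(B) - H(A,B), in bits."""
    return entropy(hist.marginal_a) + entropy(hist.marginal_b) - joint_entropy(hist)


def normalized_mutual_information(hist: HistogramModel) -> float:
    """NMI(A,B) = (H(A) + H(B)) / H(A,B); lies in [1, 2]."""
    hab = joint_entropy(hist)
    if hab == 0.0:
        raise DegenerateEntropyError("joint entropy is zero (both images constant)")
    return (entropy(hist.marginal_a) + entropy(hist.marginal_b)) / hab


def logistic_weight(v: float, T: float = 0.04) -> float:
    """f(v) = 1 / (1 + exp(-(v - 0.5) / T)), the fusion weight."""
    if T <= 0:
        raise ValueError("T must be > 0")
    # clip the exponent so extreme v saturate to 0/1 without overflow
    z = np.clip(-(v - 0.5) / T, -700.0, 700.0)
    return float(1.0 / (1.0 + np.exp(z)))


def combined_measure(nmi_i: float, nmi_g: float, cfg: MeasureConfig | None = None) -> float:
    """Logistic-weighted convex combination of the two NMI components.

    Returns ``f(v) * nmi_i + (1 - f(v)) * nmi_g`` with
    ``v = (x + y) / 2``; by default ``x, y`` are the components shifted
    by -1 so that v spans the logistic's [0, 1] active range.
    """
    cfg = cfg or MeasureConfig()
    if not (np.isfinite(nmi_i) and np.isfinite(nmi_g)):
        raise ValueError("NMI components must be finite")
    x, y = (nmi_i - 1.0, nmi_g - 1.0) if cfg.nmi_rescale else (nmi_i, nmi_g)
    f = logistic_weight((x + y) / 2.0, cfg.T)
    return f * nmi_i + (1.0 - f) * nmi_g
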