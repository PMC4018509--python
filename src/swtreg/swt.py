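"""Stationary (undecimated, à-trous) 2D wavelet transform.

The stationary wavelet transform (SWT) filters the image with wavelet
filters that are dilated by zero-insertion at each level (``2^j - 1``
zeros between taps at level ``j``) and never downsamples, so every
sub-band keeps the input shape and the transform commutes with circular
shifts.  That translation equivariance is what makes detail bands a
reliable edge detector for registration: edges stay put.

A level splits the running approximation ``A_{j-1}`` into four bands:
approximation ``A_j`` (LL), horizontal detail ``D1`` (LH), vertical
detail ``D2`` (HL) and diagonal detail ``D3`` (HH).  Reconstruction
applies the adjoint filters and averages the redundant phases (the
classical 1/4 factor in 2D).  For orthonormal filter banks this inverse
is exact under periodic boundary handling.

The *gradient image* is the inverse transform of the detail bands alone
(all approximation content zeroed): a mean-suppressed, edge-dominant
version of the input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pywt

from .image_io import Image2D

__all__ = [
    "FilterBank",
    "WaveletPyramid",
    "swt_decompose",
    "swt_reconstruct",
    "synthesize_gradient_image",
]

_BOUNDARIES = ("periodic", "symmetric")


@dataclass(frozen=True)
class FilterBank:
    """Analysis (h0, g0) and synthesis (h1, g1) filter taps.

    Only orthonormal banks are supported: they satisfy
    ``|H0(w)|^2 + |G0(w)|^2 = 2``, which makes the adjoint-based
    undecimated inverse exact (after the per-level 1/4 normalization).
    """

    h0: np.ndarray
    g0: np.ndarray
    h1: np.ndarray
    g1: np.ndarray
    name: str = "custom"

    @classmethod
    def from_wavelet(cls, name: str = "haar") -> "FilterBank":
        w = pywt.Wavelet(name)
        if not w.orthogonal:
            raise ValueError(f"wavelet {name!r} is not orthogonal; SWT inverse requires an orthonormal bank")
        return cls(
            h0=np.asarray(w.dec_lo, dtype=np.float64),
            g0=np.asarray(w.dec_hi, dtype=np.float64),
            h1=np.asarray(w.rec_lo, dtype=np.float64),
            g1=np.asarray(w.rec_hi, dtype=np.float64),
            name=name,
        )

    @property
    def support(self) -> int:
        return len(self.h0)


def _as_filterbank(filters) -> FilterBank:
    if isinstance(filters, FilterBank):
        return filters
    return FilterBank.from_wavelet(filters)


@dataclass
class WaveletPyramid:
    """Per-level sub-bands of an undecimated decomposition.

    All bands have the input's shape ``base_shape``; ``approx[j-1]``,
    ``detail_h[j-1]`` etc. hold level-``j`` bands for ``j = 1..levels``.
    """

    levels: int
    approx: list = field(default_factory=list)
    detail_h: list = field(default_factory=list)
    detail_v: list = field(default_factory=list)
    detail_d: list = field(default_factory=list)
    base_shape: tuple[int, int] = (0, 0)

    def validate(self) -> None:
        if self.levels < 1:
            raise ValueError("pyramid must have at least one level")
        for bands in (self.approx, self.detail_h, self.detail_v, self.detail_d):
            if len(bands) != self.levels:
                raise ValueError("pyramid band lists are inconsistent with its level count")
            for b in bands:
                if b.shape != tuple(self.base_shape):
                    raise ValueError(
                        f"band shape {b.shape} does not match base shape {self.base_shape}"
                    )

    def copy(self) -> "WaveletPyramid":
        return WaveletPyramid(
            self.levels,
            [a.copy() for a in self.approx],
            [d.copy() for d in self.detail_h],
            [d.copy() for d in self.detail_v],
            [d.copy() for d in self.detail_d],
            self.base_shape,
        )

    def save(self, directory) -> None:
        """Dump each band as ``A_j.csv`` / ``D1_j.csv`` ... for debugging."""
        import os

        os.makedirs(directory, exist_ok=True)
        for j in range(1, self.levels + 1):
            for tag, bands in (
                ("A", self.approx),
                ("D1", self.detail_h),
                ("D2", self.detail_v),
                ("D3", self.detail_d),
            ):
                np.savetxt(os.path.join(directory, f"{tag}_{j}.csv"), bands[j - 1], delimiter=",")


def _analyze_1d(x: np.ndarray, taps: np.ndarray, dilation: int, axis: int) -> np.ndarray:
    # correlation with the dilated filter: out[k] = sum_n taps[n] x[k + d n]
    out = np.zeros_like(x)
    for n, t in enumerate(taps):
        if t != 0.0:
            out += t * np.roll(x, -dilation * n, axis=axis)
    return out


def _synthesize_1d(b: np.ndarray, taps: np.ndarray, dilation: int, axis: int) -> np.ndarray:
    # adjoint of _analyze_1d with the time-reversed (synthesis) taps:
    # out[k] = sum_m taps[m] b[k + d m - d (L-1)]
    L = len(taps)
    out = np.zeros_like(b)
    for m, t in enumerate(taps):
        if t != 0.0:
            out += t * np.roll(b, dilation * (L - 1 - m), axis=axis)
    return out


def _pad(x: np.ndarray, p: int) -> np.ndarray:
    return np.pad(x, p, mode="symmetric")


def _crop(x: np.ndarray, p: int) -> np.ndarray:
    return x[p : x.shape[0] - p, p : x.shape[1] - p] if p else x


def _check_args(shape, levels: int, fb: FilterBank, boundary: str) -> None:
    if levels < 1:
        raise ValueError("levels must be >= 1")
    if boundary not in _BOUNDARIES:
        raise ValueError(f"boundary must be one of {_BOUNDARIES}, got {boundary!r}")
    deepest = (fb.support - 1) * 2 ** (levels - 1) + 1
    if min(shape) < deepest:
        raise ValueError(
            f"image of shape {shape} is too small for {levels}-level SWT with "
            f"{fb.support}-tap filters (needs >= {deepest} px per side)"
        )


def swt_decompose(img, levels: int = 3, filters="haar", boundary: str = "symmetric") -> WaveletPyramid:
    """Decompose an image into ``levels`` undecimated wavelet levels.

    ``boundary='periodic'`` treats the image as circular (exact inverse,
    shift-equivariant); ``'symmetric'`` reflect-extends each level before
    filtering, avoiding wrap-around ghost edges in the detail bands.
    """
    x = img.pixels if isinstance(img, Image2D) else np.asarray(img, dtype=np.float64)
    fb = _as_filterbank(filters)
    _check_args(x.shape, levels, fb, boundary)
    pyr = WaveletPyramid(levels=levels, base_shape=x.shape)
    a = x
    for j in range(1, levels + 1):
        d = 2 ** (j - 1)
        p = d * (fb.support - 1) if boundary == "symmetric" else 0
        ap = _pad(a, p) if p else a
        lo = _analyze_1d(ap, fb.h0, d, axis=0)
        hi = _analyze_1d(ap, fb.g0, d, axis=0)
        pyr.approx.append(_crop(_analyze_1d(lo, fb.h0, d, axis=1), p))
        pyr.detail_h.append(_crop(_analyze_1d(lo, fb.g0, d, axis=1), p))
        pyr.detail_v.append(_crop(_analyze_1d(hi, fb.h0, d, axis=1), p))
        pyr.detail_d.append(_crop(_analyze_1d(hi, fb.g0, d, axis=1), p))
        a = pyr.approx[-1]
    return pyr


def _invert_level(a, d1, d2, d3, fb: FilterBank, j: int, boundary: str) -> np.ndarray:
    d = 2 ** (j - 1)
    p = d * (fb.support - 1) if boundary == "symmetric" else 0
    if p:
        a, d1, d2, d3 = _pad(a, p), _pad(d1, p), _pad(d2, p), _pad(d3, p)
    lo = _synthesize_1d(a, fb.h1, d, axis=1) + _synthesize_1d(d1, fb.g1, d, axis=1)
    hi = _synthesize_1d(d2, fb.h1, d, axis=1) + _synthesize_1d(d3, fb.g1, d, axis=1)
    out = _synthesize_1d(lo, fb.h1, d, axis=0) + _synthesize_1d(hi, fb.g1, d, axis=0)
    return _crop(out, p) / 4.0


def swt_reconstruct(pyr: WaveletPyramid, filters="haar", boundary: str = "symmetric") -> np.ndarray:
    """Inverse undecimated transform (phase-averaged adjoint).

    Linear in the coefficients; inverts :func:`swt_decompose` exactly
    (to floating-point round-off) under periodic boundary handling.
    """
    fb = _as_filterbank(filters)
    pyr.validate()
    a = pyr.approx[-1]
    for j in range(pyr.levels, 0, -1):
        a = _invert_level(a, pyr.detail_h[j - 1], pyr.detail_v[j - 1], pyr.detail_d[j - 1], fb, j, boundary)
    return a


def synthesize_gradient_image(img, levels: int = 3, filters="haar", boundary: str = "symmetric"):
    """Reconstruct from detail bands only: the SWT gradient image.

    The final approximation band is zeroed and the inverse transform run,
    leaving a mean-suppressed, edge-dominant image.  Adding a constant to
    the input leaves the result unchanged; a constant input maps to zero.
    """
    pyr = swt_decompose(img, levels=levels, filters=filters, boundary=boundary)
    pyr.approx[-1] = np.zeros_like(pyr.approx[-1])
    out = swt_reconstruct(pyr, filters=filters, boundary=boundary)
    if isinstance(img, Image2D):
        return img.with_pixels(out)
    return out
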