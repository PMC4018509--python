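"""Image containers, file I/O, grid resampling and synthetic phantoms.

Coordinate convention, used everywhere in the package: arrays are row-major
and 0-based; physical ``x`` runs along columns and ``y`` along rows.  The
physical position of pixel ``(r, c)`` is ``origin + ((r + 0.5) * row_mm,
(c + 0.5) * col_mm)`` — i.e. grids are aligned on pixel *centers* with a
half-pixel offset from the array origin.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import imageio.v3 as iio
import numpy as np
import pydicom
from scipy import ndimage

from .errors import UnsupportedFormatError

__all__ = [
    "Image2D",
    "PhantomSpec",
    "load_image",
    "save_image",
    "save_csv",
    "load_csv",
    "resample_to_grid",
    "make_phantom",
    "degrade_cbct_like",
]


@dataclass
class Image2D:
    """A 2D grayscale image with physical pixel spacing.

    Parameters
    ----------
    pixels : ndarray
        ``(M, N)`` float array of gray values, ``M, N >= 8``, all finite.
    spacing : tuple of float
        ``(row_mm, col_mm)`` physical pixel size, strictly positive.
    origin : tuple of float
        Physical coordinates (mm) of the array origin corner.
    """

    pixels: np.ndarray
    spacing: tuple[float, float] = (1.0, 1.0)
    origin: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels, dtype=np.float64)
        if self.pixels.ndim != 2:
            raise ValueError(f"pixels must be 2D, got ndim={self.pixels.ndim}")
        if min(self.pixels.shape) < 8:
            raise ValueError(f"image must be at least 8x8, got {self.pixels.shape}")
        if not np.all(np.isfinite(self.pixels)):
            raise ValueError("pixels contain NaN or Inf")
        self.spacing = (float(self.spacing[0]), float(self.spacing[1]))
        if self.spacing[0] <= 0 or self.spacing[1] <= 0:
            raise ValueError(f"spacing must be strictly positive, got {self.spacing}")
        self.origin = (float(self.origin[0]), float(self.origin[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    def with_pixels(self, pixels: np.ndarray) -> "Image2D":
        """Copy of this image with new pixel data on the same grid."""
        return Image2D(pixels, self.spacing, self.origin)


@dataclass
class PhantomSpec:
    """Recipe for a deterministic anatomical-like test phantom.

    The phantom is a piecewise-constant slice: an elliptical "body" on a
    dark background, containing internal structures with curved and
    straight boundaries, each with a distinct gray value.  It stands in
    for an axial CT slice in experiments with known ground truth.

    ``noise_sigma`` adds Gaussian noise (gray units) as the last step and
    ``contrast_offset`` shifts all intensities globally — together these
    emulate the noise and intensity inconsistency of setup CBCT images.
    """

    shape: tuple[int, int] = (256, 256)
    n_regions: int = 6
    noise_sigma: float = 0.0
    contrast_offset: float = 0.0
    seed: int = 0
    spacing: tuple[float, float] = (1.0, 1.0)

    def __post_init__(self):
        if self.n_regions < 1:
            raise ValueError("n_regions must be >= 1")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")


def _read_dicom(path: str) -> Image2D:
    ds = pydicom.dcmread(path)
    if int(getattr(ds, "NumberOfFrames", 1)) > 1:
        raise UnsupportedFormatError(f"{path}: multi-frame DICOM is not supported")
    if int(getattr(ds, "SamplesPerPixel", 1)) != 1:
        raise UnsupportedFormatError(f"{path}: only single-sample (grayscale) DICOM is supported")
    arr = ds.pixel_array.astype(np.float64)
    slope = float(getattr(ds, "RescaleSlope", 1.0))
    intercept = float(getattr(ds, "RescaleIntercept", 0.0))
    if slope != 1.0 or intercept != 0.0:
        arr = arr * slope + intercept
    spacing = getattr(ds, "PixelSpacing", None)
    spacing = (float(spacing[0]), float(spacing[1])) if spacing is not None else (1.0, 1.0)
    return Image2D(arr, spacing)


def load_image(path: str | os.PathLike, format_hint: str | None = None) -> Image2D:
    """Read a DICOM, PNG or TIFF grayscale image.

    Pixel spacing is taken from DICOM metadata when present; raster
    formats default to ``(1.0, 1.0)``.  Values are cast to float without
    any rescaling beyond what the file itself declares.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    UnsupportedFormatError
        For color or multi-frame inputs.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    fmt = (format_hint or os.path.splitext(path)[1].lstrip(".")).lower()
    if fmt in ("dcm", "dicom", "ima") or pydicom.misc.is_dicom(path):
        return _read_dicom(path)
    if fmt not in ("png", "tif", "tiff"):
        raise UnsupportedFormatError(f"{path}: unsupported format {fmt!r}")
    arr = iio.imread(path)
    if arr.ndim == 3:
        if arr.shape[2] == 1:
            arr = arr[:, :, 0]
        else:
            raise UnsupportedFormatError(f"{path}: color images are not supported")
    return Image2D(arr.astype(np.float64))


def save_image(img: Image2D, path: str | os.PathLike, dtype=np.uint16) -> None:
    """Write pixels to PNG/TIFF. Values are clipped to the dtype range."""
    info = np.iinfo(dtype)
    arr = np.clip(np.rint(img.pixels), info.min, info.max).astype(dtype)
    iio.imwrite(os.fspath(path), arr)


def save_csv(img: Image2D, path: str | os.PathLike) -> None:
    """Dump the pixel array plus spacing as a plain-text fixture."""
    header = f"spacing {img.spacing[0]} {img.spacing[1]}"
    np.savetxt(os.fspath(path), img.pixels, delimiter=",", header=header)


def load_csv(path: str | os.PathLike) -> Image2D:
    spacing = (1.0, 1.0)
    with open(path) as fh:
        first = fh.readline()
    if first.startswith("# spacing"):
        parts = first.split()
        spacing = (float(parts[2]), float(parts[3]))
    return Image2D(np.loadtxt(os.fspath(path), delimiter=","), spacing)


def resample_to_grid(
    img: Image2D,
    target_spacing: tuple[float, float],
    target_shape: tuple[int, int],
    interpolation: str = "bilinear",
) -> Image2D:
    """Resample an image onto a new pixel grid.

    Used to up-sample CBCT slices (384x384 @ 1.27 mm) onto the planning-CT
    grid (512x512 @ 1.17 mm) before registration.  The physical field of
    view is preserved up to edge truncation; samples falling outside the
    source are padded with the source minimum, which mimics the air
    background of CT slices and avoids spurious bright edges in gradient
    images.
    """
    ts = (float(target_spacing[0]), float(target_spacing[1]))
    if ts[0] <= 0 or ts[1] <= 0:
        raise ValueError(f"target_spacing must be strictly positive, got {ts}")
    if interpolation not in ("nearest", "bilinear"):
        raise ValueError(f"interpolation must be 'nearest' or 'bilinear', got {interpolation!r}")
    if ts == img.spacing and tuple(target_shape) == img.shape:
        return Image2D(img.pixels.copy(), img.spacing, img.origin)
    # Map target pixel centers to source index coordinates (half-pixel centers).
    scale = (ts[0] / img.spacing[0], ts[1] / img.spacing[1])
    offset = (0.5 * scale[0] - 0.5, 0.5 * scale[1] - 0.5)
    order = 0 if interpolation == "nearest" else 1
    out = ndimage.affine_transform(
        img.pixels,
        np.diag(scale),
        offset=offset,
        output_shape=tuple(target_shape),
        order=order,
        mode="grid-constant",  # honors the half-pixel cell extent at borders
        cval=float(img.pixels.min()),
    )
    return Image2D(out, ts, img.origin)


def window_intensity(img: Image2D, lo: float, hi: float) -> Image2D:
    """Clip gray values to [lo, hi] (CT-style windowing).

    Neither CT nor CBCT values are rescaled by default anywhere in the
    package; this is an opt-in preprocessing step for images whose
    extreme values (e.g. metal, couch hardware) would otherwise dominate
    the histogram range.
    """
    if hi <= lo:
        raise ValueError(f"window must satisfy lo < hi, got ({lo}, {hi})")
    return img.with_pixels(np.clip(img.pixels, lo, hi))


def _disk_mask(shape, center, radii, angle_deg=0.0):
    rr, cc = np.mgrid[0 : shape[0], 0 : shape[1]].astype(np.float64)
    rr -= center[0]
    cc -= center[1]
    if angle_deg:
        a = np.deg2rad(angle_deg)
        rr, cc = rr * np.cos(a) - cc * np.sin(a), rr * np.sin(a) + cc * np.cos(a)
    return (rr / radii[0]) ** 2 + (cc / radii[1]) ** 2 <= 1.0


def make_phantom(spec: PhantomSpec) -> Image2D:
    """Generate a deterministic piecewise-constant anatomical phantom.

    Region 1 is the dark background; region 2 (when requested) is a large
    body ellipse; further regions alternate between elliptical inclusions
    (curved boundaries) and axis-aligned rectangles (straight boundaries),
    all placed reproducibly from ``spec.seed``.  Each region has a
    distinct gray value, so a noiseless ``n_regions`` phantom has exactly
    ``n_regions`` distinct values.
    """
    rng = np.random.default_rng(spec.seed)
    M, N = spec.shape
    values = np.linspace(0.0, 240.0, spec.n_regions)
    img = np.full((M, N), values[0])
    if spec.n_regions >= 2:
        body_c = (M / 2 + rng.uniform(-M * 0.02, M * 0.02), N / 2 + rng.uniform(-N * 0.02, N * 0.02))
        body_r = (M * rng.uniform(0.32, 0.38), N * rng.uniform(0.36, 0.42))
        body = _disk_mask((M, N), body_c, body_r, rng.uniform(-10, 10))
        img[body] = values[1]
        for k in range(2, spec.n_regions):
            # keep structures well inside the body so rigid motions keep them in frame
            c = (
                body_c[0] + rng.uniform(-0.45, 0.45) * body_r[0],
                body_c[1] + rng.uniform(-0.45, 0.45) * body_r[1],
            )
            if k % 2 == 0:
                r = (rng.uniform(0.08, 0.22) * body_r[0], rng.uniform(0.08, 0.22) * body_r[1])
                mask = _disk_mask((M, N), c, r, rng.uniform(0, 180))
            else:
                h = rng.uniform(0.10, 0.25) * body_r[0]
                w = rng.uniform(0.10, 0.25) * body_r[1]
                rr, cc = np.mgrid[0:M, 0:N]
                mask = (np.abs(rr - c[0]) <= h) & (np.abs(cc - c[1]) <= w)
            img[mask & body] = values[k]
    img += spec.contrast_offset
    if spec.noise_sigma > 0:
        img = img + rng.normal(0.0, spec.noise_sigma, size=img.shape)
    return Image2D(img, spec.spacing)


def degrade_cbct_like(
    img: Image2D, noise_sigma: float, contrast_offset: float = 0.0, seed: int = 0
) -> Image2D:
    """Additive Gaussian noise plus a global intensity shift.

    Emulates the two dominant CBCT degradations relative to planning CT:
    elevated noise and a modality intensity offset.
    """
    rng = np.random.default_rng(seed)
    out = img.pixels + contrast_offset
    if noise_sigma > 0:
        out = out + rng.normal(0.0, noise_sigma, size=out.shape)
    return img.with_pixels(out)
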