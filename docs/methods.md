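# Methods

## Problem and model

Image-guided radiotherapy aligns the cone-beam CT (CBCT) acquired at the
treatment machine with the planning CT so that the dose is delivered to
the planned target.  `swtreg` performs this alignment for 2D slices as a
rigid registration: it searches for the translation and in-plane
rotation (dx, dy, theta) that maximizes a histogram-based similarity
between a fixed reference image R and a moving floating image F.

Plain mutual-information registration uses only the gray-value
co-occurrence statistics of the pair and ignores where things are in the
image.  The method implemented here restores spatial sensitivity by
scoring *edge structure* alongside intensity:

1. Both images are decomposed three levels with the **stationary
   (undecimated, a-trous) wavelet transform** (SWT).  At level *j* the
   analysis filters are dilated by inserting `2^j - 1` zeros between
   taps and applied with stride 1, so every sub-band keeps the image
   shape and the transform commutes with shifts — edges do not move
   between decomposition levels.
2. The approximation (low-frequency) content is zeroed and the detail
   bands (LH, HL, HH of every level) are inverse-transformed.  The
   result, the **gradient image**, is mean-suppressed and concentrates
   its energy at tissue boundaries.  This is done once per image,
   before optimization; candidate transforms are applied to the
   floating gradient image rather than recomputing it.
3. Alignment of a candidate transform is scored by the normalized
   mutual information of the intensity pair, `NMI_i`, and of the
   gradient pair, `NMI_g`, fused by a logistic weight:

       NMI = f(v) * NMI_i + (1 - f(v)) * NMI_g
       f(v) = 1 / (1 + exp(-(v - 0.5) / T)),   v = (x + y) / 2

   with temperature `T = 0.04`.  Entropies use log base 2; NMI =
   (H(A) + H(B)) / H(A,B) lies in [1, 2] and is insensitive to the size
   of the overlap region, which changes with every candidate transform.
4. The fused measure is maximized over (dx, dy, theta) with Powell's
   direction-set method using Brent line searches (the driver minimizes
   the negated measure).

`mode="mi_only"` scores with `NMI_i` alone — the classical baseline the
method is compared against.

## The NMI range mapping inside f(v)

The logistic weight is centered at v = 0.5, but raw NMI lives in
[1, 2]: fed directly, f saturates at 1 and the fusion collapses to the
intensity term.  By default the components are therefore mapped through
`NMI - 1` when computing v (the combination itself always mixes the raw
values), so v spans the logistic's active range: near-perfect alignment
(both NMI → 2) drives f → 1 and the intensity term takes over, while
far from alignment f → 0 and the edge-driven gradient term dominates.
A literal mode (`nmi_rescale=False`) retains the saturating behavior
for comparison.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `levels` | 3 | SWT decomposition depth |
| `wavelet` | `haar` | orthonormal filter bank (`db2`–`db8` supported); shortest support gives the sharpest edge localization and, empirically, the least-biased optimum |
| `boundary` | `symmetric` | reflect extension per level; `periodic` is exactly invertible and shift-equivariant |
| `bins` | 64 | joint-histogram size per axis; the usual bias/variance compromise for images of ~10^4–10^5 px |
| `T` | 0.04 | logistic temperature; smaller values switch between the two regimes more abruptly |
| `xtol` / `ftol` | 1e-3 / 1e-5 | Powell tolerances in scaled units (1 px, 1 px, 1 degree); xtol well below 1 px is required for subpixel recovery |
| `initial_shift` | (0, 0) | optimizer start, in px; used to bring grossly misaligned pairs (e.g. an 80 mm couch offset) into capture range |

Translations are in pixels internally; physical units enter through
`Image2D.spacing` (mm per pixel), and the CLI converts mm to px.
Angles are degrees throughout.

## Numerical choices

**Sampling-grid offset.**  Histogram measures spike whenever a
candidate maps every sample exactly onto the pixel lattice (integer
shifts at theta = 0): interpolation blur vanishes, the joint histogram
sharpens, and line searches park on the artifact.  The driver therefore
evaluates both images on a grid shifted by half a pixel
(`GRID_OFFSET`), so every candidate interpolates and no lattice point
is special.  The measure's true optimum is unmoved because both images
are sampled identically.

**Coarse capture stage.**  Two facts limit the fused measure's capture
range: far from alignment f ≈ 0 reduces it to the gradient NMI, which
is flat on images whose gradient content is a sparse set of thin edges;
and on noisy images the histogram ripples at sub-pixel scale, trapping
unit-step line searches in local dimples.  The driver therefore runs a
first Powell pass on the intensity NMI with line-search steps enlarged
4x (`coarse_scale`) from the starting shift, then refines the mode's
own measure from the result.  This is the automatic counterpart of the
manual pre-shift used clinically to narrow a large initial offset, and
it is applied identically in both modes so comparisons between them
reflect the measures, not the initialization.  `coarse_init="none"`
disables it.

**Boundary handling.**  The periodic transform is a circulant operator:
reconstruction is exact to machine precision and circular shifts commute
with decomposition — these identities are asserted in the tests under
`boundary="periodic"`.  The symmetric mode reflect-extends each level
to avoid wrap-around ghost edges in the gradient images used for
registration; with asymmetric orthogonal Daubechies filters no
symmetric extension is exactly invertible at the borders, so its
reconstruction is exact only in the interior (beyond the cumulative
filter reach).  Registration accuracy is unaffected because both images
are treated identically.

**Histogram ranges.**  Bin edges span each image's own (min, max),
captured once at registration start and reused for every candidate so
the objective stays smooth across iterations.  Out-of-bounds samples of
the transformed floating image are excluded (overlap-only estimation);
candidates with empty overlap score the worst possible measure (1)
rather than raising, so line searches can traverse them.

**Degenerate inputs.**  Constant image pairs have zero joint entropy
and undefined NMI (raised as a degenerate-entropy error); an empty
overlap at the optimizer's starting position is a hard error.

**Rotation convention.**  Rotation is about the image center
`((M-1)/2, (N-1)/2)`, counter-clockwise in (x, y) = (column, row)
coordinates; transforms compose and invert exactly through homogeneous
3x3 matrices.

## Synthetic data

`make_phantom` generates a deterministic piecewise-constant slice: a
large body ellipse on a dark background containing elliptical and
rectangular inclusions with distinct gray values — curved and straight
boundaries at several scales, so gradient images are non-trivial.
`degrade_cbct_like` adds the two dominant CBCT degradations relative to
planning CT: Gaussian noise and a global contrast offset.

The experiment protocols run at desk scale: a 256x256 phantom instead
of the 512x512 clinical CT grid.  The recovery protocol applies ten
preset motions spanning +-30 px and -5..+2 degrees and checks that the
recovered parameters match; the linearity protocol declares a CT-like
600 mm field of view (spacing 600/256 mm/px), pre-shifts a noisy
floating image along one axis by 80–100 mm in 5 mm steps, and fits
recovered vs. preset shift (slope -1, R^2 ~ 1, rotation ~ 0 indicate
consistency).  Noise in these protocols is 5% of the phantom's dynamic
range.

What the phantom does *not* emulate: anatomical texture (real CT slices
have dense gradient content everywhere, which widens the fused
measure's capture basin), CBCT shading/cupping artifacts and scatter
(low-frequency intensity inconsistency — precisely what the gradient
term is insensitive to), and genuinely multimodal intensity mappings.
Passing the phantom protocols therefore demonstrates the geometry,
measures and optimization are correct, not that the method's clinical
advantage over plain NMI transfers to every noise regime: under purely
additive noise the two modes recover transforms equally well (the
paired comparison in the acceptance script computes both means), and
the fused measure's edge comes into play only when low-frequency
intensity inconsistency is present.

## Known limitations

- Capture range is finite (roughly +-30 px / +-10 degrees on the
  256 px phantom with the coarse stage); larger offsets need
  `initial_shift`, mirroring clinical practice.
- The symmetric-boundary inverse transform is approximate within the
  filter reach of image borders (see above).
- Gradient images of noisy inputs are noisy: the detail bands pass
  high-frequency noise, so under heavy noise (>= ~10% of the dynamic
  range at 64 bins) both similarity measures lose their far-field
  signal and capture fails before accuracy degrades.
- Only single-frame grayscale inputs; 3D volumes, deformable models and
  HU calibration are out of scope.
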