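# Methods

This note records the model, the parameter defaults and why they are what
they are, the numerical choices, and what the synthetic evaluation does
and does not establish.

## Pipeline model

The segmentation target is the retinal vessel tree in a color fundus
photograph.  Vessels are elongated, locally line-like, darkest in the
green channel, and span widths from ~1 px (capillary endpoints) to ~10 px
(arcade vessels, at DRIVE-scale resolution).  The pipeline assumes
nothing else about the scene: no optic-disc, lesion, or illumination
model.  All intensities are scaled to [0, 1] at load time so thresholds
and bias parameters operate on a fixed scale; no contrast preprocessing
(CLAHE or otherwise) is applied before filtering.

Stage order: inverted green channel → directional filter bank →
direction-restricted multi-scale line detection → coherence-enhancing
diffusion → per-direction binarization → OR-recombination.  Directions
are processed independently, so the output is independent of their
execution order; the whole pipeline is deterministic.

## Directional filter bank

Each transfer function is a separable polar product on the DFT grid.

- **Angular factor**: Knutsson's `cos²(π(ϕ−ϕ_c)/(2ϕ_BW))` kernel with
  centers `ϕ_c = iπ/k` and half-support `ϕ_BW = π/k`.  At this spacing
  the kernels sum to exactly 1 at every orientation, which makes the
  bank self-inverting up to the radial factor.  `k = 8` is the default
  (22.5° apart); `k` and `ϕ_BW` are configurable, including the
  16-band/π/16 variant.
- **Radial factor**: the analog band-pass Butterworth
  `(ρB)^{2n} / ((ρB)^{2n} + (ρ²−ρ_o²)^{2n})` with `ρ_o = 30`, `B = 60`
  bins, `n = 2`, giving half-power edges near ρ ≈ 12 and ρ ≈ 64 — i.e.
  spatial periods of roughly 2–10 px on a 128-px raster, matching vessel
  cross-sections.  An alternative reading of the band-pass, with the
  bandwidth constant alone in the numerator
  (`B^{2n}/(B^{2n}+(ρ²−ρ_o²)^{2n})`), is selectable as
  `dfb.radial_form: constant_bw`; with these parameter values it
  collapses to a ±1-bin ring at ρ = 30 and is useless for segmentation,
  which is why it is not the default.
- **Conventions**: frequency-plane angles are folded modulo π so each
  filter passes both antipodal half-planes and outputs stay real; the
  two aliases on the Nyquist row/column of even-sized grids are averaged
  to keep the transfer functions exactly Hermitian; the DC bin is forced
  to zero (a constant image decomposes to exactly zero).  A filter
  tagged with center angle ϕ_c passes *spatial* structures oriented at
  ϕ_c; since a line's spectrum is perpendicular to the line, the angular
  kernel is centered at ϕ_c + π/2 in the frequency plane.
- **Aperture handling**: the dark region outside the field of view is a
  step of ~0.5 intensity; pushed through a sharp band-pass it rings
  across the whole raster at amplitudes far above vessel contrast.
  Before decomposition the exterior is filled with the in-FOV mean
  intensity; in-FOV values are untouched.

## Multi-scale line detector

Per sub-band and scale `L` (odd, 1…15; window `W = 15`), the response at
a pixel is the maximum over 11 scan angles, evenly spaced across
±ϕ_BW/2 around the band orientation, of the mean intensity along the
length-`L` line through the pixel, minus the `W×W` window mean.  The
printed form of the detector adds the window mean instead; a sum cannot
separate a line from flat background (a constant image would score `2c`
rather than 0), so the subtractive form is the default and the additive
one remains selectable (`msld.eq4_sign: plus_as_printed`).

Line sampling uses bilinear interpolation at unit spacing.  Samples (or
bilinear corner pixels) outside the raster are dropped and the mean is
renormalized over the remaining weight — an edge-shrink policy that
avoids rim artifacts inside the FOV.  The production implementation
accumulates integer-shifted copies of the image weighted by the merged
bilinear tap weights, which is exactly equivalent to the per-pixel
definition (the test suite checks equality to 1e-9 against an
independent gather implementation).

Each scale's response is standardized to zero mean and unit standard
deviation (population convention) over the FOV, and the scales are
averaged together with the inverted green channel at equal weight,
divisor `n_L + 1 = 9`.  Standardization is per scale, before combining,
and FOV-restricted.

The omni-directional baseline (`segment_baseline` /
`omnidirectional_msld`) is the classic detector: the same multi-scale
machinery with the winning line searched over 12 angles at 15° on the
inverted green channel itself, binarized once.  It exists for
comparison and is not a mode of the main pipeline.

## Coherence-enhancing diffusion

The structure tensor uses Gaussian derivatives at `σ_grad = 1 px` and
tensor smoothing at `ρ_tensor = 4 px`.  Its closed-form eigensystem
(`α = √((s₁₁−s₂₂)² + 4s₁₂²)`, `μ₁,₂ = (s₁₁+s₂₂±α)/2`,
`θ = ½·atan2(2s₁₂, s₁₁−s₂₂)`) feeds the diffusion tensor: `λ₁ = c₁`
across the dominant gradient and
`λ₂ = c₁ + (1−c₁)·exp(−c₂/(μ₁−μ₂)²)` along the coherent orientation, so
`λ₂ → 1` as coherence grows and smoothing runs parallel to edges.  When
`μ₁ = μ₂` the tensor is the isotropic floor `c₁·I`.

Defaults `c₁ = 0.01`, `c₂ = 1.0`, `Δt = 0.15`, 20 steps are conventional
coherence-enhancing settings; all are configurable.  The update is an
explicit finite-volume step: fluxes are evaluated on cell faces
(arithmetic-mean tensor components, two-point normal derivative,
averaged tangential derivative) and differenced, with zero flux through
the boundary.  Interior face fluxes telescope, so the global mean is
conserved to machine precision, and a constant image is an exact fixed
point.  `Δt ≤ 0.25` is enforced (explicit 2-D stability with
conductivities ≤ 1).  With `D = I` the scheme reduces to the five-point
heat stencil and converges to the continuous Gaussian kernel, which the
tests verify on a delta image.

## Binarization

Two stages per direction:

1. **Extension removal.**  Pixels whose response falls below
   `mean − k·std` of their local window are reset to the in-region
   minimum (`k = −1.5`, i.e. the cut sits at mean + 1.5 std — only
   locally outstanding responses survive; a constant response passes
   unchanged because the inequality is strict).  Local statistics are
   computed over in-FOV pixels only.  The statistics window defaults to
   31 px: it must be large compared to the widest vessel, because a
   window comparable to the vessel width lets the vessel dominate its
   own statistics and the rule then removes vessel interiors rather than
   endpoint extensions (with a 15-px window, interior survival on
   wide-vessel phantoms drops from 93% to 71%).  Whole-region statistics
   are selectable (`niblack.local: false`).  The background value is the
   in-region minimum rather than 0 so the reset mass sits at the edge of
   the histogram instead of mid-range.
2. **Otsu-seeded scalar LBG.**  The threshold is fit on the *surviving*
   response values: the seed center (Otsu's 256-bin threshold) is split
   by ±δ, pixels are assigned to the nearest center, centers update to
   their cluster means, and the absolute distortion `D_k = Σ|x−C|` is
   tracked until its relative decrease reaches ε (defaults
   δ = 10⁻³ of the range, ε = 10⁻⁴, ≤ 100 iterations); the threshold is
   the midpoint of the converged centers.  Fitting on all in-region
   values instead (selectable as `lbg.sample: region`) puts over 90% of
   the sample mass in the artificial spike of reset pixels; Otsu and LBG
   then merely re-find the spike boundary, every survivor is classified
   vessel, and the clustering stage does no work — hence the
   survivors-only default.  An emptied cluster is re-seeded at the
   extreme sample value on its side.

Vessels are the strictly-above-threshold survivors; the directional maps
are OR-ed (for boolean maps, OR equals saturating addition) and clipped
to the FOV.  No region growing, hysteresis, or morphological cleanup is
applied.

## FOV estimation

When no mask is supplied, the FOV is estimated from the red channel
(strongest aperture/background contrast): pixels brighter than half the
midpoint of the two class means at the red channel's Otsu cut, largest
connected component, holes ≤ 1024 px filled, 2 px rim erosion.  The
two-means midpoint is used instead of the raw Otsu threshold because on
near-binary histograms the between-class variance plateaus and the raw
argmax can land at the low edge.  A supplied mask always bypasses
estimation.

## Synthetic phantoms: what they emulate and what they do not

The generator renders quadratic-Bézier centerlines as flat-top tubes
with a 1-px anti-aliased edge, widths tapering to 60% from root to tip,
vessels darker than background in the green channel by a per-vessel
contrast fraction, an optional central light reflex (a Gaussian midline
bump restoring 50% of the vessel's depth), a smooth illumination
gradient, additive Gaussian noise, and a circular FOV.  Ground truth is
the tube support (pixel centers inside the tube).  All randomness
derives from the spec seed; identical seeds give bit-identical images.

Two fixed suites define the evaluation conditions, chosen once as a
scaled-down (128², roughly ¼ DRIVE resolution) version of fundus
phenomenology:

- **easy** (10 images, seeds 100–109): 4 straight vessels, widths
  2–6 px, contrast 50–80% of background, noise σ = 0.01;
- **hard** (8 images, seeds 200–207): 5 curved vessels, widths 1–3 px
  (one exactly 1 px), contrast 30–35%, central reflex, noise σ = 0.02 —
  the faint-vessel regime the directional design targets.

The phantoms exercise every pipeline stage with exact ground truth, but
they are sparse (4–5 vessels versus hundreds of segments in a real
retina), have no optic disc, exudates, hemorrhages, or vessel
branching/crossings, and use white noise rather than sensor texture.
Passing the phantom suites therefore demonstrates the mechanics and the
directional-vs-omni-directional ordering, not dataset-level accuracy;
numbers on DRIVE-class data must be measured on that data via the CLI.

One consequence of sparsity is visible in the results: each directional
response is standardized to unit variance, so a sub-band containing no
aligned vessel amplifies its band-pass noise to vessel-like amplitude,
and after diffusion (which enhances coherent streaks in noise) some of
those survivors are indistinguishable from faint vessels by any
threshold.  On the easy suite this caps the mean specificity near 0.95;
on dense real vasculature every band carries vessels and the effect is
correspondingly weaker.

## Numerical choices and degenerate inputs

- Coordinates are 0-based, row-major, pixel centers at integers; spatial
  angles measured from the column axis toward increasing rows.
- Population (divide-by-N) standard deviation throughout.
- Standardizing a constant response, thresholding a constant sample, or
  computing metrics with an empty class raises a specific error rather
  than returning silent zeros; a direction whose cleaned response is
  constant yields an empty map.
- LBG ties in the assignment step go to the lower center; distortion
  monotonicity holds for well-separated clusters (and is tested on the
  two-Gaussian reference mixture) but is not guaranteed for strongly
  skewed data, since the mean update does not minimize absolute
  distortion.
- The detector's rotation covariance is only approximate on a square
  grid (DFT anisotropy, exact-vs-bilinear line taps): rotating the scene
  by one band spacing reproduces the shifted band's response to within
  ~4–5% of the response range, with correlation above 0.99.

## Known limitations

- No multi-annotator ground-truth handling; mask readers binarize at
  nonzero.
- The pipeline is tuned by configuration, not learned; parameters that
  depend on image scale (`ρ_o`, `B`, window sizes) must be adjusted for
  rasters far from the 128–600 px range, and the radial band is
  specified in absolute frequency bins by default.
- ROC/AUC analysis is intentionally out of scope: the method produces
  per-direction hard decisions, not a single ranked response.
- Per-direction processing is embarrassingly parallel but executed
  serially.
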