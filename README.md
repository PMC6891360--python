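# dirvessel

Directional multi-scale line detection for retinal blood-vessel
segmentation.

Automated mapping of the retinal vasculature from color fundus
photographs is a standard first step in screening for diabetic
retinopathy and related pathologies.  Classical multi-scale line
detectors score each pixel by the best-matching ("winning") line segment
through it, but when one detector scans all orientations at once,
high-contrast vessels dominate the response and faint vessels — above all
the 1-pixel-wide endpoints of the vascular tree — are washed out at the
binarization step.  `dirvessel` implements the directional variant of
the approach: the image is first split into orientation sub-bands, and a
line detector restricted to each band's narrow angular range scans only
structures aligned with it, so faint vessels never compete with strong
structure at other angles.

## Method

For an RGB fundus image the pipeline works on the inverted green channel
`I_igc = 1 − g` (vessels bright on dark background) and proceeds:

1. **Directional filter bank (DFB).**  `k = 8` oriented band-pass
   filters in the frequency domain, `H(ρ, ϕ) = H_radial(ρ) · H_angular(ϕ)`
   with a Butterworth band-pass radial factor (order `n = 2`, center
   `ρ_o = 30`, bandwidth `B = 60` frequency bins) and Knutsson's `cos²`
   orientation kernel with half-support `ϕ_BW = π/k`.  The angular
   kernels form an exact partition of unity, so the sub-images sum back
   to the band-pass-filtered image.
2. **Direction-restricted multi-scale line detector (MSLD).**  In each
   sub-band, and at each scale `L ∈ {1, 3, …, 15}` inside a `W = 15`
   window, the response is the winning-line average over 11 scan angles
   spanning ±ϕ_BW/2 around the band's orientation, minus the window
   mean: `M_W^L = I_max^L − I_avg^W`.  Each scale is standardized to zero
   mean / unit variance over the field of view (FOV) and the scales are
   combined with the inverted green channel at equal weight:
   `M_combined = (Σ_L M′_W^L + I_igc) / (n_L + 1)`.
3. **Coherence-enhancing diffusion (CED).**  Each combined response is
   regularized by anisotropic diffusion `∂_t L = ∇·(D ∇L)` steered by the
   structure-tensor eigensystem: conductivity `c₁ = 0.01` across the
   dominant gradient and `c₁ + (1−c₁)·exp(−c₂/(μ₁−μ₂)²)` along the
   coherent orientation, so smoothing runs along vessels, not across
   them.
4. **Per-direction binarization.**  A standard-deviation-guided rule
   removes detector artifacts (pixels below `mean − k·std` of their
   local window, bias `k = −1.5`, are reset to background), then the
   surviving response values are split into two clusters by the scalar
   Linde–Buzo–Gray algorithm seeded from Otsu's threshold; the vessel
   threshold is the midpoint of the converged cluster centers.
5. **Recombination.**  The 8 directional binary maps are OR-ed and
   clipped to the FOV.

Evaluation follows the usual FOV-restricted pixel counts:
`Sn = TP/(TP+FN)`, `Sp = TN/(TN+FP)`, `Acc = (TP+TN)/total`.

Because public fundus datasets cannot be bundled, the package ships a
first-class phantom generator (`dirvessel.phantom`) that renders
curvilinear vessels with known ground truth — tapering widths down to
1 px, adjustable contrast, curvature, central light reflex, noise, and a
circular FOV — plus two fixed evaluation suites ("easy" and "hard").
Dataset images (DRIVE/STARE/CHASE_DB1 and the like) can be processed
directly through the CLI.

## Worked example

```bash
python examples/03_segment_phantom.py
```

```
confusion inside FOV: tp=852 fp=423 tn=9949 fn=148
Sn=0.8520  Sp=0.9592  Acc=0.9498
```

The pipeline recovered 85.2% of the phantom's vessel pixels while
keeping 95.9% of the background clean, for 95.0% overall pixel accuracy
inside the field of view.  The other examples show the phantom geometry
(`01`), the orientation selectivity of the filter bank — 98.7% of a
22.5° line's energy lands in the 22.5° band (`02`) — and the headline
comparison (`04`): on hard phantoms (curved 1–3 px vessels at 30%
contrast with central reflex) the directional pipeline reaches a mean
sensitivity of 0.939 against 0.710 for the omni-directional baseline
detector on the same images.

## Command line

```bash
dirvessel phantom --level hard --n 10 --out data/        # image/gt/mask triples
dirvessel segment -i img.png [-m mask.png] -o out.png [--config cfg.yaml]
dirvessel evaluate --pred pred/ --truth gt/ --mask mask/ -o report.csv
```

When no mask is given, the FOV is estimated from the red channel
(Otsu-based level, largest component, hole fill, 2 px rim erosion).  The
YAML config mirrors `PipelineConfig`; every stage parameter
(`dfb.*`, `msld.*`, `ced.*`, `niblack.*`, `lbg.*`) is exposed.

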