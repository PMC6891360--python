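"""Synthetic curvilinear-vessel phantoms with known ground truth.

The generator emulates the aspects of fundus-image vasculature the
pipeline is sensitive to — elongated structures of varying width,
orientation and contrast on a smoothly illuminated background inside a
circular field of view — without attempting photorealism (no optic disc,
exudates or hemorrhages).  Each vessel is a quadratic Bezier centerline
rendered as a flat-top tube with a 1-px anti-aliased edge, darker than the
background in the green channel; an optional central light reflex adds a
Gaussian midline bump at 50% of the vessel's depth, the classic failure
mode of intensity thresholding.  Ground truth is the rasterized tube
support.  All randomness derives from the spec's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
from scipy.spatial import cKDTree

from .errors import ConfigurationError

__all__ = ["PhantomSpec", "generate_phantom", "phantom_suite", "analytic_vessel_fraction"]

EASY_SUITE_SEED = 100
HARD_SUITE_SEED = 200


@dataclass(frozen=True)
class PhantomSpec:
    """Conditions for one synthetic image.

    shape : raster size (rows, cols).
    n_vessels : number of vessel centerlines.
    width_range : full vessel width in px at the root (tapers to 60%).
    contrast_range : vessel darkening as a fraction of the local
        background green level.
    curvature : maximum centerline curvature (radians per pixel);
        0 gives straight vessels.
    reflex : add a central light reflex (brightened midline).
    noise_sd : additive Gaussian intensity noise (per channel).
    background : green-channel background level inside the FOV.
    gradient : amplitude of the smooth illumination gradient.
    seed : fixes all randomness.
    """

    shape: tuple = (128, 128)
    n_vessels: int = 4
    width_range: tuple = (1.0, 10.0)
    contrast_range: tuple = (0.4, 0.8)
    curvature: float = 0.0
    reflex: bool = False
    noise_sd: float = 0.01
    background: float = 0.55
    gradient: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if min(self.shape) < 32:
            raise ConfigurationError("phantom shape must be at least 32x32")
        if self.width_range[0] < 1:
            raise ConfigurationError("vessel widths must be >= 1 px")
        if self.contrast_range[0] <= 0:
            raise ConfigurationError("vessel contrast must be > 0")
        if self.n_vessels < 0:
            raise ConfigurationError("n_vessels must be >= 0")
        r = 0.47 * min(self.shape)
        if self.width_range[1] > r:
            raise ConfigurationError("vessels too wide to fit inside the FOV")


def _fov_geometry(shape):
    h, w = shape
    center = np.array([(h - 1) / 2.0, (w - 1) / 2.0])
    radius = 0.47 * min(h, w)
    return center, radius


def _sample_vessels(spec: PhantomSpec, rng: np.random.Generator):
    """Sample centerline point chains with per-point radii.

    Returns a list of (points (M, 2) row/col, radii (M,), contrast)
    triples.  The first vessel takes the minimum width of the range so a
    width-1 request is always honored exactly.
    """
    center, radius = _fov_geometry(spec.shape)
    vessels = []
    for v in range(spec.n_vessels):
        a0 = rng.uniform(0, 2 * math.pi)
        a1 = a0 + rng.uniform(0.6 * math.pi, 1.4 * math.pi)
        r_end = 0.85 * radius
        p0 = center + r_end * np.array([math.sin(a0), math.cos(a0)])
        p2 = center + r_end * np.array([math.sin(a1), math.cos(a1)])
        chord = np.linalg.norm(p2 - p0)
        mid = 0.5 * (p0 + p2)
        if spec.curvature > 0 and chord > 1:
            # sagitta of a circular arc with curvature kappa over the chord
            sag = rng.uniform(-1, 1) * spec.curvature * chord**2 / 8.0
            perp = np.array([-(p2 - p0)[1], (p2 - p0)[0]]) / chord
            p1 = mid + 2.0 * sag * perp  # Bezier control doubles the sagitta
            if np.linalg.norm(p1 - center) > 0.9 * radius:
                p1 = center + (p1 - center) * 0.9 * radius / np.linalg.norm(p1 - center)
        else:
            p1 = mid
        if v == 0:
            w0 = spec.width_range[0]
        else:
            w0 = rng.uniform(*spec.width_range)
        contrast = rng.uniform(*spec.contrast_range)
        n_pts = max(8, int(4 * chord))
        t = np.linspace(0.0, 1.0, n_pts)[:, None]
        pts = (1 - t) ** 2 * p0 + 2 * (1 - t) * t * p1 + t**2 * p2
        widths = w0 * (1.0 - 0.4 * t[:, 0])  # taper to 60% at the far end
        vessels.append((pts, widths / 2.0, contrast))
    return vessels


def analytic_vessel_fraction(spec: PhantomSpec) -> float:
    """Expected vessel-pixel fraction of the FOV (overlap ignored),
    integrated as width x arc length along each sampled centerline."""
    rng = np.random.default_rng(spec.seed)
    vessels = _sample_vessels(spec, rng)
    _, radius = _fov_geometry(spec.shape)
    area = 0.0
    for pts, radii, _ in vessels:
        seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
        mean_r = 0.5 * (radii[:-1] + radii[1:])
        area += float((2.0 * mean_r * seg).sum())
    return area / (math.pi * radius**2)


def _render(spec: PhantomSpec, vessels, rng: np.random.Generator):
    h, w = spec.shape
    center, radius = _fov_geometry(spec.shape)
    rows, cols = np.mgrid[0:h, 0:w]
    dist_c = np.hypot(rows - center[0], cols - center[1])
    fov = dist_c <= radius

    # smooth illumination gradient across the aperture
    gdir = rng.uniform(0, 2 * math.pi)
    ramp = ((rows - center[0]) * math.sin(gdir) + (cols - center[1]) * math.cos(gdir)) / radius
    bg = spec.background * (1.0 + spec.gradient * ramp)

    darkening = np.zeros((h, w))
    truth = np.zeros((h, w), dtype=bool)
    for pts, radii, contrast in vessels:
        max_r = radii.max()
        tree = cKDTree(pts)
        lo = np.maximum(pts.min(axis=0) - max_r - 2, 0).astype(int)
        hi = np.minimum(pts.max(axis=0) + max_r + 3, [h, w]).astype(int)
        rr, cc = np.mgrid[lo[0]:hi[0], lo[1]:hi[1]]
        q = np.column_stack([rr.ravel(), cc.ravel()]).astype(float)
        d, idx = tree.query(q, workers=1)
        signed = radii[idx] - d                      # >= 0 inside the tube
        alpha = np.clip(signed + 0.5, 0.0, 1.0)      # 1-px anti-aliased edge
        depth = contrast * alpha
        if spec.reflex:
            sigma = np.maximum(radii[idx] / 2.5, 0.3)
            bump = 0.5 * contrast * np.exp(-0.5 * (d / sigma) ** 2)
            depth = np.maximum(depth - bump * (alpha > 0), 0.0)
        block = darkening[lo[0]:hi[0], lo[1]:hi[1]]
        np.maximum(block, depth.reshape(rr.shape), out=block)
        t_block = truth[lo[0]:hi[0], lo[1]:hi[1]]
        t_block |= (signed >= 0).reshape(rr.shape)
    truth &= fov

    green = bg * (1.0 - darkening)
    red = (0.80 + 0.05 * ramp) - 0.25 * darkening
    blue = 0.25 - 0.10 * darkening
    rgb = np.stack([red, green, blue], axis=-1)
    rgb[~fov] = 0.02
    rgb += rng.normal(0.0, spec.noise_sd, rgb.shape)
    np.clip(rgb, 0.0, 1.0, out=rgb)
    return rgb, truth, fov


def generate_phantom(spec: PhantomSpec):
    """Render one phantom.

    Returns ``(rgb, truth, fov)``: the (H, W, 3) image in [0, 1], the
    boolean ground-truth vessel map (rasterized tube support), and the
    circular FOV mask.  The same seed yields bit-identical outputs.
    """
    rng = np.random.default_rng(spec.seed)
    vessels = _sample_vessels(spec, rng)
    return _render(spec, vessels, rng)


def _easy_spec(seed: int) -> PhantomSpec:
    return PhantomSpec(
        shape=(128, 128), n_vessels=4, width_range=(2.0, 6.0),
        contrast_range=(0.5, 0.8), curvature=0.0, reflex=False,
        noise_sd=0.01, seed=seed,
    )


def _hard_spec(seed: int) -> PhantomSpec:
    return PhantomSpec(
        shape=(128, 128), n_vessels=5, width_range=(1.0, 3.0),
        contrast_range=(0.30, 0.35), curvature=0.01, reflex=True,
        noise_sd=0.02, seed=seed,
    )


def phantom_suite(level: str, n: int | None = None, base_seed: int | None = None):
    """Generate the fixed evaluation suite.

    ``easy``: 10 images of straight, high-contrast vessels (width 2-6 px,
    contrast 0.5-0.8).  ``hard``: 8 images of curved low-contrast vessels
    (width 1-3 px at 30-35% contrast, at least one exactly 1 px wide) with
    central light reflex and doubled noise.  Per-suite base seeds (100
    easy, 200 hard) are fixed so suites are stable across runs.

    Returns a list of (rgb, truth, fov) triples.
    """
    if level == "easy":
        n = 10 if n is None else n
        base = EASY_SUITE_SEED if base_seed is None else base_seed
        specs = [_easy_spec(base + i) for i in range(n)]
    elif level == "hard":
        n = 8 if n is None else n
        base = HARD_SUITE_SEED if base_seed is None else base_seed
        specs = [_hard_spec(base + i) for i in range(n)]
    else:
        raise ConfigurationError("suite level must be 'easy' or 'hard'")
    return [generate_phantom(s) for s in specs]
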