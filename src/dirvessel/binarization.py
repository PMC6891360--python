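"""Per-direction binarization of line-detector responses.

Large-scale line detectors leave spurious "extensions" past vessel
endpoints.  These are suppressed first with a standard-deviation-guided
rule in the spirit of Niblack's local thresholding: a pixel whose response
falls below ``mean - k * std`` of its local window (bias ``k = -1.5`` by
default, i.e. below mean + 1.5 std) is reset to the background level (the
in-region minimum).  The surviving response values are then split into
two clusters with the scalar Linde-Buzo-Gray (LBG) algorithm, seeded from
the Otsu threshold, and the final threshold is the midpoint of the two
converged cluster centers.  Each directional map is thresholded
independently; the vessel map is their pixel-wise OR restricted to the
field of view.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import ConfigurationError, DegenerateInputError, GeometryError

__all__ = [
    "NiblackConfig",
    "LBGConfig",
    "remove_extensions",
    "otsu_threshold",
    "lbg_threshold",
    "binarize_direction",
    "recombine",
]


@dataclass
class NiblackConfig:
    """Extension-removal parameters.

    ``bias_k`` (default -1.5) sets the cut at ``mean - k * std``, i.e.
    mean + 1.5 std: only locally outstanding responses survive.  The
    statistics window (default 31) must be large relative to the widest
    vessel: with a window comparable to the vessel width the vessel
    dominates its own statistics and the rule removes vessel interiors
    instead of endpoint extensions.  ``local=False`` switches to
    whole-region statistics."""

    bias_k: float = -1.5
    window: int = 31
    local: bool = True

    def __post_init__(self):
        if self.window < 3 or self.window % 2 == 0:
            raise ConfigurationError("niblack window must be odd and >= 3")


@dataclass
class LBGConfig:
    """Scalar LBG parameters: the initial center split ``split_delta``
    (fraction of the sample range), the relative-distortion stopping
    tolerance ``epsilon``, and the iteration cap.

    ``sample`` chooses the pixels the threshold is fit on:
    ``"survivors"`` (default) clusters only the pixels that survived
    extension removal — the pixels already reset to the background level
    would otherwise form a dominant spike at the sample minimum that
    drags the threshold below every survivor and reduces the LBG stage to
    a no-op; ``"region"`` uses every in-region value of the cleaned
    response."""

    split_delta: float = 1e-3
    epsilon: float = 1e-4
    max_iter: int = 100
    sample: str = "survivors"

    def __post_init__(self):
        if self.split_delta <= 0 or self.epsilon <= 0:
            raise ConfigurationError("lbg split_delta and epsilon must be > 0")
        if self.max_iter < 1:
            raise ConfigurationError("lbg max_iter must be >= 1")
        if self.sample not in ("survivors", "region"):
            raise ConfigurationError("lbg sample must be 'survivors' or 'region'")


def _local_mean_std(values: np.ndarray, window: int, region: np.ndarray):
    """Sliding-window mean and population std over in-region pixels only."""
    w = region.astype(np.float64)
    cnt = ndimage.uniform_filter(w, size=window, mode="constant", cval=0.0)
    cnt = np.maximum(cnt, 1e-12)
    m = ndimage.uniform_filter(values * w, size=window, mode="constant", cval=0.0) / cnt
    m2 = ndimage.uniform_filter(values**2 * w, size=window, mode="constant", cval=0.0) / cnt
    var = np.maximum(m2 - m * m, 0.0)
    return m, np.sqrt(var)


def remove_extensions(
    response: np.ndarray,
    config: NiblackConfig | None = None,
    region: np.ndarray | None = None,
) -> np.ndarray:
    """Reset weak-response pixels to the background level.

    A pixel with response strictly below ``mean - k * std`` of its window
    is set to the in-region minimum; a constant response is returned
    unchanged (the inequality is strict and std is 0).
    """
    config = config or NiblackConfig()
    region = np.ones(response.shape, bool) if region is None else np.asarray(region, bool)
    background = float(response[region].min())
    if config.local:
        mean, std = _local_mean_std(response, config.window, region)
    else:
        vals = response[region]
        mean = np.full_like(response, vals.mean())
        std = np.full_like(response, vals.std())
    cut = mean - config.bias_k * std
    out = np.where(response < cut, background, response)
    out[~region] = background
    return out


def otsu_threshold(values: np.ndarray) -> float:
    """Otsu threshold of a 1-D intensity sample over a 256-bin histogram."""
    values = np.asarray(values, dtype=np.float64).ravel()
    if np.unique(values).size < 2:
        raise DegenerateInputError("otsu_threshold needs >= 2 distinct values")
    return float(threshold_otsu(values, nbins=256))


def lbg_threshold(
    values: np.ndarray,
    config: LBGConfig | None = None,
    init: float | None = None,
) -> float:
    """Two-cluster scalar LBG threshold seeded from Otsu.

    The seed center C0 (Otsu by default) is split into C0 -+ delta; pixels
    are assigned to the nearest center, centers updated to their cluster
    means, and the absolute distortion D_k = sum |x - C| tracked until the
    relative decrease (D_{k-1} - D_k) / D_k drops to ``epsilon`` or the
    iteration cap is hit.  Returns the midpoint (C1 + C2) / 2.  A cluster
    that empties is re-seeded at the extreme sample value on its side.
    """
    c1, c2, _ = _lbg_iterate(values, config or LBGConfig(), init)
    return float((c1 + c2) / 2.0)


def _lbg_iterate(values, config: LBGConfig, init: float | None):
    """LBG inner loop; returns (c1, c2, per-iteration distortions D_k)."""
    x = np.asarray(values, dtype=np.float64).ravel()
    if np.unique(x).size < 2:
        raise DegenerateInputError("lbg_threshold needs >= 2 distinct values")
    if init is None:
        init = otsu_threshold(x)
    delta = config.split_delta * (x.max() - x.min())
    c1, c2 = init - delta, init + delta
    history: list[float] = []
    d_prev = None
    for _ in range(config.max_iter):
        assign2 = np.abs(x - c2) < np.abs(x - c1)  # ties go to c1
        s1, s2 = x[~assign2], x[assign2]
        if s1.size == 0:
            c1 = x.min()
            s1 = x[x == c1]
            s2 = x[x != c1]
        elif s2.size == 0:
            c2 = x.max()
            s2 = x[x == c2]
            s1 = x[x != c2]
        c1, c2 = s1.mean(), s2.mean()
        d = np.abs(s1 - c1).sum() + np.abs(s2 - c2).sum()
        history.append(float(d))
        if d == 0.0:
            break
        if d_prev is not None and (d_prev - d) / d <= config.epsilon:
            break
        d_prev = d
    return float(c1), float(c2), history


def binarize_direction(
    response: np.ndarray,
    region: np.ndarray,
    nib: NiblackConfig | None = None,
    lbg: LBGConfig | None = None,
) -> np.ndarray:
    """Threshold one directional response into a boolean vessel map.

    Extension removal, then an LBG (Otsu-seeded) threshold computed from
    the surviving in-region values; vessels are the strictly-above-
    threshold pixels.  A response that is constant after extension
    removal yields an empty map (nothing distinguishable from
    background).
    """
    lbg = lbg or LBGConfig()
    region = np.asarray(region, bool)
    cleaned = remove_extensions(response, nib, region)
    if lbg.sample == "survivors":
        sel = region & (cleaned > cleaned[region].min())
    else:
        sel = region
    vals = cleaned[sel]
    if np.unique(vals).size < 2:
        return np.zeros(response.shape, dtype=bool)
    t = lbg_threshold(vals, lbg)
    out = cleaned > t
    out &= sel
    return out


def recombine(directional_maps) -> np.ndarray:
    """Pixel-wise OR of the per-direction binary maps."""
    maps = list(directional_maps)
    if not maps:
        raise ConfigurationError("recombine needs at least one map")
    shape = maps[0].shape
    out = np.zeros(shape, dtype=bool)
    for m in maps:
        if m.shape != shape:
            raise GeometryError("directional maps must share one geometry")
        out |= np.asarray(m, bool)
    return out
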