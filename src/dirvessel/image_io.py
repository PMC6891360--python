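"""Image and mask I/O, green-channel extraction, automatic FOV estimation.

Fundus photographs are read as RGB rasters normalized to [0, 1].  Vessels
have their best contrast in the green channel, where they appear dark; the
pipeline works on the *inverted* green channel so vessels are bright.  The
field of view (FOV) — the circular imaged region inside the camera
aperture — is either supplied as a mask image or estimated automatically
from the red channel, which has the strongest aperture/background contrast.

Coordinates are 0-based, row-major, with pixel centers at integer
coordinates.
"""

from __future__ import annotations

import numpy as np
import imageio.v3 as iio
from scipy import ndimage
from skimage.filters import threshold_otsu

from .errors import FormatError, EstimationError, GeometryError

__all__ = [
    "load_image",
    "inverted_green",
    "estimate_fov_mask",
    "load_mask",
    "save_mask",
]


def _to_unit_float(arr: np.ndarray) -> np.ndarray:
    """Scale an integer raster to [0, 1] by its dtype maximum."""
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(np.float64) / np.iinfo(arr.dtype).max
    out = arr.astype(np.float64)
    if out.size and out.max() > 1.0 + 1e-9:
        out = out / out.max()
    return out


def load_image(path) -> np.ndarray:
    """Read an RGB fundus image and scale intensities to [0, 1].

    Parameters
    ----------
    path : str or Path
        PNG/TIFF/PPM/JPEG raster, 8- or 16-bit.

    Returns
    -------
    (H, W, 3) float64 array with values in [0, 1].

    Raises
    ------
    OSError
        If the file cannot be read or decoded.
    FormatError
        If the raster is not 3-channel RGB (an RGBA alpha channel is
        silently dropped).
    """
    arr = iio.imread(path)
    if arr.ndim == 2 or (arr.ndim == 3 and arr.shape[2] == 1):
        raise FormatError(
            f"{path}: expected a 3-channel RGB image, got a single-channel "
            "raster; the pipeline needs the green channel of a color fundus "
            "photograph"
        )
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise FormatError(f"{path}: unsupported raster layout {arr.shape}")
    rgb = _to_unit_float(arr[..., :3])
    if rgb.shape[0] < 32 or rgb.shape[1] < 32:
        raise FormatError(f"{path}: image must be at least 32x32 pixels")
    return rgb


def inverted_green(image: np.ndarray) -> np.ndarray:
    """Return the inverted green channel (vessels become bright).

    ``igc = 1 - g`` elementwise; applying the inversion twice recovers the
    green channel exactly.
    """
    if image.ndim != 3 or image.shape[2] < 2:
        raise FormatError("inverted_green expects an (H, W, 3) RGB image")
    return 1.0 - image[..., 1]


def estimate_fov_mask(
    image: np.ndarray,
    threshold_fraction: float = 0.5,
    min_hole: int = 1024,
    erosion_margin: int = 2,
) -> np.ndarray:
    """Estimate the circular field-of-view mask from the red channel.

    The red channel separates the illuminated aperture from the dark
    background most sharply.  The reference level is the midpoint of the
    two class means at the red channel's Otsu cut (the two-means fixed
    point, which is stable even when the between-class variance plateaus
    on near-binary histograms); the mask is the largest connected
    component of pixels brighter than ``threshold_fraction`` times that
    level, with holes up to ``min_hole`` pixels filled and the result
    eroded by ``erosion_margin`` pixels to drop the bright rim.

    Raises
    ------
    EstimationError
        If thresholding yields an empty mask (e.g. an all-black image);
        the message suggests lowering ``threshold_fraction``.
    """
    red = image[..., 0] if image.ndim == 3 else image
    if float(red.max()) - float(red.min()) < 1e-12:
        raise EstimationError(
            "FOV estimation failed: the red channel is constant; "
            "try a lower threshold_fraction or supply a mask"
        )
    t = threshold_otsu(red, nbins=256)
    level = 0.5 * (red[red <= t].mean() + red[red > t].mean())
    rough = red > threshold_fraction * level
    if not rough.any():
        raise EstimationError(
            "FOV estimation produced an empty mask; "
            "try a lower threshold_fraction"
        )
    labels, n = ndimage.label(rough)
    if n > 1:
        sizes = ndimage.sum_labels(np.ones_like(labels), labels, range(1, n + 1))
        rough = labels == (1 + int(np.argmax(sizes)))
    # fill holes no larger than min_hole
    inv_labels, m = ndimage.label(~rough)
    if m:
        sizes = ndimage.sum_labels(np.ones_like(inv_labels), inv_labels, range(1, m + 1))
        for lab in range(1, m + 1):
            if sizes[lab - 1] <= min_hole:
                comp = inv_labels == lab
                # never fill the region touching the border (true outside)
                if not (comp[0].any() or comp[-1].any() or comp[:, 0].any() or comp[:, -1].any()):
                    rough |= comp
    if erosion_margin > 0:
        rough = ndimage.binary_erosion(rough, iterations=erosion_margin, border_value=1)
    if not rough.any():
        raise EstimationError("FOV mask is empty after rim erosion")
    return rough


def load_mask(path, shape=None) -> np.ndarray:
    """Read a mask image; nonzero pixels mark the inside of the FOV."""
    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    mask = arr > 0
    if shape is not None and mask.shape != tuple(shape):
        raise GeometryError(f"mask shape {mask.shape} does not match image shape {tuple(shape)}")
    return mask


def save_mask(path, mask: np.ndarray) -> None:
    """Write a boolean raster as an 8-bit PNG (0/255)."""
    iio.imwrite(path, (np.asarray(mask, bool) * np.uint8(255)))
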