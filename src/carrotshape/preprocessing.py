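"""Segmentation of a carrot silhouette from an RGB image.

A carrot photographed on a bright background is dark in the blue channel
(orange flesh reflects little blue light), so the blue plane is thresholded,
the polarity inverted so the carrot is foreground, interior holes are filled
and stray components removed.  The result is a single 8-connected,
hole-free boolean mask — the substrate every shape descriptor is computed
from.

Conventions used throughout the package: row-major arrays, origin at the
top-left, 0-based indices, coordinates refer to pixel centers.  Foreground
components use 8-connectivity; the background flood used for hole filling
uses 4-connectivity (the conventional dual pairing).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .errors import DegenerateImageError, MalformedImageError, NoObjectError

__all__ = [
    "split_channels",
    "segment_blue",
    "fill_holes",
    "remove_noise",
    "segment_image",
    "read_image",
    "write_mask",
    "read_mask",
]

_STRUCT8 = np.ones((3, 3), dtype=bool)


def split_channels(img):
    """Split an RGB image into its red, green and blue planes.

    Parameters
    ----------
    img : (H, W, 3) array
        8-bit RGB image.

    Returns
    -------
    r, g, b : (H, W) arrays
        The three channel planes; stacking them along a third axis
        reproduces the input exactly.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise MalformedImageError(
            f"expected an H x W x 3 RGB image, got shape {img.shape}"
        )
    if img.shape[0] < 1 or img.shape[1] < 1:
        raise MalformedImageError("image has no pixels")
    return img[..., 0], img[..., 1], img[..., 2]


def segment_blue(blue, threshold="otsu", invert=False):
    """Threshold the blue plane into a carrot-foreground mask.

    Foreground is the *dark* side of the threshold (``blue < t``): the
    carrot absorbs blue while the background reflects it.  ``invert=True``
    flips the polarity for rigs with a dark background.

    Parameters
    ----------
    blue : (H, W) array
        Blue-channel intensities in 0-255.
    threshold : "otsu" or int
        Threshold selection.  Otsu's method is parameter-free and suits the
        strongly bimodal dark-object / bright-background histograms this
        pipeline expects; an integer fixes the threshold explicitly.
    invert : bool
        If True, foreground is ``blue > t`` instead.

    Returns
    -------
    mask : (H, W) bool array
    t : float
        The threshold actually applied (recorded for run logs).
    """
    blue = np.asarray(blue, dtype=float)
    if threshold == "otsu":
        if np.ptp(blue) == 0:
            raise DegenerateImageError(
                "constant intensity plane: no threshold separates two classes"
            )
        t = float(threshold_otsu(blue))
    else:
        t = float(threshold)
    mask = blue > t if invert else blue < t
    return mask, t


def fill_holes(mask):
    """Fill interior holes: background components not connected to the
    image border (4-connected flood) become foreground.  Foreground never
    shrinks; the operation is idempotent."""
    mask = np.asarray(mask, dtype=bool)
    return ndi.binary_fill_holes(mask)


def remove_noise(mask, min_area_fraction=0.05):
    """Remove speckle and frame artifacts, keeping the dominant component.

    Components touching the image border that hold less than half the total
    foreground are treated as marginal-line artifacts and cleared first;
    then any component smaller than ``min_area_fraction`` of the largest is
    dropped, and finally only the largest 8-connected component survives.

    Raises
    ------
    NoObjectError
        If the mask has no foreground, or nothing survives cleaning.
    """
    mask = np.asarray(mask, dtype=bool)
    if not mask.any():
        raise NoObjectError("mask has no foreground pixels")

    labels, n = ndi.label(mask, structure=_STRUCT8)
    areas = np.bincount(labels.ravel())[1:]
    total = areas.sum()

    border = np.zeros_like(mask)
    border[0, :] = border[-1, :] = True
    border[:, 0] = border[:, -1] = True
    border_labels = np.unique(labels[border & mask])

    keep = np.ones(n + 1, dtype=bool)
    keep[0] = False
    for lab in border_labels:
        if lab and areas[lab - 1] < 0.5 * total:
            keep[lab] = False
    if not keep[1:].any():
        raise NoObjectError("all foreground components were border artifacts")

    largest = areas[keep[1:]].max()
    keep[1:] &= areas >= min_area_fraction * largest
    # only the single largest surviving component is retained
    surviving = np.flatnonzero(keep[1:]) + 1
    best = surviving[np.argmax(areas[surviving - 1])]
    return labels == best


def segment_image(img, threshold="otsu", invert=False, min_area_fraction=0.05):
    """Full preprocessing chain: split -> threshold blue -> fill -> clean.

    Returns the cleaned mask and the threshold used.  The chain is
    idempotent: feeding a rendering of the output mask back through
    produces the same mask.
    """
    _, _, b = split_channels(img)
    mask, t = segment_blue(b, threshold=threshold, invert=invert)
    mask = fill_holes(mask)
    mask = remove_noise(mask, min_area_fraction=min_area_fraction)
    mask = fill_holes(mask)
    return mask, t


def read_image(path):
    """Read an 8-bit RGB PNG/JPEG, dropping any alpha channel."""
    import imageio.v3 as iio

    img = iio.imread(path)
    if img.ndim == 3 and img.shape[2] == 4:
        img = img[..., :3]
    if img.ndim != 3 or img.shape[2] != 3:
        raise MalformedImageError(f"{path}: not an RGB image (shape {img.shape})")
    return img


def write_mask(path, mask):
    """Write a boolean mask as a single-channel 0/255 PNG."""
    import imageio.v3 as iio

    iio.imwrite(path, (np.asarray(mask, bool) * 255).astype(np.uint8))


def read_mask(path):
    """Read a 0/255 (or any grayscale) PNG back into a boolean mask."""
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr > 127
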