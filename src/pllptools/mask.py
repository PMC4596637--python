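"""Binary primordium mask by Gaussian smoothing and Otsu thresholding.

The whole-cluster mask is computed on the smoothed raw intensity image:
smoothing bridges the dark cell interiors between bright membranes so the
cluster thresholds as one solid region, and the threshold minimizing the
within-class (intraclass) intensity variance separates it from background.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .core import Mask, Volume

__all__ = ["MaskParams", "otsu_threshold", "primordium_mask", "largest_component"]


@dataclass(frozen=True)
class MaskParams:
    """Mask-stage parameters.

    sigma_mask  : Gaussian smoothing scale in µm; should be about half a
                  cell diameter so membrane/interior contrast is averaged
                  out but the cluster outline is preserved.
    keep_largest: keep only the largest 26-connected component (the cluster
                  is a single cohesive group; nearby deposited organs must
                  not inflate the mask).
    fill_holes  : fill enclosed background holes.
    """

    sigma_mask: float = 3.5
    keep_largest: bool = True
    fill_holes: bool = True

    def __post_init__(self):
        if self.sigma_mask < 0:
            raise ValueError("sigma_mask must be >= 0")


def otsu_threshold(v, nbins: int = 256) -> float:
    """Threshold minimizing within-class variance of the two-class split.

    Works on a :class:`Volume` or any array of values.  The histogram has
    ``nbins`` equal bins over the (min, max) range; the returned threshold
    is the upper edge of the last below-threshold bin, mapped back to the
    original intensity scale, so ``values > t`` is the foreground class.
    """
    x = (v.data if isinstance(v, Volume) else np.asarray(v, dtype=float)).ravel()
    lo, hi = float(x.min()), float(x.max())
    if lo == hi:
        raise ValueError("cannot threshold a constant image (degenerate histogram)")
    counts, edges = np.histogram(x, bins=nbins, range=(lo, hi))
    counts = counts.astype(np.float64)
    mids = 0.5 * (edges[:-1] + edges[1:])
    w0 = np.cumsum(counts)
    w1 = w0[-1] - w0
    sum0 = np.cumsum(counts * mids)
    mu0 = np.divide(sum0, w0, out=np.zeros_like(sum0), where=w0 > 0)
    mu1 = np.divide(sum0[-1] - sum0, w1, out=np.zeros_like(sum0), where=w1 > 0)
    # maximize between-class variance == minimize within-class variance
    between = w0 * w1 * (mu0 - mu1) ** 2
    between = between[:-1]  # split after bin k leaves both classes non-empty
    k = int(np.argmax(between))
    return float(edges[k + 1])


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Largest 26-connected component of a boolean array."""
    lab, n = ndi.label(mask, structure=np.ones((3, 3, 3)))
    if n <= 1:
        return mask
    sizes = np.bincount(lab.ravel())
    sizes[0] = 0
    return lab == int(np.argmax(sizes))


def primordium_mask(v: Volume, p: MaskParams | None = None) -> Mask:
    """Smooth, Otsu-binarize, optionally fill holes and keep the largest
    connected component."""
    p = p or MaskParams()
    if p.sigma_mask > 0:
        smoothed = ndi.gaussian_filter(v.data, sigma=v.sigma_voxels(p.sigma_mask),
                                       mode="nearest")
    else:
        smoothed = v.data
    t = otsu_threshold(smoothed)
    m = smoothed > t
    if p.fill_holes:
        m = ndi.binary_fill_holes(m)
    if p.keep_largest:
        m = largest_component(m)
    return Mask(m, v.spacing)
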