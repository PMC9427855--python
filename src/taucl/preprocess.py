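"""Image-level transforms: [0,1] scaling, SUVR, masking, FWHM smoothing.

These are the standard preparation steps of the pipeline: each tau volume is
min-max scaled to [0, 1] within the brain mask before it enters the CNN;
SUVR volumes (voxel value divided by the mean uptake of the cerebellar
reference region) feed the linear voxel-wise comparison; saliency maps are
smoothed with a small Gaussian kernel (default 2 mm FWHM) before GLM
analysis.
"""

from __future__ import annotations

import logging
from typing import NamedTuple

import numpy as np
from scipy import ndimage

from .volume import Atlas, Volume, check_same_grid

logger = logging.getLogger(__name__)

#: FWHM of a unit-variance Gaussian
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def _as_mask(mask) -> np.ndarray:
    if isinstance(mask, Atlas):
        return mask.brain_mask
    if isinstance(mask, Volume):
        return mask.data > 0
    return np.asarray(mask) > 0


class ScaleResult(NamedTuple):
    volume: Volume
    vmin: float
    vmax: float


def minmax_scale(v: Volume, mask) -> ScaleResult:
    """Scale a volume to [0, 1] using the in-mask min and max.

    Out-of-mask voxels are forced to 0 (background zeros would otherwise pin
    the minimum).  A constant in-mask image degenerates to all zeros with a
    logged warning rather than failing, so batch jobs survive pathological
    inputs.  Returns the scaled volume together with the (min, max) used,
    for provenance.
    """
    m = _as_mask(mask)
    check_same_grid(v, m, "volume and mask")
    if not m.any():
        raise ValueError("minmax_scale: mask is empty")
    vmin = float(v.data[m].min())
    vmax = float(v.data[m].max())
    out = np.zeros_like(v.data)
    if vmax > vmin:
        out[m] = (v.data[m] - vmin) / (vmax - vmin)
    else:
        logger.warning("minmax_scale: constant image inside mask (value=%g); "
                       "returning zeros", vmin)
    scaled = v.with_data(out, "scaled")
    scaled.meta.update(scale_min=vmin, scale_max=vmax)
    return ScaleResult(scaled, vmin, vmax)


def compute_suvr(v: Volume, atlas: Atlas) -> Volume:
    """Standardised uptake value ratio against the atlas reference region."""
    check_same_grid(v, atlas, "volume and atlas")
    ref = atlas.role_mask("reference")
    if not ref.any():
        raise ValueError("compute_suvr: reference region is empty")
    ref_mean = float(v.data[ref].mean())
    if ref_mean <= 0:
        raise ValueError(f"compute_suvr: nonpositive reference-region mean ({ref_mean:g})")
    out = v.with_data(v.data / ref_mean, "SUVR")
    out.meta["reference_mean"] = ref_mean
    return out


def fwhm_to_sigma_voxels(fwhm_mm: float, voxel_size_mm) -> np.ndarray:
    """Per-axis Gaussian sigma in voxel units for a given FWHM in mm."""
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    return fwhm_mm / (vs * FWHM_PER_SIGMA)


def gaussian_smooth(v: Volume, fwhm_mm: float = 2.0, truncate: float = 4.0) -> Volume:
    """Separable Gaussian smoothing with an edge-renormalised kernel.

    sigma per axis is ``fwhm_mm / (voxel_size * 2*sqrt(2*ln 2))``.  At the
    grid boundary the truncated kernel is renormalised (smooth the image and
    an all-ones image with zero padding, then divide), so no intensity mass
    drains into the outside of the field of view.
    """
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be positive")
    sigma = fwhm_to_sigma_voxels(fwhm_mm, v.voxel_size_mm)
    num = ndimage.gaussian_filter(v.data, sigma, mode="constant", truncate=truncate)
    den = ndimage.gaussian_filter(np.ones_like(v.data), sigma, mode="constant",
                                  truncate=truncate)
    out = v.with_data(num / den)
    out.meta["smoothing_fwhm_mm"] = fwhm_mm
    return out


def apply_mask(v: Volume, mask) -> Volume:
    """Zero every out-of-mask voxel; in-mask voxels pass through unchanged."""
    m = _as_mask(mask)
    check_same_grid(v, m, "volume and mask")
    out = v.data.copy()
    out[~m] = 0.0
    return v.with_data(out)
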