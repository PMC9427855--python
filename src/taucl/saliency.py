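"""Gradient saliency maps: per-subject, per-instance input attributions.

A saliency map assigns each input voxel the magnitude of the gradient of
the CNN's scalar Centiloid output with respect to that voxel's tau value,
evaluated at the subject's observed (scaled) input.  The gradient is exact
— computed by the same backward pass used in training — not approximated.
Maps default to absolute values (the classic saliency convention rectifies
sign); signed maps are available behind a flag for sensitivity analysis.

Before GLM analysis, maps are masked to the brain and smoothed with a
Gaussian kernel (default 2 mm FWHM) because voxel-wise gradients are
visually noisy.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .preprocess import apply_mask, gaussian_smooth
from .volume import Volume

__all__ = ["SaliencyMap", "compute_saliency", "prepare_saliency", "saliency_stack"]


@dataclass
class SaliencyMap:
    """One subject's saliency volume for one trained instance."""

    volume: Volume  # value_kind == "saliency"
    subject_id: str
    fold: int
    fwhm_mm: float = 0.0  # smoothing applied so far
    signed: bool = False

    @property
    def data(self) -> np.ndarray:
        return self.volume.data


def compute_saliency(instance, v: Volume, signed: bool = False) -> SaliencyMap:
    """Exact gradient saliency of one scaled input volume.

    ``instance`` is anything exposing ``input_gradient(x)`` (a fitted
    :class:`~taucl.model.CNNResults`, or a surrogate model in tests).  The
    map has the same grid as the input and carries |d yhat / d x_voxel|
    (or the signed gradient with ``signed=True``), unsmoothed.
    """
    grad = np.asarray(instance.input_gradient(v.data))
    if grad.shape != v.data.shape:
        raise ValueError(f"gradient shape {grad.shape} != input {v.data.shape}")
    if not np.all(np.isfinite(grad)):
        raise FloatingPointError(
            f"non-finite saliency gradients (fold {getattr(instance, 'fold', '?')}, "
            f"subject {v.meta.get('subject_id', '?')})")
    data = grad if signed else np.abs(grad)
    vol = Volume(data, v.affine, "saliency",
                 meta={**v.meta, "signed": signed})
    return SaliencyMap(vol, str(v.meta.get("subject_id", "")),
                       int(getattr(instance, "fold", 0)), signed=signed)


def prepare_saliency(maps: list[SaliencyMap], mask,
                     fwhm_mm: float = 2.0) -> list[SaliencyMap]:
    """Mask then smooth saliency maps for GLM analysis.

    ``fwhm_mm = 0`` applies masking only.  The smoothing FWHM actually
    applied is recorded on each returned map.
    """
    out = []
    for m in maps:
        vol = apply_mask(m.volume, mask)
        if fwhm_mm > 0:
            vol = gaussian_smooth(vol, fwhm_mm)
        out.append(SaliencyMap(vol, m.subject_id, m.fold,
                               fwhm_mm=m.fwhm_mm + fwhm_mm, signed=m.signed))
    return out


def saliency_stack(cohort: pd.DataFrame, scaled_volumes: dict,
                   instances, mask=None, fwhm_mm: float = 2.0,
                   signed: bool = False) -> dict[int, list[SaliencyMap]]:
    """Prepared saliency maps for every (instance, subject) pair.

    ``scaled_volumes`` maps subject id -> scaled :class:`Volume`.  Returns
    ``{fold: [map per subject in cohort order]}``; masking/smoothing is
    applied when ``mask`` is given.
    """
    missing = [s for s in cohort["id"] if s not in scaled_volumes]
    if missing:
        raise KeyError(f"saliency_stack: no volume for subjects {missing[:10]}")
    stacks: dict[int, list[SaliencyMap]] = {}
    for inst in instances:
        maps = []
        for sid in cohort["id"]:
            m = compute_saliency(inst, scaled_volumes[sid], signed=signed)
            m.subject_id = str(sid)
            maps.append(m)
        if mask is not None:
            maps = prepare_saliency(maps, mask, fwhm_mm)
        stacks[int(inst.fold)] = maps
    return stacks


def save_stack(stacks: dict[int, list[SaliencyMap]], out_dir) -> list[str]:
    """Write each map as NIfTI-1 ``sal_f{fold}_{subject}.nii.gz``."""
    from pathlib import Path

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    for fold, maps in stacks.items():
        for m in maps:
            path = out / f"sal_f{fold}_{m.subject_id}.nii.gz"
            m.volume.save(path)
            written.append(path.name)
    return written
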