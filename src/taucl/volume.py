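"""In-memory containers for 3D image data.

A :class:`Volume` is a 3D grid of scalars with a voxel->mm affine and a
``value_kind`` tag tracking what stage of the pipeline produced it (raw SUV,
[0,1]-scaled CNN input, SUVR, saliency, or a t-statistic map).  An
:class:`Atlas` is an integer-labelled grid naming regions, with designated
roles (brain mask, reference region for SUVR, planted effect regions, null
regions) resolved through a small role table.

NIfTI-1 is the on-disk format throughout; nibabel handles I/O.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import nibabel as nib
import numpy as np

VALUE_KINDS = ("SUV", "scaled", "SUVR", "saliency", "tstat")


@dataclass
class Volume:
    """A 3D scalar image with spatial metadata.

    Parameters
    ----------
    data : ndarray, shape (nx, ny, nz)
        Voxel values; must be finite.
    affine : ndarray, shape (4, 4)
        Voxel-index to mm (RAS+) transform.
    value_kind : str
        One of ``SUV``, ``scaled``, ``SUVR``, ``saliency``, ``tstat``.
    """

    data: np.ndarray
    affine: np.ndarray
    value_kind: str = "SUV"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {self.data.shape}")
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"value_kind must be one of {VALUE_KINDS}")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Volume contains non-finite values")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size_mm(self) -> np.ndarray:
        """Per-axis voxel edge length in mm (from the affine)."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def with_data(self, data: np.ndarray, value_kind: str | None = None) -> "Volume":
        """Return a copy carrying new voxel values (same affine)."""
        return replace(
            self,
            data=np.asarray(data, dtype=np.float64),
            value_kind=value_kind or self.value_kind,
            meta=dict(self.meta),
        )

    def to_nifti(self) -> nib.Nifti1Image:
        return nib.Nifti1Image(self.data.astype(np.float32), self.affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def load(cls, path, value_kind: str = "SUV") -> "Volume":
        img = nib.load(str(path))
        return cls(np.asarray(img.get_fdata(), dtype=np.float64), img.affine, value_kind)


def default_affine(voxel_size_mm: float | tuple = 1.0) -> np.ndarray:
    """RAS+ affine with the given voxel size and origin at the corner."""
    vs = np.broadcast_to(np.asarray(voxel_size_mm, dtype=float), (3,))
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = vs
    return aff


@dataclass
class Atlas:
    """Integer-labelled parcellation with designated region roles.

    ``labels == 0`` is background (outside the brain).  ``roles`` maps a role
    name — ``reference`` (SUVR normalisation), ``effect_low`` (region whose
    signal tracks Centiloid below the changepoint), ``effect_high_left`` /
    ``effect_high_right`` (regions tracking Centiloid above it), ``null``
    (regions carrying no Centiloid signal) — to one or more labels.
    """

    labels: np.ndarray
    affine: np.ndarray
    name_map: dict[int, str]
    roles: dict[str, tuple[int, ...]]

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise ValueError("atlas labels must be integers")
        for role, labs in self.roles.items():
            self.roles[role] = tuple(int(l) for l in np.atleast_1d(labs))
            for lab in self.roles[role]:
                if lab not in self.name_map:
                    raise ValueError(f"role {role!r} refers to unnamed label {lab}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape  # type: ignore[return-value]

    @property
    def brain_mask(self) -> np.ndarray:
        """Boolean in-brain mask (every nonzero label)."""
        return self.labels > 0

    @property
    def voxel_size_mm(self) -> np.ndarray:
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def role_mask(self, role: str) -> np.ndarray:
        """Boolean mask of all voxels whose label fills ``role``."""
        if role not in self.roles:
            raise KeyError(f"atlas has no role {role!r}; roles: {sorted(self.roles)}")
        return np.isin(self.labels, self.roles[role])

    def label_mask(self, label: int) -> np.ndarray:
        return self.labels == label

    def save(self, path) -> None:
        nib.save(nib.Nifti1Image(self.labels.astype(np.int16), self.affine), str(path))

    @classmethod
    def load(cls, path, name_map: dict[int, str], roles: dict[str, tuple[int, ...]]) -> "Atlas":
        img = nib.load(str(path))
        return cls(np.asarray(img.dataobj).astype(np.int32), img.affine, name_map, roles)


def check_same_grid(a, b, what: str = "inputs") -> None:
    """Raise if two Volume/Atlas/ndarray grids disagree in shape."""
    sa = a.shape if not hasattr(a, "labels") else a.labels.shape
    sb = b.shape if not hasattr(b, "labels") else b.labels.shape
    if tuple(sa) != tuple(sb):
        raise ValueError(f"grid shape mismatch between {what}: {tuple(sa)} vs {tuple(sb)}")
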