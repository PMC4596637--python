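"""Core containers shared by every pipeline stage.

All image data live on a regular 3D grid with axis order ``(z, y, x)`` and
anisotropic physical voxel spacing in micrometres.  Every operation in the
package works in physical units, so confocal stacks with coarse z sampling
are handled without resampling.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

Spacing = tuple[float, float, float]


def _check_spacing(spacing) -> Spacing:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3:
        raise ValueError("spacing must have three components (z, y, x)")
    if any(s <= 0 or not np.isfinite(s) for s in spacing):
        raise ValueError(f"voxel spacing must be strictly positive, got {spacing}")
    return spacing


@dataclass(frozen=True)
class Volume:
    """A 3D scalar field with physical voxel spacing.

    Parameters
    ----------
    data
        3D array, axis order ``(z, y, x)``.  Stored as float64.
    spacing
        Voxel edge lengths in µm, ``(dz, dy, dx)``.
    """

    data: np.ndarray
    spacing: Spacing

    def __post_init__(self):
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 3:
            raise ValueError(f"Volume data must be 3D, got shape {data.shape}")
        if not np.all(np.isfinite(data)):
            raise ValueError("Volume data contains non-finite values")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in µm³."""
        return float(np.prod(self.spacing))

    def sigma_voxels(self, sigma_um: float) -> tuple[float, float, float]:
        """Convert an isotropic physical scale (µm) to per-axis voxel sigmas."""
        return tuple(sigma_um / s for s in self.spacing)

    def with_data(self, data: np.ndarray) -> "Volume":
        return Volume(data, self.spacing)


@dataclass(frozen=True)
class LabelVolume:
    """Integer cell segmentation aligned with a :class:`Volume`.

    Labels are contiguous positive integers ``1..K``; 0 is background.
    """

    labels: np.ndarray
    spacing: Spacing

    def __post_init__(self):
        labels = np.asarray(self.labels)
        if labels.ndim != 3:
            raise ValueError(f"labels must be 3D, got shape {labels.shape}")
        if not np.issubdtype(labels.dtype, np.integer):
            raise ValueError("labels must be integer-typed")
        if labels.min() < 0:
            raise ValueError("labels must be non-negative")
        object.__setattr__(self, "labels", labels.astype(np.int32, copy=False))
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    @property
    def n_labels(self) -> int:
        return int(self.labels.max())

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))


@dataclass(frozen=True)
class Mask:
    """Boolean region-of-interest volume aligned with a :class:`Volume`."""

    mask: np.ndarray
    spacing: Spacing

    def __post_init__(self):
        mask = np.asarray(self.mask)
        if mask.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {mask.shape}")
        object.__setattr__(self, "mask", mask.astype(bool, copy=False))
        object.__setattr__(self, "spacing", _check_spacing(self.spacing))

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.mask.shape

    @property
    def voxel_volume(self) -> float:
        return float(np.prod(self.spacing))

    def volume_um3(self) -> float:
        """Total physical volume of the masked region in µm³."""
        return float(self.mask.sum()) * self.voxel_volume


def check_same_grid(a, b, what: str = "inputs") -> None:
    """Raise if two grid-aligned objects differ in shape or spacing."""
    if a.shape != b.shape:
        raise ValueError(f"{what} have mismatched shapes {a.shape} vs {b.shape}")
    sa = getattr(a, "spacing")
    sb = getattr(b, "spacing")
    if not np.allclose(sa, sb):
        raise ValueError(f"{what} have mismatched spacings {sa} vs {sb}")
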