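"""Core containers for multi-channel volumes, logit maps and lesion instances.

A volume is a D-dimensional (D=3 by default, D=2 supported for cheap tests)
multi-channel image over the full rectangular index grid Gamma.  A lesion
instance is a set of voxel indices Omega within that grid, carrying a label
and its physical volume in mm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


def softmax_probability(logits: np.ndarray) -> np.ndarray:
    """Two-class Softmax probability of the foreground class.

    The models here emit a single foreground logit per voxel; the background
    logit is fixed at zero, so the two-class Softmax reduces to the logistic
    function sigma(y) = 1 / (1 + exp(-y)), a monotone map of the logit.
    """
    out = np.empty_like(logits, dtype=float)
    pos = logits >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-logits[pos]))
    ey = np.exp(logits[~pos])
    out[~pos] = ey / (1.0 + ey)
    return out


@dataclass(frozen=True)
class Volume:
    """Multi-channel image over the grid Gamma.

    Parameters
    ----------
    data:
        Array of shape ``(C, N1, ..., ND)`` — one leading channel axis
        followed by the spatial axes.
    channels:
        Ordered channel names, e.g. ``("flair", "mprage")``.
    spacing:
        Physical size of one voxel along each spatial axis, in mm.
    """

    data: np.ndarray
    channels: tuple[str, ...] = ("flair", "mprage")
    spacing: tuple[float, ...] = ()

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        object.__setattr__(self, "data", data)
        if data.ndim < 2:
            raise ValueError("volume data must have a channel axis plus >=1 spatial axis")
        if len(self.channels) != data.shape[0]:
            raise ValueError(
                f"{len(self.channels)} channel names for {data.shape[0]} data channels"
            )
        spacing = tuple(self.spacing) if self.spacing else (1.0,) * (data.ndim - 1)
        if len(spacing) != data.ndim - 1:
            raise ValueError("spacing length must match the number of spatial axes")
        if any(s <= 0 for s in spacing):
            raise ValueError("voxel spacing must be strictly positive")
        object.__setattr__(self, "spacing", spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        """Spatial dimensions N1 x ... x ND."""
        return self.data.shape[1:]

    @property
    def ndim_spatial(self) -> int:
        return self.data.ndim - 1

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def voxel_volume(self) -> float:
        """Physical volume of one voxel in mm^D."""
        return float(np.prod(self.spacing))

    def channel(self, name: str) -> np.ndarray:
        return self.data[self.channels.index(name)]

    def with_data(self, data: np.ndarray) -> "Volume":
        return Volume(data=data, channels=self.channels, spacing=self.spacing)


@dataclass(frozen=True)
class LogitMap:
    """Raw per-voxel network output y[v] with its Softmax companion p[v]."""

    values: np.ndarray
    threshold: float = 0.3

    @property
    def probabilities(self) -> np.ndarray:
        return softmax_probability(self.values)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape


@dataclass(frozen=True)
class InstanceMask:
    """One lesion domain Omega: a set of voxel indices inside Gamma.

    ``voxels`` is an ``(|Omega|, D)`` integer array sorted in C scan order.
    """

    voxels: np.ndarray
    shape: tuple[int, ...]
    spacing: tuple[float, ...]
    label: int = 0
    origin: str = "manual"

    def __post_init__(self):
        vox = np.atleast_2d(np.asarray(self.voxels, dtype=np.intp))
        if vox.size and (vox.min() < 0 or np.any(vox >= np.asarray(self.shape))):
            raise ValueError("instance voxels fall outside the image grid")
        if vox.size:
            # canonical C scan order: lexicographic with the first axis slowest
            order = np.lexsort(vox.T[::-1])
            vox = vox[order]
        object.__setattr__(self, "voxels", vox)
        object.__setattr__(self, "shape", tuple(self.shape))
        object.__setattr__(self, "spacing", tuple(self.spacing))

    @property
    def cardinality(self) -> int:
        return 0 if self.voxels.size == 0 else self.voxels.shape[0]

    def __len__(self) -> int:
        return self.cardinality

    @property
    def physical_volume(self) -> float:
        """|Omega| times the voxel volume, in mm^D."""
        return self.cardinality * float(np.prod(self.spacing))

    @property
    def index(self) -> tuple[np.ndarray, ...]:
        """Fancy-index tuple usable as ``array[mask.index]``."""
        return tuple(self.voxels.T)

    def to_dense(self) -> np.ndarray:
        dense = np.zeros(self.shape, dtype=bool)
        if self.cardinality:
            dense[self.index] = True
        return dense

    def centroid(self) -> np.ndarray:
        if self.cardinality == 0:
            raise ValueError("empty instance has no centroid")
        return self.voxels.mean(axis=0)

    def bounding_box(self, margin: int = 0) -> tuple[slice, ...]:
        """Axis-aligned bounding box of Omega grown by ``margin``, clipped to Gamma."""
        if self.cardinality == 0:
            raise ValueError("empty instance has no bounding box")
        lo = np.maximum(self.voxels.min(axis=0) - margin, 0)
        hi = np.minimum(self.voxels.max(axis=0) + margin + 1, self.shape)
        return tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))

    @classmethod
    def from_dense(
        cls,
        dense: np.ndarray,
        spacing: tuple[float, ...],
        label: int = 0,
        origin: str = "manual",
    ) -> "InstanceMask":
        vox = np.argwhere(np.asarray(dense) != 0)
        return cls(voxels=vox, shape=dense.shape, spacing=spacing, label=label, origin=origin)


class EmptyDomainError(ValueError):
    """Raised when an operation requires a non-empty voxel domain."""


def require_nonempty(omega: InstanceMask, what: str = "domain") -> None:
    if omega.cardinality == 0:
        raise EmptyDomainError(f"{what} Omega is empty")
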