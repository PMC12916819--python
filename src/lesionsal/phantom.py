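"""Synthetic two-channel phantoms with blob lesions, and tiny-model training.

The phantoms emulate the statistical structure the saliency methods assume
of preprocessed MR volumes: two co-registered channels where lesions are
hyperintense in channel 1 (FLAIR-like) and hypointense in channel 2
(MPRAGE-like), a noisy tissue background inside a brain-shaped ellipsoid
support, a constant air value far below tissue outside it, and z-score
intensity normalisation computed over the brain mask.  Lesions are smooth
spherical blobs with a one-voxel cosine-tapered edge, placed fully inside
the brain and pairwise non-overlapping, each large enough to survive the
5 mm^3 instance filter.

They make no attempt at realistic MRI physics (no bias fields, partial
volume, anatomy or scanner variability): what they support are controlled,
seeded experiments on models whose receptive field and training data are
fully known.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._nn import AdamState
from .instances import label_instances
from .models import TinyCNN
from .volume import InstanceMask, Volume


class PlacementError(RuntimeError):
    """Lesion placement failed after the capped number of retries."""


@dataclass(frozen=True)
class PhantomConfig:
    """Generation parameters for one synthetic phantom.

    Defaults give a 64^3 volume at 1 mm isotropic spacing with 8 lesions of
    1.5–4 mm radius, +3 channel-1 and -2 channel-2 lesion contrast against a
    unit-variance background — a separation comparable to what z-scored
    FLAIR lesions show against normal-appearing white matter.
    """

    dims: tuple[int, ...] = (64, 64, 64)
    spacing: tuple[float, ...] = (1.0, 1.0, 1.0)
    n_lesions: int = 8
    radius_range_mm: tuple[float, float] = (1.5, 4.0)
    contrast_ch1: float = 3.0
    contrast_ch2: float = 2.0
    noise_std: float = 1.0
    air_value: float = -10.0
    brain_semi_axes: tuple[float, ...] | None = None  # default: 0.42 * dims
    channels: tuple[str, ...] = ("flair", "mprage")
    seed: int = 0
    #: explicit lesion centres (voxel coords) and radii (mm); when given they
    #: override random placement — used for controlled two-lesion setups
    lesion_centers: tuple[tuple[float, ...], ...] | None = None
    lesion_radii: tuple[float, ...] | None = None

    def __post_init__(self):
        if self.radius_range_mm[0] <= 0:
            raise ValueError("lesion radii must be positive")
        if self.contrast_ch1 <= 0 or self.contrast_ch2 <= 0:
            raise ValueError("lesion contrasts must be positive")

    @property
    def semi_axes(self) -> tuple[float, ...]:
        if self.brain_semi_axes is not None:
            return self.brain_semi_axes
        return tuple(0.42 * d for d in self.dims)


@dataclass
class Phantom:
    """A generated volume with its ground-truth and brain masks."""

    volume: Volume
    gt_mask: np.ndarray
    brain_mask: np.ndarray
    config: PhantomConfig = field(repr=False, default=None)

    @property
    def gt_instances(self) -> list[InstanceMask]:
        return label_instances(self.gt_mask, self.volume.spacing,
                               origin="ground_truth", min_volume_mm3=0.0)


def make_brain_mask(dims: tuple[int, ...], semi_axes: tuple[float, ...]) -> np.ndarray:
    """Centred ellipsoid support mask; semi-axes in voxel units.

    Semi-axes larger than the grid allows are clipped (with a warning) so the
    ellipsoid always fits.
    """
    import warnings

    dims = tuple(dims)
    semi = np.asarray(semi_axes, dtype=float)
    limit = (np.asarray(dims) - 1) / 2.0
    if np.any(semi > limit):
        warnings.warn("brain semi-axes exceed the grid; clipping", stacklevel=2)
        semi = np.minimum(semi, limit)
    centre = (np.asarray(dims) - 1) / 2.0
    grids = np.meshgrid(*[np.arange(n) for n in dims], indexing="ij")
    r2 = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, centre, semi))
    return r2 <= 1.0


def _lesion_profile(dims, centre, radius_vox, spacing):
    """Smooth blob: 1 inside radius-1, cosine taper over the last voxel, 0 outside."""
    grids = np.meshgrid(*[np.arange(n) for n in dims], indexing="ij")
    d = np.sqrt(sum(((g - c) * s) ** 2 for g, c, s in zip(grids, centre, spacing)))
    taper = 1.0  # mm of smooth edge
    profile = np.clip((radius_vox - d) / taper + 0.5, 0.0, 1.0)
    smooth = 0.5 - 0.5 * np.cos(np.pi * profile)
    return smooth, d <= radius_vox


def generate_phantom(cfg: PhantomConfig, max_attempts: int = 2000) -> Phantom:
    """Generate one phantom reproducibly from its configuration."""
    rng = np.random.default_rng(cfg.seed)
    dims = tuple(cfg.dims)
    ndim = len(dims)
    spacing = cfg.spacing[:ndim]
    brain = make_brain_mask(dims, cfg.semi_axes)
    centre = (np.asarray(dims) - 1) / 2.0
    semi = np.asarray(cfg.semi_axes, dtype=float)

    # place pairwise non-overlapping lesions fully inside the brain
    placed: list[tuple[np.ndarray, float]] = []
    if cfg.lesion_centers is not None:
        radii = cfg.lesion_radii or (np.mean(cfg.radius_range_mm),) * len(cfg.lesion_centers)
        placed = [(np.asarray(c, dtype=float), float(r))
                  for c, r in zip(cfg.lesion_centers, radii)]
    else:
        placed = _random_placement(cfg, rng, dims, ndim, spacing, centre, semi,
                                   max_attempts)

    lesion_field = np.zeros(dims)
    gt = np.zeros(dims, dtype=bool)
    for pos, radius in placed:
        profile, core = _lesion_profile(dims, pos, radius, spacing)
        lesion_field = np.maximum(lesion_field, profile)
        gt |= core

    noise = rng.normal(0.0, cfg.noise_std, size=(2,) + dims)
    ch1 = np.where(brain, noise[0] + cfg.contrast_ch1 * lesion_field, cfg.air_value)
    ch2 = np.where(brain, noise[1] - cfg.contrast_ch2 * lesion_field, cfg.air_value)
    data = np.stack([ch1, ch2])

    # z-score each channel over the brain mask only
    for c in range(2):
        mu = data[c][brain].mean()
        sd = data[c][brain].std()
        data[c] = (data[c] - mu) / sd

    vol = Volume(data=data, channels=cfg.channels, spacing=spacing)
    return Phantom(volume=vol, gt_mask=gt, brain_mask=brain, config=cfg)


def _random_placement(cfg, rng, dims, ndim, spacing, centre, semi, max_attempts):
    placed: list[tuple[np.ndarray, float]] = []
    for _ in range(cfg.n_lesions):
        for _attempt in range(max_attempts):
            radius = rng.uniform(*cfg.radius_range_mm)
            pos = rng.uniform(0, 1, size=ndim) * (np.asarray(dims) - 1)
            margin = radius / np.asarray(spacing) + 1.5
            inside = np.sum(((pos - centre) / np.maximum(semi - margin, 1e-9)) ** 2) <= 1.0
            if not inside:
                continue
            clash = any(
                np.linalg.norm((pos - p) * spacing) < radius + r + 2.0
                for p, r in placed
            )
            if not clash:
                placed.append((pos, radius))
                break
        else:
            raise PlacementError(
                f"could not place lesion {len(placed) + 1} of {cfg.n_lesions}"
            )
    return placed


def phantom_stream(base: PhantomConfig, n: int, seed: int):
    """Yield ``n`` phantoms with seeds derived deterministically from ``seed``."""
    ss = np.random.SeedSequence(seed)
    for child in ss.spawn(n):
        child_seed = int(child.generate_state(1)[0] % (2**31))
        yield generate_phantom(
            PhantomConfig(**{**base.__dict__, "seed": child_seed})
        )


@dataclass
class TrainingSummary:
    """Validation metrics of a trained tiny model."""

    losses: list[float]
    lesion_tpr: float
    n_val_lesions: int
    n_val_detected: int
    epochs: int
    seed: int


def lesionwise_tpr(model, phantoms, threshold: float = 0.3,
                   connectivity: int = 18, min_volume_mm3: float = 5.0) -> tuple[int, int]:
    """Count ground-truth lesions touched by the thresholded prediction."""
    detected = total = 0
    for ph in phantoms:
        logit = model.forward(ph.volume, threshold=threshold)
        pred = logit.probabilities > threshold
        for inst in label_instances(ph.gt_mask, ph.volume.spacing,
                                    connectivity, 0.0, origin="ground_truth"):
            total += 1
            if pred[inst.index].any():
                detected += 1
    return detected, total


def train_tiny_model(
    train_phantoms: list[Phantom],
    val_phantoms: list[Phantom],
    epochs: int = 20,
    lr: float = 6e-3,
    pos_weight: float = 1.0,
    seed: int = 0,
    min_train: int = 20,
) -> tuple[TinyCNN, TrainingSummary]:
    """Train the tiny encoder–decoder on phantoms with weighted cross-entropy.

    The loss is a plain class-weighted binary cross-entropy on logits —
    deliberately simple; instance-imbalance-aware losses are out of scope
    here.  Training is deterministic given the seed and the phantom list.
    With ``epochs=0`` the freshly initialised model is returned with a
    warning.
    """
    import warnings

    if len(train_phantoms) < min_train:
        raise ValueError(f"need at least {min_train} training phantoms, "
                         f"got {len(train_phantoms)}")
    ndim = train_phantoms[0].volume.ndim_spatial
    model = TinyCNN(channels_in=train_phantoms[0].volume.n_channels, ndim=ndim, seed=seed)
    if epochs == 0:
        warnings.warn("epochs=0: returning an untrained model", stacklevel=2)
        detected, total = lesionwise_tpr(model, val_phantoms)
        return model, TrainingSummary([], detected / max(total, 1), total,
                                      detected, 0, seed)

    opt = AdamState(model.params, lr=lr)
    rng = np.random.default_rng(seed)
    losses = []
    for _epoch in range(epochs):
        order = rng.permutation(len(train_phantoms))
        epoch_loss = 0.0
        for i in order:
            ph = train_phantoms[i]
            loss, grads = model.loss_and_gradients(
                ph.volume.data, ph.gt_mask.astype(float), pos_weight=pos_weight)
            if not np.isfinite(loss):
                raise RuntimeError("training diverged: non-finite loss")
            opt.step(model.params, grads)
            epoch_loss += loss
        losses.append(epoch_loss / len(train_phantoms))
    detected, total = lesionwise_tpr(model, val_phantoms)
    summary = TrainingSummary(losses=losses, lesion_tpr=detected / max(total, 1),
                              n_val_lesions=total, n_val_detected=detected,
                              epochs=epochs, seed=seed)
    return model, summary
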