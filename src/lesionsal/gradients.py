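"""Instance-level gradient saliency: vanilla gradients and SmoothGrad.

For a lesion domain Omega the per-voxel gradients of each output logit
``y[v']``, ``v' in Omega``, with respect to each input channel are combined
into a single map per channel.  Two aggregation rules are provided:

``mean``
    ``M[v] = (1 / (N |Omega|)) * sum_n sum_{v' in Omega} dy(x_n)[v'] / dx_n[v]``
    — the plain average over noise repetitions and source voxels.  Its
    magnitude shrinks roughly like ``1/|Omega|`` for extensive lesions.

``max_signed``
    per repetition ``n`` and map voxel ``v`` only the candidate
    ``D^n_{v'} = dy(x_n)[v'] / dx_n[v]`` of largest absolute value is kept,
    with its sign, and the kept maps are averaged over ``n`` — this makes
    saliency magnitudes comparable across lesions of very different sizes.

SmoothGrad perturbs the input with independent Gaussian noise of standard
deviation ``sigma`` (on the z-scored intensity scale), ``N`` repetitions;
``N=1, sigma=0`` reduces exactly to vanilla gradients.

Because gradients vanish beyond the model's receptive field, computation is
restricted to a crop around Omega (margin = receptive-field radius when the
model reports one) and re-embedded at the original offset.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .models import SegmentationModel
from .volume import InstanceMask, Volume, require_nonempty

AGGREGATIONS = ("mean", "max_signed")


@dataclass(frozen=True)
class NoiseConfig:
    """SmoothGrad noise parameters: N repetitions of N(0, sigma) noise."""

    n: int = 50
    sigma: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n < 1:
            raise ValueError("number of noise repetitions must be >= 1")
        if self.sigma < 0:
            raise ValueError("noise standard deviation must be >= 0")


VANILLA = NoiseConfig(n=1, sigma=0.0, seed=0)


@dataclass(frozen=True)
class SaliencyMap:
    """Per-channel instance saliency values on the full input grid."""

    values: np.ndarray  # (C, *spatial)
    channels: tuple[str, ...]
    method: str
    aggregation: str
    instance_label: int
    noise: NoiseConfig
    crop: tuple[slice, ...] | None = None

    def channel(self, name: str) -> np.ndarray:
        return self.values[self.channels.index(name)]


def max_signed_aggregate(candidates: np.ndarray, axis: int = 0) -> np.ndarray:
    """Keep, along ``axis``, the candidate of maximal absolute value with its sign.

    Ties are broken in favour of the earliest candidate along the axis, which
    corresponds to the smallest source voxel in scan order when candidates
    are stacked in that order.
    """
    candidates = np.asarray(candidates, dtype=float)
    if candidates.shape[axis] == 0:
        raise ValueError("empty candidate set")
    pick = np.argmax(np.abs(candidates), axis=axis)  # first max wins ties
    return np.take_along_axis(candidates, np.expand_dims(pick, axis), axis=axis).squeeze(axis)


def _crop_slices(model, x: Volume, omega: InstanceMask, crop_margin) -> tuple[slice, ...]:
    if crop_margin is None:
        r = model.receptive_field_radius
        crop_margin = int(np.ceil(r)) if np.isfinite(r) else 48
    return omega.bounding_box(margin=int(crop_margin))


def smoothgrad_instance(
    model: SegmentationModel,
    x: Volume,
    omega: InstanceMask,
    cfg: NoiseConfig = NoiseConfig(),
    aggregation: str = "max_signed",
    crop_margin: int | None = None,
) -> SaliencyMap:
    """SmoothGrad instance saliency for one lesion domain, per input channel.

    ``crop_margin`` overrides the crop half-width around Omega's bounding
    box; the default uses the model's receptive-field radius (48 voxels when
    the model does not report a finite one).
    """
    require_nonempty(omega, "lesion")
    if omega.shape != x.shape:
        raise ValueError("instance grid does not match the volume")
    if aggregation not in AGGREGATIONS:
        raise ValueError(f"aggregation must be one of {AGGREGATIONS}")

    crop = _crop_slices(model, x, omega, crop_margin)
    sub = x.data[(slice(None),) + crop]
    offset = np.array([s.start for s in crop])
    local = omega.voxels - offset
    rng = np.random.default_rng(cfg.seed)

    accum = np.zeros_like(sub)
    for _ in range(cfg.n):
        noisy = sub if cfg.sigma == 0 else sub + rng.normal(0.0, cfg.sigma, size=sub.shape)
        if aggregation == "mean":
            seed = np.zeros(sub.shape[1:])
            seed[tuple(local.T)] = 1.0 / len(omega)
            accum += model.input_gradient(noisy, seed)
        else:
            maps = _per_voxel_gradients(model, noisy, local)
            accum += max_signed_aggregate(maps, axis=0)
    accum /= cfg.n

    full = np.zeros_like(x.data)
    full[(slice(None),) + crop] = accum
    return SaliencyMap(values=full, channels=x.channels,
                       method="vanilla" if (cfg.n == 1 and cfg.sigma == 0) else "smoothgrad",
                       aggregation=aggregation, instance_label=omega.label,
                       noise=cfg, crop=crop)


def _per_voxel_gradients(model, data, local_voxels, chunk: int = 32) -> np.ndarray:
    """Stack of gradient maps, one per source voxel in scan order: (|Omega|, C, *S)."""
    spatial = data.shape[1:]
    out = []
    for start in range(0, len(local_voxels), chunk):
        block = local_voxels[start:start + chunk]
        seeds = np.zeros((len(block),) + spatial)
        seeds[(np.arange(len(block)),) + tuple(block.T)] = 1.0
        out.append(model.input_gradient_batch(data, seeds))
    return np.concatenate(out, axis=0)


def vanilla_instance_map(
    model: SegmentationModel,
    x: Volume,
    omega: InstanceMask,
    aggregation: str = "max_signed",
    crop_margin: int | None = None,
) -> SaliencyMap:
    """Vanilla-gradient instance saliency: SmoothGrad with N=1 and no noise."""
    return smoothgrad_instance(model, x, omega, VANILLA, aggregation, crop_margin)


def saliency_band_filter(sal: SaliencyMap, band: tuple[float, float] = (-0.1, 0.1)) -> SaliencyMap:
    """Discard low-attention gradient values strictly inside the open band.

    Values v with ``band[0] < v < band[1]`` are set to zero; boundary values
    are kept.  The default band (-0.1, 0.1) focuses the analysis on voxels
    with a higher attention level.
    """
    lo, hi = band
    if not lo < hi:
        raise ValueError("band lower bound must be below the upper bound")
    vals = np.where((sal.values > lo) & (sal.values < hi), 0.0, sal.values)
    return replace(sal, values=vals)
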