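"""Lesion-instance extraction and example classification.

The probability map of a segmentation model is binarized at a threshold,
split into connected components (18-connectivity by default), filtered by a
minimum physical volume (5 mm^3 by default) and the surviving components are
matched against ground truth:

* TP — predicted instance with non-zero overlap with the ground-truth mask;
* FP — predicted instance with zero overlap with the ground-truth mask;
* FN — ground-truth instance with zero overlap with the full predicted mask;
* TN — control spheres (93 mm^3 by default, roughly the cohort-average
  lesion volume) sampled inside the brain mask away from both masks.

Matching is deliberately one-sided: a single prediction overlapping two
ground-truth lesions counts as one TP, and no one-to-one assignment is
attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .volume import InstanceMask

#: scipy structuring elements for the standard 3D connectivities and their
#: 2D counterparts (4- and 8-neighbourhoods)
_CONNECTIVITY_RANK = {6: 1, 18: 2, 26: 3, 4: 1, 8: 2}


class SamplingExhaustedError(RuntimeError):
    """Rejection sampling could not place the requested number of spheres."""

    def __init__(self, placed: int, requested: int):
        super().__init__(
            f"placed only {placed} of {requested} control spheres before "
            "exhausting the attempt budget"
        )
        self.placed = placed
        self.requested = requested


def binarize_probability(prob: np.ndarray, threshold: float = 0.3) -> np.ndarray:
    """Binary mask of voxels with probability strictly greater than ``threshold``."""
    prob = np.asarray(prob, dtype=float)
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    if prob.min() < 0 or prob.max() > 1:
        raise ValueError("probability map has values outside [0, 1]")
    return prob > threshold


def _structure(ndim: int, connectivity: int) -> np.ndarray:
    if connectivity not in _CONNECTIVITY_RANK:
        raise ValueError(f"unsupported connectivity {connectivity}")
    rank = min(_CONNECTIVITY_RANK[connectivity], ndim)
    return ndimage.generate_binary_structure(ndim, rank)


def label_instances(
    mask: np.ndarray,
    spacing: tuple[float, ...],
    connectivity: int = 18,
    min_volume_mm3: float = 5.0,
    origin: str = "prediction",
) -> list[InstanceMask]:
    """Connected components of a binary mask, filtered by physical volume.

    Components whose physical volume (voxel count times voxel volume) is
    smaller than ``min_volume_mm3`` are discarded.  Labels are assigned in
    scan order of each component's first voxel, starting at 1.
    """
    mask = np.asarray(mask).astype(bool)
    structure = _structure(mask.ndim, connectivity)
    labelled, n = ndimage.label(mask, structure=structure)
    voxel_volume = float(np.prod(spacing))
    out: list[InstanceMask] = []
    label = 1
    for comp in range(1, n + 1):
        vox = np.argwhere(labelled == comp)
        if vox.shape[0] * voxel_volume < min_volume_mm3:
            continue
        out.append(
            InstanceMask(voxels=vox, shape=mask.shape, spacing=spacing,
                         label=label, origin=origin)
        )
        label += 1
    return out


@dataclass
class ExampleSet:
    """TP/FP/FN/TN example instances with the provenance of their extraction."""

    tp: list[InstanceMask] = field(default_factory=list)
    fp: list[InstanceMask] = field(default_factory=list)
    fn: list[InstanceMask] = field(default_factory=list)
    tn: list[InstanceMask] = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def category(self, name: str) -> list[InstanceMask]:
        return {"TP": self.tp, "FP": self.fp, "FN": self.fn, "TN": self.tn}[name]

    @property
    def counts(self) -> dict[str, int]:
        return {"TP": len(self.tp), "FP": len(self.fp),
                "FN": len(self.fn), "TN": len(self.tn)}


def classify_examples(
    pred_instances: list[InstanceMask],
    gt_instances: list[InstanceMask],
    pred_mask: np.ndarray,
    gt_mask: np.ndarray,
    provenance: dict | None = None,
) -> ExampleSet:
    """Split instances into TP/FP (predictions) and FN (ground truth).

    A prediction is TP iff it shares at least one voxel with the ground-truth
    mask, otherwise FP; a ground-truth instance is FN iff no voxel of the
    full predicted mask touches it.
    """
    pred_mask = np.asarray(pred_mask).astype(bool)
    gt_mask = np.asarray(gt_mask).astype(bool)
    if pred_mask.shape != gt_mask.shape:
        raise ValueError("prediction and ground-truth masks have different shapes")
    out = ExampleSet(provenance=dict(provenance or {}))
    for inst in pred_instances:
        if inst.shape != pred_mask.shape:
            raise ValueError("instance grid does not match the masks")
        (out.tp if gt_mask[inst.index].any() else out.fp).append(inst)
    for inst in gt_instances:
        if inst.shape != gt_mask.shape:
            raise ValueError("instance grid does not match the masks")
        if not pred_mask[inst.index].any():
            out.fn.append(inst)
    return out


def sphere_radius_mm(volume_mm3: float) -> float:
    """Radius of a sphere with the given volume (about 2.81 mm at 93 mm^3)."""
    return float((3.0 * volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0))


def sample_tn_spheres(
    brain_mask: np.ndarray,
    gt_mask: np.ndarray,
    pred_mask: np.ndarray,
    spacing: tuple[float, ...],
    n: int = 10,
    target_volume_mm3: float = 93.0,
    seed: int = 0,
    max_attempts: int = 10_000,
) -> list[InstanceMask]:
    """Random control spheres inside the brain mask, away from both lesion masks.

    Each sphere is the set of voxels whose centre lies within the target
    radius of a sampled centre voxel; a candidate is rejected unless it lies
    entirely inside the brain mask and intersects neither the ground-truth
    nor the predicted mask.  Spheres may overlap each other.  The discrete
    volume of each accepted sphere is recorded on the instance, not forced
    to the nominal target.
    """
    brain_mask = np.asarray(brain_mask).astype(bool)
    gt_mask = np.asarray(gt_mask).astype(bool)
    pred_mask = np.asarray(pred_mask).astype(bool)
    if not brain_mask.any():
        raise ValueError("brain mask is empty")
    rng = np.random.default_rng(seed)
    radius = sphere_radius_mm(target_volume_mm3)
    spacing_arr = np.asarray(spacing, dtype=float)

    # precompute the sphere footprint as offsets around a centre voxel
    half = np.ceil(radius / spacing_arr).astype(int)
    grids = np.meshgrid(*[np.arange(-h, h + 1) for h in half], indexing="ij")
    offsets = np.stack([g.ravel() for g in grids], axis=1)
    dist2 = ((offsets * spacing_arr) ** 2).sum(axis=1)
    offsets = offsets[dist2 <= radius**2]

    candidates = np.argwhere(brain_mask)
    shape = np.asarray(brain_mask.shape)
    spheres: list[InstanceMask] = []
    for k in range(n):
        for _ in range(max_attempts):
            centre = candidates[rng.integers(len(candidates))]
            vox = centre[None, :] + offsets
            if (vox < 0).any() or (vox >= shape).any():
                continue
            idx = tuple(vox.T)
            if not brain_mask[idx].all():
                continue
            if gt_mask[idx].any() or pred_mask[idx].any():
                continue
            spheres.append(
                InstanceMask(voxels=vox, shape=brain_mask.shape, spacing=spacing,
                             label=k + 1, origin="tn_sphere")
            )
            break
        else:
            raise SamplingExhaustedError(placed=len(spheres), requested=n)
    return spheres


def center_of_mass_domain(instance: InstanceMask) -> InstanceMask:
    """Single-voxel domain at the centre of mass of a lesion instance.

    The mean voxel index is rounded to the grid; when that voxel does not
    belong to the instance (e.g. a C-shaped lesion) the member voxel nearest
    to the mean is used, ties broken by scan order.
    """
    if instance.cardinality == 0:
        raise ValueError("cannot take the centre of mass of an empty instance")
    mean = instance.centroid()
    rounded = np.round(mean).astype(np.intp)
    member = (instance.voxels == rounded).all(axis=1).any()
    if member:
        chosen = rounded
    else:
        d2 = ((instance.voxels - mean) ** 2).sum(axis=1)
        chosen = instance.voxels[int(np.argmin(d2))]  # voxels are in scan order
    return InstanceMask(voxels=chosen[None, :], shape=instance.shape,
                        spacing=instance.spacing, label=instance.label,
                        origin=instance.origin)


def extract_examples(
    prob: np.ndarray,
    gt_mask: np.ndarray,
    brain_mask: np.ndarray,
    spacing: tuple[float, ...],
    threshold: float = 0.3,
    connectivity: int = 18,
    min_volume_mm3: float = 5.0,
    tn_n: int = 10,
    tn_volume_mm3: float = 93.0,
    seed: int = 0,
    filter_gt: bool = True,
) -> ExampleSet:
    """End-to-end example extraction from a probability map and ground truth."""
    pred_mask = binarize_probability(prob, threshold)
    pred_instances = label_instances(pred_mask, spacing, connectivity,
                                     min_volume_mm3, origin="prediction")
    gt_instances = label_instances(
        gt_mask, spacing, connectivity,
        min_volume_mm3 if filter_gt else 0.0, origin="ground_truth")
    out = classify_examples(
        pred_instances, gt_instances, pred_mask, np.asarray(gt_mask).astype(bool),
        provenance=dict(threshold=threshold, connectivity=connectivity,
                        min_volume_mm3=min_volume_mm3, tn_n=tn_n,
                        tn_volume_mm3=tn_volume_mm3, seed=seed),
    )
    out.tn = sample_tn_spheres(brain_mask, gt_mask, pred_mask, spacing,
                               n=tn_n, target_volume_mm3=tn_volume_mm3, seed=seed)
    return out
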