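"""Validation experiments for instance saliency.

Four families of checks, mirroring how one would validate saliency on a
trained lesion-segmentation model:

* **Peak-value statistics** — the distribution of each example's maximum and
  minimum saliency value across TP/FP/FN/TN example categories, with
  bootstrap confidence intervals for the medians and pairwise two-sided
  Mann-Whitney U tests (exact enumeration for small groups).
* **Sanity checks** — saliency of a probe domain placed in healthy tissue,
  and lesion transplantation (moving a lesion's intensities, optionally with
  a shell of surrounding tissue, elsewhere in the volume).
* **Context probe** — mask everything but a lesion, then grow the visible
  region by morphological dilation one step at a time, recording the mean
  Softmax score inside the lesion and whether it is detected; this reveals
  how much perilesional context the model needs.
* **Size selection** — restricting to lesions of near-average physical
  volume (90–120 mm^3 by default) for the context probe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .gradients import NoiseConfig, SaliencyMap, smoothgrad_instance
from .instances import ExampleSet
from .models import SegmentationModel
from .volume import InstanceMask, Volume, require_nonempty, softmax_probability

CATEGORIES = ("TP", "FP", "FN", "TN")


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic of the first sample: #{x > y} + 0.5 #{x == y} over all pairs."""
    diff = x[:, None] - y[None, :]
    return float((diff > 0).sum() + 0.5 * (diff == 0).sum())


def mannwhitney_exact(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney U test by enumeration of group assignments.

    Enumerates all C(n+m, n) splits of the pooled sample (ties handled by the
    0.5-per-tie U statistic) and returns ``(U, p)`` with
    ``p = min(1, 2 * min(P(U <= u), P(U >= u)))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    n, total = len(x), len(pooled)
    u_obs = _u_statistic(x, y)
    count_le = count_ge = 0
    idx_all = np.arange(total)
    for picks in combinations(range(total), n):
        sel = np.zeros(total, dtype=bool)
        sel[list(picks)] = True
        u = _u_statistic(pooled[sel], pooled[~sel])
        count_le += u <= u_obs + 1e-12
        count_ge += u >= u_obs - 1e-12
    m = comb(total, n)
    p = min(1.0, 2.0 * min(count_le / m, count_ge / m))
    return u_obs, p


def mannwhitney(x, y, exact_max_n: int = 8) -> tuple[float, float]:
    """Two-sided Mann-Whitney U: exact enumeration for small groups,
    tie-corrected normal approximation otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) <= exact_max_n and len(y) <= exact_max_n:
        return mannwhitney_exact(x, y)
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# peak-value distributions
# ---------------------------------------------------------------------------

def bootstrap_ci(values, n_boot: int = 1000, seed: int = 0,
                 level: float = 0.95) -> tuple[float, float]:
    """Percentile bootstrap confidence interval for the median."""
    values = np.asarray(values, dtype=float)
    rng = np.random.default_rng(seed)
    meds = np.median(
        values[rng.integers(0, len(values), size=(n_boot, len(values)))], axis=1)
    lo = (1 - level) / 2
    return float(np.quantile(meds, lo)), float(np.quantile(meds, 1 - lo))


def saliency_peaks(sal: SaliencyMap, channel: int = 0) -> tuple[float, float]:
    """(max, min) of one channel of a saliency map over its computed region."""
    vals = sal.values[channel]
    if sal.crop is not None:
        vals = vals[sal.crop]
    return float(vals.max()), float(vals.min())


@dataclass
class PeakStats:
    """Per-example saliency extrema and per-category summary statistics."""

    table: pd.DataFrame                      # category, label, channel, max, min
    summaries: dict[str, dict] = field(default_factory=dict)
    pairwise: dict[str, dict] = field(default_factory=dict)

    def category_values(self, category: str, which: str = "max") -> np.ndarray:
        sub = self.table[self.table.category == category]
        return sub[which].to_numpy()


def peak_value_distributions(
    maps: dict[str, list[SaliencyMap]],
    channel: int = 0,
    n_boot: int = 1000,
    seed: int = 0,
) -> PeakStats:
    """Distribution of per-example saliency extrema across example categories.

    ``maps`` holds one saliency map per example, keyed by category
    (``"TP"/"FP"/"FN"/"TN"``; missing categories are skipped).  Medians get
    bootstrap 95% CIs; all available category pairs are compared with
    two-sided Mann-Whitney tests on the maxima and on the minima.
    """
    rows = []
    for cat, sal_list in maps.items():
        for sal in sal_list:
            mx, mn = saliency_peaks(sal, channel)
            rows.append(dict(category=cat, label=sal.instance_label,
                             channel=channel, max=mx, min=mn))
    table = pd.DataFrame(rows, columns=["category", "label", "channel", "max", "min"])
    out = PeakStats(table=table)

    for cat in CATEGORIES:
        vals = table[table.category == cat]
        if len(vals) < 2:
            if len(vals) or cat in maps:
                warnings.warn(f"category {cat} has <2 examples; statistics skipped",
                              stacklevel=2)
            continue
        summary = {}
        for which in ("max", "min"):
            v = vals[which].to_numpy()
            ci = bootstrap_ci(v, n_boot=n_boot, seed=seed)
            summary[which] = dict(median=float(np.median(v)), ci_low=ci[0],
                                  ci_high=ci[1], n=len(v))
        out.summaries[cat] = summary

    for a, b in combinations([c for c in CATEGORIES if c in out.summaries], 2):
        entry = {}
        for which in ("max", "min"):
            u, p = mannwhitney(out.category_values(a, which),
                               out.category_values(b, which))
            entry[which] = dict(U=u, p=p)
        out.pairwise[f"{a}_vs_{b}"] = entry
    return out


# ---------------------------------------------------------------------------
# sanity checks
# ---------------------------------------------------------------------------

def empty_region_check(
    model: SegmentationModel,
    x: Volume,
    probe_omega: InstanceMask,
    gt_mask: np.ndarray,
    pred_mask: np.ndarray,
    cfg: NoiseConfig = NoiseConfig(),
    aggregation: str = "max_signed",
) -> tuple[SaliencyMap, dict[str, tuple[float, float]]]:
    """Saliency of a probe domain placed in lesion-free tissue.

    The probe must not intersect the ground-truth or predicted masks; the
    returned per-channel (max, min) peaks are meant to be compared with the
    range observed for true lesions.
    """
    require_nonempty(probe_omega, "probe")
    gt_mask = np.asarray(gt_mask).astype(bool)
    pred_mask = np.asarray(pred_mask).astype(bool)
    if gt_mask[probe_omega.index].any() or pred_mask[probe_omega.index].any():
        raise ValueError("probe domain intersects a lesion or prediction mask")
    sal = smoothgrad_instance(model, x, probe_omega, cfg, aggregation)
    peaks = {name: saliency_peaks(sal, i) for i, name in enumerate(x.channels)}
    return sal, peaks


def transplant_lesion(
    x: Volume,
    source: InstanceMask,
    dest_center,
    context_margin_mm: float = 0.0,
) -> tuple[Volume, InstanceMask]:
    """Copy a lesion's intensities (optionally with surrounding tissue) elsewhere.

    The source footprint is the lesion domain dilated by
    ``context_margin_mm`` (face-connected steps, one per mm at the first-axis
    spacing).  Its translate, centred at ``dest_center``, receives the source
    intensities channel by channel; every other voxel is untouched.  Raises
    when the translated footprint leaves the grid.
    """
    require_nonempty(source, "source lesion")
    steps = int(round(context_margin_mm / x.spacing[0]))
    dense = source.to_dense()
    if steps > 0:
        struct = ndimage.generate_binary_structure(dense.ndim, 1)
        footprint = ndimage.binary_dilation(dense, structure=struct, iterations=steps)
    else:
        footprint = dense
    src_vox = np.argwhere(footprint)
    offset = np.round(np.asarray(dest_center, dtype=float)
                      - source.centroid()).astype(int)
    dst_vox = src_vox + offset
    if (dst_vox < 0).any() or (dst_vox >= np.asarray(x.shape)).any():
        raise ValueError("translated footprint falls outside the image grid")
    data = x.data.copy()
    data[(slice(None),) + tuple(dst_vox.T)] = x.data[(slice(None),) + tuple(src_vox.T)]
    dest = InstanceMask(voxels=source.voxels + offset, shape=x.shape,
                        spacing=x.spacing, label=source.label, origin="manual")
    return x.with_data(data), dest


# ---------------------------------------------------------------------------
# context probe
# ---------------------------------------------------------------------------

@dataclass
class LesionContextCurve:
    """Per-iteration scores of the context probe for a single lesion."""

    mean_score: np.ndarray     # mean Softmax score inside Omega, per iteration
    detected: np.ndarray       # bool per iteration: any in-Omega score > t
    covered_at: int | None     # first iteration where the mask covers the grid
    threshold: float
    label: int

    @property
    def detection_iteration(self) -> int | None:
        hits = np.flatnonzero(self.detected)
        return int(hits[0]) if hits.size else None


@dataclass
class ContextProbeResult:
    """Cohort aggregation of context-probe curves.

    ``mean``/``std`` are taken across lesions at each dilation iteration;
    ``detected_count`` counts lesions with at least one in-domain Softmax
    score above the threshold at that iteration.
    """

    iterations: np.ndarray
    mean: np.ndarray
    std: np.ndarray
    detected_count: np.ndarray
    n_lesions: int
    threshold: float
    structuring_element: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(dict(iteration=self.iterations, mean=self.mean,
                                 std=self.std, detected=self.detected_count))


def context_probe(
    model: SegmentationModel,
    x: Volume,
    omega: InstanceMask,
    iterations: int = 35,
    threshold: float = 0.3,
    connectivity: int = 1,
) -> LesionContextCurve:
    """Grow the visible region around one lesion and track its Softmax score.

    Iteration 0 shows the model only the lesion's own intensities (all other
    voxels zeroed, i.e. set to the z-scored tissue mean); iteration ``i``
    shows the lesion mask dilated ``i`` times with the face-connected unit
    element (``connectivity=1``; pass 3 for the 26-connected element).  Once
    the dilated mask covers the whole grid the input equals the original
    volume exactly.
    """
    require_nonempty(omega, "lesion")
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    struct = ndimage.generate_binary_structure(len(x.shape), connectivity)
    mask = omega.to_dense()
    means = np.empty(iterations + 1)
    detected = np.empty(iterations + 1, dtype=bool)
    covered_at = None
    idx = omega.index
    for i in range(iterations + 1):
        if i > 0 and not mask.all():
            mask = ndimage.binary_dilation(mask, structure=struct)
        if covered_at is None and mask.all():
            covered_at = i
        if covered_at is not None and i > covered_at:
            # masking is a no-op from here on; the scores are constant
            means[i] = means[i - 1]
            detected[i] = detected[i - 1]
            continue
        data = np.where(mask, x.data, 0.0)
        p = softmax_probability(model.logits(data))
        means[i] = float(p[idx].mean())
        detected[i] = bool((p[idx] > threshold).any())
    return LesionContextCurve(mean_score=means, detected=detected,
                              covered_at=covered_at, threshold=threshold,
                              label=omega.label)


def context_probe_cohort(
    model: SegmentationModel,
    items: list[tuple[Volume, InstanceMask]],
    iterations: int = 35,
    threshold: float = 0.3,
    connectivity: int = 1,
) -> tuple[ContextProbeResult, list[LesionContextCurve]]:
    """Context probe over a cohort of lesions, aggregated per iteration."""
    curves = [context_probe(model, x, om, iterations, threshold, connectivity)
              for x, om in items]
    scores = np.stack([c.mean_score for c in curves])
    det = np.stack([c.detected for c in curves])
    result = ContextProbeResult(
        iterations=np.arange(iterations + 1),
        mean=scores.mean(axis=0),
        std=scores.std(axis=0),
        detected_count=det.sum(axis=0),
        n_lesions=len(curves),
        threshold=threshold,
        structuring_element="face-connected" if connectivity == 1 else "full",
    )
    return result, curves


def select_average_size_lesions(
    instances: list[InstanceMask],
    low_mm3: float = 90.0,
    high_mm3: float = 120.0,
) -> list[InstanceMask]:
    """Lesions whose physical volume lies in the closed interval [low, high] mm^3."""
    return [i for i in instances
            if low_mm3 <= i.physical_volume <= high_mm3]


def compute_example_maps(
    model: SegmentationModel,
    x: Volume,
    examples: ExampleSet,
    cfg: NoiseConfig = NoiseConfig(),
    aggregation: str = "max_signed",
    max_per_category: int | None = None,
) -> dict[str, list[SaliencyMap]]:
    """SmoothGrad maps for every example of every category of one volume.

    FN and TN examples have no predicted component, so their maps use the
    ground-truth instance / control sphere as the domain Omega.
    """
    out: dict[str, list[SaliencyMap]] = {}
    for cat in CATEGORIES:
        insts = examples.category(cat)
        if max_per_category is not None:
            insts = insts[:max_per_category]
        out[cat] = [smoothgrad_instance(model, x, inst, cfg, aggregation)
                    for inst in insts]
    return out
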