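"""NIfTI I/O, run configuration and the end-to-end pipeline.

Multi-channel inputs arrive as one single-channel NIfTI file per modality;
all channels (and masks) must share grid dimensions and affine exactly — no
implicit resampling is ever performed.  Every output map is written on the
input grid with the input affine.  Voxel indexing is 0-based throughout;
instance tables report voxel indices and affine-applied mm coordinates side
by side.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from . import __version__
from .experiments import context_probe_cohort, peak_value_distributions, select_average_size_lesions
from .gradcam import gradcam_instance_map
from .gradients import NoiseConfig, smoothgrad_instance
from .instances import extract_examples
from .models import SegmentationModel, TinyCNN, build_model
from .volume import Volume

log = logging.getLogger("lesionsal")


class AlignmentError(ValueError):
    """Input files do not share grid and affine."""


def read_volume(paths, channels=None) -> tuple[Volume, np.ndarray]:
    """Read one single-channel NIfTI per modality into a Volume.

    Returns the volume and the shared affine.  Raises
    :class:`AlignmentError` when grids or affines differ across channels.
    """
    paths = [Path(p) for p in paths]
    imgs = [nib.load(str(p)) for p in paths]
    ref = imgs[0]
    for p, img in zip(paths[1:], imgs[1:]):
        if img.shape != ref.shape or not np.allclose(img.affine, ref.affine):
            raise AlignmentError(f"{p} is not aligned with {paths[0]}")
    data = np.stack([np.asarray(img.dataobj, dtype=float) for img in imgs])
    spacing = tuple(float(s) for s in ref.header.get_zooms()[: data.ndim - 1])
    names = tuple(channels) if channels else tuple(p.stem.split(".")[0] for p in paths)
    return Volume(data=data, channels=names, spacing=spacing), ref.affine.copy()


def read_mask(path) -> tuple[np.ndarray, np.ndarray]:
    """Read an integer mask; returns (array, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj).astype(np.int32), img.affine.copy()


def write_map(values: np.ndarray, path, affine: np.ndarray) -> None:
    """Write a map on the reference grid; integer arrays stay integer."""
    arr = np.asarray(values)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8)
    nib.save(nib.Nifti1Image(arr, affine), str(path))


def load_model(path) -> SegmentationModel:
    """Load a model: a ``.npz`` of trained weights or a JSON registry config."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model file {path} does not exist")
    if path.suffix == ".npz":
        return TinyCNN.load(path)
    with open(path) as fh:
        return build_model(json.load(fh))


@dataclass
class RunConfig:
    """Paths and method parameters of a full pipeline run.

    The method-parameter defaults are the reference operating point of the
    pipeline: detection threshold t=0.3, 18-connectivity with a 5 mm^3
    minimum component volume, SmoothGrad with N=50 repetitions of sigma=0.05
    noise, ten 93 mm^3 control spheres, the (-0.1, 0.1) low-attention band,
    35 context-probe dilations and the 90-120 mm^3 size window.
    """

    image_paths: list[str] = field(default_factory=list)
    gt_path: str = ""
    brain_mask_path: str = ""
    model_path: str = ""
    output_dir: str = "lesionsal_out"
    channels: tuple[str, ...] = ("flair", "mprage")
    threshold: float = 0.3
    n_noise: int = 50
    sigma: float = 0.05
    connectivity: int = 18
    min_volume_mm3: float = 5.0
    tn_n: int = 10
    tn_volume_mm3: float = 93.0
    band: tuple[float, float] = (-0.1, 0.1)
    probe_iterations: int = 35
    volume_window: tuple[float, float] = (90.0, 120.0)
    aggregation: str = "max_signed"
    gradcam_layer: str = "features"
    gradcam_route: str = "power"
    max_instances: int | None = None
    seed: int = 0

    def validate(self) -> None:
        if not self.image_paths:
            raise ValueError("no image paths configured")
        for p in list(self.image_paths) + [self.gt_path, self.brain_mask_path,
                                           self.model_path]:
            if p and not Path(p).exists():
                raise FileNotFoundError(f"configured path {p} does not exist")
        if not self.model_path:
            raise ValueError("no model path configured")


def instance_table(instances, affine) -> pd.DataFrame:
    rows = []
    for inst in instances:
        centroid = inst.centroid()
        mm = (affine @ np.append(centroid, 1.0))[:3]
        rows.append(dict(label=inst.label, origin=inst.origin,
                         cardinality=inst.cardinality,
                         volume_mm3=inst.physical_volume,
                         centroid_i=centroid[0], centroid_j=centroid[1],
                         centroid_k=centroid[2] if len(centroid) > 2 else np.nan,
                         centroid_x_mm=mm[0], centroid_y_mm=mm[1],
                         centroid_z_mm=mm[2]))
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> Path:
    """Run instance extraction, saliency and experiments; write an artifact dir.

    Produces an instance table (CSV), labelled instance map (NIfTI),
    per-instance SmoothGrad and Grad-CAM++ maps (NIfTI), peak statistics
    (CSV + JSON) and a context-probe table (CSV), plus a JSON manifest with
    all parameters and stage statuses.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = dict(version=__version__, config=asdict(config), stages={})
    path = out / "manifest.json"

    def stage(name):
        log.info("stage: %s", name)
        manifest["stages"][name] = "running"

    try:
        stage("read")
        x, affine = read_volume(config.image_paths, config.channels)
        gt, gt_aff = read_mask(config.gt_path)
        brain, br_aff = read_mask(config.brain_mask_path)
        for name, aff, arr in (("gt", gt_aff, gt), ("brain", br_aff, brain)):
            if arr.shape != x.shape or not np.allclose(aff, affine):
                raise AlignmentError(f"{name} mask is not aligned with the image")
        model = load_model(config.model_path)

        stage("instances")
        prob = model.forward(x, threshold=config.threshold).probabilities
        examples = extract_examples(
            prob, gt > 0, brain > 0, x.spacing, threshold=config.threshold,
            connectivity=config.connectivity, min_volume_mm3=config.min_volume_mm3,
            tn_n=config.tn_n, tn_volume_mm3=config.tn_volume_mm3, seed=config.seed)
        labelled = np.zeros(x.shape, dtype=np.int32)
        all_instances = examples.tp + examples.fp + examples.fn + examples.tn
        for inst in examples.tp + examples.fp:
            labelled[inst.index] = inst.label
        write_map(labelled, out / "instances.nii.gz", affine)
        table = instance_table(all_instances, affine)
        cats = (["TP"] * len(examples.tp) + ["FP"] * len(examples.fp)
                + ["FN"] * len(examples.fn) + ["TN"] * len(examples.tn))
        table.insert(1, "category", cats)
        table.to_csv(out / "instances.csv", index=False)

        stage("saliency")
        noise = NoiseConfig(n=config.n_noise, sigma=config.sigma, seed=config.seed)
        maps = {c: [] for c in ("TP", "FP", "FN", "TN")}
        for cat in maps:
            insts = examples.category(cat)
            if config.max_instances is not None:
                insts = insts[: config.max_instances]
            for inst in insts:
                sal = smoothgrad_instance(model, x, inst, noise, config.aggregation)
                maps[cat].append(sal)
                for ci, ch in enumerate(x.channels):
                    write_map(sal.values[ci],
                              out / f"smoothgrad_{cat.lower()}_{inst.label}_{ch}.nii.gz",
                              affine)
                if cat in ("TP", "FP"):
                    heat = gradcam_instance_map(model, x, config.gradcam_layer,
                                                inst, route=config.gradcam_route)
                    write_map(heat.values,
                              out / f"gradcam_{cat.lower()}_{inst.label}.nii.gz",
                              affine)

        stage("peaks")
        stats = peak_value_distributions(maps, channel=0, seed=config.seed)
        stats.table.to_csv(out / "peaks.csv", index=False)
        with open(out / "peaks_tests.json", "w") as fh:
            json.dump(dict(summaries=stats.summaries, pairwise=stats.pairwise),
                      fh, indent=2)
        from .plots import plot_peak_violins
        plot_peak_violins(stats, out / "peaks_violin.png",
                          channel_name=x.channels[0])

        stage("context")
        probe_insts = select_average_size_lesions(examples.tp, *config.volume_window)
        if not probe_insts:
            probe_insts = examples.tp[: config.max_instances or len(examples.tp)]
        if probe_insts:
            result, _ = context_probe_cohort(
                model, [(x, inst) for inst in probe_insts],
                iterations=config.probe_iterations, threshold=config.threshold)
            result.to_frame().to_csv(out / "context_probe.csv", index=False)
            from .plots import plot_context_curves
            plot_context_curves(result, out / "context_probe.png")

        for name in manifest["stages"]:
            manifest["stages"][name] = "ok"
    except Exception as exc:  # noqa: BLE001 — manifest must record the failure
        for name, status in manifest["stages"].items():
            if status == "running":
                manifest["stages"][name] = f"failed: {exc}"
        manifest["exit_status"] = 1
        with open(path, "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
        raise
    manifest["exit_status"] = 0
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return out
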