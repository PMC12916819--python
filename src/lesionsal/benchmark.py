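"""Seeded end-to-end synthetic benchmark.

Trains the tiny reference model on a stream of phantoms, extracts TP/FP/FN/TN
examples from a held-out set, and computes instance saliency maps for them.
This is the standing test bed for the stochastic properties of the saliency
methods (sign structure, peak-value ordering, instance separation): every
random choice derives from a single seed, so a run is reproducible
end to end.

Problem sizes are kept at desk scale by design — 32^3 phantoms, 24 training
and 10 held-out volumes, 4 noise repetitions per saliency map, at most 40
maps per example category (30 for the voluminous control spheres).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .experiments import compute_example_maps
from .gradients import NoiseConfig, SaliencyMap
from .instances import ExampleSet, extract_examples
from .models import TinyCNN
from .phantom import Phantom, PhantomConfig, phantom_stream, train_tiny_model


@dataclass
class BenchmarkResult:
    model: TinyCNN
    training_summary: object
    phantoms: list[Phantom]
    example_sets: list[ExampleSet]
    maps: dict[str, list[SaliencyMap]]
    #: (phantom index, map) per category, aligned with ``maps``
    map_sources: dict[str, list[int]] = field(default_factory=dict)
    seed: int = 0


def default_phantom_config(seed: int = 0) -> PhantomConfig:
    """The 32^3 fast-benchmark phantom configuration."""
    return PhantomConfig(dims=(32, 32, 32), n_lesions=4,
                         radius_range_mm=(1.5, 3.0), seed=seed)


def run_benchmark(
    seed: int = 0,
    n_train: int = 24,
    n_val: int = 10,
    epochs: int = 20,
    noise: NoiseConfig | None = None,
    aggregation: str = "max_signed",
    threshold: float = 0.3,
    max_maps_per_category: dict[str, int] | None = None,
    phantom_config: PhantomConfig | None = None,
) -> BenchmarkResult:
    """Train, extract examples and compute saliency maps, all from one seed."""
    ss = np.random.SeedSequence(seed)
    s_train, s_val, s_fit, s_tn, s_noise = [
        int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(5)]
    base = phantom_config or default_phantom_config()
    train = list(phantom_stream(base, n_train, seed=s_train))
    val = list(phantom_stream(base, n_val, seed=s_val))
    model, summary = train_tiny_model(train, val, epochs=epochs, seed=s_fit)

    noise = noise or NoiseConfig(n=4, sigma=0.05, seed=s_noise)
    caps = max_maps_per_category or {"TP": 40, "FP": 40, "FN": 40, "TN": 30}
    maps: dict[str, list[SaliencyMap]] = {c: [] for c in ("TP", "FP", "FN", "TN")}
    sources: dict[str, list[int]] = {c: [] for c in maps}
    example_sets = []
    for i, ph in enumerate(val):
        prob = model.forward(ph.volume, threshold=threshold).probabilities
        examples = extract_examples(prob, ph.gt_mask, ph.brain_mask,
                                    ph.volume.spacing, threshold=threshold,
                                    seed=s_tn + i)
        example_sets.append(examples)
        cfg_i = NoiseConfig(n=noise.n, sigma=noise.sigma, seed=noise.seed + i)
        trimmed = ExampleSet(provenance=examples.provenance)
        for cat in maps:
            budget = max(caps[cat] - len(maps[cat]), 0)
            trimmed.category(cat).extend(examples.category(cat)[:budget])
        per_volume = compute_example_maps(model, ph.volume, trimmed, cfg_i,
                                          aggregation)
        for cat, sal_list in per_volume.items():
            maps[cat].extend(sal_list)
            sources[cat].extend([i] * len(sal_list))
    return BenchmarkResult(model=model, training_summary=summary, phantoms=val,
                           example_sets=example_sets, maps=maps,
                           map_sources=sources, seed=seed)
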