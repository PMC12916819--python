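import numpy as np
import pytest

from lesionsal.benchmark import run_benchmark
from lesionsal.phantom import PhantomConfig, generate_phantom
from lesionsal.volume import InstanceMask, Volume

#: single seed for the expensive trained-model benchmark shared by the
#: stochastic tests; everything derived from it is reproducible
BENCH_SEED = 11


@pytest.fixture(scope="session")
def bench():
    """Trained tiny model plus extracted examples and their saliency maps."""
    return run_benchmark(seed=BENCH_SEED)


@pytest.fixture(scope="session")
def trained_model(bench):
    return bench.model


@pytest.fixture(scope="session")
def two_lesion_phantom():
    """A phantom with exactly two lesions separated well beyond the
    receptive-field diameter of the tiny model (radius 5, diameter 10)."""
    cfg = PhantomConfig(
        dims=(32, 32, 32),
        n_lesions=2,
        lesion_centers=((9.0, 9.0, 9.0), (23.0, 23.0, 23.0)),
        lesion_radii=(2.2, 2.2),
        seed=4,
    )
    return generate_phantom(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


def make_volume(data, spacing=None):
    data = np.asarray(data, dtype=float)
    names = tuple(f"ch{i + 1}" for i in range(data.shape[0]))
    return Volume(data=data, channels=names, spacing=spacing or ())


def cube_instance(shape, lo, size, spacing=(1.0, 1.0, 1.0), label=1):
    """Axis-aligned cube of voxels as an InstanceMask."""
    ranges = [np.arange(l, l + s) for l, s in zip(lo, size)]
    grid = np.meshgrid(*ranges, indexing="ij")
    vox = np.stack([g.ravel() for g in grid], axis=1)
    return InstanceMask(voxels=vox, shape=shape, spacing=spacing[: len(shape)],
                        label=label)
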