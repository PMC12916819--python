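"""Gradient saliency: aggregation rules, SmoothGrad, locality, band filter."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lesionsal.gradients import (
    NoiseConfig,
    max_signed_aggregate,
    saliency_band_filter,
    smoothgrad_instance,
    vanilla_instance_map,
)
from lesionsal.models import AnalyticLinearModel, FixedConvModel
from lesionsal.volume import EmptyDomainError, InstanceMask

from conftest import cube_instance, make_volume

SHAPE = (8, 8, 8)
SP = (1.0, 1.0, 1.0)


def linear_setup(n_omega=8):
    model = AnalyticLinearModel(weights=(2.0, -0.5))
    rng = np.random.default_rng(0)
    x = make_volume(rng.normal(size=(2,) + SHAPE))
    side = round(n_omega ** (1 / 3))
    omega = cube_instance(SHAPE, (2, 2, 2), (side, side, side))
    return model, x, omega


class TestAggregation:
    def test_mean_scales_inversely_with_domain_size(self):
        model, x, omega = linear_setup(8)
        sal = vanilla_instance_map(model, x, omega, "mean")
        inside = sal.values[:, omega.to_dense()]
        assert np.allclose(inside[0], 2.0 / 8)
        assert np.allclose(inside[1], -0.5 / 8)
        outside = sal.values[:, ~omega.to_dense()]
        assert np.all(outside == 0)

    def test_max_signed_recovers_weights_exactly(self):
        model, x, omega = linear_setup(8)
        sal = vanilla_instance_map(model, x, omega, "max_signed")
        inside = sal.values[:, omega.to_dense()]
        assert np.all(inside[0] == 2.0)
        assert np.all(inside[1] == -0.5)

    @pytest.mark.parametrize("size", [1, 8, 64])
    def test_size_invariance_of_max_signed(self, size):
        """Signed-max in-lesion values do not depend on |Omega| while the
        mean shrinks as 1/|Omega| — the size-comparability property."""
        model, x, _ = linear_setup()
        side = round(size ** (1 / 3))
        omega = cube_instance(SHAPE, (1, 1, 1), (side, side, side))
        mx = vanilla_instance_map(model, x, omega, "max_signed")
        mn = vanilla_instance_map(model, x, omega, "mean")
        dense = omega.to_dense()
        assert np.all(mx.values[0][dense] == 2.0)
        assert np.allclose(mn.values[0][dense], 2.0 / size)

    def test_zero_weight_model(self):
        model = AnalyticLinearModel(weights=(0.0, 0.0))
        x = make_volume(np.ones((2,) + SHAPE))
        omega = cube_instance(SHAPE, (2, 2, 2), (2, 2, 2))
        sal = vanilla_instance_map(model, x, omega, "max_signed")
        assert np.all(sal.values == 0)

    def test_empty_domain(self):
        model, x, _ = linear_setup()
        empty = InstanceMask(np.empty((0, 3), int), SHAPE, SP)
        with pytest.raises(EmptyDomainError):
            vanilla_instance_map(model, x, empty)


class TestMaxSignedAggregate:
    def test_sign_preserved(self):
        assert max_signed_aggregate(np.array([0.2, -0.5, 0.4])) == -0.5

    def test_tie_breaks_to_earliest(self):
        assert max_signed_aggregate(np.array([0.3, -0.3])) == 0.3

    def test_singleton(self):
        assert max_signed_aggregate(np.array([-1.7])) == -1.7

    def test_empty(self):
        with pytest.raises(ValueError):
            max_signed_aggregate(np.empty((0, 2)))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-10, 10, allow_nan=False), min_size=1, max_size=12))
    def test_matches_brute_force(self, cand):
        cand = np.asarray(cand)
        got = max_signed_aggregate(cand)
        assert abs(got) == pytest.approx(max(np.abs(cand)))
        assert got in cand


class TestSmoothGrad:
    def test_reduces_to_vanilla(self):
        model, x, omega = linear_setup()
        a = smoothgrad_instance(model, x, omega, NoiseConfig(n=1, sigma=0.0),
                                "max_signed")
        b = vanilla_instance_map(model, x, omega, "max_signed")
        assert np.array_equal(a.values, b.values)
        assert b.method == "vanilla"

    def test_linear_model_noise_invariant(self):
        """Gradients of a per-voxel linear model do not depend on the input,
        so SmoothGrad equals vanilla for any sigma."""
        model, x, omega = linear_setup()
        noisy = smoothgrad_instance(model, x, omega,
                                    NoiseConfig(n=5, sigma=0.3, seed=2), "mean")
        clean = vanilla_instance_map(model, x, omega, "mean")
        assert np.allclose(noisy.values, clean.values, atol=1e-12)

    def test_fixed_conv_single_voxel_footprint(self):
        kernel = np.array([1.0, 2.0, 1.0]).reshape(3, 1, 1)
        model = FixedConvModel(kernel=kernel)
        x = make_volume(np.random.default_rng(0).normal(size=(1,) + SHAPE))
        omega = cube_instance(SHAPE, (4, 4, 4), (1, 1, 1))
        sal = smoothgrad_instance(model, x, omega, NoiseConfig(n=1, sigma=0.0),
                                  "max_signed")
        assert sal.values[0][4, 4, 4] == 2.0
        assert sal.values[0][3, 4, 4] == 1.0 and sal.values[0][5, 4, 4] == 1.0
        assert np.count_nonzero(sal.values) == 3

    def test_seeded_bit_reproducibility(self, bench):
        model = bench.model
        ph = bench.phantoms[0]
        omega = bench.example_sets[0].tp[0]
        cfg = NoiseConfig(n=3, sigma=0.05, seed=77)
        a = smoothgrad_instance(model, ph.volume, omega, cfg, "max_signed")
        b = smoothgrad_instance(model, ph.volume, omega, cfg, "max_signed")
        assert np.array_equal(a.values, b.values)

    def test_invalid_config(self):
        with pytest.raises(ValueError):
            NoiseConfig(n=0)
        with pytest.raises(ValueError):
            NoiseConfig(sigma=-0.1)


class TestOracleEquivalence:
    def test_mean_equals_brute_force_average(self):
        """Single backward pass on the summed logits against the average of
        per-voxel gradient maps (the brute-force oracle)."""
        kernel = np.zeros((3, 3, 3))
        kernel[1, 1, 1] = 2.0
        kernel[0, 1, 1] = kernel[2, 1, 1] = 1.0
        kernel[1, 0, 1] = kernel[1, 2, 1] = -0.5
        model = FixedConvModel(kernel=kernel)
        rng = np.random.default_rng(4)
        x = make_volume(rng.normal(size=(1, 16, 16, 16)))
        vox = rng.integers(2, 14, size=(20, 3))
        vox = np.unique(vox, axis=0)
        omega = InstanceMask(vox, (16, 16, 16), SP)
        fast = smoothgrad_instance(model, x, omega, NoiseConfig(1, 0.0), "mean")
        brute = np.zeros((16, 16, 16))
        for v in omega.voxels:
            seed = np.zeros((16, 16, 16))
            seed[tuple(v)] = 1.0
            brute += model.input_gradient(x.data, seed)[0]
        brute /= len(omega)
        assert np.allclose(fast.values[0], brute, atol=1e-5)

    def test_locality_beyond_receptive_field(self):
        kernel = np.ones((3, 3, 3))
        model = FixedConvModel(kernel=kernel)
        x = make_volume(np.random.default_rng(0).normal(size=(1, 12, 12, 12)))
        omega = cube_instance((12, 12, 12), (5, 5, 5), (2, 2, 2))
        for agg in ("mean", "max_signed"):
            sal = smoothgrad_instance(model, x, omega, NoiseConfig(1, 0.0), agg,
                                      crop_margin=4)
            dense = omega.to_dense()
            dist = np.full((12, 12, 12), 99)
            for v in omega.voxels:
                cheb = np.max(np.abs(np.indices((12, 12, 12)) - v.reshape(3, 1, 1, 1)),
                              axis=0)
                dist = np.minimum(dist, cheb)
            assert np.all(sal.values[0][dist > 1] == 0)
            assert np.any(sal.values[0][dist <= 1] != 0)

    def test_crop_equals_full_volume(self):
        kernel = np.ones((3, 3, 3))
        model = FixedConvModel(kernel=kernel)
        x = make_volume(np.random.default_rng(2).normal(size=(1, 14, 14, 14)))
        omega = cube_instance((14, 14, 14), (6, 6, 6), (2, 2, 2))
        cropped = smoothgrad_instance(model, x, omega, NoiseConfig(1, 0.0),
                                      "max_signed")
        full = smoothgrad_instance(model, x, omega, NoiseConfig(1, 0.0),
                                   "max_signed", crop_margin=14)
        assert np.allclose(cropped.values, full.values, atol=1e-12)


class TestBandFilter:
    def test_open_interval(self):
        model, x, omega = linear_setup()
        sal = vanilla_instance_map(model, x, omega, "mean")
        vals = np.array([[0.05, -0.09, 0.11, 0.1, -0.1, 0.0]])
        sal = type(sal)(values=vals, channels=("ch1",), method="vanilla",
                        aggregation="mean", instance_label=1, noise=sal.noise)
        out = saliency_band_filter(sal, (-0.1, 0.1))
        assert out.values.tolist() == [[0.0, 0.0, 0.11, 0.1, -0.1, 0.0]]

    def test_zero_map_unchanged(self):
        model, x, omega = linear_setup()
        sal = vanilla_instance_map(AnalyticLinearModel(weights=(0.0, 0.0)), x,
                                   omega, "mean")
        out = saliency_band_filter(sal)
        assert np.array_equal(out.values, sal.values)

    def test_invalid_band(self):
        model, x, omega = linear_setup()
        sal = vanilla_instance_map(model, x, omega, "mean")
        with pytest.raises(ValueError):
            saliency_band_filter(sal, (0.2, 0.1))
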