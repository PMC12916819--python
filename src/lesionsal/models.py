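"""Segmentation-model contract and small reference models.

Saliency computation only needs three things from a model: a forward pass to
per-voxel logits, gradients of weighted sums of output logits with respect to
the input channels, and (for Grad-CAM++) access to the activation maps of a
named layer together with derivatives of logit functionals with respect to
them.  ``SegmentationModel`` pins that contract down; three reference models
implement it:

* :class:`AnalyticLinearModel` — ``y[v] = sum_c w_c x_c[v] + b`` per voxel,
  no spatial mixing, every derivative known in closed form.
* :class:`FixedConvModel` — one fixed convolution kernel applied to one
  channel; its receptive field equals the kernel radius exactly.
* :class:`TinyCNN` — a small two-resolution encoder–decoder with LeakyReLU
  units, trainable on synthetic phantoms, with named activation layers.

All gradients are computed by explicit backpropagation (no autodiff
framework); batched seeds let the per-voxel gradient maps of a whole lesion
domain be obtained in one sweep.
"""

from __future__ import annotations

import json
from abc import ABC, abstractmethod
from dataclasses import dataclass

import numpy as np

from . import _nn
from .volume import LogitMap, Volume


class CapabilityError(RuntimeError):
    """The model cannot provide the requested derivative or layer."""


# ---------------------------------------------------------------------------
# layer sub-networks: y' as a function of one layer's activations
# ---------------------------------------------------------------------------

class LayerSubnetwork(ABC):
    """The part of a model downstream of a chosen layer.

    Exposes the logits as a function of that layer's activation maps ``A``
    (shape ``(K, *S_layer)``), everything else held fixed at the values from
    the original forward pass.
    """

    #: activations recorded during the forward pass
    activations: np.ndarray
    #: True when the logits are an affine function of A (exact higher-order
    #: diagonal derivatives vanish identically)
    is_affine: bool = False
    #: True when the map A -> logits is piecewise affine (ReLU networks):
    #: exact diagonal second/third derivatives vanish almost everywhere
    is_piecewise_affine: bool = False

    @abstractmethod
    def logits_from(self, A: np.ndarray) -> np.ndarray:
        """Recompute the logit map from activations ``A``."""

    @abstractmethod
    def gradient_from(self, A: np.ndarray, seed: np.ndarray) -> np.ndarray:
        """d(sum_v seed[v] * y[v]) / dA for the given activations."""


class ActivationFunctional:
    """Scalar functional ``y' = sum_v w[v] y[v]`` as a function of activations."""

    def __init__(self, sub: LayerSubnetwork, weights: np.ndarray):
        self.sub = sub
        self.weights = np.asarray(weights, dtype=float)

    @property
    def activations(self) -> np.ndarray:
        return self.sub.activations

    def value(self, A: np.ndarray) -> float:
        return float(np.sum(self.weights * self.sub.logits_from(A)))

    def gradient(self, A: np.ndarray) -> np.ndarray:
        return self.sub.gradient_from(A, self.weights)

    def diag_second(self, A: np.ndarray) -> np.ndarray:
        if self.sub.is_affine or self.sub.is_piecewise_affine:
            return np.zeros_like(A)
        raise CapabilityError("no exact second-order derivative for this layer path")

    def diag_third(self, A: np.ndarray) -> np.ndarray:
        if self.sub.is_affine or self.sub.is_piecewise_affine:
            return np.zeros_like(A)
        raise CapabilityError("no exact third-order derivative for this layer path")


# ---------------------------------------------------------------------------
# the model contract
# ---------------------------------------------------------------------------

class SegmentationModel(ABC):
    """Contract any model must satisfy for saliency computation."""

    name: str = "model"
    channels_in: int = 1
    #: maximal Chebyshev voxel distance at which an input perturbation can
    #: change a given output voxel; derived from architecture, not measured
    receptive_field_radius: float = np.inf
    layer_names: tuple[str, ...] = ()

    @abstractmethod
    def logits(self, data: np.ndarray) -> np.ndarray:
        """Raw forward pass on an array ``(C, *spatial)`` to logits ``(*spatial)``."""

    @abstractmethod
    def input_gradient_batch(self, data: np.ndarray, seeds: np.ndarray) -> np.ndarray:
        """Gradients of ``sum_v seeds[b, v] * y[v]`` w.r.t. the input.

        ``seeds`` has shape ``(B, *spatial)``; the result ``(B, C, *spatial)``.
        """

    @abstractmethod
    def layer_subnetwork(self, data: np.ndarray, layer: str) -> LayerSubnetwork:
        """Activations of ``layer`` and the downstream map to logits."""

    # -- conveniences shared by all models ---------------------------------

    def _check_input(self, data: np.ndarray) -> np.ndarray:
        data = np.asarray(data, dtype=float)
        if data.ndim < 2 or data.shape[0] != self.channels_in:
            raise ValueError(
                f"model {self.name!r} expects (C={self.channels_in}, *spatial) input, "
                f"got shape {data.shape}"
            )
        return data

    def forward(self, x: Volume, threshold: float = 0.3) -> LogitMap:
        y = self.logits(self._check_input(x.data))
        if y.shape != x.shape:
            raise RuntimeError("model changed spatial dimensions")
        return LogitMap(values=y, threshold=threshold)

    def input_gradient(self, data: np.ndarray, seed: np.ndarray) -> np.ndarray:
        """Gradient of one weighted sum of logits: ``(C, *spatial)``."""
        return self.input_gradient_batch(data, np.asarray(seed, dtype=float)[None])[0]


def forward_logits(model: SegmentationModel, x: Volume, threshold: float = 0.3) -> LogitMap:
    """Forward pass returning logits and their Softmax companion map."""
    return model.forward(x, threshold=threshold)


def gradient_wrt_input(model: SegmentationModel, x: Volume, weights: np.ndarray) -> np.ndarray:
    """Per-channel gradient maps of the functional ``sum_v weights[v] y[v]``.

    ``weights`` is a dense array over the output grid; it is typically a
    (scaled) indicator of a lesion domain.  Raises if no voxel is referenced.
    """
    weights = np.asarray(weights, dtype=float)
    if weights.shape != x.shape:
        raise ValueError("functional weights must cover the output grid")
    if not np.any(weights != 0):
        raise ValueError("functional references an empty voxel set")
    return model.input_gradient(x.data, weights)


def gradient_wrt_activation(
    model: SegmentationModel,
    x: Volume,
    layer: str,
    weights: np.ndarray,
    order: int = 1,
    method: str = "exact",
    fd_step: float = 1e-3,
):
    """Derivatives of ``y' = sum_v weights[v] y[v]`` w.r.t. a layer's activations.

    Orders 2 and 3 are diagonal (pure) derivatives per activation element.
    ``method`` is ``"exact"`` (closed form where the layer path allows it) or
    ``"finite_difference"`` (central differences on the activations, step
    ``fd_step``).  Returns ``(derivative_array, metadata_dict)``.
    """
    if order not in (1, 2, 3):
        raise ValueError(f"unsupported derivative order {order}")
    sub = model.layer_subnetwork(model._check_input(x.data), layer)
    func = ActivationFunctional(sub, weights)
    A = sub.activations
    meta = {"layer": layer, "order": order, "method": method}
    if order == 1:
        return func.gradient(A), meta
    if method == "exact":
        deriv = func.diag_second(A) if order == 2 else func.diag_third(A)
        return deriv, meta
    if method == "finite_difference":
        deriv = fd_diag_derivative(func.value, A, order, fd_step)
        return deriv, meta
    raise ValueError(f"unknown derivative method {method!r}")


def fd_diag_derivative(value, A: np.ndarray, order: int, step: float) -> np.ndarray:
    """Central finite differences of a scalar function, one coordinate at a time.

    O(#elements) function evaluations — intended for small layers and oracle
    checks, not for production-size volumes.
    """
    out = np.zeros_like(A, dtype=float)
    flat = out.reshape(-1)
    base = A.copy()
    bflat = base.reshape(-1)
    for i in range(bflat.size):
        a0 = bflat[i]

        def f(delta, i=i, a0=a0):
            bflat[i] = a0 + delta
            v = value(base)
            bflat[i] = a0
            return v

        if order == 2:
            flat[i] = (f(step) - 2.0 * f(0.0) + f(-step)) / step**2
        else:
            flat[i] = (f(2 * step) - 2 * f(step) + 2 * f(-step) - f(-2 * step)) / (2 * step**3)
    return out


# ---------------------------------------------------------------------------
# reference models
# ---------------------------------------------------------------------------

class _InputSubnetwork(LayerSubnetwork):
    def __init__(self, model, data):
        self.model = model
        self.activations = np.asarray(data, dtype=float)
        self.is_affine = True

    def logits_from(self, A):
        return self.model.logits(A)

    def gradient_from(self, A, seed):
        return self.model.input_gradient_batch(A, np.asarray(seed, float)[None])[0]


class AnalyticLinearModel(SegmentationModel):
    """Per-voxel linear model ``y[v] = sum_c w_c x_c[v] + b``.

    No spatial mixing: the receptive-field radius is zero and every gradient
    is constant in the input, which makes this the cheapest oracle for
    aggregation rules.
    """

    name = "analytic_linear"
    layer_names = ("input",)
    receptive_field_radius = 0

    def __init__(self, weights=(1.0, 0.0), bias: float = 0.0):
        self.weights = np.asarray(weights, dtype=float)
        self.bias = float(bias)
        self.channels_in = self.weights.size

    def logits(self, data):
        data = self._check_input(data)
        return np.tensordot(self.weights, data, axes=([0], [0])) + self.bias

    def input_gradient_batch(self, data, seeds):
        data = self._check_input(data)
        seeds = np.asarray(seeds, dtype=float)
        return seeds[:, None] * self.weights.reshape((1, -1) + (1,) * (data.ndim - 1))

    def layer_subnetwork(self, data, layer):
        if layer != "input":
            raise CapabilityError(f"layer {layer!r} not exposed by {self.name}")
        return _InputSubnetwork(self, data)


class FixedConvModel(SegmentationModel):
    """A single fixed convolution kernel applied to one input channel.

    The kernel is given explicitly (odd sizes along each axis); the
    receptive-field radius equals the kernel's Chebyshev radius, so gradient
    support can be checked exactly.
    """

    name = "fixed_conv"
    layer_names = ("input",)

    def __init__(self, kernel: np.ndarray, n_channels: int = 1, channel: int = 0):
        self.kernel = np.asarray(kernel, dtype=float)
        self.channels_in = n_channels
        self.channel = channel
        self.receptive_field_radius = max(k // 2 for k in self.kernel.shape)

    def logits(self, data):
        data = self._check_input(data)
        w = np.zeros((1, self.channels_in) + self.kernel.shape)
        w[0, self.channel] = self.kernel
        return _nn.conv_forward(data, w)[0]

    def input_gradient_batch(self, data, seeds):
        data = self._check_input(data)
        seeds = np.asarray(seeds, dtype=float)
        w = np.zeros((1, self.channels_in) + self.kernel.shape)
        w[0, self.channel] = self.kernel
        out = _nn.conv_backward_input(seeds[None], w, data.shape[1:])
        return np.swapaxes(out, 0, 1)

    def layer_subnetwork(self, data, layer):
        if layer != "input":
            raise CapabilityError(f"layer {layer!r} not exposed by {self.name}")
        return _InputSubnetwork(self, data)


# ---------------------------------------------------------------------------
# tiny trainable CNN
# ---------------------------------------------------------------------------

def _tiny_rf_radius(r1: int, r2: int, r3: int) -> int:
    """Chebyshev receptive-field radius of the two-level encoder–decoder.

    Propagates index intervals analytically through conv (radius grows by the
    kernel radius), 2x average pooling (interval [a,b] -> [2a, 2b+1]) and 2x
    nearest upsampling ([a,b] -> [floor(a/2), floor(b/2)]), over all pooling
    parities of the queried output voxel.
    """
    radius = 0
    for o in range(4):
        lo, hi = o - r3, o + r3                      # decoder conv
        s_lo, s_hi = lo - r1, hi + r1                # skip branch: encoder conv
        d_lo, d_hi = lo // 2, hi // 2                # deep branch: upsample
        d_lo, d_hi = d_lo - r2, d_hi + r2            # bottleneck conv
        d_lo, d_hi = 2 * d_lo, 2 * d_hi + 1          # pooling
        d_lo, d_hi = d_lo - r1, d_hi + r1            # encoder conv
        lo, hi = min(s_lo, d_lo), max(s_hi, d_hi)
        radius = max(radius, o - lo, hi - o)
    return radius


@dataclass
class _TinyCache:
    data: np.ndarray
    padded: np.ndarray
    pre1: np.ndarray
    a1: np.ndarray
    pooled: np.ndarray
    pre2: np.ndarray
    a2: np.ndarray
    up: np.ndarray
    cat: np.ndarray
    pre3: np.ndarray
    a3: np.ndarray
    y: np.ndarray
    orig_shape: tuple[int, ...]


class TinyCNN(SegmentationModel):
    """Two-resolution encoder–decoder with a skip connection.

    ``conv(3) -> act -> avgpool(2) -> conv(3) -> act -> nearest-up(2) ->
    concat(skip) -> conv(3) -> act -> 1x1 conv`` with LeakyReLU activations
    (slope 0.01 — the choice common in segmentation U-Nets, which also keeps
    rarely-used channels trainable); well under 50k parameters
    at the default widths.  Inputs with odd spatial sizes are zero-padded to
    even sizes internally and outputs cropped back.

    Exposed activation layers: ``enc1`` (first activation, full
    resolution), ``enc2`` (bottleneck activation, half resolution),
    ``features`` (last activation before the logit head, full resolution —
    the default layer for Grad-CAM++ on a segmentation architecture).
    """

    name = "tiny_cnn"
    layer_names = ("enc1", "enc2", "features")

    def __init__(self, channels_in=2, f1=8, f2=16, f3=8, ndim=3, seed=0,
                 leaky_slope=0.01):
        self.channels_in = channels_in
        self.f1, self.f2, self.f3 = f1, f2, f3
        self.ndim = ndim
        self.leaky_slope = float(leaky_slope)
        rng = np.random.default_rng(seed)
        k = (3,) * ndim

        def he(shape, fan_in):
            return rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape)

        kn = 3 ** ndim
        self.params = {
            "W1": he((f1, channels_in) + k, channels_in * kn),
            "b1": np.zeros(f1),
            "W2": he((f2, f1) + k, f1 * kn),
            "b2": np.zeros(f2),
            "W3": he((f3, f1 + f2) + k, (f1 + f2) * kn),
            "b3": np.zeros(f3),
            "Wh": he((1, f3) + (1,) * ndim, f3),
            "bh": np.zeros(1),
        }
        self.receptive_field_radius = _tiny_rf_radius(1, 1, 1)

    @property
    def n_parameters(self) -> int:
        return sum(int(p.size) for p in self.params.values())

    def _act(self, pre: np.ndarray) -> np.ndarray:
        """LeakyReLU — keeps gradient flow alive in rarely-active channels."""
        return np.where(pre > 0, pre, self.leaky_slope * pre)

    def _act_grad(self, pre: np.ndarray) -> np.ndarray:
        return np.where(pre > 0, 1.0, self.leaky_slope)

    # -- forward -----------------------------------------------------------

    def _pad_even(self, data):
        spatial = data.shape[1:]
        pads = [(0, 0)] + [(0, n % 2) for n in spatial]
        if any(p[1] for p in pads):
            data = np.pad(data, pads)
        return data

    def _forward_cache(self, data) -> _TinyCache:
        data = self._check_input(data)
        orig = data.shape[1:]
        xp = self._pad_even(data)
        p = self.params
        pre1 = _nn.conv_forward(xp, p["W1"], p["b1"])
        a1 = self._act(pre1)
        pooled = _nn.avgpool2_forward(a1, self.ndim)
        pre2 = _nn.conv_forward(pooled, p["W2"], p["b2"])
        a2 = self._act(pre2)
        up = _nn.repeat2(a2, self.ndim)
        cat = np.concatenate([up, a1], axis=0)
        pre3 = _nn.conv_forward(cat, p["W3"], p["b3"])
        a3 = self._act(pre3)
        y = _nn.conv_forward(a3, p["Wh"], p["bh"])[0]
        return _TinyCache(data, xp, pre1, a1, pooled, pre2, a2, up, cat, pre3, a3, y, orig)

    @staticmethod
    def _crop(arr, orig):
        return arr[(...,) + tuple(slice(0, n) for n in orig)]

    def logits(self, data):
        c = self._forward_cache(data)
        return self._crop(c.y, c.orig_shape)

    # -- backward ----------------------------------------------------------

    def _backward_from_logits(self, cache: _TinyCache, seeds: np.ndarray, stop: str | None = None):
        """Backpropagate batched logit seeds; stop early at a named layer.

        Returns the gradient at the stop layer, or the input gradient when
        ``stop`` is None.  ``seeds`` has shape ``(B, *orig_spatial)``; the
        result ``(B, C, *spatial)``.  Internally the batch axis sits after
        the channel axis to keep every GEMM copy-free.
        """
        p = self.params
        nd = self.ndim
        even = cache.padded.shape[1:]
        half = cache.pooled.shape[1:]
        seeds = np.asarray(seeds, dtype=float)
        pads = [(0, 0)] + [(0, e - n) for e, n in zip(even, cache.orig_shape)]
        g_y = np.pad(seeds, pads)[None]  # (Cout=1, B, *even)

        def done(g):  # (C, B, ...) -> (B, C, ...)
            return np.swapaxes(g, 0, 1)

        g_a3 = _nn.conv_backward_input(g_y, p["Wh"], even)
        if stop == "features":
            return done(g_a3)
        g_pre3 = g_a3 * self._act_grad(cache.pre3)[:, None]
        g_cat = _nn.conv_backward_input(g_pre3, p["W3"], even)
        g_up = g_cat[: self.f2]
        g_a1 = g_cat[self.f2:]
        g_a2 = _nn.upsample2_backward(g_up, nd)
        if stop == "enc2":
            return done(g_a2)
        g_pre2 = g_a2 * self._act_grad(cache.pre2)[:, None]
        g_pool = _nn.conv_backward_input(g_pre2, p["W2"], half)
        g_a1 = g_a1 + _nn.avgpool2_backward(g_pool, nd)
        if stop == "enc1":
            return done(g_a1)
        g_pre1 = g_a1 * self._act_grad(cache.pre1)[:, None]
        g_x = _nn.conv_backward_input(g_pre1, p["W1"], even)
        return done(self._crop(g_x, cache.orig_shape))

    def input_gradient_batch(self, data, seeds):
        cache = self._forward_cache(data)
        return self._backward_from_logits(cache, seeds)

    # -- training ----------------------------------------------------------

    def loss_and_gradients(self, data, target, pos_weight: float = 5.0):
        """Per-voxel binary cross-entropy with logits and positive-class weight.

        Returns ``(loss, grads)`` with grads keyed like ``self.params``.
        """
        cache = self._forward_cache(data)
        y = self._crop(cache.y, cache.orig_shape)
        t = np.asarray(target, dtype=float)
        w = np.where(t > 0, pos_weight, 1.0)
        # stable formulation: max(y,0) - y*t + log(1+exp(-|y|)), class-weighted
        loss_map = w * (np.maximum(y, 0.0) - y * t + np.log1p(np.exp(-np.abs(y))))
        n = loss_map.size
        loss = float(loss_map.sum() / n)
        p = 1.0 / (1.0 + np.exp(-y))
        g_y = w * (p - t) / n

        prm = self.params
        nd = self.ndim
        even = cache.padded.shape[1:]
        half = cache.pooled.shape[1:]
        pads = [(0, e - m) for e, m in zip(even, cache.orig_shape)]
        g_yp = np.pad(g_y, pads)[None]  # (1, *even): channel axis for the head
        grads = {}
        grads["Wh"], grads["bh"] = _nn.conv_backward_weights(g_yp, cache.a3, (1,) * nd)
        g_a3 = _nn.conv_backward_input(g_yp[:, None], prm["Wh"], even)[:, 0]
        g_pre3 = g_a3 * self._act_grad(cache.pre3)
        grads["W3"], grads["b3"] = _nn.conv_backward_weights(g_pre3, cache.cat, prm["W3"].shape[2:])
        g_cat = _nn.conv_backward_input(g_pre3[:, None], prm["W3"], even)[:, 0]
        g_up = g_cat[: self.f2]
        g_skip = g_cat[self.f2:]
        g_a2 = _nn.upsample2_backward(g_up, nd)
        g_pre2 = g_a2 * self._act_grad(cache.pre2)
        grads["W2"], grads["b2"] = _nn.conv_backward_weights(g_pre2, cache.pooled, prm["W2"].shape[2:])
        g_pool = _nn.conv_backward_input(g_pre2[:, None], prm["W2"], half)[:, 0]
        g_a1 = g_skip + _nn.avgpool2_backward(g_pool, nd)
        g_pre1 = g_a1 * self._act_grad(cache.pre1)
        grads["W1"], grads["b1"] = _nn.conv_backward_weights(g_pre1, cache.padded, prm["W1"].shape[2:])
        return loss, grads

    # -- activation layers -------------------------------------------------

    def layer_subnetwork(self, data, layer):
        if layer not in self.layer_names:
            raise CapabilityError(f"layer {layer!r} not exposed by {self.name}")
        cache = self._forward_cache(data)
        return _TinySubnetwork(self, cache, layer)

    # -- persistence -------------------------------------------------------

    def save(self, path):
        meta = dict(channels_in=self.channels_in, f1=self.f1, f2=self.f2,
                    f3=self.f3, ndim=self.ndim, leaky_slope=self.leaky_slope)
        np.savez(path, __meta__=json.dumps(meta), **self.params)

    @classmethod
    def load(cls, path) -> "TinyCNN":
        with np.load(path, allow_pickle=False) as npz:
            meta = json.loads(str(npz["__meta__"]))
            model = cls(**meta)
            for key in model.params:
                model.params[key] = npz[key]
        return model


class _TinySubnetwork(LayerSubnetwork):
    """Downstream map from a TinyCNN layer's activations to the logits."""

    is_piecewise_affine = True

    def __init__(self, model: TinyCNN, cache: _TinyCache, layer: str):
        self.model = model
        self.cache = cache
        self.layer = layer
        # enc2 lives at half resolution of the internally padded grid
        acts = {"enc1": cache.a1, "enc2": cache.a2, "features": cache.a3}[layer]
        self.activations = acts
        self.is_affine = layer == "features"  # only a 1x1 conv downstream

    def logits_from(self, A):
        m, c = self.model, self.cache
        p = m.params
        nd = m.ndim
        if self.layer == "features":
            y = _nn.conv_forward(A, p["Wh"], p["bh"])[0]
            return m._crop(y, c.orig_shape)
        if self.layer == "enc2":
            up = _nn.repeat2(A, nd)
            cat = np.concatenate([up, c.a1], axis=0)
        else:  # enc1: feeds both the pooling path and the skip connection
            pooled = _nn.avgpool2_forward(A, nd)
            a2 = m._act(_nn.conv_forward(pooled, p["W2"], p["b2"]))
            cat = np.concatenate([_nn.repeat2(a2, nd), A], axis=0)
        a3 = m._act(_nn.conv_forward(cat, p["W3"], p["b3"]))
        y = _nn.conv_forward(a3, p["Wh"], p["bh"])[0]
        return m._crop(y, c.orig_shape)

    def gradient_from(self, A, seed):
        m = self.model
        base = {"enc1": self.cache.a1, "enc2": self.cache.a2,
                "features": self.cache.a3}[self.layer]
        if np.array_equal(A, base):
            return m._backward_from_logits(self.cache, np.asarray(seed, float)[None],
                                           stop=self.layer)[0]
        # recompute the downstream caches for perturbed activations
        cache = self._perturbed_cache(A)
        return m._backward_from_logits(cache, np.asarray(seed, float)[None],
                                       stop=self.layer)[0]

    def _perturbed_cache(self, A):
        m, c = self.model, self.cache
        p = m.params
        nd = m.ndim
        if self.layer == "features":
            a3, pre3, cat, a2, pre2, a1, pre1 = A, c.pre3, c.cat, c.a2, c.pre2, c.a1, c.pre1
        elif self.layer == "enc2":
            a2 = A
            up = _nn.repeat2(a2, nd)
            cat = np.concatenate([up, c.a1], axis=0)
            pre3 = _nn.conv_forward(cat, p["W3"], p["b3"])
            a3 = m._act(pre3)
            pre2, a1, pre1 = c.pre2, c.a1, c.pre1
        else:
            a1 = A
            pooled = _nn.avgpool2_forward(a1, nd)
            pre2 = _nn.conv_forward(pooled, p["W2"], p["b2"])
            a2 = m._act(pre2)
            cat = np.concatenate([_nn.repeat2(a2, nd), a1], axis=0)
            pre3 = _nn.conv_forward(cat, p["W3"], p["b3"])
            a3 = m._act(pre3)
            pre1 = c.pre1
        y = _nn.conv_forward(a3, p["Wh"], p["bh"])[0]
        return _TinyCache(c.data, c.padded, pre1, a1,
                          _nn.avgpool2_forward(a1, nd), pre2, a2,
                          _nn.repeat2(a2, nd), cat, pre3, a3, y, c.orig_shape)


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

MODEL_REGISTRY = {
    "analytic_linear": AnalyticLinearModel,
    "fixed_conv": FixedConvModel,
    "tiny_cnn": TinyCNN,
}


def build_model(config: dict) -> SegmentationModel:
    """Construct a model from a plain configuration mapping.

    ``config["type"]`` selects the registry entry; remaining keys are passed
    to the constructor (``kernel`` and ``weights`` entries are converted to
    arrays).
    """
    cfg = dict(config)
    kind = cfg.pop("type")
    if kind not in MODEL_REGISTRY:
        raise KeyError(f"unknown model type {kind!r}; known: {sorted(MODEL_REGISTRY)}")
    for key in ("kernel", "weights"):
        if key in cfg:
            cfg[key] = np.asarray(cfg[key], dtype=float)
    return MODEL_REGISTRY[kind](**cfg)
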