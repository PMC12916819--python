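"""Minimal dimension-agnostic neural-network primitives with explicit backprop.

Everything operates on arrays shaped ``(C, *spatial)``; backward passes accept
an extra leading batch axis ``(B, C, *spatial)`` so that the gradients of many
scalar functionals (e.g. one per lesion voxel) can be propagated in one sweep.
Convolutions use zero padding and odd kernels, implemented as a loop over
kernel offsets with one GEMM per offset — fast enough for the small reference
models used here and bit-deterministic.
"""

from __future__ import annotations

from itertools import product

import numpy as np


def _offset_slices(shape, off):
    return tuple(slice(o, o + n) for o, n in zip(off, shape))


def conv_forward(x: np.ndarray, weights: np.ndarray, bias: np.ndarray | None = None) -> np.ndarray:
    """Cross-correlation of ``x`` (Cin, *S) with ``weights`` (Cout, Cin, *k)."""
    kshape = weights.shape[2:]
    if any(k % 2 == 0 for k in kshape):
        raise ValueError("kernels must have odd sizes")
    spatial = x.shape[1:]
    n = int(np.prod(spatial))
    cin = x.shape[0]
    cout = weights.shape[0]
    kprod = int(np.prod(kshape))
    pad = [(0, 0)] + [(k // 2, k // 2) for k in kshape]
    xp = np.pad(x, pad)
    w_mat = weights.reshape(cout, cin * kprod)
    offsets = list(product(*(range(k) for k in kshape)))
    # im2col over spatial chunks (first axis) keeps the GEMM fat and memory low
    chunk = max(1, 6_000_000 // (cin * kprod * n // spatial[0]))
    out = np.empty((cout,) + spatial, dtype=float)
    for start in range(0, spatial[0], chunk):
        stop = min(start + chunk, spatial[0])
        sub = (stop - start,) + spatial[1:]
        n_sub = int(np.prod(sub))
        cols = np.empty((cin, kprod, n_sub), dtype=float)
        for j, off in enumerate(offsets):
            sl = (slice(start + off[0], stop + off[0]),) + _offset_slices(spatial[1:], off[1:])
            cols[:, j, :] = xp[(slice(None),) + sl].reshape(cin, n_sub)
        out[:, start:stop] = (w_mat @ cols.reshape(cin * kprod, n_sub)).reshape((cout,) + sub)
    if bias is not None:
        out += bias.reshape((-1,) + (1,) * len(spatial))
    return out


def conv_backward_input(g: np.ndarray, weights: np.ndarray, spatial: tuple[int, ...]) -> np.ndarray:
    """Gradient w.r.t. the conv input for upstream gradient ``g``.

    ``g`` is shaped ``(Cout, B, *S)`` — the batch axis sits *after* the
    channel axis so each kernel offset is a single GEMM with no transposition
    copies; the result is ``(Cin, B, *S)``.
    """
    kshape = weights.shape[2:]
    cout, b = g.shape[:2]
    n = int(np.prod(spatial))
    cin = weights.shape[1]
    kprod = int(np.prod(kshape))
    # full correlation with the flipped kernel, as one fat GEMM per batch
    # chunk: dx = W_mat (Cin, Cout*kprod) @ G (Cout*kprod, chunk*n)
    flip = (slice(None), slice(None)) + tuple(slice(None, None, -1) for _ in kshape)
    w_mat = np.ascontiguousarray(
        weights[flip].reshape(cout, cin, kprod).transpose(1, 0, 2).reshape(cin, cout * kprod)
    )
    pad = [(0, 0), (0, 0)] + [(k // 2, k // 2) for k in kshape]
    gp = np.pad(g, pad)
    chunk = max(1, 6_000_000 // (cout * kprod * n))
    out = np.empty((cin, b) + spatial, dtype=float)
    cols = np.empty((cout, kprod, chunk * n), dtype=float)
    offsets = list(product(*(range(k) for k in kshape)))
    for start in range(0, b, chunk):
        bc = min(chunk, b - start)
        batch_sl = slice(start, start + bc)
        for j, off in enumerate(offsets):
            view = gp[(slice(None), batch_sl) + _offset_slices(spatial, off)]
            cols[:, j, : bc * n] = view.reshape(cout, bc * n)
        prod_ = w_mat @ cols[:, :, : bc * n].reshape(cout * kprod, bc * n)
        out[:, batch_sl] = prod_.reshape((cin, bc) + spatial)
    return out


def conv_backward_weights(g: np.ndarray, x: np.ndarray, kshape: tuple[int, ...]):
    """Gradients w.r.t. weights and bias; ``g`` (Cout, *S), ``x`` (Cin, *S)."""
    spatial = x.shape[1:]
    pad = [(0, 0)] + [(k // 2, k // 2) for k in kshape]
    xp = np.pad(x, pad)
    dW = np.zeros((g.shape[0], x.shape[0]) + kshape, dtype=float)
    for off in product(*(range(k) for k in kshape)):
        xs = xp[(slice(None),) + _offset_slices(spatial, off)]
        sp = list(range(1, g.ndim))
        dW[(slice(None), slice(None)) + off] = np.tensordot(g, xs, axes=(sp, sp))
    db = g.reshape(g.shape[0], -1).sum(axis=1)
    return dW, db


def _block2(x: np.ndarray, n_spatial: int, reduce: str) -> np.ndarray:
    """Reduce each spatial axis (the last ``n_spatial``) by a factor of 2."""
    for ax in range(x.ndim - n_spatial, x.ndim):
        if x.shape[ax] % 2:
            raise ValueError("pooled axes must have even length")
        shp = x.shape[:ax] + (x.shape[ax] // 2, 2) + x.shape[ax + 1:]
        x = x.reshape(shp)
        x = x.mean(axis=ax + 1) if reduce == "mean" else x.sum(axis=ax + 1)
    return x


def repeat2(x: np.ndarray, n_spatial: int) -> np.ndarray:
    """Nearest-neighbour upsampling by 2 along the last ``n_spatial`` axes."""
    for ax in range(x.ndim - n_spatial, x.ndim):
        x = np.repeat(x, 2, axis=ax)
    return x


def avgpool2_forward(x: np.ndarray, n_spatial: int) -> np.ndarray:
    return _block2(x, n_spatial, "mean")


def avgpool2_backward(g: np.ndarray, n_spatial: int) -> np.ndarray:
    return repeat2(g, n_spatial) / float(2 ** n_spatial)


def upsample2_backward(g: np.ndarray, n_spatial: int) -> np.ndarray:
    return _block2(g, n_spatial, "sum")


def relu(x: np.ndarray) -> np.ndarray:
    return np.maximum(x, 0.0)


class AdamState:
    """Plain Adam optimizer over a dict of named parameter arrays."""

    def __init__(self, params: dict[str, np.ndarray], lr=1e-2, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1 ** self.t
        b2t = 1.0 - self.beta2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= self.lr * (self.m[k] / b1t) / (np.sqrt(self.v[k] / b2t) + self.eps)
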