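"""Grad-CAM++ for segmentation, class-level and instance-level.

A heatmap is a rectified linear combination of the activation maps
``A^k`` of a chosen layer.  In class mode the scalar logit aggregate is
``y' = sum_{v | y[v] > t} y[v]`` and each map gets one weight

    ``w^k = sum_v alpha^k[v] * Relu(dy'/dA^k[v])``,

with the coefficients

    ``alpha^k[v] = d2 / (2*d2 + (sum_{v'} A^k[v']) * d3)``,

where ``d2`` and ``d3`` are the diagonal second and third derivatives of
``y'`` with respect to ``A^k[v]``.  In instance mode ``y'`` is the plain sum
of logits over one lesion domain Omega and the spatial summation in the
weight is dropped so every activation element keeps its own weight
``w^k[v] = alpha^k[v] * Relu(dy'/dA^k[v])`` — this is what stops the
activations of other lesion instances from leaking into the map.

Derivative routes for ``d2``/``d3``:

``exact``
    closed-form nested differentiation.  For layers whose downstream path is
    (piecewise) affine — the usual case in ReLU segmentation heads — these
    derivatives vanish identically (almost everywhere), the guarded division
    yields ``alpha = 0`` and the heatmap is degenerately zero.  The route is
    kept because it is the literal reading of the formulas and the right one
    for smooth reference functionals.
``power``
    the classical Grad-CAM++ closed form obtained by passing ``y'`` through
    an exponential before differentiating a piecewise-affine network:
    ``d2 = g^2`` and ``d3 = g^3`` with ``g = dy'/dA`` — one backward pass,
    and the practical route for trained ReLU models.
``finite_difference``
    central differences on the activations (small layers / oracle checks).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .models import ActivationFunctional, SegmentationModel, fd_diag_derivative
from .volume import InstanceMask, LogitMap, Volume, require_nonempty

ROUTES = ("exact", "power", "finite_difference")


@dataclass(frozen=True)
class Heatmap:
    """Non-negative Grad-CAM++ heatmap on the input grid."""

    values: np.ndarray
    mode: str  # "class" | "instance"
    layer: str
    instance_label: int | None = None
    route: str = "exact"
    third_term: str = "global"


def aggregate_logits_class(y: LogitMap | np.ndarray, threshold: float) -> float:
    """Sum of logits strictly above the threshold (class-level ``y'``)."""
    values = y.values if isinstance(y, LogitMap) else np.asarray(y, dtype=float)
    selected = values[values > threshold]
    if selected.size == 0:
        warnings.warn("no logit exceeds the threshold; class aggregate is 0",
                      stacklevel=2)
        return 0.0
    return float(selected.sum())


def aggregate_logits_instance(y: LogitMap | np.ndarray, omega: InstanceMask) -> float:
    """Signed sum of logits over one lesion domain (instance-level ``y'``)."""
    require_nonempty(omega, "lesion")
    values = y.values if isinstance(y, LogitMap) else np.asarray(y, dtype=float)
    return float(values[omega.index].sum())


def alpha_from_derivatives(
    activations: np.ndarray,
    d2: np.ndarray,
    d3: np.ndarray,
    eps: float = 1e-8,
    third_term: str = "global",
) -> np.ndarray:
    """Grad-CAM++ alpha coefficients from diagonal derivatives, per map.

    ``third_term="global"`` multiplies the local third derivative by the sum
    of the whole activation map (the literal reading of the formula, which
    matches the original classification derivation); ``"local"`` uses only
    the activation at the same location.  Where the denominator's magnitude
    falls below ``eps`` the coefficient is set to zero — at such points the
    first derivative is degenerate as well.
    """
    A = np.asarray(activations, dtype=float)
    spatial_axes = tuple(range(1, A.ndim))
    if third_term == "global":
        a_sum = A.sum(axis=spatial_axes, keepdims=True)
        denom = 2.0 * d2 + a_sum * d3
    elif third_term == "local":
        denom = 2.0 * d2 + A * d3
    else:
        raise ValueError("third_term must be 'global' or 'local'")
    alpha = np.zeros_like(A)
    ok = np.abs(denom) >= eps
    np.divide(d2, denom, out=alpha, where=ok)
    alpha[~ok] = 0.0
    return alpha


def alpha_coefficients(
    functional: ActivationFunctional,
    route: str = "exact",
    eps: float = 1e-8,
    third_term: str = "global",
    fd_step: float = 1e-3,
) -> np.ndarray:
    """Alpha coefficients of a scalar activation functional, by chosen route."""
    A = functional.activations
    g = functional.gradient(A)
    if route == "exact":
        d2 = functional.diag_second(A)
        d3 = functional.diag_third(A)
    elif route == "power":
        d2, d3 = g * g, g * g * g
    elif route == "finite_difference":
        d2 = fd_diag_derivative(functional.value, A, 2, fd_step)
        d3 = fd_diag_derivative(functional.value, A, 3, fd_step)
    else:
        raise ValueError(f"route must be one of {ROUTES}")
    return alpha_from_derivatives(A, d2, d3, eps=eps, third_term=third_term)


def _upsample_to(values: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Linear upsampling of a heatmap to the input grid (identity when equal)."""
    if values.shape == tuple(shape):
        return values
    factors = [t / s for t, s in zip(shape, values.shape)]
    out = ndimage.zoom(values, factors, order=1, grid_mode=True, mode="nearest")
    # zoom with order=1 cannot overshoot, but guard against -0.0 noise
    return np.maximum(out, 0.0)


def _heatmap(model, x, layer, weights, mode, label, route, eps, third_term, per_voxel):
    sub = model.layer_subnetwork(model._check_input(x.data), layer)
    func = ActivationFunctional(sub, weights)
    A = sub.activations
    g = func.gradient(A)
    alpha = alpha_coefficients(func, route=route, eps=eps, third_term=third_term)
    rect = np.maximum(g, 0.0)
    if per_voxel:
        omega_w = alpha * rect                      # one weight per element
        combined = (omega_w * A).sum(axis=0)
    else:
        spatial_axes = tuple(range(1, A.ndim))
        omega_w = (alpha * rect).sum(axis=spatial_axes)  # one weight per map
        combined = np.tensordot(omega_w, A, axes=([0], [0]))
    values = _upsample_to(np.maximum(combined, 0.0), x.shape)
    return Heatmap(values=values, mode=mode, layer=layer, instance_label=label,
                   route=route, third_term=third_term)


def gradcam_class_map(
    model: SegmentationModel,
    x: Volume,
    layer: str,
    threshold: float = 0.3,
    route: str = "exact",
    eps: float = 1e-8,
    third_term: str = "global",
) -> Heatmap:
    """Class-level Grad-CAM++ heatmap: one weight per activation map.

    Merges the contributions of every predicted instance of the class into a
    single heatmap.
    """
    y = model.forward(x, threshold=threshold)
    weights = (y.values > threshold).astype(float)
    if not weights.any():
        warnings.warn("no logit exceeds the threshold; heatmap is zero", stacklevel=2)
        return Heatmap(values=np.zeros(x.shape), mode="class", layer=layer,
                       route=route, third_term=third_term)
    return _heatmap(model, x, layer, weights, "class", None, route, eps,
                    third_term, per_voxel=False)


def gradcam_instance_map(
    model: SegmentationModel,
    x: Volume,
    layer: str,
    omega: InstanceMask,
    route: str = "exact",
    eps: float = 1e-8,
    third_term: str = "global",
) -> Heatmap:
    """Instance-level Grad-CAM++ heatmap for one lesion domain.

    ``y'`` sums the logits over Omega only, and the per-element weights keep
    the explanation from lighting up other instances.
    """
    require_nonempty(omega, "lesion")
    if omega.shape != x.shape:
        raise ValueError("instance grid does not match the volume")
    weights = np.zeros(x.shape)
    weights[omega.index] = 1.0
    return _heatmap(model, x, layer, weights, "instance", omega.label, route,
                    eps, third_term, per_voxel=True)
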