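"""Decoding hidden membrane potentials as local label predictions.

A layer fitted against targets ``z_tilde = g(aQ) + g(yU)`` stores label
information additively in its potentials.  Inverting the construction on
the *realised* potentials ``z = aW`` gives a local label estimate without
any downstream computation:

    y_hat_l = g_inv(z - g(a @ Q)) @ U_pinv

where ``g_inv`` is the (surrogate) inverse of the target nonlinearity —
tanh when ``g`` is the sign function.  If the ridge fit were exact
(z = z_tilde) and ``g`` invertible this recovers ``y U U_pinv = y``
exactly; in practice the decoding degrades with the layer's training
residual, which is therefore carried on every explanation as a
reliability measure.

For convolutional layers the decoding is applied per receptive field,
yielding a label-score map over spatial positions that can be projected
back to input coordinates as a saliency map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .layers import FPConvLayer, FPDenseLayer, extract_patches

__all__ = [
    "LayerExplanation",
    "explain_layer",
    "saliency_map",
    "localization_score",
    "explanation_accuracy",
]

#: training residual above which explanations are flagged unreliable
DEFAULT_RELIABILITY_THRESHOLD = 0.9


@dataclass
class LayerExplanation:
    """Per-sample label scores decoded from one hidden layer.

    ``values`` has shape (B, m_L) for dense layers and (B, *spatial, m_L)
    for convolutional layers, where the spatial grid matches the layer's
    output.  ``reliability`` is the layer's relative training residual;
    ``low_reliability`` flags residuals above the configured threshold.
    ``centers`` (conv only) holds, per spatial axis, the input-coordinate
    centre of each output position's receptive field.
    """

    layer_index: int
    values: np.ndarray
    reliability: float
    low_reliability: bool
    spatial_shape: tuple[int, ...] | None = None
    centers: tuple[np.ndarray, ...] | None = None

    @property
    def is_spatial(self) -> bool:
        return self.spatial_shape is not None


def _layer_out_spatial(layer: FPConvLayer, in_spatial: tuple[int, ...]) -> tuple[int, ...]:
    import math

    out = []
    for s, k in zip(in_spatial, layer.spec.kernel_tuple):
        if layer.spec.padding == "same":
            out.append(math.ceil(s / layer.spec.stride))
        else:
            out.append((s - k) // layer.spec.stride + 1)
    return tuple(out)


def _receptive_centers(layers, layer_index: int, input_spatial: tuple[int, ...]):
    """Input-coordinate centres of layer ``layer_index``'s output positions.

    Walks the conv geometry forward to get each layer's spatial extents,
    then maps output grid indices back through stride/kernel/padding:
    position i of a layer with stride s, kernel k and left padding p sits
    at coordinate i*s + (k-1)/2 - p of its own input.
    """
    spatials = [tuple(input_spatial)]
    for layer in layers[: layer_index + 1]:
        spatials.append(_layer_out_spatial(layer, spatials[-1]))

    n_axes = len(input_spatial)
    coords = [np.arange(spatials[layer_index + 1][a], dtype=np.float64) for a in range(n_axes)]
    for j in range(layer_index, -1, -1):
        layer = layers[j]
        for a in range(n_axes):
            k = layer.spec.kernel_tuple[a]
            s = layer.spec.stride
            if layer.spec.padding == "same":
                from .layers import _same_padding

                pad_left, _ = _same_padding(spatials[j][a], k, s)
            else:
                pad_left = 0
            coords[a] = coords[a] * s + (k - 1) / 2.0 - pad_left
    return tuple(coords)


def explain_layer(
    model,
    l: int,
    x: np.ndarray,
    reliability_threshold: float = DEFAULT_RELIABILITY_THRESHOLD,
) -> LayerExplanation:
    """Decode hidden layer ``l`` (0-based) of a fitted model on batch ``x``.

    Requires the layer to have been fitted in ``fp`` mode (the projection
    pair is part of the decoding).  Returns dense scores (B, m_L) or a
    conv label-score map (B, *spatial, m_L).
    """
    layers = model.layers_
    if not 0 <= l < len(layers):
        raise IndexError(f"layer index {l} out of range for {len(layers)} hidden layers")
    layer = layers[l]
    if not layer.fitted:
        raise RuntimeError("layer is not fitted")
    if layer.fit_mode != "fp":
        raise ValueError(
            f"layer {l} was fitted in mode {layer.fit_mode!r}; explanations "
            "require the fp target construction"
        )
    a = model.hidden_activations(x, l)
    g = layer.g
    reliability = float(layer.train_residual)
    low = reliability > reliability_threshold

    if isinstance(layer, FPDenseLayer):
        z = a @ layer.W
        decoded = g.inverse(z - g(a @ layer.pair.Q)) @ layer.pair.U_pinv
        return LayerExplanation(l, decoded, reliability, low)

    pm = extract_patches(a, layer.spec)
    z_rows = pm.rows @ layer.W
    decoded = g.inverse(z_rows - g(pm.rows @ layer.pair.Q)) @ layer.pair.U_pinv
    decoded = decoded.reshape(pm.batch, *pm.out_shape, decoded.shape[-1])
    centers = _receptive_centers(layers, l, model.input_shape_[1:])
    return LayerExplanation(
        l, decoded, reliability, low, spatial_shape=pm.out_shape, centers=centers
    )


def _nearest_index(centers: np.ndarray, n_out: int) -> np.ndarray:
    """For each of ``n_out`` input coordinates, the nearest centre index."""
    targets = np.arange(n_out, dtype=np.float64)
    idx = np.searchsorted(centers, targets)
    idx = np.clip(idx, 1, len(centers) - 1) if len(centers) > 1 else np.zeros(n_out, int)
    if len(centers) > 1:
        left = centers[idx - 1]
        right = centers[idx]
        idx = idx - (targets - left <= right - targets)
    return np.asarray(idx, dtype=int)


def saliency_map(
    expl: LayerExplanation,
    class_index: int,
    spatial_shape: tuple[int, ...],
    rescale: bool = False,
) -> np.ndarray:
    """Project a conv-layer explanation to input coordinates.

    Selects the ``class_index`` score at every position and upsamples to
    ``spatial_shape`` by nearest-receptive-field-centre assignment.  With
    ``rescale=True`` each sample's map is min-max scaled to [0, 1]
    (visualisation only — rescaled maps are not comparable across
    samples).  Maps of several seeded models may be ensemble-averaged
    element-wise.
    """
    if not expl.is_spatial:
        raise ValueError("saliency maps require a convolutional layer explanation")
    spatial_shape = tuple(spatial_shape)
    if len(spatial_shape) != len(expl.spatial_shape):
        raise ValueError("spatial_shape dimensionality does not match the explanation")
    values = expl.values[..., class_index]  # (B, *out_shape)
    for axis, n_out in enumerate(spatial_shape):
        idx = _nearest_index(expl.centers[axis], n_out)
        values = np.take(values, idx, axis=1 + axis)
    if rescale:
        flat = values.reshape(values.shape[0], -1)
        lo = flat.min(axis=1, keepdims=True)
        hi = flat.max(axis=1, keepdims=True)
        span = np.where(hi > lo, hi - lo, 1.0)
        values = ((flat - lo) / span).reshape(values.shape)
    return values


def localization_score(heat_map: np.ndarray, mask: np.ndarray) -> dict:
    """Rank the map's positions against a binary ground-truth region.

    Positions are treated as instances and the mask as their labels;
    returns the ranking AUC (average-rank tie handling) and the area
    under the precision-recall curve.
    """
    heat_map = np.asarray(heat_map, dtype=np.float64).ravel()
    mask = np.asarray(mask).ravel().astype(bool)
    if heat_map.shape != mask.shape:
        raise ValueError("map and mask must have the same spatial shape")
    if not mask.any() or mask.all():
        raise ValueError("mask is degenerate (empty or full); metrics undefined")
    return {
        "auc": float(roc_auc_score(mask, heat_map)),
        "aupr": float(average_precision_score(mask, heat_map)),
    }


def explanation_accuracy(model, l: int, x: np.ndarray, y) -> float:
    """Argmax accuracy of layer ``l``'s decoded label predictions.

    Conv explanations are averaged over spatial positions before the
    argmax."""
    from .model import _coerce_labels

    labels, _ = _coerce_labels(y)
    expl = explain_layer(model, l, x)
    values = expl.values
    if expl.is_spatial:
        values = values.reshape(values.shape[0], -1, values.shape[-1]).mean(axis=1)
    pred = model.classes_[np.argmax(values, axis=1)]
    return float(np.mean(pred == labels))
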