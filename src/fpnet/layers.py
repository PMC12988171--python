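"""Dense and convolutional layers fitted in closed form.

A dense layer holds weights ``W`` mapping pre-synaptic activations to
membrane potentials ``z = a @ W`` and an element-wise activation ``f``.
Fitting streams the data once: per batch, target potentials are generated
from the layer's fixed projection pair and accumulated into ridge
sufficient statistics; a single solve at the end of the stream yields
``W``.  A convolutional layer is realised as the same dense regression
applied to im2col patch rows — every receptive field becomes one
regression row and inherits its sample's label — so closed-form fitting
carries over unchanged, and the learned row weights reshape into filters.

The relative training residual ``||Z - Z_tilde|| / ||Z_tilde||`` is
recorded at fit time (second streaming pass) as a reliability measure for
downstream interpretation: when it is large, decoding potentials as label
predictions is unreliable.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Iterable, Iterator

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from . import _macs
from .linear_solver import RidgeAccumulator, RidgePenalty
from .targets import (
    Nonlinearity,
    ProjectionPair,
    TargetMode,
    derive_seed,
    get_nonlinearity,
    make_projection_pair,
    target_potentials,
)

__all__ = [
    "ConvSpec",
    "PatchMatrix",
    "FPDenseLayer",
    "FPConvLayer",
    "extract_patches",
    "fit_dense",
    "fit_conv",
    "global_avg_pool",
]


def _as_nl(x) -> Nonlinearity:
    return x if isinstance(x, Nonlinearity) else get_nonlinearity(x)


@dataclass(frozen=True)
class ConvSpec:
    """Geometry of one convolutional layer.

    ``kernel`` is an int (1-D) or an (kh, kw) pair (2-D); ``padding`` is
    'valid' (no padding) or 'same' (zero padding chosen so the output
    length is ceil(L/stride), symmetric with the extra zero on the
    trailing side).
    """

    n_filters: int
    kernel: int | tuple[int, int]
    stride: int = 1
    padding: str = "valid"

    def __post_init__(self) -> None:
        if self.n_filters < 1:
            raise ValueError("n_filters must be >= 1")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.padding not in ("valid", "same"):
            raise ValueError(f"unknown padding {self.padding!r}")

    @property
    def kernel_tuple(self) -> tuple[int, ...]:
        if isinstance(self.kernel, int):
            return (self.kernel,)
        return tuple(self.kernel)

    @property
    def ndim(self) -> int:
        return len(self.kernel_tuple)


@dataclass
class PatchMatrix:
    """im2col view of a batch: one row per receptive field.

    Rows are channel-major flattenings (channel index slowest, then raster
    order within the window).  ``sample_index`` / ``position_index`` give
    each row's provenance; ``out_shape`` is the spatial grid of positions
    per sample, enumerated in raster order.
    """

    rows: np.ndarray
    sample_index: np.ndarray
    position_index: np.ndarray
    out_shape: tuple[int, ...]
    batch: int

    @property
    def positions_per_sample(self) -> int:
        return int(np.prod(self.out_shape))


def _same_padding(length: int, kernel: int, stride: int) -> tuple[int, int]:
    out = math.ceil(length / stride)
    total = max((out - 1) * stride + kernel - length, 0)
    return total // 2, total - total // 2


def extract_patches(x: np.ndarray, spec: ConvSpec) -> PatchMatrix:
    """Enumerate receptive fields of ``x`` as regression rows.

    ``x`` is (B, C, L) for 1-D convolution or (B, C, H, W) for 2-D.
    Positions are 0-based and raster ordered; 'same' padding inserts
    symmetric zeros.
    """
    x = np.asarray(x, dtype=np.float64)
    kernel = spec.kernel_tuple
    if x.ndim != 2 + len(kernel):
        raise ValueError(
            f"input has {x.ndim} axes but kernel is {len(kernel)}-dimensional; "
            "expected (B, C, spatial...)"
        )
    b, c = x.shape[0], x.shape[1]
    spatial = x.shape[2:]
    if spec.padding == "same":
        pads = [(0, 0), (0, 0)] + [
            _same_padding(s, k, spec.stride) for s, k in zip(spatial, kernel)
        ]
        x = np.pad(x, pads)
        spatial = x.shape[2:]
    for s, k in zip(spatial, kernel):
        if s < k:
            raise ValueError(f"kernel {k} larger than (padded) spatial extent {s}")

    if len(kernel) == 1:
        (k,) = kernel
        windows = sliding_window_view(x, k, axis=2)[:, :, :: spec.stride, :]
        # (B, C, P, k) -> (B, P, C, k)
        windows = windows.transpose(0, 2, 1, 3)
        out_shape = (windows.shape[1],)
    else:
        kh, kw = kernel
        windows = sliding_window_view(x, (kh, kw), axis=(2, 3))
        windows = windows[:, :, :: spec.stride, :: spec.stride, :, :]
        # (B, C, Ph, Pw, kh, kw) -> (B, Ph, Pw, C, kh, kw)
        windows = windows.transpose(0, 2, 3, 1, 4, 5)
        out_shape = (windows.shape[1], windows.shape[2])

    p = int(np.prod(out_shape))
    rows = windows.reshape(b * p, c * int(np.prod(kernel)))
    return PatchMatrix(
        rows=np.ascontiguousarray(rows),
        sample_index=np.repeat(np.arange(b), p),
        position_index=np.tile(np.arange(p), b),
        out_shape=out_shape,
        batch=b,
    )


def global_avg_pool(x: np.ndarray) -> np.ndarray:
    """Average a (B, C, spatial...) tensor over all spatial axes -> (B, C)."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim < 3:
        raise ValueError("expected (B, C, spatial...) with at least one spatial axis")
    return x.mean(axis=tuple(range(2, x.ndim)))


BatchStream = Callable[[], Iterator[tuple[np.ndarray, np.ndarray]]]


def _as_stream(batches) -> BatchStream:
    if callable(batches):
        return batches
    batches = list(batches)
    return lambda: iter(batches)


class _FittableMixin:
    """Shared streaming fit machinery for dense and conv layers."""

    def _fit_rows(
        self,
        row_stream: BatchStream,
        penalty: RidgePenalty,
        mode: TargetMode,
        noise_seed: int,
    ) -> None:
        acc = RidgeAccumulator(self.m_in, self.m_out)
        n_batches = 0
        for i, (rows, labels) in enumerate(row_stream()):
            zt = target_potentials(
                rows, labels, self.pair, self.g, mode,
                noise_seed=derive_seed(noise_seed, i),
            )
            acc.update(rows, zt)
            n_batches += 1
        if acc.n_seen == 0:
            raise ValueError("cannot fit: the training stream is empty")
        self.W = acc.solve(penalty)
        # second streaming pass: exact relative residual ||Z - Zt||/||Zt||
        num = 0.0
        den = 0.0
        for i, (rows, labels) in enumerate(row_stream()):
            zt = target_potentials(
                rows, labels, self.pair, self.g, mode,
                noise_seed=derive_seed(noise_seed, i),
            )
            z = rows @ self.W
            num += float(np.sum((z - zt) ** 2))
            den += float(np.sum(zt**2))
        self.train_residual = math.sqrt(num) / math.sqrt(den) if den > 0 else math.inf
        self.fit_mode = mode.mode if isinstance(mode, TargetMode) else mode
        self.fitted = True


class FPDenseLayer(_FittableMixin):
    """A fully connected layer with closed-form feedback-free fitting."""

    def __init__(
        self,
        m_in: int,
        m_out: int,
        m_label: int,
        f: Nonlinearity | str = "relu",
        g: Nonlinearity | str = "sign",
        seed: int = 0,
        pair: ProjectionPair | None = None,
    ) -> None:
        self.m_in = int(m_in)
        self.m_out = int(m_out)
        self.m_label = int(m_label)
        self.f = _as_nl(f)
        self.g = _as_nl(g)
        self.seed = int(seed)
        self.pair = pair if pair is not None else make_projection_pair(
            m_in, m_out, m_label, seed
        )
        self.W: np.ndarray | None = None
        self.fitted = False
        self.fit_mode: str | None = None
        self.train_residual: float | None = None

    def set_random_weights(self, seed: int | None = None) -> "FPDenseLayer":
        """Install fixed Gaussian weights (random-features baseline)."""
        rng = np.random.default_rng(self.seed if seed is None else seed)
        self.W = rng.normal(0.0, 1.0 / math.sqrt(self.m_in), (self.m_in, self.m_out))
        self.fitted = True
        self.fit_mode = "rf"
        self.train_residual = math.inf
        return self

    def fit(
        self,
        batches,
        penalty: RidgePenalty = RidgePenalty(),
        mode: TargetMode | str = "fp",
        noise_seed: int = 0,
    ) -> "FPDenseLayer":
        """Fit from a (re-iterable) stream of (pre_acts, one_hot_labels)."""
        if self.fitted:
            raise RuntimeError("layer is already fitted")
        if isinstance(mode, str):
            mode = TargetMode(mode, 1.0 if mode == "noisy_label_projection" else 0.0)
        self._fit_rows(_as_stream(batches), penalty, mode, noise_seed)
        return self

    def potentials(self, a: np.ndarray) -> np.ndarray:
        """Membrane potentials z = a @ W (pre-activation)."""
        if not self.fitted:
            raise RuntimeError("layer is not fitted")
        a = np.asarray(a, dtype=np.float64)
        if a.shape[1] != self.m_in:
            raise ValueError(f"input has {a.shape[1]} features, expected {self.m_in}")
        _macs.record_matmul("forward", a.shape[0], self.m_in, self.m_out)
        return a @ self.W

    def forward(self, a: np.ndarray) -> np.ndarray:
        return self.f(self.potentials(a))


class FPConvLayer(_FittableMixin):
    """A convolutional layer fitted as patch-wise dense regression.

    Every receptive field of every sample is one regression row; the
    sample's one-hot label is broadcast to all of its positions.  The
    solved row weights (patch_dim x n_filters) are the flattened kernels.
    ``subsample`` optionally keeps a seeded uniform fraction of positions
    per batch during fitting (bounds patch-row counts on large inputs;
    forward passes always use every position).
    """

    def __init__(
        self,
        in_channels: int,
        spec: ConvSpec,
        m_label: int,
        f: Nonlinearity | str = "relu",
        g: Nonlinearity | str = "sign",
        seed: int = 0,
        subsample: float | None = None,
    ) -> None:
        self.in_channels = int(in_channels)
        self.spec = spec
        self.m_label = int(m_label)
        self.m_in = in_channels * int(np.prod(spec.kernel_tuple))
        self.m_out = spec.n_filters
        self.f = _as_nl(f)
        self.g = _as_nl(g)
        self.seed = int(seed)
        self.subsample = subsample
        self.pair = make_projection_pair(self.m_in, self.m_out, m_label, seed)
        self.W: np.ndarray | None = None
        self.fitted = False
        self.fit_mode: str | None = None
        self.train_residual: float | None = None

    def set_random_weights(self, seed: int | None = None) -> "FPConvLayer":
        rng = np.random.default_rng(self.seed if seed is None else seed)
        self.W = rng.normal(0.0, 1.0 / math.sqrt(self.m_in), (self.m_in, self.m_out))
        self.fitted = True
        self.fit_mode = "rf"
        self.train_residual = math.inf
        return self

    def _patch_row_stream(self, batches: BatchStream) -> BatchStream:
        def stream() -> Iterator[tuple[np.ndarray, np.ndarray]]:
            for i, (x, labels) in enumerate(batches()):
                pm = extract_patches(x, self.spec)
                rows = pm.rows
                row_labels = np.asarray(labels, dtype=np.float64)[pm.sample_index]
                if self.subsample is not None and self.subsample < 1.0:
                    rng = np.random.default_rng(derive_seed(self.seed, 1000 + i))
                    keep = rng.random(rows.shape[0]) < self.subsample
                    rows, row_labels = rows[keep], row_labels[keep]
                yield rows, row_labels

        return stream

    def fit(
        self,
        batches,
        penalty: RidgePenalty = RidgePenalty(),
        mode: TargetMode | str = "fp",
        noise_seed: int = 0,
    ) -> "FPConvLayer":
        """Fit from a (re-iterable) stream of (x, one_hot_labels) with
        x shaped (B, C, L) or (B, C, H, W)."""
        if self.fitted:
            raise RuntimeError("layer is already fitted")
        if isinstance(mode, str):
            mode = TargetMode(mode, 1.0 if mode == "noisy_label_projection" else 0.0)
        self._fit_rows(self._patch_row_stream(_as_stream(batches)), penalty, mode, noise_seed)
        return self

    def potentials(self, x: np.ndarray) -> np.ndarray:
        """Membrane potentials as a (B, n_filters, spatial...) map."""
        if not self.fitted:
            raise RuntimeError("layer is not fitted")
        pm = extract_patches(x, self.spec)
        _macs.record_matmul("forward", pm.rows.shape[0], self.m_in, self.m_out)
        z = pm.rows @ self.W  # (B*P, F)
        z = z.reshape(pm.batch, *pm.out_shape, self.m_out)
        # move filter axis to channel position
        return np.moveaxis(z, -1, 1)

    def forward(self, x: np.ndarray) -> np.ndarray:
        return self.f(self.potentials(x))

    @property
    def filters(self) -> np.ndarray:
        """Kernels as (n_filters, in_channels, kernel...)."""
        if not self.fitted:
            raise RuntimeError("layer is not fitted")
        return self.W.T.reshape(self.m_out, self.in_channels, *self.spec.kernel_tuple)


def fit_dense(layer: FPDenseLayer, pre_acts_stream, labels_stream=None, penalty=RidgePenalty(), mode="fp", noise_seed=0):
    """Functional wrapper: fit a dense layer from streams.

    ``pre_acts_stream`` may already be a stream of (pre_acts, labels)
    pairs; if ``labels_stream`` is given separately the two are zipped.
    """
    if labels_stream is not None:
        a_batches = list(pre_acts_stream() if callable(pre_acts_stream) else pre_acts_stream)
        y_batches = list(labels_stream() if callable(labels_stream) else labels_stream)
        batches = list(zip(a_batches, y_batches))
    else:
        batches = pre_acts_stream
    return layer.fit(batches, penalty=penalty, mode=mode, noise_seed=noise_seed)


def fit_conv(layer: FPConvLayer, input_stream, labels_stream=None, penalty=RidgePenalty(), mode="fp", noise_seed=0):
    """Functional wrapper: fit a conv layer from streams (see fit_dense)."""
    if labels_stream is not None:
        x_batches = list(input_stream() if callable(input_stream) else input_stream)
        y_batches = list(labels_stream() if callable(labels_stream) else labels_stream)
        batches = list(zip(x_batches, y_batches))
    else:
        batches = input_stream
    return layer.fit(batches, penalty=penalty, mode=mode, noise_seed=noise_seed)
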