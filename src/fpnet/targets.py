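"""Random-projection target generation for feedback-free layer fitting.

Each hidden layer gets a pair of fixed Gaussian projection matrices drawn
before training: ``Q`` (m_in x m_out) projects pre-synaptic activity and
``U`` (m_label x m_out) projects the one-hot label.  The layer's target
membrane potential is

    z_tilde = g(a @ Q) + g(y @ U)

with ``g`` an element-wise nonlinearity (the sign function by default).
Because the target mixes a random encoding of the inputs with a random
encoding of the label, hidden potentials jointly encode both — the input
term prevents the representation from collapsing onto the (rank-limited)
label subspace, and the label term is what makes hidden potentials
decodable as local label predictions through the pseudo-inverse of ``U``.

Two degraded target modes are provided as baselines: plain label
projection ``z_tilde = y @ U`` (rank-limited by the label dimension) and
label projection plus Gaussian noise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from . import _macs

__all__ = [
    "Nonlinearity",
    "ProjectionPair",
    "TargetMode",
    "get_nonlinearity",
    "make_projection_pair",
    "target_potentials",
    "target_rank_ceiling",
    "derive_seed",
]

_ARTANH_CLIP = 1.0 - 1e-7


def _artanh_clipped(x: np.ndarray) -> np.ndarray:
    return np.arctanh(np.clip(x, -_ARTANH_CLIP, _ARTANH_CLIP))


@dataclass(frozen=True)
class Nonlinearity:
    """An element-wise nonlinearity with a (surrogate) inverse.

    The forward map is total on finite reals.  ``surrogate_inverse`` is the
    function used to undo ``g`` when decoding hidden potentials as label
    predictions; for non-invertible ``g`` it is a smooth stand-in (tanh for
    sign), for invertible ``g`` it is the true inverse (clipped artanh for
    tanh).
    """

    name: str
    func: Callable[[np.ndarray], np.ndarray]
    surrogate_inverse: Callable[[np.ndarray], np.ndarray]
    surrogate_inverse_name: str
    params: dict = field(default_factory=dict)

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.func(np.asarray(x, dtype=np.float64))

    def inverse(self, x: np.ndarray) -> np.ndarray:
        return self.surrogate_inverse(np.asarray(x, dtype=np.float64))


def get_nonlinearity(name: str, **params) -> Nonlinearity:
    """Build a named nonlinearity.

    Supported names: ``sign`` (sign(0)=0; surrogate inverse tanh),
    ``tanh`` (inverse: clipped artanh), ``identity``, ``relu``
    (surrogate inverse: identity), ``modulo`` (param ``period``; surrogate
    inverse: identity), ``polynomial`` (param ``coefficients``, highest
    degree first as in numpy.polyval; surrogate inverse: identity).
    """
    if name == "sign":
        return Nonlinearity("sign", np.sign, np.tanh, "tanh")
    if name == "tanh":
        return Nonlinearity("tanh", np.tanh, _artanh_clipped, "artanh")
    if name == "identity":
        ident = lambda x: x  # noqa: E731
        return Nonlinearity("identity", ident, ident, "identity")
    if name == "relu":
        relu = lambda x: np.maximum(x, 0.0)  # noqa: E731
        return Nonlinearity("relu", relu, lambda x: x, "identity")
    if name == "modulo":
        period = float(params.get("period", 2.0))
        if period <= 0:
            raise ValueError("modulo period must be positive")
        return Nonlinearity(
            "modulo",
            lambda x: np.mod(x, period),
            lambda x: x,
            "identity",
            {"period": period},
        )
    if name == "polynomial":
        coeffs = tuple(params.get("coefficients", (1.0, 0.0, 0.0)))
        return Nonlinearity(
            "polynomial",
            lambda x: np.polyval(coeffs, x),
            lambda x: x,
            "identity",
            {"coefficients": coeffs},
        )
    raise ValueError(f"unknown nonlinearity {name!r}")


def _as_nonlinearity(g) -> Nonlinearity:
    return g if isinstance(g, Nonlinearity) else get_nonlinearity(g)


@dataclass(frozen=True)
class TargetMode:
    """Which target generator a layer is fitted against.

    ``fp`` is the full input-plus-label construction; ``label_projection``
    and ``noisy_label_projection`` are the degraded baselines.  ``noise_sd``
    is the standard deviation of the additive Gaussian term and is only
    meaningful for the noisy mode.
    """

    mode: str = "fp"
    noise_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.mode not in ("fp", "label_projection", "noisy_label_projection"):
            raise ValueError(f"unknown target mode {self.mode!r}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        if self.mode != "noisy_label_projection" and self.noise_sd != 0:
            raise ValueError("noise_sd must be 0 unless mode is noisy_label_projection")


@dataclass(frozen=True)
class ProjectionPair:
    """Fixed random projections defining one layer's target generator.

    ``Q`` (m_in x m_out) and ``U`` (m_label x m_out) have i.i.d. zero-mean
    Gaussian entries with standard deviations ``scale_q`` and ``scale_u``,
    fully determined by ``seed``.  ``U_pinv`` is the cached Moore-Penrose
    pseudo-inverse of ``U`` used to decode potentials back to label space.
    """

    Q: np.ndarray
    U: np.ndarray
    U_pinv: np.ndarray
    seed: int
    scale_q: float
    scale_u: float

    @property
    def m_in(self) -> int:
        return self.Q.shape[0]

    @property
    def m_out(self) -> int:
        return self.Q.shape[1]

    @property
    def m_label(self) -> int:
        return self.U.shape[0]


def make_projection_pair(
    m_in: int,
    m_out: int,
    m_label: int,
    seed: int,
    scale_q: float | None = None,
    scale_u: float | None = None,
) -> ProjectionPair:
    """Draw the fixed (Q, U) projection pair for one layer.

    Scales default to fan-in normalisation (1/sqrt(m_in) and
    1/sqrt(m_label)), keeping pre-nonlinearity magnitudes O(1); under
    ``g=sign`` the scale is immaterial.  Deterministic in ``seed``.
    """
    for nm, d in (("m_in", m_in), ("m_out", m_out), ("m_label", m_label)):
        if d < 1:
            raise ValueError(f"{nm} must be >= 1, got {d}")
    if scale_q is None:
        scale_q = 1.0 / math.sqrt(m_in)
    if scale_u is None:
        scale_u = 1.0 / math.sqrt(m_label)
    rng = np.random.default_rng(seed)
    q = rng.normal(0.0, scale_q, size=(m_in, m_out))
    u = rng.normal(0.0, scale_u, size=(m_label, m_out))
    return ProjectionPair(
        Q=q, U=u, U_pinv=np.linalg.pinv(u), seed=int(seed),
        scale_q=float(scale_q), scale_u=float(scale_u),
    )


def validate_one_hot(labels: np.ndarray) -> None:
    """Raise if any row of ``labels`` is not one-hot in {0,1} (all-zero rows
    are rejected too), listing the offending row indices."""
    labels = np.asarray(labels)
    is_binary = np.all((labels == 0) | (labels == 1), axis=1)
    sums_to_one = labels.sum(axis=1) == 1
    bad = np.nonzero(~(is_binary & sums_to_one))[0]
    if bad.size:
        raise ValueError(f"rows are not valid one-hot labels: {bad.tolist()}")


def target_potentials(
    pre_acts: np.ndarray,
    labels: np.ndarray,
    pair: ProjectionPair,
    g: Nonlinearity | str = "sign",
    mode: TargetMode | str = "fp",
    noise_seed: int = 0,
) -> np.ndarray:
    """Generate target membrane potentials for one batch.

    Returns a (B, m_out) array: ``g(a @ Q) + g(y @ U)`` in ``fp`` mode,
    ``y @ U`` for label projection, and ``y @ U + E`` with
    ``E ~ N(0, noise_sd^2)`` (seeded by ``noise_seed``) for noisy label
    projection.
    """
    g = _as_nonlinearity(g)
    if isinstance(mode, str):
        mode = TargetMode(mode, noise_sd=1.0 if mode == "noisy_label_projection" else 0.0)
    pre_acts = np.asarray(pre_acts, dtype=np.float64)
    labels = np.asarray(labels, dtype=np.float64)
    if pre_acts.shape[0] != labels.shape[0]:
        raise ValueError(
            f"row count mismatch: pre_acts {pre_acts.shape[0]} vs labels {labels.shape[0]}"
        )
    if pre_acts.shape[1] != pair.m_in:
        raise ValueError(f"pre_acts have {pre_acts.shape[1]} columns, expected {pair.m_in}")
    if labels.shape[1] != pair.m_label:
        raise ValueError(f"labels have {labels.shape[1]} columns, expected {pair.m_label}")
    validate_one_hot(labels)

    b = pre_acts.shape[0]
    label_term = labels @ pair.U
    _macs.record_matmul("target", b, pair.m_label, pair.m_out)
    if mode.mode == "fp":
        input_term = pre_acts @ pair.Q
        _macs.record_matmul("target", b, pair.m_in, pair.m_out)
        return g(input_term) + g(label_term)
    if mode.mode == "label_projection":
        return label_term
    noise = np.random.default_rng(noise_seed).normal(
        0.0, mode.noise_sd, size=label_term.shape
    )
    return label_term + noise


def target_rank_ceiling(mode: TargetMode | str, m_label: int) -> float:
    """Upper bound on the rank of the target matrix a mode can produce.

    Plain label projection targets ``Y @ U`` have rank at most ``m_label``
    (the informational-collapse mechanism); the fp and noisy modes are
    unbounded (returned as ``inf``) because the input/noise term breaks
    the ceiling.
    """
    mode_name = mode.mode if isinstance(mode, TargetMode) else mode
    if mode_name == "label_projection":
        return float(m_label)
    return math.inf


def derive_seed(root_seed: int, *indices: int) -> int:
    """Derive a per-component seed from a root seed and a counter path.

    Counter-based: hashes ``(root_seed, *indices)`` through SeedSequence so
    a whole model is reproducible from one integer with independent
    per-layer streams.
    """
    ss = np.random.SeedSequence([int(root_seed), *[int(i) for i in indices]])
    return int(ss.generate_state(1, dtype=np.uint32)[0])
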