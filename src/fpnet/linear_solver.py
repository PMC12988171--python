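"""Streaming closed-form ridge regression.

A layer's weights are the one-step ridge solution

    W = (A^T A + lam I)^(-1) (A^T Z)

where ``A`` stacks pre-synaptic activations over the training set and ``Z``
stacks the regression targets.  Both sufficient statistics ``A^T A`` (Gram)
and ``A^T Z`` (cross-moment) are plain sums over rows, so they can be
accumulated batch by batch in fixed memory: the accumulator's footprint
depends only on the layer widths, never on the number of samples seen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy import linalg

from . import _macs

__all__ = ["RidgeAccumulator", "RidgePenalty", "accumulate", "solve", "merge"]

#: condition-number threshold above which an unpenalised solve is refused
_COND_LIMIT = 1e12


@dataclass(frozen=True)
class RidgePenalty:
    """Ridge regularisation strength.

    Parameters
    ----------
    lam : float
        Nonnegative penalty weight.
    mode : {"trace_scaled", "absolute"}
        ``absolute`` uses ``lam`` directly.  ``trace_scaled`` resolves the
        effective penalty at solve time as ``lam * trace(gram) / m_in``,
        which adapts the penalty to the scale of the accumulated
        activations (the mean squared activation energy per input unit).
    """

    lam: float = 1e-2
    mode: str = "trace_scaled"

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError(f"lam must be nonnegative, got {self.lam}")
        if self.mode not in ("absolute", "trace_scaled"):
            raise ValueError(f"unknown penalty mode {self.mode!r}")

    def effective(self, gram: np.ndarray) -> float:
        if self.mode == "absolute":
            return float(self.lam)
        m_in = gram.shape[0]
        return float(self.lam) * float(np.trace(gram)) / m_in


class RidgeAccumulator:
    """Running sufficient statistics for the closed-form ridge solve.

    Holds ``gram = A^T A`` (m_in x m_in), ``cross = A^T Z`` (m_in x m_out)
    and the row count ``n_seen``.  Accumulation order is immaterial: any
    partition of the rows into batches yields the same statistics.
    Statistics are kept in float64 regardless of input dtype, so long
    streams do not lose precision to single-precision summation.
    """

    def __init__(self, m_in: int, m_out: int) -> None:
        if m_in < 1 or m_out < 1:
            raise ValueError(f"dimensions must be >= 1, got ({m_in}, {m_out})")
        self.m_in = int(m_in)
        self.m_out = int(m_out)
        self.gram = np.zeros((m_in, m_in), dtype=np.float64)
        self.cross = np.zeros((m_in, m_out), dtype=np.float64)
        self.n_seen = 0

    def update(self, inputs: np.ndarray, targets: np.ndarray) -> "RidgeAccumulator":
        """Accumulate one batch of (inputs, targets) rows in place."""
        inputs = np.asarray(inputs, dtype=np.float64)
        targets = np.asarray(targets, dtype=np.float64)
        if inputs.ndim != 2 or targets.ndim != 2:
            raise ValueError("inputs and targets must be 2-D row batches")
        if inputs.shape[0] != targets.shape[0]:
            raise ValueError(
                f"row count mismatch on axis 0: inputs {inputs.shape[0]} "
                f"vs targets {targets.shape[0]}"
            )
        if inputs.shape[1] != self.m_in:
            raise ValueError(
                f"inputs axis 1 has {inputs.shape[1]} columns, expected {self.m_in}"
            )
        if targets.shape[1] != self.m_out:
            raise ValueError(
                f"targets axis 1 has {targets.shape[1]} columns, expected {self.m_out}"
            )
        if inputs.shape[0] == 0:
            return self
        if not np.all(np.isfinite(inputs)):
            raise ValueError("non-finite entries in inputs")
        if not np.all(np.isfinite(targets)):
            raise ValueError("non-finite entries in targets")
        b = inputs.shape[0]
        _macs.record_matmul("solve", self.m_in, b, self.m_in)
        _macs.record_matmul("solve", self.m_in, b, self.m_out)
        self.gram += inputs.T @ inputs
        self.cross += inputs.T @ targets
        self.n_seen += inputs.shape[0]
        return self

    def solve(self, penalty: RidgePenalty | float = RidgePenalty()) -> np.ndarray:
        """Return the ridge weight matrix for the accumulated data.

        Solves ``(gram + lam I) W = cross`` by Cholesky factorisation of the
        symmetrised penalised Gram matrix (it is SPD for lam > 0), falling
        back to an eigendecomposition solve if factorisation fails.  The
        explicit inverse is never formed.
        """
        if isinstance(penalty, (int, float)):
            penalty = RidgePenalty(lam=float(penalty), mode="absolute")
        if self.n_seen < 1:
            raise ValueError("cannot solve: no samples accumulated")
        lam = penalty.effective(self.gram)
        sym = 0.5 * (self.gram + self.gram.T)
        if lam == 0.0:
            cond = np.linalg.cond(sym)
            if not np.isfinite(cond) or cond > _COND_LIMIT:
                raise np.linalg.LinAlgError(
                    "gram matrix is numerically singular with lam=0 "
                    f"(condition estimate {cond:.3g}); use a positive penalty"
                )
        a = sym + lam * np.eye(self.m_in)
        # factorisation ~ m^3/3 plus two triangular solves per target column
        _macs.record("solve", self.m_in**3 // 3 + self.m_in**2 * self.m_out)
        try:
            c, low = linalg.cho_factor(a, check_finite=False)
            return linalg.cho_solve((c, low), self.cross, check_finite=False)
        except np.linalg.LinAlgError:
            pass
        except linalg.LinAlgError:
            pass
        # symmetric fallback: solve through the eigenbasis, clipping
        # nonpositive eigenvalues that arise from roundoff
        w, v = linalg.eigh(a)
        w = np.maximum(w, np.finfo(np.float64).eps * np.max(np.abs(w)))
        return v @ ((v.T @ self.cross) / w[:, None])

    def merge(self, other: "RidgeAccumulator") -> "RidgeAccumulator":
        """Return a new accumulator summing this one with ``other``."""
        if (other.m_in, other.m_out) != (self.m_in, self.m_out):
            raise ValueError(
                f"dimension mismatch: ({self.m_in},{self.m_out}) vs "
                f"({other.m_in},{other.m_out})"
            )
        out = RidgeAccumulator(self.m_in, self.m_out)
        out.gram = self.gram + other.gram
        out.cross = self.cross + other.cross
        out.n_seen = self.n_seen + other.n_seen
        return out

    # -- checkpointing -------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Checkpoint the accumulator to ``directory`` (two matrix files
        plus a JSON manifest)."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.save(directory / "gram.npy", self.gram)
        np.save(directory / "cross.npy", self.cross)
        manifest = {
            "kind": "ridge_accumulator",
            "m_in": self.m_in,
            "m_out": self.m_out,
            "n_seen": self.n_seen,
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "RidgeAccumulator":
        directory = Path(directory)
        manifest = json.loads((directory / "manifest.json").read_text())
        acc = cls(manifest["m_in"], manifest["m_out"])
        acc.gram = np.load(directory / "gram.npy")
        acc.cross = np.load(directory / "cross.npy")
        acc.n_seen = int(manifest["n_seen"])
        return acc

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"RidgeAccumulator(m_in={self.m_in}, m_out={self.m_out}, "
            f"n_seen={self.n_seen})"
        )


def accumulate(
    acc: RidgeAccumulator, inputs: np.ndarray, targets: np.ndarray
) -> RidgeAccumulator:
    """Functional wrapper over :meth:`RidgeAccumulator.update`."""
    return acc.update(inputs, targets)


def solve(
    acc: RidgeAccumulator, penalty: RidgePenalty | float = RidgePenalty()
) -> np.ndarray:
    """Functional wrapper over :meth:`RidgeAccumulator.solve`."""
    return acc.solve(penalty)


def merge(acc1: RidgeAccumulator, acc2: RidgeAccumulator) -> RidgeAccumulator:
    """Functional wrapper over :meth:`RidgeAccumulator.merge`."""
    return acc1.merge(acc2)
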