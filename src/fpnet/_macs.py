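"""Process-wide multiply-accumulate (MAC) instrumentation.

One MAC = one fused multiply-add.  Counting is off unless a
:class:`MacCounter` context is active; call sites in the fitting and
forward paths record the analytic MAC cost of each matrix product they
perform.  Nonlinearity evaluations are not counted.
"""

from __future__ import annotations

from contextlib import contextmanager

_ACTIVE: list["MacCounter"] = []


class MacCounter:
    """Accumulates MAC counts by category (forward / target / solve)."""

    def __init__(self) -> None:
        self.counts: dict[str, int] = {}

    def add(self, category: str, macs: int) -> None:
        self.counts[category] = self.counts.get(category, 0) + int(macs)

    @property
    def total(self) -> int:
        return sum(self.counts.values())


def record(category: str, macs: int) -> None:
    for counter in _ACTIVE:
        counter.add(category, macs)


def record_matmul(category: str, n_rows: int, n_inner: int, n_cols: int) -> None:
    if _ACTIVE:
        record(category, n_rows * n_inner * n_cols)


@contextmanager
def counting():
    """Context manager yielding a live :class:`MacCounter`."""
    counter = MacCounter()
    _ACTIVE.append(counter)
    try:
        yield counter
    finally:
        _ACTIVE.remove(counter)
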