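"""Sliding-window iterative base-scale entropy (the streaming analyzer).

Instead of re-symbolizing all window - m + 1 vectors per beat, the
streaming analyzer keeps the mode histogram alive across beats.  When a
new beat arrives with a full buffer, only two vectors change: the
trailing vector formed by the last m - 1 retained beats plus the new
one (address k), and the oldest vector about to slide out (address h).
The histogram update is n(h) -= 1, n(k) += 1, and the entropy is
corrected in O(1) according to which of four situations occurred:

1. n(h) > 0 and n(k) > 1 — both modes existed and still exist: the
   generic two-term correction applies.
2. h == k — the departing and arriving vector express the same mode:
   the histogram, and hence the entropy, is unchanged.
3. n(h) == 0 and n(k) > 1 — the departing mode just became disabled.
4. n(h) > 0 and n(k) == 1 — the arriving mode just appeared.
5. n(h) == 0 and n(k) == 1 — one mode disappeared and another appeared:
   the mode-count multiset is unchanged and so is the entropy.

Rather than adding the per-case correction terms to a running entropy
(which accumulates rounding error without bound over long streams), the
state carries the accumulator A = sum_j n(j) * log2 n(j) over occupied
modes, from which

    BSE = log2 D - A / D,        D = histogram total,

an algebraic identity with the definition of the entropy.  The
per-case decision structure above is still evaluated and instrumented
on every push (``case_counts``), and the no-change cases 2 and 5 leave
the entropy bit-identical by construction.
"""

from __future__ import annotations

import math
from collections import deque

import numpy as np

from .batch import EntropyTrace, entropy_from_counts
from .core import BseParams, ModeHistogram, as_intervals, symbolize

__all__ = ["WindowState", "stream_profile", "CASE_NAMES"]

#: Instrumentation keys for the steady-state update cases.
CASE_NAMES = (
    "both_persist",  # n(h) > 0 and n(k) > 1
    "same_mode",  # h == k
    "mode_disappeared",  # n(h) == 0 and n(k) > 1
    "mode_appeared",  # n(h) > 0 and n(k) == 1
    "swap",  # n(h) == 0 and n(k) == 1
)


def _nlog2n(n: int) -> float:
    """n * log2(n) with the 0 * log2(0) := 0 convention."""
    return 0.0 if n <= 0 else n * math.log2(n)


class WindowState:
    """Ring-buffered sliding window with an incrementally maintained
    mode histogram and entropy.

    The buffer holds the most recent ``window`` beats in arrival order.
    During the fill phase each new beat contributes at most one new
    trailing vector to the histogram and the entropy grows with the
    number of vectors seen; once full, each push replaces exactly one
    vector's contribution (see module docstring).
    """

    def __init__(self, params: BseParams):
        if not isinstance(params, BseParams):
            params = BseParams(*params)
        self.params = params
        self.buffer: deque = deque(maxlen=params.window)
        self.histogram = ModeHistogram(m=params.m)
        self._accumulator = 0.0  # A = sum n(j) log2 n(j) over n(j) > 0
        self._entropy = 0.0
        self.case_counts = {name: 0 for name in CASE_NAMES}
        self.pushes = 0

    # -- accessors -----------------------------------------------------

    @property
    def filled(self) -> int:
        """Number of beats currently buffered."""
        return len(self.buffer)

    def current_entropy(self) -> float:
        """The latest entropy (bits); 0 before any vector exists."""
        return self._entropy

    def contents(self) -> np.ndarray:
        """Buffered beats, oldest first (for oracle recomputation)."""
        return np.asarray(self.buffer, dtype=float)

    # -- internals -----------------------------------------------------

    def _address_of(self, vector) -> int:
        return symbolize(np.asarray(vector, dtype=float), self.params.alpha).address

    def _entropy_from_accumulator(self) -> float:
        total = self.histogram.total
        if total <= 0:
            return 0.0
        return math.log2(total) - self._accumulator / total

    def _increment(self, address: int) -> int:
        counts = self.histogram.counts
        n_new = int(counts[address]) + 1
        counts[address] = n_new
        self._accumulator += _nlog2n(n_new) - _nlog2n(n_new - 1)
        return n_new

    def _decrement(self, address: int) -> int:
        counts = self.histogram.counts
        n_new = int(counts[address]) - 1
        if n_new < 0:
            raise RuntimeError(f"histogram underflow at mode {address}")
        counts[address] = n_new
        self._accumulator += _nlog2n(n_new) - _nlog2n(n_new + 1)
        return n_new

    # -- the update ----------------------------------------------------

    def push(self, datum: float) -> float:
        """Consume one beat interval and return the updated entropy."""
        datum = float(datum)
        if not (datum > 0):
            raise ValueError(f"beat interval must be positive, got {datum}")
        m = self.params.m
        self.pushes += 1

        if self.filled < self.params.window:
            # Fill phase: the new beat completes at most one new
            # trailing vector; probabilities use the current vector
            # count, so the entropy grows as the window populates.
            self.buffer.append(datum)
            if self.filled >= m:
                tail = [self.buffer[i] for i in range(self.filled - m, self.filled)]
                self._increment(self._address_of(tail))
                self._entropy = self._entropy_from_accumulator()
            return self._entropy

        # Steady state: the arriving beat creates one trailing vector
        # (address k) and evicts the oldest beat, destroying the oldest
        # vector (address h).
        head = [self.buffer[i] for i in range(m)]
        tail = [self.buffer[i] for i in range(self.filled - m + 1, self.filled)]
        tail.append(datum)
        h = self._address_of(head)
        k = self._address_of(tail)

        if h == k:
            self.case_counts["same_mode"] += 1
            # Same mode leaves and arrives: nothing changes, including
            # the entropy, bit for bit.
        else:
            n_h = self._decrement(h)
            n_k = self._increment(k)
            if n_h > 0 and n_k > 1:
                self.case_counts["both_persist"] += 1
            elif n_h == 0 and n_k > 1:
                self.case_counts["mode_disappeared"] += 1
            elif n_h > 0 and n_k == 1:
                self.case_counts["mode_appeared"] += 1
            else:  # n_h == 0 and n_k == 1
                self.case_counts["swap"] += 1
                # One singleton mode replaced another: both touched
                # accumulator terms are 1*log2(1) = 0, so the
                # accumulator — and the entropy — are unchanged exactly.
            self._entropy = self._entropy_from_accumulator()

        self.buffer.append(datum)  # deque(maxlen) evicts the oldest beat
        return self._entropy

    def recompute(self) -> float:
        """Rebuild accumulator and entropy exactly from the histogram.

        Optional refresh hook; the accumulator form does not drift in
        normal use, so this is never called automatically.
        """
        counts = self.histogram.counts
        occupied = counts[counts > 0]
        self._accumulator = float(sum(_nlog2n(int(n)) for n in occupied))
        self._entropy = self._entropy_from_accumulator()
        return self._entropy

    def batch_entropy(self) -> float:
        """Entropy of the histogram by direct summation (cross-check)."""
        return entropy_from_counts(self.histogram.counts)


def stream_profile(
    series, params: BseParams, emit_partial: bool = False
) -> EntropyTrace:
    """Push an entire series through a fresh :class:`WindowState`.

    Records the entropy after every beat.  With ``emit_partial=False``
    the fill-phase emissions (beats 1 .. window-1) are dropped so the
    trace aligns position-for-position with
    :func:`~bsentropy.batch.bse_profile_batch`.
    """
    values = as_intervals(series).values
    state = WindowState(params)
    out = np.empty(values.size)
    for i, x in enumerate(values):
        out[i] = state.push(x)
    if emit_partial:
        return EntropyTrace(values=out, start_index=1, params=params)
    nw = params.window
    if values.size < nw:
        return EntropyTrace(values=np.empty(0), start_index=nw, params=params)
    return EntropyTrace(values=out[nw - 1 :], start_index=nw, params=params)
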