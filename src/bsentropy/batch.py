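"""Batch base-scale entropy: the reference, recompute-everything analyzer.

For a window of N beats, every one of the N - m + 1 vectors is
symbolized, the mode histogram is rebuilt from scratch, and the Shannon
entropy of the mode probabilities is returned in bits:

    BSE(m) = - sum_pi p(pi) * log2 p(pi),      p(pi) = n(pi) / (N - m + 1)

Disabled modes (count zero) contribute nothing (0 * log2 0 := 0), so
0 <= BSE(m) <= log2 4**m = 2m.  A sliding pass over a long series
re-runs this from scratch at every window position; it is the oracle the
streaming analyzer is checked against, and the baseline of the resource
model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import BseParams, as_intervals, symbolize_series

__all__ = [
    "EntropyTrace",
    "entropy_from_counts",
    "bse_window",
    "bse_profile_batch",
    "mse",
]


@dataclass(frozen=True)
class EntropyTrace:
    """A sequence of entropy emissions aligned to the input series.

    ``values[i]`` is the entropy emitted when beat number
    ``start_index + i`` (1-based position in the input series) arrived.
    """

    values: np.ndarray
    start_index: int
    params: BseParams

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))

    def __len__(self) -> int:
        return int(self.values.size)

    @property
    def indices(self) -> np.ndarray:
        """1-based input positions of the emissions."""
        return np.arange(self.start_index, self.start_index + len(self))


def entropy_from_counts(counts) -> float:
    """Shannon entropy (bits) of a count histogram; zero counts are ignored."""
    counts = np.asarray(counts)
    total = counts.sum()
    if total <= 0:
        return 0.0
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum()) + 0.0  # normalize -0.0


def bse_window(window, params: BseParams) -> float:
    """Base-scale entropy of one window, recomputed from scratch.

    Requires at least m + 1 data (two vectors); a single vector always
    has probability one and a trivial entropy of zero, so it is treated
    as insufficient data rather than silently returning 0.
    """
    values = as_intervals(window).values
    if values.size < params.m + 1:
        raise ValueError(
            f"need at least m + 1 = {params.m + 1} data for a window, "
            f"got {values.size}"
        )
    addresses = symbolize_series(values, params.m, params.alpha)
    counts = np.bincount(addresses, minlength=params.n_modes)
    return entropy_from_counts(counts)


def bse_profile_batch(
    series, params: BseParams, emit_partial: bool = False
) -> EntropyTrace:
    """Entropy trace of a sliding full-recomputation pass over a series.

    One value is emitted per window position, i.e. per beat t from
    t = window .. N, each recomputed over the 4**m-bin histogram of that
    window alone (no state carried between positions).  With
    ``emit_partial=True`` the trace additionally covers beats 1 ..
    window-1 with zeros: before the buffer fills, this analyzer has no
    full window and by convention reports 0.
    """
    values = as_intervals(series).values
    n = values.size
    nw = params.window
    if n < nw:
        raise ValueError(f"series length {n} is shorter than the window {nw}")
    addresses = symbolize_series(values, params.m, params.alpha)
    per_window = params.vectors_per_window
    n_modes = params.n_modes
    full = np.empty(n - nw + 1)
    for t in range(n - nw + 1):
        counts = np.bincount(addresses[t : t + per_window], minlength=n_modes)
        full[t] = entropy_from_counts(counts)
    if emit_partial:
        return EntropyTrace(
            values=np.concatenate([np.zeros(nw - 1), full]),
            start_index=1,
            params=params,
        )
    return EntropyTrace(values=full, start_index=nw, params=params)


def mse(trace_a: EntropyTrace, trace_b: EntropyTrace) -> float:
    """Mean squared error between two aligned entropy traces.

    ``MSE = (1/L) * sum_i (a_i - b_i)**2`` over the region where both
    traces emit; the traces must cover identical emission positions.
    """
    if len(trace_a) != len(trace_b) or trace_a.start_index != trace_b.start_index:
        raise ValueError(
            "traces are not aligned: "
            f"lengths {len(trace_a)}/{len(trace_b)}, "
            f"start indices {trace_a.start_index}/{trace_b.start_index}"
        )
    if len(trace_a) == 0:
        raise ValueError("cannot compute MSE of empty traces")
    d = trace_a.values - trace_b.values
    return float(np.mean(d * d))
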