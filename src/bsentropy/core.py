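"""Shared symbolic-dynamics primitives for base-scale entropy.

Both the batch and the streaming analyzer are built from the same three
steps: slice the beat-interval series into overlapping vectors of length
``m`` (temporal sequence vectors, TSVs), quantize each vector into a word
over the four-letter alphabet {0, 1, 2, 3} using thresholds placed at the
vector mean plus/minus ``alpha`` times its *base scale* (the RMS of
successive differences), and encode the word as a base-4 integer address
into a histogram of the ``4**m`` possible beat modes.

The quantizer is relative to each vector's own mean and spread, which
makes the whole analysis invariant under additive shifts and positive
rescaling of the input — the entropy of a series in seconds equals the
entropy of the same series in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

#: Number of quantization levels per datum.
N_SYMBOLS = 4

#: Largest supported vector length.  The mode histogram holds 4**m counts,
#: so m = 10 already means ~1M bins; larger m is rejected outright.
MAX_M = 10

__all__ = [
    "N_SYMBOLS",
    "MAX_M",
    "IntervalSeries",
    "BseParams",
    "SymbolVector",
    "ModeHistogram",
    "as_intervals",
    "build_tsv",
    "base_scale",
    "symbolize",
    "encode",
    "decode",
    "symbolize_series",
]


@dataclass(frozen=True)
class IntervalSeries:
    """An ordered series of strictly positive beat-to-beat intervals.

    Parameters
    ----------
    values
        The PP (or RR) intervals, in the time units given by ``units``.
    units
        Metadata label, typically ``"ms"`` or ``"s"``.  The entropy is
        scale-invariant, so the units never affect results.
    """

    values: np.ndarray
    units: str = "ms"

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=float)
        if arr.ndim != 1:
            raise ValueError("interval series must be one-dimensional")
        if arr.size and not np.all(arr > 0):
            bad = int(np.flatnonzero(arr <= 0)[0])
            raise ValueError(
                f"beat intervals must be strictly positive; "
                f"value {arr[bad]!r} at position {bad + 1} is not"
            )
        object.__setattr__(self, "values", arr)

    def __len__(self) -> int:
        return int(self.values.size)

    def __iter__(self):
        return iter(self.values)

    def __array__(self, dtype=None, copy=None):
        if dtype is None:
            return self.values
        return self.values.astype(dtype)


def as_intervals(series, units: str = "ms") -> IntervalSeries:
    """Coerce an array-like (or pass through an :class:`IntervalSeries`)."""
    if isinstance(series, IntervalSeries):
        return series
    return IntervalSeries(np.asarray(series, dtype=float), units=units)


@dataclass(frozen=True)
class BseParams:
    """Analysis parameters: vector length ``m``, threshold multiplier
    ``alpha`` and sliding-window width ``window`` (number of beats).

    Defaults follow the short-term configuration m=3, alpha=0.5,
    window=300; an alternative preset m=4, alpha=0.2, window=500 is
    common for ~5-minute records.
    """

    m: int = 3
    alpha: float = 0.5
    window: int = 300

    def __post_init__(self) -> None:
        if not (2 <= int(self.m) <= MAX_M):
            raise ValueError(f"m must be an integer in [2, {MAX_M}], got {self.m}")
        if not (self.alpha > 0):
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if int(self.window) - int(self.m) + 1 < 2:
            raise ValueError(
                f"window must allow at least two vectors "
                f"(window - m + 1 >= 2); got window={self.window}, m={self.m}"
            )
        object.__setattr__(self, "m", int(self.m))
        object.__setattr__(self, "window", int(self.window))

    @property
    def n_modes(self) -> int:
        """Size of the mode alphabet, ``4**m``."""
        return N_SYMBOLS**self.m

    @property
    def vectors_per_window(self) -> int:
        """Number of vectors in a full window, ``window - m + 1``."""
        return self.window - self.m + 1


@dataclass(frozen=True)
class SymbolVector:
    """A length-``m`` word over {0,1,2,3} plus its base-4 address."""

    symbols: tuple
    address: int


@dataclass
class ModeHistogram:
    """Counts of each of the ``4**m`` beat modes within a window.

    A mode with count zero is a *disabled mode*; it contributes exactly
    nothing to the entropy.
    """

    m: int
    counts: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.counts is None:
            self.counts = np.zeros(N_SYMBOLS**self.m, dtype=np.int64)
        else:
            self.counts = np.asarray(self.counts, dtype=np.int64)
            if self.counts.shape != (N_SYMBOLS**self.m,):
                raise ValueError("counts must have length 4**m")
            if np.any(self.counts < 0):
                raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def build_tsv(series, i: int, m: int) -> np.ndarray:
    """Return the ``i``-th temporal sequence vector (1-based start index).

    The vector is the slice ``(PP(i), ..., PP(i+m-1))``; a series of
    length N yields N - m + 1 such vectors.
    """
    values = as_intervals(series).values
    n = values.size
    if m < 2:
        raise ValueError(f"vector length m must be >= 2, got {m}")
    if not (1 <= i <= n - m + 1):
        raise IndexError(
            f"start index {i} out of range [1, {n - m + 1}] for N={n}, m={m}"
        )
    return values[i - 1 : i - 1 + m].copy()


def base_scale(vector) -> float:
    """Root mean square of successive differences within a vector.

    ``BS = sqrt( sum_{j=1..m-1} (x[j+1] - x[j])**2 / (m-1) )``.  This is
    the adaptive quantization width: vectors with large beat-to-beat
    swings get proportionally wide symbol bands.
    """
    v = np.asarray(vector, dtype=float)
    if v.size < 2:
        raise ValueError("base scale needs a vector of length >= 2")
    d = np.diff(v)
    return float(np.sqrt(np.mean(d * d)))


def symbolize(vector, alpha: float) -> SymbolVector:
    """Quantize one vector into a four-symbol word around mean +/- alpha*BS.

    With mu the vector mean and B its base scale, each datum x maps to::

        0  if  mu          <  x  <=  mu + alpha*B
        1  if  x  >  mu + alpha*B
        2  if  mu - alpha*B  <  x  <=  mu
        3  if  x  <=  mu - alpha*B

    The four half-open bands partition the line, so every datum receives
    exactly one symbol.  For a constant vector B = 0 and the bands 0-2
    are empty, so every datum falls through to symbol 3; this degenerate
    case is deliberate, not special-cased.
    """
    v = np.asarray(vector, dtype=float)
    if not (alpha > 0):
        raise ValueError(f"alpha must be positive, got {alpha}")
    mu = float(np.mean(v))
    band = alpha * base_scale(v)
    hi, lo = mu + band, mu - band
    symbols = []
    for x in v:
        if x > hi:
            symbols.append(1)
        elif x > mu:
            symbols.append(0)
        elif x > lo:
            symbols.append(2)
        else:
            symbols.append(3)
    symbols = tuple(symbols)
    return SymbolVector(symbols=symbols, address=encode(symbols))


def encode(symbols) -> int:
    """Base-4 address of a symbol word, leftmost symbol most significant.

    ``address = sum_{j=1..m} s[j] * 4**(m-j)``; a bijection from symbol
    words onto [0, 4**m - 1], used as the storage address of the word's
    count in the mode histogram.
    """
    address = 0
    n = 0
    for s in symbols:
        s = int(s)
        if not (0 <= s < N_SYMBOLS):
            raise ValueError(f"symbol {s} outside alphabet 0..{N_SYMBOLS - 1}")
        address = address * N_SYMBOLS + s
        n += 1
    if n == 0:
        raise ValueError("cannot encode an empty symbol word")
    return address


def decode(address: int, m: int) -> tuple:
    """Inverse of :func:`encode`: recover the length-``m`` symbol word."""
    if not (0 <= address < N_SYMBOLS**m):
        raise ValueError(f"address {address} outside [0, {N_SYMBOLS ** m - 1}]")
    symbols = []
    a = int(address)
    for _ in range(m):
        symbols.append(a % N_SYMBOLS)
        a //= N_SYMBOLS
    return tuple(reversed(symbols))


def symbolize_series(series, m: int, alpha: float) -> np.ndarray:
    """Vectorized symbolization of every length-``m`` vector of a series.

    Returns the int64 array of N - m + 1 mode addresses.  Row-wise
    reductions mirror the scalar :func:`symbolize` arithmetic so the two
    paths agree on borderline data.
    """
    values = as_intervals(series).values
    if not (2 <= m <= MAX_M):
        raise ValueError(f"m must be in [2, {MAX_M}], got {m}")
    if not (alpha > 0):
        raise ValueError(f"alpha must be positive, got {alpha}")
    if values.size < m:
        return np.empty(0, dtype=np.int64)
    windows = sliding_window_view(values, m)
    mu = windows.mean(axis=1)
    d = np.diff(windows, axis=1)
    band = alpha * np.sqrt((d * d).mean(axis=1))
    hi = (mu + band)[:, None]
    lo = (mu - band)[:, None]
    muc = mu[:, None]
    symbols = np.where(
        windows > hi, 1, np.where(windows > muc, 0, np.where(windows > lo, 2, 3))
    ).astype(np.int64)
    weights = N_SYMBOLS ** np.arange(m - 1, -1, -1, dtype=np.int64)
    return symbols @ weights
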