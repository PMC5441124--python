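"""Seeded synthetic beat-interval and pulse-waveform generators.

Every analyzer in this package is testable offline with these
generators; no physiological recording is required.  All randomness
flows through :func:`numpy.random.default_rng` (PCG64), so a given spec
and seed reproduce bit-identical output on any platform.

The interval generators emulate the gross statistics of resting human
pulse series — intervals on the order of 800-1000 ms with beat-to-beat
fluctuations of tens of milliseconds — at several complexity levels:

``constant``       a single repeated interval (entropy exactly 0);
``periodic``       a short repeating pattern (a few modes, low entropy);
``ar1``            a mean-reverting AR(1) process, the workhorse
                   stochastic fixture;
``uniform_modes``  a periodic series engineered so its distinct beat
                   modes occur equally often (exact entropy log2 P);
``random_walk``    bounded cumulative jitter, wandering slowly enough
                   to exercise mode appearance and disappearance.

They are statistical stand-ins, not cardiovascular models: no
respiratory sinus arrhythmia, no 1/f background, no ectopy unless you
inject it yourself.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import IntervalSeries, N_SYMBOLS, symbolize_series
from .preprocess import BeatLocations

__all__ = [
    "GeneratorSpec",
    "generate_intervals",
    "constant_intervals",
    "periodic_intervals",
    "ar1_intervals",
    "random_walk_intervals",
    "uniform_mode_intervals",
    "generate_pulse_waveform",
    "reachable_mode_bound",
    "INTERVAL_FLOOR_MS",
]

#: Stochastic generators clip intervals at this floor to keep them positive
#: (200 ms ~ 300 bpm, far below any plausible beat interval).
INTERVAL_FLOOR_MS = 200.0

KINDS = ("constant", "periodic", "ar1", "uniform_modes", "random_walk")


@dataclass(frozen=True)
class GeneratorSpec:
    """Declarative description of a synthetic series: kind, length, seed
    and kind-specific parameters (see the individual generator functions
    for parameter names and defaults)."""

    kind: str
    n: int
    seed: int = 0
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown generator kind {self.kind!r}; one of {KINDS}")
        if self.n < 1:
            raise ValueError(f"series length must be >= 1, got {self.n}")


def generate_intervals(spec: GeneratorSpec) -> IntervalSeries:
    """Dispatch a :class:`GeneratorSpec` to the matching generator."""
    fn = {
        "constant": constant_intervals,
        "periodic": periodic_intervals,
        "ar1": ar1_intervals,
        "uniform_modes": uniform_mode_intervals,
        "random_walk": random_walk_intervals,
    }[spec.kind]
    if spec.kind in ("constant", "periodic"):
        return fn(spec.n, **spec.params)
    return fn(spec.n, seed=spec.seed, **spec.params)


def constant_intervals(n: int, value: float = 810.0) -> IntervalSeries:
    """``n`` identical intervals: exactly one beat mode, entropy 0."""
    return IntervalSeries(np.full(n, float(value)))


def periodic_intervals(n: int, pattern=(800.0, 820.0, 810.0)) -> IntervalSeries:
    """The pattern repeated/truncated to length ``n``."""
    pattern = np.asarray(pattern, dtype=float)
    reps = int(np.ceil(n / pattern.size))
    return IntervalSeries(np.tile(pattern, reps)[:n])


def ar1_intervals(
    n: int,
    seed: int = 0,
    mean: float = 850.0,
    phi: float = 0.9,
    sigma: float = 20.0,
) -> IntervalSeries:
    """Mean-reverting AR(1): x_t = mean + phi*(x_{t-1} - mean) + eps_t.

    Defaults (mean 850 ms, phi 0.9, sigma 20 ms) give a series with the
    autocorrelation and spread of a resting pulse series.  Clipped at
    :data:`INTERVAL_FLOOR_MS` to preserve positivity.
    """
    if not (0 <= abs(phi) < 1):
        raise ValueError(f"AR coefficient must satisfy |phi| < 1, got {phi}")
    rng = np.random.default_rng(seed)
    eps = rng.normal(0.0, sigma, size=n)
    x = np.empty(n)
    prev = mean
    for t in range(n):
        prev = mean + phi * (prev - mean) + eps[t]
        x[t] = prev
    return IntervalSeries(np.maximum(x, INTERVAL_FLOOR_MS))


def random_walk_intervals(
    n: int,
    seed: int = 0,
    start: float = 850.0,
    step_sd: float = 20.0,
    low: float = 600.0,
    high: float = 1200.0,
) -> IntervalSeries:
    """Bounded random walk: cumulative Gaussian jitter reflected at
    [low, high].

    Wanders across the interval range on a timescale of hundreds of
    beats, so a sliding window sees modes drift in and out — the
    fixture of choice for exercising every incremental-update case.
    """
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, step_sd, size=n)
    x = np.empty(n)
    cur = float(start)
    for t in range(n):
        cur += steps[t]
        # reflect into [low, high]
        while cur < low or cur > high:
            if cur < low:
                cur = 2 * low - cur
            else:
                cur = 2 * high - cur
        x[t] = cur
    return IntervalSeries(x)


def reachable_mode_bound(m: int) -> int:
    """Upper bound on how many of the 4**m beat modes data can realize.

    Symbols 0 and 1 both mean "strictly above the vector's own mean", so
    no vector can produce a word drawn entirely from {0, 1} (its data
    cannot all exceed their own mean): 2**m words are unreachable.
    Dually, "all data <= mean" forces all data equal, which the
    quantizer maps to the all-3 word; the other 2**m - 1 words over
    {2, 3} are unreachable too.  Hence at most

        4**m - 2**(m+1) + 1

    modes can occur, and the theoretical entropy ceiling log2(4**m) = 2m
    bits is unattainable for any real-valued series.
    """
    return N_SYMBOLS**m - 2 ** (m + 1) + 1


def uniform_mode_intervals(
    n: int,
    seed: int = 0,
    m: int = 3,
    alpha: float = 0.5,
    n_modes: int = 16,
    low: float = 700.0,
    high: float = 1000.0,
    max_tries: int = 20_000,
) -> IntervalSeries:
    """A periodic series whose distinct beat modes occur equally often.

    Searches (seeded, deterministic) for a period-``n_modes`` pattern
    whose ``n_modes`` cyclic length-``m`` windows all symbolize to
    distinct mode addresses under the given ``alpha``; the pattern is
    then tiled and padded with its first m - 1 values so every cyclic
    window occurs exactly ``n // n_modes`` times.  The window entropy of
    the result is exactly log2(n_modes) bits (choose a power of two for
    a floating-point-exact value).

    ``n`` is the number of *vectors*; the returned series has
    n + m - 1 data and must have ``n`` divisible by ``n_modes``.  Note
    that not all 4**m modes can be represented no matter the pattern
    (see :func:`reachable_mode_bound`), so the entropy ceiling is
    log2 of that bound, not 2m — and in practice the quantizer's
    geometry concentrates probability on far fewer modes (around 18 at
    m=3), so requests much beyond the default will exhaust the search.
    """
    if n % n_modes != 0:
        raise ValueError(f"n={n} must be a multiple of n_modes={n_modes}")
    if n_modes > reachable_mode_bound(m):
        raise ValueError(
            f"n_modes={n_modes} exceeds the {reachable_mode_bound(m)} "
            f"modes reachable at m={m}"
        )
    rng = np.random.default_rng(seed)
    # stochastic local search: redraw one value inside a duplicated
    # window until all cyclic windows symbolize to distinct modes
    pattern = rng.uniform(low, high, size=n_modes)
    for _ in range(max_tries):
        cyclic = np.concatenate([pattern, pattern[: m - 1]])
        addresses = symbolize_series(cyclic, m, alpha)
        _, first_idx, counts = np.unique(
            addresses, return_index=True, return_counts=True
        )
        if counts.max() == 1:
            reps = n // n_modes
            series = np.concatenate([np.tile(pattern, reps), pattern[: m - 1]])
            return IntervalSeries(series)
        candidates = first_idx[counts > 1]
        dup_window = int(candidates[rng.integers(candidates.size)])
        position = (dup_window + int(rng.integers(m))) % n_modes
        pattern[position] = rng.uniform(low, high)
    raise RuntimeError(
        f"no pattern with {n_modes} distinct modes found in {max_tries} tries "
        f"(m={m}, alpha={alpha}); try fewer modes or another alpha"
    )


def generate_pulse_waveform(
    intervals,
    fs: float = 250.0,
    pulse_width_s: float = 0.05,
    noise_sd: float = 0.0,
    seed: int = 0,
):
    """Superpose Gaussian pulses at cumulative beat positions.

    Beat times are quantized to the sample grid, so
    :func:`~bsentropy.preprocess.beats_to_prv` applied to the returned
    ground truth recovers the input intervals exactly whenever they are
    integer multiples of the sample period (4 ms at the default 250 Hz).

    Returns ``(waveform, BeatLocations)`` where the locations are the
    ground-truth pulse centers for detector benchmarking.
    """
    iv = np.asarray(
        intervals.values if hasattr(intervals, "values") else intervals, dtype=float
    )
    if not (fs > 0):
        raise ValueError(f"sampling frequency must be positive, got {fs}")
    if np.any(iv <= 0):
        raise ValueError("beat intervals must be positive")
    # first pulse half a second in; subsequent pulses at cumulative intervals
    times_s = 0.5 + np.concatenate([[0.0], np.cumsum(iv) / 1000.0])
    locations = np.round(times_s * fs).astype(np.int64)
    n_samples = int(locations[-1] + fs)  # half-second margins either side
    x = np.zeros(n_samples)
    sigma = pulse_width_s * fs
    half = int(np.ceil(5 * sigma))
    kernel = np.exp(-0.5 * (np.arange(-half, half + 1) / sigma) ** 2)
    for loc in locations:
        lo, hi = loc - half, loc + half + 1
        x[max(lo, 0) : min(hi, n_samples)] += kernel[
            max(-lo, 0) : kernel.size - max(hi - n_samples, 0)
        ]
    if noise_sd > 0:
        x += np.random.default_rng(seed).normal(0.0, noise_sd, size=n_samples)
    return x, BeatLocations(locations, fs=fs)
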