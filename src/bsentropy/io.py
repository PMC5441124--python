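"""Plain-text readers and writers for interval series, beat locations
and entropy traces.

Interval files are one numeric value per line (plain text or one-column
CSV; a header line ``pp_ms`` or ``pp_s`` is accepted and sets the units
tag).  Lines starting with ``#`` and blank lines are skipped.  Beat
locations are two-column CSV ``index[,amplitude]``; the amplitude
column is ignored on read.
"""

from __future__ import annotations

import numpy as np

from .batch import EntropyTrace
from .core import BseParams, IntervalSeries
from .preprocess import BeatLocations

__all__ = [
    "read_intervals",
    "write_intervals",
    "read_beats",
    "write_trace",
    "read_trace",
]

_HEADERS = {"pp_ms": "ms", "pp_s": "s", "pp": "ms", "interval": "ms", "bse": None}


def _data_lines(path):
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            yield lineno, line


def read_intervals(path, units: str = "ms") -> IntervalSeries:
    """Read a one-column interval file; returns an :class:`IntervalSeries`.

    A non-numeric row raises a parse error naming its line number;
    non-positive values raise a validation error.
    """
    values = []
    for lineno, line in _data_lines(path):
        token = line.split(",")[0].strip()
        if not values and token.lower() in _HEADERS:
            units = _HEADERS[token.lower()] or units
            continue
        try:
            values.append(float(token))
        except ValueError:
            raise ValueError(
                f"{path}: line {lineno}: expected a number, got {token!r}"
            ) from None
    return IntervalSeries(np.asarray(values), units=units)


def write_intervals(series: IntervalSeries, path) -> None:
    """Write a series as one-column CSV with a units header."""
    with open(path, "w") as fh:
        fh.write(f"pp_{series.units}\n")
        for v in series.values:
            fh.write(f"{float(v)!r}\n")


def read_beats(path, fs: float) -> BeatLocations:
    """Read beat locations from one- or two-column CSV (index[,amplitude])."""
    indices = []
    for lineno, line in _data_lines(path):
        token = line.split(",")[0].strip()
        if not indices and token.lower() in ("index", "sample", "location"):
            continue
        try:
            indices.append(int(float(token)))
        except ValueError:
            raise ValueError(
                f"{path}: line {lineno}: expected a sample index, got {token!r}"
            ) from None
    return BeatLocations(np.asarray(indices, dtype=np.int64), fs=fs)


def write_trace(trace: EntropyTrace, path) -> None:
    """Write an entropy trace as ``index,bse`` CSV.

    ``index`` is the 1-based position in the input series of the beat
    that triggered the emission; values round-trip at full float
    precision via ``repr``.
    """
    with open(path, "w") as fh:
        fh.write("index,bse\n")
        for idx, value in zip(trace.indices, trace.values):
            fh.write(f"{int(idx)},{float(value)!r}\n")


def read_trace(path, params: BseParams | None = None) -> EntropyTrace:
    """Read back a trace written by :func:`write_trace`."""
    indices, values = [], []
    for lineno, line in _data_lines(path):
        first, _, rest = line.partition(",")
        if not indices and first.strip().lower() == "index":
            continue
        try:
            indices.append(int(first))
            values.append(float(rest))
        except ValueError:
            raise ValueError(
                f"{path}: line {lineno}: malformed trace row {line!r}"
            ) from None
    if indices and np.any(np.diff(indices) != 1):
        raise ValueError(f"{path}: trace emission indices are not contiguous")
    start = indices[0] if indices else 1
    return EntropyTrace(
        values=np.asarray(values), start_index=start, params=params or BseParams()
    )


def wfdb_record_to_intervals(record_name: str, channel: int = 0):  # pragma: no cover
    """Convert a PhysioNet WFDB record to an interval series (optional).

    Requires the optional ``wfdb`` package; reads the waveform, runs the
    naive beat detector, and differences the beat locations.  Intended
    for exploratory use against e.g. the Fantasia blood-pressure
    records; no test or core path depends on it.
    """
    try:
        import wfdb  # type: ignore
    except ImportError as exc:
        raise ImportError(
            "the optional 'wfdb' package is required for WFDB conversion; "
            "install with: pip install bsentropy[wfdb]"
        ) from exc
    from .preprocess import beats_to_prv, detect_beats_naive

    record = wfdb.rdrecord(record_name, channels=[channel])
    beats = detect_beats_naive(record.p_signal[:, 0], fs=float(record.fs))
    return beats_to_prv(beats)
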