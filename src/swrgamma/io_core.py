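"""Domain types and file I/O for traces, event tables and reports.

Time conventions used throughout the package: times are in seconds, sample
indices are 0-based (sample ``i`` of a trace lives at ``t0 + i/fs``), and all
event intervals are half-open ``[t_start, t_end)`` so that an event ending at
``t`` and one starting at ``t`` do not overlap.

Two on-disk trace formats are supported:

* *delimited* — CSV with a comment header ``# fs=<Hz> units=<mV|pA> t0=<s>``
  and columns ``time,value``; convenient for small fixtures.
* *container* — a single HDF5 file with named datasets, bit-exact round-trip;
  the practical choice for traces sampled at 10-20 kHz.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from pathlib import Path
from typing import Literal, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "Trace",
    "BaselineStats",
    "SWREvent",
    "GammaEpoch",
    "SessionComparison",
    "PSCEvent",
    "FormatError",
    "DataError",
    "read_trace",
    "write_trace",
    "read_events",
    "write_events",
]

Units = Literal["mV", "pA"]


class FormatError(ValueError):
    """A file does not conform to the declared on-disk format."""


class DataError(ValueError):
    """Input data violate a contract (non-finite samples, degenerate input...)."""


@dataclass
class Trace:
    """A uniformly sampled voltage (mV) or current (pA) time series.

    Parameters
    ----------
    samples
        Amplitude values; coerced to a float64 array.
    fs
        Sampling rate in Hz, strictly positive.
    t0
        Time of the first sample in seconds.
    units
        ``"mV"`` for field potentials, ``"pA"`` for clamp currents.
    label
        Free-text channel label.
    """

    samples: np.ndarray
    fs: float
    t0: float = 0.0
    units: Units = "mV"
    label: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 1:
            raise DataError("trace samples must be one-dimensional")
        if self.fs <= 0:
            raise DataError("sampling rate must be positive")
        if self.samples.size < 2:
            raise DataError("a trace needs at least two samples")
        bad = np.flatnonzero(~np.isfinite(self.samples))
        if bad.size:
            raise DataError(f"non-finite sample at index {bad[0]}")
        if self.units not in ("mV", "pA"):
            raise DataError(f"unsupported units {self.units!r}")

    def __len__(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Length of the trace in seconds (n / fs)."""
        return self.samples.size / self.fs

    @property
    def t_end(self) -> float:
        return self.t0 + self.duration

    def times(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.fs

    def index_at(self, t: float) -> int:
        """Index of the sample at or immediately after time ``t``."""
        return int(np.ceil(round((t - self.t0) * self.fs, 9)))

    def slice(self, t_start: float, t_end: float) -> "Trace":
        """Return the sub-trace covering the half-open window [t_start, t_end)."""
        i0 = max(self.index_at(t_start), 0)
        i1 = min(self.index_at(t_end), len(self))
        if i1 - i0 < 2:
            raise DataError(f"window [{t_start}, {t_end}) holds fewer than 2 samples")
        return Trace(self.samples[i0:i1], self.fs, self.t0 + i0 / self.fs,
                     self.units, self.label)

    def copy_with(self, samples: np.ndarray) -> "Trace":
        """A trace with the same metadata but new samples (same length)."""
        return Trace(np.asarray(samples, float), self.fs, self.t0, self.units, self.label)


@dataclass
class BaselineStats:
    """Mean/SD of the event-free portion of a trace, with the mask used.

    ``mean`` and ``sd`` are computed over the signed samples where ``mask`` is
    True; detection thresholds of the form ``mean + k*sd`` are then applied to
    the rectified trace.
    """

    mean: float
    sd: float
    n_samples: int
    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, bool)
        if self.sd < 0:
            raise DataError("baseline SD must be non-negative")
        if int(self.mask.sum()) != self.n_samples:
            raise DataError("baseline mask does not cover n_samples entries")

    def threshold(self, k: float) -> float:
        return self.mean + k * self.sd


_REJECTION_REASONS = ("none", "spectral", "manual", "boundary")


@dataclass
class SWREvent:
    """One detected sharp wave-ripple with its quantification.

    ``area`` (mV·s) is the magnitude of the integral of the baseline-subtracted
    sharp-wave deflection over ``[t_start, t_end)``; ``sw_amplitude`` the peak
    deflection; ``ripple_count``/``ripple_freq`` describe the fast oscillation
    riding on the sharp wave; ``max_abs_coeff`` is the event's maximum absolute
    complex-Morlet wavelet coefficient used by the spectral criterion.
    """

    t_start: float
    t_end: float
    area: float = 0.0
    sw_amplitude: float = 0.0
    duration: float = 0.0  # ms
    ripple_count: int = 0
    ripple_freq: float = float("nan")
    max_abs_coeff: float = 0.0
    accepted: bool = False
    rejection_reason: str = "none"

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise DataError("event must satisfy t_start < t_end")
        if self.area < 0:
            raise DataError("event area must be non-negative")
        if self.rejection_reason not in _REJECTION_REASONS:
            raise DataError(f"unknown rejection reason {self.rejection_reason!r}")


@dataclass
class GammaEpoch:
    """A contiguous oscillatory episode and its spectral summary.

    ``power_x_duration`` (peak power times episode duration) is the exposure
    metric correlated with subsequent SWR-area change.
    """

    t_start: float
    t_end: float
    peak_freq: float = float("nan")
    peak_power: float = float("nan")

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise DataError("epoch must satisfy t_start < t_end")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def power_x_duration(self) -> float:
        return self.peak_power * self.duration


@dataclass
class SessionComparison:
    """Paired pre- vs post-gamma values of one metric with test results."""

    pre_values: np.ndarray
    post_values: np.ndarray
    metric_name: str
    normalized_post: np.ndarray
    pct_change: float
    sem: float
    test_name: str
    p_value: float
    n: int
    degenerate: bool = False
    n_zero_diffs: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise DataError("p-value outside [0, 1]")
        if self.n != len(self.pre_values) or self.n != len(self.post_values):
            raise DataError("pair count does not match value sequences")


@dataclass
class PSCEvent:
    """One postsynaptic-current event; ``area`` is the transferred charge (pA·s)."""

    t_start: float
    t_end: float
    area: float
    polarity: Literal["EPSC", "IPSC"]
    holding_potential: float = float("nan")

    _EXPECTED_HOLDING = {"EPSC": -70.0, "IPSC": 0.0}

    def __post_init__(self) -> None:
        if not self.t_start < self.t_end:
            raise DataError("event must satisfy t_start < t_end")
        if self.area < 0:
            raise DataError("PSC area is a magnitude and must be non-negative")
        if self.polarity not in ("EPSC", "IPSC"):
            raise DataError(f"unknown polarity {self.polarity!r}")
        expected = self._EXPECTED_HOLDING[self.polarity]
        if np.isfinite(self.holding_potential) and self.holding_potential != expected:
            import warnings

            warnings.warn(
                f"{self.polarity} recorded at {self.holding_potential} mV; "
                f"conventional holding potential is {expected} mV",
                stacklevel=2,
            )


# ---------------------------------------------------------------------------
# Trace I/O


def write_trace(trace: Trace, path: str | Path,
                format: Literal["delimited", "container"] = "container") -> None:
    """Write a trace to disk in the delimited-text or HDF5 container format."""
    path = Path(path)
    if format == "delimited":
        with open(path, "w") as fh:
            fh.write(f"# fs={trace.fs:.10g} units={trace.units} t0={trace.t0:.10g}\n")
            fh.write("time,value\n")
            t = trace.times()
            for ti, vi in zip(t, trace.samples):
                fh.write(f"{ti:.9f},{vi:.10g}\n")
    elif format == "container":
        with h5py.File(path, "w") as f:
            f.create_dataset("samples", data=trace.samples)
            f.attrs["fs"] = trace.fs
            f.attrs["t0"] = trace.t0
            f.attrs["units"] = trace.units
            f.attrs["label"] = trace.label
    else:
        raise FormatError(f"unknown trace format {format!r}")


def read_trace(path: str | Path,
               format: Literal["delimited", "container"] | None = None) -> Trace:
    """Read a trace written by :func:`write_trace`.

    ``format`` is inferred from the file when omitted (HDF5 magic bytes vs
    text header).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format is None:
        with open(path, "rb") as fh:
            format = "container" if fh.read(8) == b"\x89HDF\r\n\x1a\n" else "delimited"
    if format == "container":
        with h5py.File(path, "r") as f:
            if "samples" not in f or "fs" not in f.attrs:
                raise FormatError(f"{path}: container missing samples/fs")
            samples = f["samples"][:]
            units = f.attrs.get("units", "mV")
            units = units.decode() if isinstance(units, bytes) else str(units)
            label = f.attrs.get("label", "")
            label = label.decode() if isinstance(label, bytes) else str(label)
            return Trace(samples, float(f.attrs["fs"]),
                         float(f.attrs.get("t0", 0.0)), units, label)
    if format != "delimited":
        raise FormatError(f"unknown trace format {format!r}")
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise FormatError(f"{path}: missing '# fs=... units=... t0=...' header")
        meta = {}
        for tok in header.lstrip("#").split():
            if "=" not in tok:
                raise FormatError(f"{path}: malformed header token {tok!r}")
            k, v = tok.split("=", 1)
            meta[k] = v
        if "fs" not in meta or "units" not in meta:
            raise FormatError(f"{path}: header must declare fs and units")
        body = fh.read()
    arr = pd.read_csv(io.StringIO(body), float_precision="round_trip")
    if "value" not in arr.columns:
        raise FormatError(f"{path}: expected a 'value' column")
    values = arr["value"].to_numpy(float)
    bad = np.flatnonzero(~np.isfinite(values))
    if bad.size:
        raise DataError(f"{path}: non-finite sample at index {bad[0]}")
    return Trace(values, float(meta["fs"]), float(meta.get("t0", 0.0)), meta["units"])


# ---------------------------------------------------------------------------
# Event-table I/O

_EVENT_COLUMNS = [
    "t_start", "t_end", "area", "sw_amplitude", "duration_ms",
    "ripple_count", "ripple_freq", "max_abs_coeff", "accepted", "rejection_reason",
]


def write_events(events: Sequence[SWREvent], path: str | Path) -> None:
    """Write a CSV event table (one row per event, header line first).

    Events must be sorted by ``t_start``; reading the table back reproduces
    the events to float64 round-trip precision.
    """
    starts = [e.t_start for e in events]
    if any(b < a for a, b in zip(starts, starts[1:])):
        raise DataError("events must be sorted by t_start")
    df = pd.DataFrame(
        [
            {
                "t_start": e.t_start,
                "t_end": e.t_end,
                "area": e.area,
                "sw_amplitude": e.sw_amplitude,
                "duration_ms": e.duration,
                "ripple_count": e.ripple_count,
                "ripple_freq": e.ripple_freq,
                "max_abs_coeff": e.max_abs_coeff,
                "accepted": e.accepted,
                "rejection_reason": e.rejection_reason,
            }
            for e in events
        ],
        columns=_EVENT_COLUMNS,
    )
    # pandas writes shortest round-trip float repr; values survive bit-exact
    df.to_csv(path, index=False)


def read_events(path: str | Path) -> list[SWREvent]:
    """Read an event table written by :func:`write_events`."""
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(_EVENT_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        out.append(
            SWREvent(
                t_start=float(row.t_start),
                t_end=float(row.t_end),
                area=float(row.area),
                sw_amplitude=float(row.sw_amplitude),
                duration=float(row.duration_ms),
                ripple_count=int(row.ripple_count),
                ripple_freq=float(row.ripple_freq),
                max_abs_coeff=float(row.max_abs_coeff),
                accepted=bool(row.accepted),
                rejection_reason=str(row.rejection_reason),
            )
        )
    return out
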