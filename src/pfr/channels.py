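"""Timestamped monitoring channels and block-averaging primitives.

A :class:`ChannelSeries` is one monitored signal (ABP, ICP, brain-tissue
perfusion, ...) with timestamps in seconds since the epoch origin, physical
units, and a nominal sampling rate.  Missing data are explicit NaNs in ``v``,
never silently dropped.  A :class:`PatientEpoch` bundles the channels recorded
over one contiguous monitoring stretch.

Block averaging uses non-overlapping, left-aligned, half-open windows
``[k*width, (k+1)*width)`` with output timestamps at block starts; a block
whose samples are all NaN stays NaN.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

#: canonical units per channel name
CHANNEL_UNITS = {
    "ABP": "mmHg",
    "ICP": "mmHg",
    "CPP": "mmHg",
    "PERF": "mL/hg/min",
    "CBF": "mL/s",
    "PBTO2": "mmHg",
    "ICT": "degC",
    "SPO2": "%",
    "ETCO2": "mmHg",
    "HR": "beats/min",
    "RR": "breaths/min",
}

KNOWN_UNITS = set(CHANNEL_UNITS.values())


class ChannelFormatError(ValueError):
    """Raised when channel data violate the format contract."""


@dataclass
class ChannelSeries:
    """One timestamped monitored signal.

    Parameters
    ----------
    name : str
        Channel identifier (ABP, ICP, PERF, PBTO2, ICT, SPO2, ETCO2, HR, RR,
        or a derived name such as CPP/CBF).
    t : ndarray
        Timestamps in seconds since the epoch origin, strictly increasing.
    v : ndarray
        Sample values; missing data are NaN.
    units : str
        Physical units, consistent with ``name`` for known channels.
    nominal_rate : float
        Nominal sampling rate in Hz.
    """

    name: str
    t: np.ndarray
    v: np.ndarray
    units: str
    nominal_rate: float

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.v = np.asarray(self.v, dtype=float)
        if self.t.ndim != 1 or self.v.ndim != 1:
            raise ChannelFormatError(f"{self.name}: t and v must be 1-D")
        if len(self.t) != len(self.v):
            raise ChannelFormatError(
                f"{self.name}: len(t)={len(self.t)} != len(v)={len(self.v)}"
            )
        if len(self.t) and not np.all(np.isfinite(self.t)):
            raise ChannelFormatError(f"{self.name}: non-finite timestamps")
        bad = np.nonzero(np.diff(self.t) <= 0)[0]
        if bad.size:
            raise ChannelFormatError(
                f"{self.name}: timestamps not strictly increasing at row {bad[0] + 1}"
            )
        expected = CHANNEL_UNITS.get(self.name)
        if expected is not None and self.units != expected:
            raise ChannelFormatError(
                f"{self.name}: units {self.units!r}, expected {expected!r}"
            )

    def __len__(self) -> int:
        return len(self.t)

    @property
    def duration(self) -> float:
        """Span in seconds (0 for fewer than 2 samples)."""
        if len(self.t) < 2:
            return 0.0
        return float(self.t[-1] - self.t[0])

    def step(self) -> float:
        """Median sampling interval in seconds."""
        if len(self.t) < 2:
            raise ValueError(f"{self.name}: need >= 2 samples for a step")
        return float(np.median(np.diff(self.t)))

    def slice(self, t0: float, t1: float) -> "ChannelSeries":
        """Samples with t0 <= t < t1."""
        m = (self.t >= t0) & (self.t < t1)
        return ChannelSeries(self.name, self.t[m], self.v[m], self.units,
                             self.nominal_rate)

    def copy(self) -> "ChannelSeries":
        return ChannelSeries(self.name, self.t.copy(), self.v.copy(),
                             self.units, self.nominal_rate)

    def equals(self, other: "ChannelSeries") -> bool:
        return (
            self.name == other.name
            and self.units == other.units
            and self.nominal_rate == other.nominal_rate
            and np.array_equal(self.t, other.t)
            and np.array_equal(self.v, other.v, equal_nan=True)
        )


@dataclass
class PatientEpoch:
    """All channels recorded over one contiguous monitoring stretch.

    Channels share the epoch time origin (t=0 at epoch start).  ``events`` is
    an optional list of ``(time_seconds, category)`` intervention markers.
    """

    patient_id: str
    epoch_id: str
    channels: dict = field(default_factory=dict)
    events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        for name, ch in self.channels.items():
            if name != ch.name:
                raise ChannelFormatError(
                    f"channel key {name!r} != series name {ch.name!r}"
                )

    def add(self, ch: ChannelSeries) -> None:
        if ch.name in self.channels:
            raise ChannelFormatError(f"duplicate channel {ch.name!r}")
        self.channels[ch.name] = ch

    def __contains__(self, name: str) -> bool:
        return name in self.channels

    def __getitem__(self, name: str) -> ChannelSeries:
        return self.channels[name]

    @property
    def duration(self) -> float:
        return max((ch.t[-1] for ch in self.channels.values() if len(ch)),
                   default=0.0)

    def copy(self) -> "PatientEpoch":
        return PatientEpoch(
            self.patient_id,
            self.epoch_id,
            {n: c.copy() for n, c in self.channels.items()},
            copy.deepcopy(self.events),
        )

    def equals(self, other: "PatientEpoch") -> bool:
        if set(self.channels) != set(other.channels):
            return False
        return all(self.channels[n].equals(other.channels[n])
                   for n in self.channels)


def block_average(series: ChannelSeries, width: float) -> ChannelSeries:
    """Average a series over non-overlapping, left-aligned windows.

    Blocks are ``[k*width, (k+1)*width)`` on the absolute time axis; the block
    value is the mean of the non-NaN samples it contains (NaN if none), and
    output timestamps sit at block starts.

    Parameters
    ----------
    series : ChannelSeries
    width : float
        Block width in seconds; must exceed the native sampling interval.
    """
    if width <= 0:
        raise ValueError("width must be positive")
    if len(series) == 0:
        return ChannelSeries(series.name, np.array([]), np.array([]),
                             series.units, 1.0 / width)
    if len(series) >= 2 and width < series.step():
        raise ValueError(
            f"width {width}s shorter than sampling interval {series.step()}s"
        )
    k = np.floor(series.t / width).astype(np.int64)
    k0, k1 = k[0], k[-1]
    idx = k - k0
    nblocks = int(k1 - k0) + 1
    finite = np.isfinite(series.v)
    sums = np.bincount(idx[finite], weights=series.v[finite], minlength=nblocks)
    counts = np.bincount(idx[finite], minlength=nblocks)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    t_out = (np.arange(nblocks) + k0) * width
    return ChannelSeries(series.name, t_out, means, series.units, 1.0 / width)


def align(a: ChannelSeries, b: ChannelSeries):
    """Restrict two series to their common timestamps (exact match)."""
    common, ia, ib = np.intersect1d(a.t, b.t, return_indices=True)
    return common, a.v[ia], b.v[ib]


def cpp_series(abp: ChannelSeries, icp: ChannelSeries,
               width: float) -> ChannelSeries:
    """Cerebral perfusion pressure: block-mean ABP minus block-mean ICP.

    NaN in either block propagates to the CPP block.
    """
    if len(abp) == 0 or len(icp) == 0:
        raise ValueError("empty input series")
    lo = max(abp.t[0], icp.t[0])
    hi = min(abp.t[-1], icp.t[-1])
    if hi < lo:
        raise ValueError("ABP and ICP supports are disjoint")
    ab = block_average(abp, width)
    ib = block_average(icp, width)
    t, va, vi = align(ab, ib)
    if t.size == 0:
        raise ValueError("ABP and ICP share no blocks")
    return ChannelSeries("CPP", t, va - vi, "mmHg", 1.0 / width)
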