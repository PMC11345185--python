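"""Experiment-interval extraction and quality control.

The unit of analysis is a 100-140 min (nominally 2-h) window in which ABP,
ICP, and perfusion are jointly recorded.  Extraction finds maximal runs where
ABP and ICP are present and every perfusion gap is at most a tolerance
(default 10 min, accommodating probe recalibration), then tiles them
greedily, left to right, into non-overlapping intervals.

QC screens each interval on physical-unit thresholds:

i.   ABP negative anywhere, or above an epoch-level outlier threshold
     (a factor times the epoch's 99.8th percentile);
ii.  perfusion negative anywhere, any sample above 130 mL/hg/min, or any
     5-min mean above 95 mL/hg/min;
iii. ICP negative anywhere, or above 100 mmHg continuously for more than
     5 min (evaluated on 1-s averaged ICP; a run is broken by any sample at
     or below 100).

QC never raises on data content; every violated rule is reported with the
offending time ranges.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .channels import ChannelSeries, PatientEpoch, block_average

REQUIRED_CHANNELS = ("ABP", "ICP", "PERF")


@dataclass
class QCConfig:
    """Thresholds for the quality-control rules, in physical units."""

    abp_outlier_percentile: float = 99.8
    abp_outlier_factor: float = 1.1  # threshold = factor * epoch percentile
    perf_max: float = 130.0          # mL/hg/min, global sample cap
    perf_mean5_max: float = 95.0     # mL/hg/min, 5-min mean cap
    perf_mean_window_s: float = 300.0
    icp_max: float = 100.0           # mmHg
    icp_max_run_s: float = 300.0     # sustained-exceedance limit


@dataclass
class QCResult:
    """Outcome of :func:`qc_filter`: ``passed`` iff ``reasons`` is empty.

    ``reasons`` is a list of ``(rule_id, [(t0, t1), ...])`` pairs.
    """

    passed: bool
    reasons: list = field(default_factory=list)

    def rule_ids(self):
        return [r for r, _ in self.reasons]


@dataclass
class ExperimentInterval:
    """A candidate 100-140 min analysis window sliced from an epoch."""

    patient_id: str
    epoch_id: str
    start: float
    end: float
    channels: dict
    abp_reference_pct: Optional[float] = None  # epoch-level 99.8th percentile
    probe_quality: Optional[float] = None      # pass-through diagnostic flag
    qc: Optional[QCResult] = None

    @property
    def duration(self) -> float:
        return self.end - self.start

    def __getitem__(self, name: str) -> ChannelSeries:
        return self.channels[name]

    def __contains__(self, name: str) -> bool:
        return name in self.channels


def _valid_seconds(ch: ChannelSeries, n_sec: int) -> np.ndarray:
    """True for each second [s, s+1) containing at least one finite sample."""
    finite = np.isfinite(ch.v)
    sec = np.floor(ch.t).astype(np.int64)
    m = (sec >= 0) & (sec < n_sec)
    counts = np.bincount(sec[m & finite], minlength=n_sec)
    return counts > 0


def _runs(mask: np.ndarray):
    """(start, stop) index pairs of True runs (stop exclusive)."""
    if mask.size == 0:
        return []
    d = np.diff(mask.astype(np.int8))
    starts = list(np.nonzero(d == 1)[0] + 1)
    stops = list(np.nonzero(d == -1)[0] + 1)
    if mask[0]:
        starts.insert(0, 0)
    if mask[-1]:
        stops.append(mask.size)
    return list(zip(starts, stops))


def extract_intervals(
    epoch: PatientEpoch,
    min_len: float = 100 * 60.0,
    max_len: float = 140 * 60.0,
    perf_gap_tol: float = 10 * 60.0,
) -> list:
    """Tile joint-coverage runs into non-overlapping experiment intervals.

    A run is a maximal stretch of seconds where ABP and ICP are both present
    and every perfusion gap is at most ``perf_gap_tol`` seconds.  Runs are cut
    greedily left-to-right into ``max_len`` chunks; a final chunk survives if
    at least ``min_len``.  Runs shorter than ``min_len`` yield nothing.
    """
    for name in REQUIRED_CHANNELS:
        if name not in epoch:
            raise ValueError(f"epoch lacks required channel {name!r}")
    n_sec = int(np.ceil(epoch.duration)) + 1
    abp_ok = _valid_seconds(epoch["ABP"], n_sec)
    icp_ok = _valid_seconds(epoch["ICP"], n_sec)
    perf_ok = _valid_seconds(epoch["PERF"], n_sec)

    joint = abp_ok & icp_ok
    # split each ABP/ICP run at perfusion gaps longer than the tolerance
    pieces = []
    for a, b in _runs(joint):
        cut = a
        for ga, gb in _runs(~perf_ok[a:b]):
            if gb - ga > perf_gap_tol:
                pieces.append((cut, a + ga))
                cut = a + gb
        pieces.append((cut, b))

    abp_all = epoch["ABP"].v
    ref_pct = float(np.nanpercentile(abp_all, 99.8)) if np.isfinite(
        abp_all).any() else np.nan

    out = []
    for a, b in pieces:
        pos = float(a)
        while b - pos >= min_len:
            stop = min(pos + max_len, float(b))
            if stop - pos < min_len:
                break
            out.append(_make_interval(epoch, pos, stop, ref_pct))
            pos = stop
    return out


def _make_interval(epoch: PatientEpoch, start: float, end: float,
                   ref_pct: float) -> ExperimentInterval:
    chans = {n: c.slice(start, end) for n, c in epoch.channels.items()}
    return ExperimentInterval(epoch.patient_id, epoch.epoch_id, start, end,
                              chans, abp_reference_pct=ref_pct)


def _offense_ranges(t: np.ndarray, mask: np.ndarray) -> list:
    return [(float(t[a]), float(t[b - 1])) for a, b in _runs(mask)]


def qc_filter(interval: ExperimentInterval,
              rules: QCConfig | None = None) -> QCResult:
    """Apply the quality-control rules; never raises on data content."""
    cfg = rules or QCConfig()
    reasons = []

    abp = interval["ABP"]
    finite = np.isfinite(abp.v)
    neg = finite & (abp.v < 0)
    if neg.any():
        reasons.append(("abp_negative", _offense_ranges(abp.t, neg)))
    ref = interval.abp_reference_pct
    if ref is None or not np.isfinite(ref):
        ref = float(np.nanpercentile(abp.v, cfg.abp_outlier_percentile)) \
            if finite.any() else np.inf
    hi = finite & (abp.v > cfg.abp_outlier_factor * ref)
    if hi.any():
        reasons.append(("abp_outlier", _offense_ranges(abp.t, hi)))

    perf = interval["PERF"]
    pf = np.isfinite(perf.v)
    pneg = pf & (perf.v < 0)
    if pneg.any():
        reasons.append(("perf_negative", _offense_ranges(perf.t, pneg)))
    spike = pf & (perf.v > cfg.perf_max)
    if spike.any():
        reasons.append(("perf_spike", _offense_ranges(perf.t, spike)))
    if len(perf) >= 2:
        win = max(int(round(cfg.perf_mean_window_s / perf.step())), 1)
        roll = (pd.Series(perf.v).rolling(win, min_periods=win).mean()
                .to_numpy())
        over = np.isfinite(roll) & (roll > cfg.perf_mean5_max)
        if over.any():
            reasons.append(("perf_mean5", _offense_ranges(perf.t, over)))

    icp = interval["ICP"]
    inf = np.isfinite(icp.v)
    ineg = inf & (icp.v < 0)
    if ineg.any():
        reasons.append(("icp_negative", _offense_ranges(icp.t, ineg)))
    icp1 = block_average(icp, 1.0)  # sustained-plateau rule on 1-s means
    over = np.isfinite(icp1.v) & (icp1.v > cfg.icp_max)
    plateau = np.zeros_like(over)
    for a, b in _runs(over):
        if (b - a) * 1.0 > cfg.icp_max_run_s:
            plateau[a:b] = True
    if plateau.any():
        reasons.append(("icp_plateau", _offense_ranges(icp1.t, plateau)))

    return QCResult(passed=not reasons, reasons=reasons)
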