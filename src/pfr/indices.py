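"""Windowed cerebral-autoregulation indices Mx and PRx.

Both indices are moving-window Pearson correlations of block-averaged
signals:

* Mx — flow vs CPP, 30 correlations of 12-s averages (a 6-min window);
* PRx — ABP vs ICP, 30 correlations of 10-s averages (a 5-min window, the
  literature convention; the window scheme has no consensus and every
  parameter is configurable).

Windows advance by a configurable step (default 60 s) and are stamped at
their end time.  Windows with fewer than the full count of valid pairs, or
with zero variance in either signal, yield NaN.  Values above ~0.3 are the
conventional reading of impaired autoregulation for both indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .channels import ChannelSeries, align, block_average


@dataclass
class IndexSeries:
    """Windowed correlation index values with window bookkeeping."""

    name: str
    t: np.ndarray                 # window-end timestamps
    v: np.ndarray                 # correlations in [-1, 1] or NaN
    avg_width: float              # seconds per averaging block
    n_samples_per_window: int

    @property
    def window_span(self) -> float:
        return self.avg_width * self.n_samples_per_window

    def mean(self) -> float:
        """Mean over valid windows (the epoch-level summary)."""
        v = self.v[np.isfinite(self.v)]
        return float(v.mean()) if v.size else np.nan

    def median(self) -> float:
        v = self.v[np.isfinite(self.v)]
        return float(np.median(v)) if v.size else np.nan


def moving_corr(x: ChannelSeries, y: ChannelSeries, avg_width: float,
                n_samples: int, step: float, name: str = "corr") -> IndexSeries:
    """Moving-window Pearson correlation of block-averaged signals.

    Both inputs are block-averaged at ``avg_width`` seconds and aligned on
    common blocks; each window spans ``n_samples`` consecutive blocks and
    advances by ``step`` seconds (a multiple of ``avg_width``).
    """
    if step < avg_width:
        raise ValueError(f"step {step}s smaller than avg_width {avg_width}s")
    stride = int(round(step / avg_width))
    if not np.isclose(stride * avg_width, step):
        raise ValueError("step must be a multiple of avg_width")
    xb = block_average(x, avg_width)
    yb = block_average(y, avg_width)
    t, xv, yv = align(xb, yb)
    if len(t) < n_samples:
        raise ValueError(
            f"{len(t)} joint blocks cover less than one {n_samples}-block window")

    xw = sliding_window_view(xv, n_samples)[::stride]
    yw = sliding_window_view(yv, n_samples)[::stride]
    tw = t[n_samples - 1 :: stride][: len(xw)] + avg_width  # window ends

    valid = np.isfinite(xw) & np.isfinite(yw)
    full = valid.all(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        xm = xw - xw.mean(axis=1, keepdims=True)
        ym = yw - yw.mean(axis=1, keepdims=True)
        sx = np.sqrt((xm**2).sum(axis=1))
        sy = np.sqrt((ym**2).sum(axis=1))
        r = (xm * ym).sum(axis=1) / (sx * sy)
    r[~full | (sx == 0) | (sy == 0)] = np.nan
    return IndexSeries(name, tw, r, avg_width, n_samples)


def mx(flow: ChannelSeries, cpp: ChannelSeries, avg_width: float = 12.0,
       n_samples: int = 30, step: float = 60.0) -> IndexSeries:
    """Mean flow index: 30-sample correlations of 12-s flow/CPP averages."""
    return moving_corr(flow, cpp, avg_width, n_samples, step, name="Mx")


def prx(abp: ChannelSeries, icp: ChannelSeries, avg_width: float = 10.0,
        n_samples: int = 30, step: float = 60.0) -> IndexSeries:
    """Pressure reactivity index: correlations of averaged ABP and ICP."""
    return moving_corr(abp, icp, avg_width, n_samples, step, name="PRx")


@dataclass
class NeutralMxResult:
    """One-sided comparison of PRx between neutral-Mx and remaining epochs."""

    n_neutral: int
    n_rest: int
    mean_neutral: float
    mean_rest: float
    statistic: float
    p_value: float
    neutral_cut: float


def neutral_mx_compare(mx_epoch_means, prx_epoch_means,
                       neutral_cut: float = 0.15,
                       equal_var: bool = True) -> NeutralMxResult:
    """Test whether epochs with neutral Mx (|Mx| < cut) carry smaller PRx.

    Splits paired epoch-level means into a neutral group and the remainder
    and runs a one-sided two-sample t-test (alternative: neutral PRx
    smaller).  Each group needs at least two epochs.
    """
    mxv = np.asarray(mx_epoch_means, dtype=float)
    prv = np.asarray(prx_epoch_means, dtype=float)
    if mxv.shape != prv.shape:
        raise ValueError("Mx and PRx epoch means must be paired")
    ok = np.isfinite(mxv) & np.isfinite(prv)
    mxv, prv = mxv[ok], prv[ok]
    neutral = np.abs(mxv) < neutral_cut
    a, b = prv[neutral], prv[~neutral]
    if len(a) < 2 or len(b) < 2:
        raise ValueError(
            f"groups of {len(a)} and {len(b)} epochs; need >= 2 each")
    res = stats.ttest_ind(a, b, equal_var=equal_var, alternative="less")
    return NeutralMxResult(
        n_neutral=len(a), n_rest=len(b),
        mean_neutral=float(a.mean()), mean_rest=float(b.mean()),
        statistic=float(res.statistic), p_value=float(res.pvalue),
        neutral_cut=neutral_cut,
    )
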