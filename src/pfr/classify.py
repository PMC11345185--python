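"""Posterior calibration of model CBF to perfusion and regime labeling.

Global model CBF (mL/s) and local thermodiffusion perfusion (mL/hg/min) live
on different, patient- and probe-specific scales.  The calibration fits a
linear correction ``m * CBF + b`` after standardizing both signals to zero
mean and unit variance, so the slope ``m`` is a correlation-type quantity in
[-1, 1], uniform across probe placements.  Its sign and magnitude decide the
pressure-flow regime of the interval:

* ``m >  threshold``   -> pPFR (pressure-passive flow, impaired CA)
* ``m < -threshold``   -> nPFR (flow opposes pressure)
* ``|m| <= threshold`` -> zPFR (no net coordination)

with a default threshold of 0.2, boundary inclusive for zPFR.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .channels import ChannelSeries, align

LABELS = ("pPFR", "zPFR", "nPFR")
DEFAULT_THRESHOLD = 0.2
MIN_JOINT_SAMPLES = 30


@dataclass
class LinearCorrection:
    """Standardized slope ``m``, offset ``b`` (perfusion units), and the
    residual RMSE of the standardized fit."""

    m: float
    b: float
    rmse: float
    n_samples: int = 0


@dataclass
class PFRLabel:
    """Regime label with the slope and threshold that produced it."""

    label: str
    m: float
    threshold: float = DEFAULT_THRESHOLD


def _as_values(x) -> np.ndarray:
    return x.v if isinstance(x, ChannelSeries) else np.asarray(x, dtype=float)


def fit_correction(q_hat, perfusion,
                   min_samples: int = MIN_JOINT_SAMPLES) -> LinearCorrection:
    """Variance-standardized linear fit of model CBF to observed perfusion.

    Both series are standardized (mean removed, unit variance); ``m`` and the
    standardized intercept minimize the RMSE of ``m*q + b`` against perfusion,
    so ``m`` equals their Pearson correlation.  ``b`` is reported
    back-transformed to perfusion units.  NaN pairs are dropped listwise.
    """
    if isinstance(q_hat, ChannelSeries) and isinstance(perfusion, ChannelSeries):
        _, qv, pv = align(q_hat, perfusion)
    else:
        qv, pv = _as_values(q_hat), _as_values(perfusion)
        if len(qv) != len(pv):
            raise ValueError("series must be aligned (equal length)")
    joint = np.isfinite(qv) & np.isfinite(pv)
    qv, pv = qv[joint], pv[joint]
    n = len(qv)
    if n < min_samples:
        raise ValueError(f"{n} joint samples, need >= {min_samples}")
    sq, sp = float(np.std(qv)), float(np.std(pv))
    if sq == 0 or sp == 0:
        raise ValueError("zero variance: standardization undefined")
    qs = (qv - qv.mean()) / sq
    ps = (pv - pv.mean()) / sp
    m = float(np.mean(qs * ps))           # OLS slope on standardized signals
    rmse = float(np.sqrt(np.mean((ps - m * qs) ** 2)))
    b = float(pv.mean() - m * (sp / sq) * qv.mean())  # perfusion units
    return LinearCorrection(m=m, b=b, rmse=rmse, n_samples=n)


def classify_pfr(corr: LinearCorrection,
                 threshold: float = DEFAULT_THRESHOLD) -> PFRLabel:
    """Label the regime from the correction slope.

    The printed rule's negative branch is ``m < -threshold`` so that the
    three labels are exhaustive and exclusive over finite ``m``.
    """
    m = corr.m if isinstance(corr, LinearCorrection) else float(corr)
    if not np.isfinite(m):
        raise ValueError("slope m must be finite")
    if m > threshold:
        label = "pPFR"
    elif m < -threshold:
        label = "nPFR"
    else:
        label = "zPFR"
    return PFRLabel(label=label, m=m, threshold=threshold)


class PFRSlopeClassifier:
    """Scikit-learn-style estimator: fit the standardized correction and
    expose the slope, offset, and regime label as fitted attributes."""

    def __init__(self, threshold: float = DEFAULT_THRESHOLD,
                 min_samples: int = MIN_JOINT_SAMPLES):
        self.threshold = threshold
        self.min_samples = min_samples

    def get_params(self, deep: bool = True) -> dict:
        return {"threshold": self.threshold, "min_samples": self.min_samples}

    def set_params(self, **params) -> "PFRSlopeClassifier":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, q_hat, perfusion) -> "PFRSlopeClassifier":
        corr = fit_correction(q_hat, perfusion, min_samples=self.min_samples)
        self.m_ = corr.m
        self.b_ = corr.b
        self.rmse_ = corr.rmse
        self.n_samples_ = corr.n_samples
        self.label_ = classify_pfr(corr, self.threshold).label
        return self

    def predict(self, m=None):
        """Label for a slope value (default: the fitted slope)."""
        if m is None:
            if not hasattr(self, "m_"):
                raise ValueError("estimator is not fitted")
            return self.label_
        m = np.atleast_1d(np.asarray(m, dtype=float))
        out = np.where(m > self.threshold, "pPFR",
                       np.where(m < -self.threshold, "nPFR", "zPFR"))
        return out if out.size > 1 else str(out[0])
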