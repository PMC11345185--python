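"""Synthetic multimodal neuromonitoring epochs with known pressure-flow regimes.

The generator emulates the channel inventory of an invasive neuromonitoring
bed: pulsatile arterial blood pressure (ABP, 125 Hz), slowly varying
intracranial pressure (ICP, 125 Hz), and thermodiffusion brain-tissue
perfusion (PERF, 1 Hz).  Perfusion is constructed with a prescribed, signed
coordination to cerebral perfusion pressure (CPP = ABP - ICP):

* ``pPFR`` — constant positive gain: perfusion tracks CPP (pressure-passive
  flow, impaired autoregulation);
* ``nPFR`` — constant negative gain: perfusion opposes CPP;
* ``zPFR`` — gain alternates +g/-g in equal-duration blocks (default 15 min),
  emulating a balance of positive and negative coordination with no net
  relationship over the 2-h interval.

Slow CPP variability is a seeded sum of three sinusoids with periods in the
1-10 min band plus an AR(1) drift, so that the Mx/PRx correlation windows see
energy at the timescales they average over.  ICP carries a small positive
dependence on the ABP slow component (default gain 0.2) so PRx is exercised
over its range.  Probe-placement heterogeneity is emulated by a seeded
per-epoch perfusion baseline/scale jitter.  Identical specs (including the
seed) produce byte-identical epochs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import lfilter

from .channels import ChannelSeries, PatientEpoch

REGIMES = ("pPFR", "zPFR", "nPFR")

ABP_RATE = 125.0
PERF_RATE = 1.0

#: default per-channel observation-noise standard deviations
DEFAULT_NOISE_SD = {"ABP": 1.0, "ICP": 0.5, "PERF": 2.0}


class SpecValidationError(ValueError):
    """Raised when a SyntheticSpec field is out of contract."""


@dataclass
class SyntheticSpec:
    """Recipe for one labeled epoch.

    Parameters
    ----------
    regime : str
        One of ``pPFR``, ``zPFR``, ``nPFR``.
    duration_min : float
        Epoch length in minutes.
    heart_rate : float
        Beats per minute, within [30, 200].
    abp_mean, pulse_pressure, icp_mean : float
        Waveform levels in mmHg.
    slow_fluctuation_scale : float
        Standard deviation (mmHg) of the 1-10 min sinusoidal CPP variability.
    coupling_gain : float
        Signed CPP-to-perfusion gain in (mL/hg/min)/mmHg.  Positive for pPFR,
        negative for nPFR; for zPFR the magnitude is used in an alternating
        +g/-g schedule.
    noise_sd : dict
        Per-channel observation noise sd, keys among {ABP, ICP, PERF}.
    gap_spec : list of (channel, start_s, length_s)
        NaN runs to punch into channels.
    defect_spec : list of dict
        QC-violating artifacts, applied via :func:`inject_defects`.
    seed : int
        Master seed; same spec => byte-identical output.
    """

    regime: str
    duration_min: float = 120.0
    heart_rate: float = 70.0
    abp_mean: float = 90.0
    pulse_pressure: float = 40.0
    icp_mean: float = 12.0
    slow_fluctuation_scale: float = 5.0
    coupling_gain: float = 1.0
    zpfr_block_min: float = 15.0
    icp_abp_gain: float = 0.2
    perf_baseline: float = 30.0
    noise_sd: dict = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    gap_spec: list = field(default_factory=list)
    defect_spec: list = field(default_factory=list)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.regime not in REGIMES:
            raise SpecValidationError(f"regime: {self.regime!r} not in {REGIMES}")
        if not self.duration_min > 0:
            raise SpecValidationError("duration_min: must be > 0")
        if not 30.0 <= self.heart_rate <= 200.0:
            raise SpecValidationError("heart_rate: must lie in [30, 200]")
        if self.pulse_pressure < 0:
            raise SpecValidationError("pulse_pressure: must be >= 0")
        if self.slow_fluctuation_scale < 0:
            raise SpecValidationError("slow_fluctuation_scale: must be >= 0")
        if self.regime == "pPFR" and self.coupling_gain <= 0:
            raise SpecValidationError("coupling_gain: must be > 0 for pPFR")
        if self.regime == "nPFR" and self.coupling_gain >= 0:
            raise SpecValidationError("coupling_gain: must be < 0 for nPFR")
        if self.zpfr_block_min <= 0:
            raise SpecValidationError("zpfr_block_min: must be > 0")
        for ch, start, length in self.gap_spec:
            if length > self.duration_min * 60.0:
                raise SpecValidationError(
                    f"gap_spec: gap of {length}s on {ch} exceeds epoch duration"
                )

    @classmethod
    def for_regime(cls, regime: str, seed: int = 0,
                   gain_magnitude: float = 1.0, **kw) -> "SyntheticSpec":
        """Spec with the coupling-gain sign set by the regime."""
        gain = -gain_magnitude if regime == "nPFR" else gain_magnitude
        return cls(regime=regime, coupling_gain=gain, seed=seed, **kw)


@dataclass
class LabeledEpoch:
    """A generated epoch plus its ground truth.

    ``gain_schedule`` holds the generating CPP->perfusion gain per 1-min
    block (timestamps at block starts), covering the full epoch.
    """

    epoch: PatientEpoch
    regime: str
    gain_schedule_t: np.ndarray
    gain_schedule: np.ndarray


def _rng(spec: SyntheticSpec, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(spec.seed), stream]))


#: period bands (seconds) for the three slow sinusoids; keeping the bands
#: disjoint prevents beat envelopes slower than the analysis window, which
#: would otherwise unbalance equal-duration coupling blocks
SLOW_PERIOD_BANDS = ((60.0, 120.0), (150.0, 300.0), (380.0, 600.0))


def _slow_component(spec: SyntheticSpec, n_sec: int, stream: int) -> np.ndarray:
    """Seeded slow variability at 1 Hz: three 1-10 min sinusoids (one per
    separated period band) plus a small AR(1) drift; total sd = scale."""
    rng = _rng(spec, stream)
    t = np.arange(n_sec, dtype=float)
    scale = spec.slow_fluctuation_scale
    out = np.zeros(n_sec)
    periods = np.array([rng.uniform(a, b) for a, b in SLOW_PERIOD_BANDS])
    phases = rng.uniform(0.0, 2.0 * np.pi, size=3)
    amp = scale * np.sqrt(2.0 / 3.0) * np.sqrt(0.9)  # 90% of variance
    for p, ph in zip(periods, phases):
        out += amp * np.sin(2.0 * np.pi * t / p + ph)
    # AR(1) drift at 1 Hz with ~minute-scale memory, 10% of variance
    phi = 0.98
    innov_sd = scale * np.sqrt(0.1) * np.sqrt(1.0 - phi**2)
    drift = lfilter([1.0], [1.0, -phi], rng.normal(0.0, innov_sd, size=n_sec))
    out += drift
    if n_sec > 0:
        out -= out.mean()
    return out


def _upsample(x_1hz: np.ndarray, n_hi: int, rate: float) -> np.ndarray:
    """Linear interpolation of a 1 Hz component onto the waveform grid."""
    t_hi = np.arange(n_hi) / rate
    t_lo = np.arange(len(x_1hz), dtype=float)
    return np.interp(t_hi, t_lo, x_1hz)


def _pulse_train(spec: SyntheticSpec, n: int) -> np.ndarray:
    """Cardiac pulse shape: half-sinusoid systolic upstroke, exponential
    diastolic decay; peak-to-trough amplitude = pulse_pressure, zero mean."""
    if spec.pulse_pressure == 0:
        return np.zeros(n)
    t = np.arange(n) / ABP_RATE
    beat = 60.0 / spec.heart_rate
    phase = np.mod(t, beat) / beat
    sys_frac, tau = 0.3, 0.2
    shape = np.where(
        phase < sys_frac,
        np.sin(0.5 * np.pi * phase / sys_frac),
        np.exp(-(phase - sys_frac) / tau),
    )
    lo = float(np.exp(-(1.0 - sys_frac) / tau))
    pulse = spec.pulse_pressure * (shape - lo) / (1.0 - lo)
    return pulse - pulse.mean()


def generate_pulsatile_abp(spec: SyntheticSpec) -> ChannelSeries:
    """Pulsatile 125 Hz arterial blood pressure.

    ABP = mean level + slow fluctuations + cardiac pulse train + Gaussian
    noise; the deterministic components are demeaned so the series mean stays
    within the noise floor of ``abp_mean``.
    """
    n_sec = int(round(spec.duration_min * 60.0))
    n = int(round(n_sec * ABP_RATE))
    slow = _upsample(_slow_component(spec, n_sec, stream=1), n, ABP_RATE)
    pulse = _pulse_train(spec, n)
    noise_sd = spec.noise_sd.get("ABP", 0.0)
    noise = _rng(spec, 2).normal(0.0, noise_sd, size=n) if noise_sd > 0 else 0.0
    v = spec.abp_mean + slow + pulse + noise
    t = np.arange(n) / ABP_RATE
    return ChannelSeries("ABP", t, v, "mmHg", ABP_RATE)


def _generate_icp(spec: SyntheticSpec, abp_slow_1hz: np.ndarray) -> ChannelSeries:
    """125 Hz ICP: mean level + own slow variability + a small positive
    dependence on the ABP slow component (exercises PRx)."""
    n_sec = len(abp_slow_1hz)
    n = int(round(n_sec * ABP_RATE))
    own = _slow_component(spec, n_sec, stream=3)
    icp_1hz = (spec.icp_mean + spec.icp_abp_gain * abp_slow_1hz + 0.3 * own)
    v = _upsample(icp_1hz, n, ABP_RATE)
    noise_sd = spec.noise_sd.get("ICP", 0.0)
    if noise_sd > 0:
        v = v + _rng(spec, 4).normal(0.0, noise_sd, size=n)
    t = np.arange(n) / ABP_RATE
    return ChannelSeries("ICP", t, v, "mmHg", ABP_RATE)


def _gain_schedule_1hz(spec: SyntheticSpec, n_sec: int) -> np.ndarray:
    g = abs(spec.coupling_gain)
    if spec.regime == "pPFR":
        return np.full(n_sec, g)
    if spec.regime == "nPFR":
        return np.full(n_sec, -g)
    block = int(round(spec.zpfr_block_min * 60.0))
    k = np.arange(n_sec) // block
    sign = np.where(k % 2 == 0, 1.0, -1.0)
    return g * sign


def generate_regime_epoch(spec: SyntheticSpec) -> LabeledEpoch:
    """Generate a labeled epoch with the prescribed pressure-flow regime.

    Perfusion is ``baseline + gain(t) * (CPP(t) - mean CPP) + noise`` at 1 Hz,
    where gain follows the regime schedule; CPP is the 1-s mean ABP-ICP
    difference of the generated waveforms.  Requested gaps and defects are
    injected and the generating gain is recorded per 1-min block.
    """
    n_sec = int(round(spec.duration_min * 60.0))
    abp = generate_pulsatile_abp(spec)
    abp_slow = _slow_component(spec, n_sec, stream=1)
    icp = _generate_icp(spec, abp_slow)

    # 1-s mean CPP of the noiseless slow structure drives perfusion; the
    # cardiac pulse averages out of 1-s blocks by construction.
    icp_slow = spec.icp_abp_gain * abp_slow + 0.3 * _slow_component(spec, n_sec, 3)
    cpp_1hz = (spec.abp_mean + abp_slow) - (spec.icp_mean + icp_slow)
    anom = cpp_1hz - cpp_1hz.mean()

    gain = _gain_schedule_1hz(spec, n_sec)
    rng = _rng(spec, 5)
    baseline = spec.perf_baseline + rng.normal(0.0, 3.0)
    probe_scale = float(np.exp(rng.normal(0.0, 0.1)))
    noise_sd = spec.noise_sd.get("PERF", 0.0)
    noise = rng.normal(0.0, noise_sd, size=n_sec) if noise_sd > 0 else 0.0
    perf_v = baseline + probe_scale * gain * anom + noise
    perf = ChannelSeries("PERF", np.arange(n_sec, dtype=float), perf_v,
                         "mL/hg/min", PERF_RATE)

    epoch = PatientEpoch(f"synthetic-{spec.seed}", f"{spec.regime}-{spec.seed}")
    epoch.add(abp)
    epoch.add(icp)
    epoch.add(perf)

    for ch, start, length in spec.gap_spec:
        _punch_nan(epoch[ch], start, length)
    if spec.defect_spec:
        epoch = inject_defects(epoch, spec.defect_spec)

    block_starts = np.arange(0, n_sec, 60, dtype=float)
    gain_min = probe_scale * gain[::60][: len(block_starts)]
    return LabeledEpoch(epoch, spec.regime, block_starts, gain_min)


def _punch_nan(ch: ChannelSeries, start: float, length: float) -> None:
    m = (ch.t >= start) & (ch.t < start + length)
    ch.v[m] = np.nan


DEFECT_KINDS = ("abp_negative", "perf_spike", "perf_high_mean",
                "icp_plateau", "nan_gap")


def inject_defects(epoch: PatientEpoch, defects: list) -> PatientEpoch:
    """Return a copy of ``epoch`` with QC-violating artifacts written.

    Each defect descriptor is a dict with a ``kind`` key:

    * ``abp_negative``: ABP set to ``value`` (default -5 mmHg) over
      [start, start+length);
    * ``perf_spike``: single perfusion sample at ``start`` set to ``value``
      (default 140 mL/hg/min);
    * ``perf_high_mean``: perfusion set to ``value`` (default 96) over
      [start, start+length) (default 300 s) so a 5-min mean exceeds 95;
    * ``icp_plateau``: ICP set to ``value`` (default 101 mmHg) over
      [start, start+length) (default 360 s);
    * ``nan_gap``: NaN run on ``channel`` over [start, start+length).

    The original epoch is untouched.
    """
    out = epoch.copy()
    dur = out.duration
    for d in defects:
        kind = d.get("kind")
        if kind not in DEFECT_KINDS:
            raise SpecValidationError(f"unknown defect kind {kind!r}")
        start = float(d.get("start", 0.0))
        if not 0.0 <= start <= dur:
            raise SpecValidationError(
                f"defect {kind}: start {start}s outside epoch [0, {dur}]s"
            )
        if kind == "abp_negative":
            length = float(d.get("length", 1.0))
            _set_range(out["ABP"], start, length, float(d.get("value", -5.0)))
        elif kind == "perf_spike":
            ch = out["PERF"]
            i = int(np.argmin(np.abs(ch.t - start)))
            ch.v[i] = float(d.get("value", 140.0))
        elif kind == "perf_high_mean":
            length = float(d.get("length", 300.0))
            _set_range(out["PERF"], start, length, float(d.get("value", 96.0)))
        elif kind == "icp_plateau":
            length = float(d.get("length", 360.0))
            _set_range(out["ICP"], start, length, float(d.get("value", 101.0)))
        elif kind == "nan_gap":
            _punch_nan(out[d["channel"]], start, float(d.get("length", 60.0)))
    return out


def _set_range(ch: ChannelSeries, start: float, length: float,
               value: float) -> None:
    m = (ch.t >= start) & (ch.t < start + length)
    ch.v[m] = value
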