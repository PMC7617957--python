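"""Intracellular sweep analysis: light-evoked EPSPs, the paired
input-bias index, and intrinsic membrane properties.

EPSP amplitude is measured on the average of 10-40 sweeps relative to a
50 ms pre-light baseline; the onset is the first crossing of
baseline + 2 SD(baseline) before the peak, linearly interpolated.  The
bias index for a simultaneously recorded pair is
``A_ip / (A_ip + A_op)`` so 0.5 means equal input strength.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "PairedSweepSet",
    "PairBiasResult",
    "IntrinsicResult",
    "EpspMeasure",
    "measure_epsp",
    "gate_monosynaptic",
    "pair_bias",
    "analyze_pair",
    "intrinsic_properties",
]

BASELINE_MS = 50.0
PEAK_SEARCH_MS = (1.0, 50.0)
MONOSYNAPTIC_MAX_LATENCY_MS = 6.0
DVDT_THRESHOLD = 20.0  # mV/ms spike-threshold criterion


@dataclass
class PairedSweepSet:
    """Sweeps for one simultaneously recorded IP/OP pair.

    ``t_ms`` is shared by both cells and aligned so the light onset is
    at t = 0 ms; sweep matrices are (n_sweeps, n_samples) in mV.
    """

    pair_id: str
    nucleus: str  # "VPM" | "POm"
    t_ms: np.ndarray
    sweeps_ip: np.ndarray
    sweeps_op: np.ndarray

    def __post_init__(self) -> None:
        if self.nucleus not in ("VPM", "POm"):
            raise ValueError("nucleus must be VPM or POm")
        self.t_ms = np.asarray(self.t_ms, dtype=float)
        self.sweeps_ip = np.atleast_2d(np.asarray(self.sweeps_ip, dtype=float))
        self.sweeps_op = np.atleast_2d(np.asarray(self.sweeps_op, dtype=float))
        for name, sw in (("ip", self.sweeps_ip), ("op", self.sweeps_op)):
            if sw.shape[1] != self.t_ms.size:
                raise ValueError(f"sweeps_{name} do not match the time base")
            if not (10 <= sw.shape[0] <= 40):
                raise ValueError(f"sweeps_{name}: n_sweeps must be in [10, 40]")


@dataclass
class EpspMeasure:
    amplitude_mv: float  # 0 when no response
    onset_ms: float  # NaN when no response
    responded: bool


@dataclass
class PairBiasResult:
    pair_id: str
    nucleus: str
    a_ip: float
    a_op: float
    onset_ip_ms: float
    onset_op_ms: float
    bias: float
    monosynaptic_ok: bool


def measure_epsp(
    sweeps: np.ndarray,
    t_ms: np.ndarray,
    baseline_ms: float = BASELINE_MS,
    peak_window_ms: tuple[float, float] = PEAK_SEARCH_MS,
    noise_criterion_sd: float = 2.0,
) -> EpspMeasure:
    """Measure EPSP amplitude and onset latency from averaged sweeps.

    The sweep average is referenced to the mean of the ``baseline_ms``
    pre-light segment.  Amplitude is the maximum deflection in
    ``(1, 50]`` ms post-light; if the peak does not exceed
    ``noise_criterion_sd`` baseline SDs the cell is scored as
    non-responding (amplitude 0, onset NaN).  The onset is where the
    rising phase first crosses baseline + 2 SD, linearly interpolated.

    Raises
    ------
    ValueError
        With fewer than 10 sweeps or no pre-light baseline segment.
    """
    sweeps = np.atleast_2d(np.asarray(sweeps, dtype=float))
    t_ms = np.asarray(t_ms, dtype=float)
    if sweeps.shape[0] < 10:
        raise ValueError("need at least 10 sweeps to average")
    base_sel = (t_ms >= -baseline_ms) & (t_ms < 0)
    if not np.any(base_sel):
        raise ValueError("no pre-light baseline segment available")
    avg = sweeps.mean(axis=0)
    baseline = float(avg[base_sel].mean())
    base_sd = float(avg[base_sel].std(ddof=1))
    v = avg - baseline

    lo, hi = peak_window_ms
    win = (t_ms > lo) & (t_ms <= hi)
    peak_rel = int(np.argmax(v[win]))
    peak_idx = np.flatnonzero(win)[peak_rel]
    amplitude = float(v[peak_idx])
    if amplitude <= noise_criterion_sd * base_sd:
        return EpspMeasure(amplitude_mv=0.0, onset_ms=float("nan"),
                           responded=False)

    thr = 2.0 * base_sd
    # walk back from the peak to the last sub-threshold sample
    post = np.flatnonzero(t_ms > 0)
    start = post[0]
    onset = float("nan")
    i = peak_idx
    while i > start and v[i - 1] > thr:
        i -= 1
    if i > 0 and v[i] >= thr and v[i - 1] < thr:
        # linear interpolation between samples i-1 and i
        f = (thr - v[i - 1]) / (v[i] - v[i - 1])
        onset = float(t_ms[i - 1] + f * (t_ms[i] - t_ms[i - 1]))
    else:
        onset = float(t_ms[i])
    return EpspMeasure(amplitude_mv=amplitude, onset_ms=onset, responded=True)


def gate_monosynaptic(
    onset_ms: float,
    max_latency_ms: float = MONOSYNAPTIC_MAX_LATENCY_MS,
) -> bool:
    """True iff the onset latency is defined and <= ``max_latency_ms``."""
    return bool(np.isfinite(onset_ms) and onset_ms <= max_latency_ms)


def pair_bias(a_ip: float, a_op: float) -> float:
    """Input-strength bias ``a_ip / (a_ip + a_op)`` in [0, 1].

    0.5 means equal input to the IP- and OP-derived cell of the pair.

    Raises
    ------
    ValueError
        If both amplitudes are zero (or the sum is non-positive).
    """
    if a_ip < 0 or a_op < 0:
        raise ValueError("amplitudes must be >= 0")
    total = a_ip + a_op
    if total <= 0:
        raise ValueError("both amplitudes are zero: bias undefined")
    return a_ip / total


def analyze_pair(
    pair: PairedSweepSet,
    max_latency_ms: float = MONOSYNAPTIC_MAX_LATENCY_MS,
) -> PairBiasResult:
    """Measure both cells of a pair and compute the bias index."""
    m_ip = measure_epsp(pair.sweeps_ip, pair.t_ms)
    m_op = measure_epsp(pair.sweeps_op, pair.t_ms)
    bias = pair_bias(m_ip.amplitude_mv, m_op.amplitude_mv)
    mono = gate_monosynaptic(m_ip.onset_ms, max_latency_ms) and \
        gate_monosynaptic(m_op.onset_ms, max_latency_ms)
    return PairBiasResult(
        pair_id=pair.pair_id, nucleus=pair.nucleus,
        a_ip=m_ip.amplitude_mv, a_op=m_op.amplitude_mv,
        onset_ip_ms=m_ip.onset_ms, onset_op_ms=m_op.onset_ms,
        bias=bias, monosynaptic_ok=mono,
    )


@dataclass
class IntrinsicResult:
    rmp_mv: float
    spike_threshold_mv: float  # NaN when no spikes
    spike_amplitude_mv: float
    spike_frequency_hz: dict  # current (pA) -> Hz during the step
    isis_ms: dict  # current (pA) -> list of inter-spike intervals


def _detect_spikes(v: np.ndarray, t_ms: np.ndarray,
                   dvdt_thr: float = DVDT_THRESHOLD):
    """Spike onsets by upward dV/dt crossings; returns (indices, thresholds)."""
    dvdt = np.gradient(v, t_ms)
    above = dvdt >= dvdt_thr
    onsets = np.flatnonzero(above[1:] & ~above[:-1]) + 1
    # merge crossings within the same spike (2 ms refractory)
    kept = []
    for i in onsets:
        if not kept or t_ms[i] - t_ms[kept[-1]] > 2.0:
            kept.append(int(i))
    return kept


def intrinsic_properties(
    sweeps_by_current: dict,
    t_ms: np.ndarray,
    stim_window_ms: tuple[float, float],
    dvdt_thr: float = DVDT_THRESHOLD,
) -> IntrinsicResult:
    """Intrinsic properties from a current-step protocol.

    Parameters
    ----------
    sweeps_by_current : dict
        Injected current (pA) -> (n_sweeps, n_samples) voltage in mV.
        The 0 pA sweeps provide the resting membrane potential.
    t_ms : ndarray
        Shared time base; the step occupies ``stim_window_ms``.

    Raises
    ------
    ValueError
        When no 0 pA sweeps are present (RMP undefined).
    """
    t_ms = np.asarray(t_ms, dtype=float)
    if 0 not in sweeps_by_current:
        raise ValueError("no 0 pA sweeps: resting potential undefined")
    lo, hi = stim_window_ms
    pre = t_ms < lo
    zero = np.atleast_2d(np.asarray(sweeps_by_current[0], dtype=float))
    rmp = float(zero[:, pre].mean())

    freqs: dict = {}
    isis: dict = {}
    thresholds, amplitudes = [], []
    step_dur_s = (hi - lo) / 1e3
    in_step = (t_ms >= lo) & (t_ms <= hi)
    for current, sw in sweeps_by_current.items():
        sw = np.atleast_2d(np.asarray(sw, dtype=float))
        n_spk, sweep_isis = 0, []
        for trace in sw:
            idx = [i for i in _detect_spikes(trace, t_ms, dvdt_thr)
                   if in_step[i]]
            n_spk += len(idx)
            times = t_ms[idx]
            sweep_isis.extend(np.diff(times).tolist())
            for i in idx:
                thr_v = trace[i]
                peak = trace[i:i + max(int(len(t_ms) * 0.01), 50)].max()
                thresholds.append(thr_v)
                amplitudes.append(peak - thr_v)
        freqs[current] = n_spk / (sw.shape[0] * step_dur_s)
        isis[current] = sweep_isis
    return IntrinsicResult(
        rmp_mv=rmp,
        spike_threshold_mv=float(np.mean(thresholds)) if thresholds else float("nan"),
        spike_amplitude_mv=float(np.mean(amplitudes)) if amplitudes else float("nan"),
        spike_frequency_hz=freqs,
        isis_ms=isis,
    )
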