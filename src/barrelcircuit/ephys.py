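"""Signal conditioning, multiunit detection, CSD, laminar assignment and
unit classification for laminar probe recordings.

Conventions
-----------
* Filters are zero-phase (forward-backward) 4th-order Butterworth; the
  mains notch is a Q=30 IIR notch at 50 Hz.  Zero-phase filtering keeps
  response latencies unbiased, which every downstream statistic uses.
* CSD is the central second spatial difference of the LFP; a *sink* is a
  local minimum.  Edge channels are undefined and dropped.
* Waveform classes: trough-to-peak >= 0.5 ms -> RS, < 0.5 ms -> FS (the
  boundary itself is assigned to RS).
* Optotagged units: mean first-spike latency < 5 ms after light onset
  AND response reliability >= a configurable floor (default 0.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal

from .core import CsdProfile, ProbeRecording, SpikeUnit, StimulusLog

__all__ = [
    "split_bands",
    "detect_mua",
    "compute_csd",
    "assign_layers",
    "classify_waveform",
    "classify_optotag",
    "OptotagResult",
    "MUA_BAND",
    "LFP_CUTOFF",
    "NOTCH_FREQ",
]

MUA_BAND = (300.0, 6000.0)
LFP_CUTOFF = 300.0
NOTCH_FREQ = 50.0
NOTCH_Q = 30.0
T2P_BOUNDARY_MS = 0.5
OPTOTAG_MAX_LATENCY_MS = 5.0


def split_bands(rec: ProbeRecording) -> tuple[np.ndarray, np.ndarray]:
    """Split a wideband recording into MUA (300-6000 Hz) and LFP bands.

    The LFP band is low-passed below 300 Hz and notch-filtered at 50 Hz.
    Both outputs have the same shape as the input.

    Raises
    ------
    ValueError
        If ``rec.fs`` is below 12 kHz (Nyquist margin for the MUA band).
    """
    if rec.fs < 2 * MUA_BAND[1]:
        raise ValueError(
            f"fs={rec.fs} Hz too low for a {MUA_BAND[1]} Hz band edge "
            f"(need >= {2 * MUA_BAND[1]} Hz)"
        )
    sos_mua = signal.butter(4, MUA_BAND, btype="bandpass", fs=rec.fs, output="sos")
    mua = signal.sosfiltfilt(sos_mua, rec.samples, axis=-1)

    sos_lfp = signal.butter(4, LFP_CUTOFF, btype="lowpass", fs=rec.fs, output="sos")
    lfp = signal.sosfiltfilt(sos_lfp, rec.samples, axis=-1)
    b, a = signal.iirnotch(NOTCH_FREQ, NOTCH_Q, fs=rec.fs)
    lfp = signal.filtfilt(b, a, lfp, axis=-1)
    return mua, lfp


def mad_sigma(x: np.ndarray) -> float:
    """Robust noise SD: median(|x - median(x)|) / 0.6745."""
    x = np.asarray(x, dtype=float)
    return float(np.median(np.abs(x - np.median(x))) / 0.6745)


def detect_mua(
    trace: np.ndarray,
    fs: float,
    k: float = 5.0,
    lockout_ms: float = 1.0,
) -> np.ndarray:
    """Detect multiunit events by MAD thresholding of a filtered trace.

    Events are negative-going crossings of ``-k * sigma_hat`` where
    ``sigma_hat`` is the MAD-based noise SD; crossings within
    ``lockout_ms`` of the previous event are suppressed.

    Returns
    -------
    ndarray
        Sorted event times in seconds.

    Raises
    ------
    ValueError
        If the MAD estimate is zero (e.g. a constant trace).
    """
    trace = np.asarray(trace, dtype=float)
    if trace.ndim != 1:
        raise ValueError("detect_mua expects a single-channel trace")
    sigma = mad_sigma(trace)
    if sigma == 0.0:
        raise ValueError("MAD noise estimate is zero; cannot threshold")
    thr = -k * sigma
    below = trace < thr
    crossings = np.flatnonzero(below[1:] & ~below[:-1]) + 1
    if crossings.size == 0:
        return np.empty(0)
    lockout = lockout_ms / 1e3 * fs
    kept = [crossings[0]]
    for c in crossings[1:]:
        if c - kept[-1] >= lockout:
            kept.append(c)
    return np.asarray(kept, dtype=float) / fs


def compute_csd(
    lfp: np.ndarray,
    spacing: float,
    times: Optional[np.ndarray] = None,
    smooth: bool = False,
) -> CsdProfile:
    """Central second spatial difference of the LFP across channels.

    ``csd[i] = (lfp[i-1] - 2 lfp[i] + lfp[i+1]) / spacing**2`` for
    interior channels; edges are dropped.  With ``smooth=True`` a
    3-channel Hamming kernel is applied along the channel axis first.

    Raises
    ------
    ValueError
        For fewer than 3 channels.
    """
    lfp = np.atleast_2d(np.asarray(lfp, dtype=float))
    if lfp.shape[0] < 3:
        raise ValueError("CSD needs at least 3 channels")
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if smooth:
        w = np.hamming(3)
        w /= w.sum()
        pad = np.pad(lfp, ((1, 1), (0, 0)), mode="edge")
        lfp = (
            w[0] * pad[:-2] + w[1] * pad[1:-1] + w[2] * pad[2:]
        )
    values = (lfp[:-2] - 2.0 * lfp[1:-1] + lfp[2:]) / spacing**2
    channels = np.arange(1, lfp.shape[0] - 1)
    if times is None:
        times = np.arange(lfp.shape[1], dtype=float)
    return CsdProfile(values=values, channels=channels, times=np.asarray(times, float),
                      spacing=float(spacing))


def assign_layers(
    csd: CsdProfile,
    onset_time: float = 0.0,
    sink_threshold_frac: float = 0.3,
) -> dict:
    """Assign layers from the deflection-triggered CSD.

    Per interior channel, the sink latency is the first time after
    ``onset_time`` at which the CSD crosses below
    ``sink_threshold_frac * global_minimum``.  The channel with the
    shortest latency is L4 (ties broken by the deeper/more negative
    sink); channels superficial to it are L2/3, the rest below-L4.

    Returns
    -------
    dict
        ``l4_channel`` (probe index), ``sink_latency`` (same units as
        ``csd.times``), and ``layers`` mapping channel index to one of
        ``{"L2/3", "L4", "below-L4"}``.

    Raises
    ------
    ValueError
        If no channel crosses the sink threshold ("no identifiable sink").
    """
    global_min = float(csd.values.min())
    if global_min >= 0:
        raise ValueError("no identifiable sink: CSD never negative")
    thr = sink_threshold_frac * global_min  # negative
    after = csd.times >= onset_time
    if not np.any(after):
        raise ValueError("onset_time beyond the CSD time axis")
    vals = csd.values[:, after]
    t_after = csd.times[after]

    latencies = np.full(vals.shape[0], np.inf)
    amplitudes = np.zeros(vals.shape[0])
    for i in range(vals.shape[0]):
        idx = np.flatnonzero(vals[i] <= thr)
        if idx.size:
            latencies[i] = t_after[idx[0]]
            amplitudes[i] = vals[i].min()
    if not np.isfinite(latencies).any():
        raise ValueError("no identifiable sink: no channel crosses threshold")
    best_lat = latencies.min()
    tied = np.flatnonzero(latencies == best_lat)
    # ties -> the larger-amplitude (more negative) sink
    row = tied[np.argmin(amplitudes[tied])]
    l4_channel = int(csd.channels[row])
    layers = {}
    for r, ch in enumerate(csd.channels):
        if ch < l4_channel:
            layers[int(ch)] = "L2/3"
        elif ch == l4_channel:
            layers[int(ch)] = "L4"
        else:
            layers[int(ch)] = "below-L4"
    return {"l4_channel": l4_channel, "sink_latency": float(best_lat), "layers": layers}


def waveform_trough_to_peak(waveform: np.ndarray, fs: float) -> float:
    """Trough-to-peak time (ms) of a waveform template.

    Time from the template minimum to the subsequent maximum.

    Raises
    ------
    ValueError
        If the trough is the last sample (no post-trough maximum).
    """
    w = np.asarray(waveform, dtype=float)
    trough = int(np.argmin(w))
    if trough >= w.size - 1:
        raise ValueError("waveform has no post-trough maximum")
    peak = trough + int(np.argmax(w[trough:]))
    if peak == trough:
        raise ValueError("waveform has no post-trough maximum")
    return (peak - trough) / fs * 1e3


def classify_waveform(unit: SpikeUnit) -> str:
    """Classify a unit as RS or FS from its trough-to-peak time.

    t2p >= 0.5 ms -> "RS"; t2p < 0.5 ms -> "FS".
    """
    if unit.waveform is None:
        raise ValueError("unit carries no waveform template")
    t2p = waveform_trough_to_peak(unit.waveform, unit.waveform_fs)
    return "RS" if t2p >= T2P_BOUNDARY_MS else "FS"


@dataclass
class OptotagResult:
    label: str  # "optotagged" | "unlabeled"
    mean_latency_ms: float  # NaN when no light-evoked spikes
    reliability: float
    n_trials: int


def classify_optotag(
    unit: SpikeUnit,
    light: StimulusLog,
    window_ms: float = 10.0,
    max_mean_latency_ms: float = OPTOTAG_MAX_LATENCY_MS,
    reliability_floor: float = 0.5,
) -> OptotagResult:
    """Classify a unit as optotagged from its light-evoked latencies.

    Per light trial, the latency is the first spike in ``(0, window_ms]``
    after onset; reliability is the fraction of trials with such a spike.
    A unit is optotagged iff the mean latency is below
    ``max_mean_latency_ms`` and reliability reaches the floor.

    Raises
    ------
    ValueError
        If the log contains no light events.
    """
    onsets = light.onsets("light")
    if onsets.size == 0:
        raise ValueError("no light events in the stimulus log")
    window_s = window_ms / 1e3
    latencies = []
    for on in onsets:
        i = np.searchsorted(unit.spike_times, on, side="right")
        if i < unit.spike_times.size and unit.spike_times[i] - on <= window_s:
            latencies.append((unit.spike_times[i] - on) * 1e3)
    reliability = len(latencies) / onsets.size
    mean_lat = float(np.mean(latencies)) if latencies else float("nan")
    tagged = (
        len(latencies) > 0
        and mean_lat < max_mean_latency_ms
        and reliability >= reliability_floor
    )
    return OptotagResult(
        label="optotagged" if tagged else "unlabeled",
        mean_latency_ms=mean_lat,
        reliability=reliability,
        n_trials=int(onsets.size),
    )
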