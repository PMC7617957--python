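"""Stimulus-locked response quantification.

Spontaneous activity is estimated trial-by-trial from a pre-stimulus
baseline and subtracted from evoked counts.  The selectivity index is

    SI = R_pw / (R_pw + R_aw)

where R is the cumulative (summed over trials) spontaneous-subtracted
spike count in a 50 ms window after each deflection; train mode sums
four 50 ms windows anchored at each deflection of the train.  Negative
cumulative counts are clipped at 0 before the ratio, so SI stays in
[0, 1]; SI is undefined (NaN) when R_pw + R_aw <= 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .core import SpikeUnit, StimulusLog

__all__ = [
    "spontaneous_rate",
    "evoked_count",
    "response_latency",
    "selectivity_index",
    "identify_pw_aw",
    "compute_tuning",
    "TuningResult",
    "SINGLE_WINDOW_S",
    "LATENCY_WINDOW_MS",
]

SINGLE_WINDOW_S = 0.050
BASELINE_WINDOW_S = 0.500
LATENCY_WINDOW_MS = (5.0, 20.0)


def _count_in_windows(spike_times: np.ndarray, starts: np.ndarray, length: float) -> np.ndarray:
    """Spike counts in half-open windows ``(start, start + length]``."""
    starts = np.asarray(starts, dtype=float)
    lo = np.searchsorted(spike_times, starts, side="right")
    hi = np.searchsorted(spike_times, starts + length, side="right")
    return (hi - lo).astype(int)


def spontaneous_rate(
    unit: SpikeUnit,
    trial_onsets: np.ndarray,
    baseline_window_s: float = BASELINE_WINDOW_S,
) -> tuple[np.ndarray, float]:
    """Per-trial spontaneous rate (Hz) over the pre-stimulus baseline.

    The baseline is the ``baseline_window_s`` seconds immediately before
    each trial onset.  Returns the per-trial vector and its mean.
    """
    if baseline_window_s <= 0:
        raise ValueError("baseline window must have positive length")
    onsets = np.asarray(trial_onsets, dtype=float)
    counts = _count_in_windows(unit.spike_times, onsets - baseline_window_s,
                               baseline_window_s)
    rates = counts / baseline_window_s
    return rates, float(rates.mean()) if rates.size else float("nan")


def evoked_count(
    unit: SpikeUnit,
    deflection_onsets: np.ndarray,
    spont_rates: np.ndarray | float,
    window_s: float = SINGLE_WINDOW_S,
) -> np.ndarray:
    """Spontaneous-subtracted spike count per trial (may be negative).

    Per trial: raw count in ``(onset, onset + window]`` minus
    ``spont_rate_trial * window``.
    """
    if window_s <= 0:
        raise ValueError("window must be positive")
    onsets = np.asarray(deflection_onsets, dtype=float)
    raw = _count_in_windows(unit.spike_times, onsets, window_s)
    return raw - np.broadcast_to(np.asarray(spont_rates, float), raw.shape) * window_s


def response_latency(
    unit: SpikeUnit,
    onsets: np.ndarray,
    window_ms: tuple[float, float] = LATENCY_WINDOW_MS,
) -> tuple[np.ndarray, float]:
    """Per-trial response latency as an integer 1 ms bin.

    The latency of a trial is the 1 ms bin containing the first spike
    5-20 ms after deflection onset; trials without such a spike
    contribute no latency.  Returns the per-trial bins and their mean
    (NaN when no trial responds).
    """
    lo, hi = window_ms[0] / 1e3, window_ms[1] / 1e3
    bins = []
    for on in np.asarray(onsets, dtype=float):
        i = np.searchsorted(unit.spike_times, on + lo, side="left")
        if i < unit.spike_times.size and unit.spike_times[i] <= on + hi:
            bins.append(int(np.floor((unit.spike_times[i] - on) * 1e3)))
    bins = np.asarray(bins, dtype=float)
    return bins, float(bins.mean()) if bins.size else float("nan")


def _train_onsets(log: StimulusLog, kind: str) -> np.ndarray:
    ev = log.events
    sel = (ev["kind"] == kind) & ev["train_index"].notna()
    return ev.loc[sel, "onset"].to_numpy(dtype=float)


def _single_onsets(log: StimulusLog, kind: str) -> np.ndarray:
    ev = log.events
    sel = (ev["kind"] == kind) & ev["train_index"].isna()
    return ev.loc[sel, "onset"].to_numpy(dtype=float)


def _cumulative_response(
    unit: SpikeUnit,
    onsets: np.ndarray,
    trial_onsets: np.ndarray,
    window_s: float,
    baseline_window_s: float,
) -> float:
    """Summed spontaneous-subtracted count over all windows, clipped at 0.

    Raw counts are integers summed before the (floating) spontaneous
    subtraction, so integer arithmetic is exact up to the subtraction.
    """
    raw = int(_count_in_windows(unit.spike_times, onsets, window_s).sum())
    spont, _ = spontaneous_rate(unit, trial_onsets, baseline_window_s)
    # one spont estimate per trial; each trial contributes windows of
    # total duration (n_windows / n_trials) * window
    n_windows_per_trial = onsets.size / max(trial_onsets.size, 1)
    expected_spont = float(spont.sum() * window_s * n_windows_per_trial)
    return max(raw - expected_spont, 0.0)


def cumulative_raw_count(
    unit: SpikeUnit,
    log: StimulusLog,
    kind: str,
    mode: str = "single",
    window_s: float = SINGLE_WINDOW_S,
) -> int:
    """Integer cumulative spike count over all response windows.

    This is the quantity the selectivity index subtracts spontaneous
    activity from; it is exposed so an independent counting oracle can
    be checked against it at the integer level.
    """
    picker = _single_onsets if mode == "single" else _train_onsets
    onsets = picker(log, kind)
    if onsets.size == 0:
        raise ValueError(f"no {kind} {mode} deflections in the log")
    return int(_count_in_windows(unit.spike_times, onsets, window_s).sum())


def selectivity_index(
    unit: SpikeUnit,
    log: StimulusLog,
    mode: str = "single",
    window_s: float = SINGLE_WINDOW_S,
    baseline_window_s: float = BASELINE_WINDOW_S,
) -> float:
    """Whisker selectivity index R_pw / (R_pw + R_aw) in [0, 1].

    ``mode="single"`` uses one 50 ms window per single-deflection trial;
    ``mode="train"`` sums four 50 ms windows anchored at each deflection
    of the 10 Hz train.  Returns NaN when R_pw + R_aw <= 0.

    Raises
    ------
    ValueError
        If either whisker condition is missing from the log.
    """
    if mode not in ("single", "train"):
        raise ValueError("mode must be 'single' or 'train'")
    picker = _single_onsets if mode == "single" else _train_onsets
    r = {}
    for kind in ("PW", "AW"):
        onsets = picker(log, kind)
        if onsets.size == 0:
            raise ValueError(f"no {kind} {mode} deflections in the log")
        if mode == "train":
            ev = log.events
            sel = (ev["kind"] == kind) & (ev["train_index"] == 0)
            trial_onsets = ev.loc[sel, "onset"].to_numpy(dtype=float)
        else:
            trial_onsets = onsets
        r[kind] = _cumulative_response(unit, onsets, trial_onsets, window_s,
                                       baseline_window_s)
    total = r["PW"] + r["AW"]
    if total <= 0:
        return float("nan")
    return r["PW"] / total


@dataclass
class TuningResult:
    unit_id: str
    r_pw: float
    r_aw: float
    si_single: float
    si_train: float
    latency_pw_ms: float
    latency_aw_ms: float
    spont_rate_hz: float
    n_trials: int


def compute_tuning(
    unit: SpikeUnit,
    log: StimulusLog,
    baseline_window_s: float = BASELINE_WINDOW_S,
) -> TuningResult:
    """Full per-unit tuning summary (SI single/train, latencies, spont)."""
    pw = _single_onsets(log, "PW")
    aw = _single_onsets(log, "AW")
    spont_vec, spont_mean = spontaneous_rate(unit, pw, baseline_window_s)
    r_pw = _cumulative_response(unit, pw, pw, SINGLE_WINDOW_S, baseline_window_s)
    r_aw = _cumulative_response(unit, aw, aw, SINGLE_WINDOW_S, baseline_window_s)
    si_single = selectivity_index(unit, log, "single",
                                  baseline_window_s=baseline_window_s)
    try:
        si_train = selectivity_index(unit, log, "train",
                                     baseline_window_s=baseline_window_s)
    except ValueError:
        si_train = float("nan")
    _, lat_pw = response_latency(unit, pw)
    _, lat_aw = response_latency(unit, aw)
    return TuningResult(
        unit_id=unit.unit_id,
        r_pw=r_pw,
        r_aw=r_aw,
        si_single=si_single,
        si_train=si_train,
        latency_pw_ms=lat_pw,
        latency_aw_ms=lat_aw,
        spont_rate_hz=spont_mean,
        n_trials=int(pw.size),
    )


def identify_pw_aw(population: pd.DataFrame) -> dict:
    """Confirm PW/AW identity from population rate and latency.

    Parameters
    ----------
    population : DataFrame
        One row per (whisker, unit) with columns ``whisker``,
        ``evoked_rate`` (Hz) and ``latency_ms``.

    Returns
    -------
    dict
        ``pw``, ``aw``, ``consistent`` (rate winner also has the shorter
        latency) and ``flags``.

    Raises
    ------
    ValueError
        On fewer than 2 candidate whiskers, or when both rate and
        latency tie (ambiguous).
    """
    grouped = population.groupby("whisker").agg(
        rate=("evoked_rate", "mean"), latency=("latency_ms", "mean")
    )
    if len(grouped) < 2:
        raise ValueError("need at least two candidate whiskers")
    flags: list[str] = []
    max_rate = grouped["rate"].max()
    rate_winners = grouped.index[grouped["rate"] == max_rate]
    if len(rate_winners) > 1:
        flags.append("rate tie")
        sub = grouped.loc[rate_winners]
        min_lat = sub["latency"].min()
        lat_winners = sub.index[sub["latency"] == min_lat]
        if len(lat_winners) > 1:
            raise ValueError("ambiguous: tie in both rate and latency")
        pw = lat_winners[0]
    else:
        pw = rate_winners[0]
    aw = grouped.drop(index=pw)["rate"].idxmax()
    consistent = grouped.loc[pw, "latency"] == grouped["latency"].min()
    if not consistent:
        flags.append("latency inconsistent with rate winner")
    return {"pw": pw, "aw": aw, "consistent": bool(consistent), "flags": flags}
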