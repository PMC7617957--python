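"""Sensory-evoked LTP quantification around a rhythmic whisker
stimulation (RWS) induction.

The protocol is 100 pre-induction multi-whisker deflections at 0.1 Hz,
60 s of 8 Hz RWS (480 deflections, one every 125 ms), then 100
post-induction deflections at 0.1 Hz.  The plasticity statistic is
``delta = 100 * post_rate / pre_rate`` on spontaneous-subtracted evoked
rates over a 250 ms response window, so 100% means "no change".
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .core import StimulusLog

__all__ = ["RwsConfig", "PlasticityResult", "build_rws_schedule", "sltp_delta"]

MULTI_WINDOW_S = 0.250


@dataclass(frozen=True)
class RwsConfig:
    n_pre: int = 100
    n_post: int = 100
    probe_rate_hz: float = 0.1
    rws_rate_hz: float = 8.0
    rws_duration_s: float = 60.0
    settle_s: float = 30.0  # gap between epochs

    @property
    def n_induction(self) -> int:
        return int(round(self.rws_rate_hz * self.rws_duration_s))


def build_rws_schedule(config: RwsConfig = RwsConfig()) -> StimulusLog:
    """Event log for a full pre / RWS-induction / post session.

    Pre and post deflections are kind "multi"; induction deflections are
    kind "RWS" spaced exactly ``1 / rws_rate_hz`` apart.
    """
    c = config
    probe_iti = 1.0 / c.probe_rate_hz
    t = c.settle_s
    onsets, kinds = [], []
    for _ in range(c.n_pre):
        onsets.append(t)
        kinds.append("multi")
        t += probe_iti
    t += c.settle_s
    rws_iti = 1.0 / c.rws_rate_hz
    for i in range(c.n_induction):
        onsets.append(t + i * rws_iti)
        kinds.append("RWS")
    t += c.rws_duration_s + c.settle_s
    for _ in range(c.n_post):
        onsets.append(t)
        kinds.append("multi")
        t += probe_iti
    return StimulusLog.from_arrays(onsets, kinds)


@dataclass
class PlasticityResult:
    pre_rate_hz: float
    post_rate_hz: float
    delta_pct: float  # NaN (flagged) when pre_rate <= 0
    delta_defined: bool
    n_pre: int
    n_post: int


def sltp_delta(
    pre_counts: np.ndarray,
    post_counts: np.ndarray,
    window_s: float = MULTI_WINDOW_S,
    spont_rate_pre: np.ndarray | float = 0.0,
    spont_rate_post: np.ndarray | float = 0.0,
) -> PlasticityResult:
    """Delta spike rate: 100 * post / pre on spontaneous-subtracted rates.

    Per epoch the rate is the mean over trials of
    ``(count - spont_rate * window) / window``.  ``spont_rate_*`` may be
    scalar or per-trial (Hz).  When the pre rate is not positive the
    delta is undefined and flagged rather than raised.

    Raises
    ------
    ValueError
        When either epoch has no trials.
    """
    pre = np.asarray(pre_counts, dtype=float)
    post = np.asarray(post_counts, dtype=float)
    if pre.size == 0 or post.size == 0:
        raise ValueError("need at least one trial in each epoch")
    if window_s <= 0:
        raise ValueError("window must be positive")
    pre_rate = float(np.mean(pre / window_s - np.broadcast_to(
        np.asarray(spont_rate_pre, float), pre.shape)))
    post_rate = float(np.mean(post / window_s - np.broadcast_to(
        np.asarray(spont_rate_post, float), post.shape)))
    defined = pre_rate > 0
    delta = 100.0 * post_rate / pre_rate if defined else float("nan")
    return PlasticityResult(
        pre_rate_hz=pre_rate,
        post_rate_hz=post_rate,
        delta_pct=delta,
        delta_defined=defined,
        n_pre=int(pre.size),
        n_post=int(post.size),
    )
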