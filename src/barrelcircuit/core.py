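"""Shared record types: probe recordings, spike units, stimulus logs, CSD profiles.

These are the carriers passed between the generator and every analysis
stage.  Validation lives in ``__post_init__`` so malformed inputs fail at
construction, not deep inside an analysis loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

#: closed set of stimulus kinds accepted by :class:`StimulusLog`
STIM_KINDS = frozenset({"PW", "AW", "light", "RWS", "multi"})


@dataclass
class ProbeRecording:
    """Multichannel extracellular voltage with linear channel geometry.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Voltage in microvolts, channel 0 most superficial.
    fs : float
        Sampling rate in Hz.
    channel_spacing : float
        Inter-channel spacing in micrometres.
    """

    samples: np.ndarray
    fs: float
    channel_spacing: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a (channels, time) matrix")
        if not np.isfinite(self.fs) or self.fs <= 0:
            raise ValueError("fs must be positive and finite")
        if not np.isfinite(self.channel_spacing) or self.channel_spacing <= 0:
            raise ValueError("channel_spacing must be positive and finite")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds, starting at 0."""
        return np.arange(self.n_samples) / self.fs


@dataclass
class StimulusLog:
    """Timestamped stimulus events.

    ``events`` holds columns ``onset`` (s, sorted ascending), ``kind``
    (one of :data:`STIM_KINDS`) and ``train_index`` (position of a
    deflection within a train, NaN for single deflections).
    """

    events: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"onset", "kind"}
        if not required.issubset(self.events.columns):
            raise ValueError(f"events table needs columns {sorted(required)}")
        if "train_index" not in self.events.columns:
            self.events = self.events.assign(train_index=np.nan)
        onsets = self.events["onset"].to_numpy(dtype=float)
        if np.any(np.diff(onsets) < 0):
            raise ValueError("event onsets must be sorted ascending")
        bad = set(self.events["kind"]) - STIM_KINDS
        if bad:
            raise ValueError(f"unknown stimulus kinds: {sorted(bad)}")

    @classmethod
    def from_arrays(cls, onsets, kinds, train_index=None) -> "StimulusLog":
        df = pd.DataFrame({"onset": np.asarray(onsets, dtype=float),
                           "kind": list(kinds)})
        if train_index is not None:
            df["train_index"] = train_index
        return cls(df.sort_values("onset", kind="stable").reset_index(drop=True))

    def onsets(self, kind: str) -> np.ndarray:
        """Onset times (s) for one stimulus kind."""
        sel = self.events["kind"] == kind
        return self.events.loc[sel, "onset"].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.events)


@dataclass
class SpikeUnit:
    """A sorted unit: spike times plus an optional waveform template."""

    unit_id: str
    spike_times: np.ndarray
    waveform: Optional[np.ndarray] = None
    waveform_fs: Optional[float] = None

    def __post_init__(self) -> None:
        self.spike_times = np.asarray(self.spike_times, dtype=float)
        if self.spike_times.ndim != 1:
            raise ValueError("spike_times must be 1-D")
        if np.any(np.diff(self.spike_times) < 0):
            raise ValueError("spike_times must be sorted ascending")
        if self.waveform is not None:
            self.waveform = np.asarray(self.waveform, dtype=float)
            if self.waveform_fs is None or self.waveform_fs <= 0:
                raise ValueError("waveform requires a positive waveform_fs")

    @property
    def n_spikes(self) -> int:
        return self.spike_times.size


@dataclass
class CsdProfile:
    """Current source density on interior channels.

    ``values`` has one row per interior channel (edge channels are
    dropped by the central second difference); ``channels`` maps rows
    back to original probe channel indices.  A sink is a local minimum.
    """

    values: np.ndarray
    channels: np.ndarray
    times: np.ndarray
    spacing: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.channels = np.asarray(self.channels, dtype=int)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape[0] != self.channels.size:
            raise ValueError("one channel index per CSD row required")
        if self.values.shape[1] != self.times.size:
            raise ValueError("one time per CSD column required")
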