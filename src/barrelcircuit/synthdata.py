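"""Synthetic ground-truth generators for every input modality.

Every generator takes a frozen parameter dataclass carrying a ``seed``
and returns both the simulated data and a ground-truth table sufficient
to score the downstream estimators without re-deriving truth.  Identical
parameters and seed give bit-identical output.

Design notes
------------
* Evoked spiking is Bernoulli-per-deflection (0 or 1 evoked spike with
  probability p), so the true selectivity index is exactly
  ``p_pw / (p_pw + p_aw)``.
* Laminar LFP is synthesized from a *target* CSD by discrete double
  integration along the channel axis, making the CSD round trip exact.
* EPSPs use an alpha kernel ``a * (t-t0)/tau * exp(1 - (t-t0)/tau)``
  whose peak value is ``a`` at ``t0 + tau``.
* Barrel images default to 1 um/px with intensities on a 16-bit scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .core import ProbeRecording, SpikeUnit, StimulusLog
from .histomorph import BarrelMap, Morphology
from .slice_circuits import PairedSweepSet

__all__ = [
    "EphysSimParams",
    "LaminarSimParams",
    "EPSPSimParams",
    "BarrelImageParams",
    "SltpSimParams",
    "EphysSession",
    "BarrelScene",
    "SltpSession",
    "gen_ephys_session",
    "gen_laminar_lfp",
    "gen_paired_epsp_sweeps",
    "gen_barrel_image",
    "gen_sltp_session",
    "planted_morphology",
]


def _require(cond: bool, msg: str) -> None:
    if not cond:
        raise ValueError(msg)


def _truncated_normal(rng, mean, sd, lo, hi, size):
    """Normal(mean, sd) truncated to (lo, hi] by rejection."""
    if sd == 0:
        _require(lo < mean <= hi, "degenerate latency outside the window")
        return np.full(size, float(mean))
    out = rng.normal(mean, sd, size)
    bad = (out <= lo) | (out > hi)
    guard = 0
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out <= lo) | (out > hi)
        guard += 1
        if guard > 1000:
            raise RuntimeError("truncated normal rejection failed to converge")
    return out


# ---------------------------------------------------------------------------
# in vivo spiking sessions


@dataclass(frozen=True)
class EphysSimParams:
    """Parameters for a stimulus-locked spiking session."""

    n_units: int = 30
    trials_per_whisker: int = 100
    p_pw: float = 0.5
    p_aw: float = 0.25
    evoked_latency_mean: float = 9.0  # ms
    evoked_latency_sd: float = 2.0
    spont_rate: float = 2.0  # Hz
    tagged_fraction: float = 0.5
    tag_latency_mean: float = 3.0  # ms
    tag_latency_sd: float = 0.5
    untagged_latency_mean: Optional[float] = None  # ms; None -> no light response
    waveform_t2p_rs: float = 0.8  # ms
    waveform_t2p_fs: float = 0.3
    sampling_rate: float = 30000.0  # Hz
    n_light_trials: int = 50
    light_reliability: float = 1.0
    include_trains: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_units > 0 and self.trials_per_whisker > 0,
                 "counts must be positive")
        for p in (self.p_pw, self.p_aw, self.tagged_fraction,
                  self.light_reliability):
            _require(np.isfinite(p) and 0.0 <= p <= 1.0,
                     "probabilities must be in [0, 1]")
        _require(self.spont_rate >= 0, "spont_rate must be >= 0")
        _require(self.waveform_t2p_fs < 0.5 < self.waveform_t2p_rs,
                 "need t2p_fs < 0.5 ms < t2p_rs for unambiguous labels")
        _require(self.sampling_rate > 0, "sampling_rate must be positive")
        _require(np.isfinite(self.evoked_latency_mean)
                 and np.isfinite(self.evoked_latency_sd),
                 "latency parameters must be finite")


@dataclass
class EphysSession:
    units: list
    log: StimulusLog
    truth: pd.DataFrame
    params: EphysSimParams
    duration_s: float


def _waveform_template(t2p_ms: float, fs: float) -> np.ndarray:
    """Biphasic template: Gaussian trough then a positive peak t2p later."""
    t = np.arange(int(round(3.0e-3 * fs))) / fs * 1e3  # ms
    trough_t = 0.8
    w = -np.exp(-0.5 * ((t - trough_t) / 0.08) ** 2)
    w += 0.5 * np.exp(-0.5 * ((t - trough_t - t2p_ms) / 0.15) ** 2)
    return w


def gen_ephys_session(params: EphysSimParams) -> EphysSession:
    """Simulate spiking units with known selectivity, tag and waveform labels.

    The session contains, in order: light pulses, single PW deflections,
    single AW deflections and (optionally) four-deflection 10 Hz trains
    for each whisker.  Spontaneous spiking is homogeneous Poisson at
    ``spont_rate``; each deflection evokes at most one spike
    (Bernoulli(p)) at a latency drawn from a Normal truncated to
    (0, 50] ms.  Tagged units also respond to light at the tag latency.
    """
    p = params
    rng = np.random.default_rng(p.seed)

    events = []
    t = 1.0
    for i in range(p.n_light_trials):
        events.append((t, "light", np.nan))
        t += 0.25
    t += 1.0
    for kind in ("PW", "AW"):
        for i in range(p.trials_per_whisker):
            events.append((t + 0.5, kind, np.nan))
            t += 1.0
        t += 1.0
    if p.include_trains:
        for kind in ("PW", "AW"):
            for i in range(p.trials_per_whisker):
                for j in range(4):
                    events.append((t + 0.5 + 0.1 * j, kind, j))
                t += 1.5
            t += 1.0
    duration = t + 1.0
    log = StimulusLog.from_arrays(
        onsets=[e[0] for e in events],
        kinds=[e[1] for e in events],
        train_index=[e[2] for e in events],
    )

    n_tagged = int(round(p.tagged_fraction * p.n_units))
    deflections = log.events[log.events["kind"].isin(["PW", "AW"])]
    light_onsets = log.onsets("light")

    units, rows = [], []
    for u in range(p.n_units):
        tagged = u < n_tagged
        is_rs = bool(rng.random() < 0.5)
        t2p = p.waveform_t2p_rs if is_rs else p.waveform_t2p_fs

        n_spont = rng.poisson(p.spont_rate * duration)
        spikes = [rng.uniform(0.0, duration, n_spont)]

        for kind, prob in (("PW", p.p_pw), ("AW", p.p_aw)):
            onsets = deflections.loc[deflections["kind"] == kind,
                                     "onset"].to_numpy(dtype=float)
            fired = rng.random(onsets.size) < prob
            n_fired = int(fired.sum())
            if n_fired:
                lat = _truncated_normal(rng, p.evoked_latency_mean,
                                        p.evoked_latency_sd, 0.0, 50.0,
                                        n_fired)
                spikes.append(onsets[fired] + lat / 1e3)

        light_mean = p.tag_latency_mean if tagged else p.untagged_latency_mean
        if light_mean is not None and light_onsets.size:
            fired = rng.random(light_onsets.size) < p.light_reliability
            n_fired = int(fired.sum())
            if n_fired:
                lat = _truncated_normal(rng, light_mean, p.tag_latency_sd,
                                        0.0, 50.0, n_fired)
                spikes.append(light_onsets[fired] + lat / 1e3)

        spike_times = np.sort(np.concatenate(spikes))
        units.append(SpikeUnit(
            unit_id=f"u{u:03d}",
            spike_times=spike_times,
            waveform=_waveform_template(t2p, p.sampling_rate),
            waveform_fs=p.sampling_rate,
        ))
        denom = p.p_pw + p.p_aw
        rows.append({
            "unit_id": f"u{u:03d}",
            "true_si": p.p_pw / denom if denom > 0 else np.nan,
            "tagged": tagged,
            "cell_class": "RS" if is_rs else "FS",
            "p_pw": p.p_pw,
            "p_aw": p.p_aw,
        })

    return EphysSession(units=units, log=log, truth=pd.DataFrame(rows),
                        params=p, duration_s=duration)


# ---------------------------------------------------------------------------
# laminar LFP with a planted CSD sink


@dataclass(frozen=True)
class LaminarSimParams:
    """Parameters for a laminar LFP session with one planted CSD sink."""

    n_channels: int = 32
    channel_spacing: float = 25.0  # um
    sink_channel: int = 12
    sink_latency: float = 6.0  # ms after deflection onset (t=0)
    sink_width: float = 1.5  # channels (Gaussian sigma)
    noise_sd: float = 0.0  # uV
    fs: float = 2000.0  # Hz
    duration_ms: float = 40.0
    sink_amplitude: float = 50.0
    sink_time_sd_ms: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_channels >= 3, "need >= 3 channels")
        _require(0 <= self.sink_channel < self.n_channels,
                 "sink_channel out of range")
        _require(self.noise_sd >= 0, "noise_sd must be >= 0")
        _require(self.channel_spacing > 0 and self.fs > 0
                 and self.duration_ms > 0, "geometry/time must be positive")


def gen_laminar_lfp(params: LaminarSimParams) -> tuple[ProbeRecording, dict]:
    """Synthesize LFP whose second spatial difference is a known CSD.

    The target CSD has a single negative Gaussian sink centred at
    ``(sink_channel, sink_latency)``.  The LFP solves the recurrence
    ``L[i+1] = 2 L[i] - L[i-1] + h^2 C[i]`` (discrete double
    integration), so ``compute_csd`` recovers the target exactly on
    interior channels before noise.  Time 0 is the deflection onset.
    """
    p = params
    if p.sink_channel in (0, p.n_channels - 1):
        warnings.warn("sink at an edge channel: CSD undefined there after "
                      "central differencing", stacklevel=2)
    rng = np.random.default_rng(p.seed)
    n_t = int(round(p.duration_ms / 1e3 * p.fs))
    t_ms = np.arange(n_t) / p.fs * 1e3
    ch = np.arange(p.n_channels)
    csd = -p.sink_amplitude * np.exp(
        -0.5 * ((ch[:, None] - p.sink_channel) / p.sink_width) ** 2
    ) * np.exp(-0.5 * ((t_ms[None, :] - p.sink_latency) / p.sink_time_sd_ms) ** 2)

    h2 = p.channel_spacing ** 2
    lfp = np.zeros_like(csd)
    for i in range(1, p.n_channels - 1):
        lfp[i + 1] = 2.0 * lfp[i] - lfp[i - 1] + h2 * csd[i]
    if p.noise_sd > 0:
        lfp = lfp + rng.normal(0.0, p.noise_sd, lfp.shape)
    rec = ProbeRecording(samples=lfp, fs=p.fs,
                         channel_spacing=p.channel_spacing)
    truth = {"sink_channel": p.sink_channel,
             "sink_latency_ms": p.sink_latency}
    return rec, truth


# ---------------------------------------------------------------------------
# paired intracellular EPSP sweeps


@dataclass(frozen=True)
class EPSPSimParams:
    """Parameters for paired light-evoked EPSP sweep sets."""

    n_pairs: int = 20
    amp_ratio: float = 1.0  # true A_ip / A_op
    base_amp: float = 1.0  # mV (OP amplitude)
    onset_latency: float = 3.5  # ms after light onset
    alpha_tau: float = 4.0  # ms
    noise_sd: float = 0.1  # mV
    sweeps_per_cell: int = 20
    fs: float = 10000.0
    nucleus: str = "VPM"
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_pairs > 0, "n_pairs must be positive")
        _require(self.amp_ratio > 0, "amp_ratio must be > 0")
        _require(self.base_amp > 0, "base_amp must be > 0")
        _require(10 <= self.sweeps_per_cell <= 40,
                 "sweeps_per_cell must be in [10, 40]")
        _require(self.nucleus in ("VPM", "POm"), "nucleus must be VPM or POm")
        if max(self.base_amp, self.base_amp * self.amp_ratio) >= 3.0:
            warnings.warn("mean EPSP peak >= 3 mV exceeds the low-amplitude "
                          "regime", stacklevel=2)


def alpha_epsp(t_ms: np.ndarray, amplitude: float, onset_ms: float,
               tau_ms: float) -> np.ndarray:
    """Alpha-function EPSP peaking at ``amplitude`` at ``onset + tau``."""
    x = (np.asarray(t_ms, dtype=float) - onset_ms) / tau_ms
    out = np.where(x > 0, amplitude * x * np.exp(1.0 - x), 0.0)
    return out


def gen_paired_epsp_sweeps(
    params: EPSPSimParams,
) -> tuple[list[PairedSweepSet], pd.DataFrame]:
    """Simulate paired sweeps with a known IP/OP amplitude ratio.

    Per pair, the OP cell's true amplitude is ``base_amp`` and the IP
    cell's is ``base_amp * amp_ratio``; sweeps are baseline Gaussian
    noise plus the alpha EPSP, time-locked to the shared light onset at
    t = 0 ms.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    dt = 1e3 / p.fs
    t_ms = np.arange(-60.0, 80.0, dt)
    kernel_ip = alpha_epsp(t_ms, p.base_amp * p.amp_ratio, p.onset_latency,
                           p.alpha_tau)
    kernel_op = alpha_epsp(t_ms, p.base_amp, p.onset_latency, p.alpha_tau)
    pairs, rows = [], []
    for i in range(p.n_pairs):
        noise_ip = rng.normal(0.0, p.noise_sd, (p.sweeps_per_cell, t_ms.size))
        noise_op = rng.normal(0.0, p.noise_sd, (p.sweeps_per_cell, t_ms.size))
        pairs.append(PairedSweepSet(
            pair_id=f"pair{i:03d}",
            nucleus=p.nucleus,
            t_ms=t_ms.copy(),
            sweeps_ip=kernel_ip[None, :] + noise_ip,
            sweeps_op=kernel_op[None, :] + noise_op,
        ))
        a_ip = p.base_amp * p.amp_ratio
        rows.append({"pair_id": f"pair{i:03d}", "nucleus": p.nucleus,
                     "a_ip_true": a_ip, "a_op_true": p.base_amp,
                     "bias_true": a_ip / (a_ip + p.base_amp)})
    return pairs, pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# barrel-field image scenes


@dataclass(frozen=True)
class BarrelImageParams:
    """Parameters for a curved barrel-field fluorescence image (1 um/px)."""

    n_barrels: int = 5
    barrel_width: float = 120.0  # um
    septum_width: float = 40.0
    l4_band_depth: float = 0.0  # normal offset of the band's deep edge, um
    l4_band_thickness: float = 80.0
    curvature: float = 5e-4  # 1/um, quadratic bend of the layer
    barrel_intensity: float = 20000.0
    septum_intensity: float = 8000.0
    background: float = 2000.0
    noise_sd: float = 0.0
    n_somata: int = 20  # per lineage
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.n_barrels >= 1, "need at least one barrel")
        _require(self.barrel_width > 0 and self.septum_width > 0
                 and self.l4_band_thickness > 0, "widths must be positive")
        _require(self.barrel_intensity > self.septum_intensity > self.background,
                 "need barrel > septum > background intensity")
        _require(self.curvature >= 0, "curvature must be >= 0")
        _require(self.noise_sd >= 0, "noise_sd must be >= 0")


@dataclass
class BarrelScene:
    """A rendered barrel-field image plus its complete ground truth."""

    image: np.ndarray  # (H, W) float, 16-bit scale
    barrel_map: BarrelMap  # true barrel intervals + reference polyline
    somata: pd.DataFrame  # x, y, s, d, lineage, true_index, barrel
    morphologies: list  # (Morphology, truth dict) pairs, straightened frame
    params: BarrelImageParams


def _reference_polyline(params: BarrelImageParams, width: float,
                        y0: float) -> np.ndarray:
    """Quadratic L4/L5 boundary sampled every 2 um across the image."""
    x = np.arange(0.0, width + 1e-9, 2.0)
    xc = width / 2.0
    y = y0 + 0.5 * params.curvature * (x - xc) ** 2
    return np.column_stack([x, y])


def _densify(polyline: np.ndarray, step: float = 0.25):
    """Resample a polyline at ~step spacing; returns points, arclength, tangents."""
    seg = np.diff(polyline, axis=0)
    seg_len = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    s = np.arange(0.0, cum[-1], step)
    x = np.interp(s, cum, polyline[:, 0])
    y = np.interp(s, cum, polyline[:, 1])
    pts = np.column_stack([x, y])
    tang = np.gradient(pts, s, axis=0)
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    return pts, s, tang


def _forward_map(s_query, d_query, pts, s, tang):
    """Map straightened (s, d) to image (x, y); +d points deeper (larger y)."""
    s_query = np.atleast_1d(np.asarray(s_query, dtype=float))
    d_query = np.broadcast_to(np.asarray(d_query, dtype=float), s_query.shape)
    x = np.interp(s_query, s, pts[:, 0])
    y = np.interp(s_query, s, pts[:, 1])
    tx = np.interp(s_query, s, tang[:, 0])
    ty = np.interp(s_query, s, tang[:, 1])
    norm = np.hypot(tx, ty)
    tx, ty = tx / norm, ty / norm
    # normal (-ty, tx) gives cross(tangent, normal) = +1
    return x + d_query * (-ty), y + d_query * tx


def gen_barrel_image(params: BarrelImageParams) -> BarrelScene:
    """Render a curved L4 band with evenly spaced barrels and known truth.

    The image is painted in (s, d) coordinates relative to the reference
    polyline (s = arc length, d = signed normal distance, +d deeper),
    so the true barrel intervals, soma positions and dendritic overlaps
    are exact by construction.

    Raises
    ------
    ValueError
        If the L4 band would leave the image bounds.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    margin = 60.0
    width = p.n_barrels * p.barrel_width + (p.n_barrels + 1) * p.septum_width \
        + 2 * margin
    band_lo = -(p.l4_band_depth + p.l4_band_thickness)  # superficial edge
    band_hi = -p.l4_band_depth
    y0 = -band_lo + 40.0  # reference depth leaving room for the band
    bend = 0.5 * p.curvature * (width / 2.0) ** 2
    height = y0 + bend + 40.0
    if y0 + band_lo < 2.0:
        raise ValueError("L4 band exceeds image bounds")

    polyline = _reference_polyline(p, width, y0)
    pts, s_dense, tang = _densify(polyline)
    total_s = s_dense[-1]

    pattern = p.n_barrels * p.barrel_width + (p.n_barrels - 1) * p.septum_width
    if pattern > total_s:
        raise ValueError("barrel pattern wider than the reference line")
    s_start = (total_s - pattern) / 2.0
    pitch = p.barrel_width + p.septum_width
    barrels = [(s_start + i * pitch, s_start + i * pitch + p.barrel_width)
               for i in range(p.n_barrels)]

    # paint the image: nearest dense sample gives (s, d) per pixel
    H, W = int(np.ceil(height)), int(np.ceil(width))
    yy, xx = np.mgrid[0:H, 0:W]
    pix = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    tree = cKDTree(pts)
    dist, idx = tree.query(pix, workers=-1)
    foot = pts[idx]
    tg = tang[idx]
    cross = tg[:, 0] * (pix[:, 1] - foot[:, 1]) - tg[:, 1] * (pix[:, 0] - foot[:, 0])
    d = np.sign(cross) * dist
    s = s_dense[idx]

    img = np.full(pix.shape[0], p.background)
    in_band = (d >= band_lo) & (d <= band_hi)
    img[in_band] = p.septum_intensity
    in_barrel = np.zeros(pix.shape[0], dtype=bool)
    for s0, s1 in barrels:
        in_barrel |= (s >= s0) & (s <= s1)
    img[in_band & in_barrel] = p.barrel_intensity
    img = img.reshape(H, W)
    if p.noise_sd > 0:
        img = img + rng.normal(0.0, p.noise_sd, img.shape)
    img = np.clip(img, 0.0, 65535.0)

    barrel_map = BarrelMap(reference_polyline=polyline,
                           barrels=barrels, l4_band=(band_lo, band_hi))

    # somata at known fractions between a septal midpoint and a barrel center
    half_gap = pitch / 2.0
    rows = []
    d_soma = (band_lo + band_hi) / 2.0
    for lineage in ("IP", "OP"):
        for _ in range(p.n_somata):
            j = int(rng.integers(p.n_barrels))
            side = 1.0 if rng.random() < 0.5 else -1.0
            f = float(rng.random())
            c = (barrels[j][0] + barrels[j][1]) / 2.0
            s_soma = c + side * (1.0 - f) * half_gap
            x_soma, y_soma = _forward_map(s_soma, d_soma, pts, s_dense, tang)
            rows.append({"x": float(x_soma[0]), "y": float(y_soma[0]),
                         "s": s_soma, "d": d_soma, "lineage": lineage,
                         "true_index": f, "barrel": j})
    somata = pd.DataFrame(rows)

    morphologies = []
    for lineage, frac in (("OP", 0.8), ("IP", 0.4)):
        j = p.n_barrels // 2
        dendrite_len = min(200.0, 0.95 * p.barrel_width / max(frac, 1e-9))
        morph, truth = planted_morphology(
            barrels[j], (band_lo, band_hi), frac_inside=frac,
            total_length=dendrite_len, d=d_soma)
        truth["lineage"] = lineage
        truth["barrel"] = j
        morphologies.append((morph, truth))

    return BarrelScene(image=img, barrel_map=barrel_map, somata=somata,
                       morphologies=morphologies, params=p)


def planted_morphology(
    barrel: tuple[float, float],
    band: tuple[float, float],
    frac_inside: float,
    total_length: float = 200.0,
    d: Optional[float] = None,
    n_nodes: int = 21,
) -> tuple[Morphology, dict]:
    """A straight dendrite with an exact in-barrel length fraction.

    The polyline runs at constant normal offset ``d`` (mid-band by
    default) from inside the barrel across its right boundary, so
    ``frac_inside * total_length`` lies inside the barrel by
    construction.  Coordinates are in the straightened (s, d) frame.
    """
    _require(0.0 <= frac_inside <= 1.0, "frac_inside must be in [0, 1]")
    s0, s1 = barrel
    if d is None:
        d = (band[0] + band[1]) / 2.0
    length_in = frac_inside * total_length
    _require(length_in <= (s1 - s0), "in-barrel portion longer than the barrel")
    start = s1 - length_in
    xs = np.linspace(start, start + total_length, n_nodes)
    nodes = pd.DataFrame({
        "id": np.arange(1, n_nodes + 1),
        "type": [1] + [3] * (n_nodes - 1),
        "x": xs,
        "y": np.full(n_nodes, d),
        "z": np.zeros(n_nodes),
        "radius": np.full(n_nodes, 0.5),
        "parent": np.concatenate([[-1], np.arange(1, n_nodes)]),
    })
    morph = Morphology(nodes=nodes)
    truth = {"total_length": total_length,
             "length_inside": length_in,
             "frac_inside": frac_inside}
    return morph, truth


# ---------------------------------------------------------------------------
# sensory-LTP sessions


@dataclass(frozen=True)
class SltpSimParams:
    """Parameters for a pre/post sensory-LTP session."""

    pre_rate: float = 40.0  # Hz evoked rate during the response window
    potentiation_factor: float = 1.0  # g; 1 encodes "no plasticity"
    n_trials_pre: int = 100
    n_trials_post: int = 100
    window_s: float = 0.250
    spont_rate: float = 2.0  # Hz
    baseline_window_s: float = 0.500
    seed: int = 0

    def __post_init__(self) -> None:
        _require(self.pre_rate >= 0 and self.spont_rate >= 0
                 and self.potentiation_factor >= 0, "rates must be >= 0")
        _require(self.n_trials_pre > 0 and self.n_trials_post > 0,
                 "need at least one trial per epoch")
        _require(self.window_s > 0 and self.baseline_window_s > 0,
                 "windows must be positive")


@dataclass
class SltpSession:
    pre_counts: np.ndarray
    post_counts: np.ndarray
    pre_baseline_counts: np.ndarray
    post_baseline_counts: np.ndarray
    params: SltpSimParams

    @property
    def truth_g(self) -> float:
        return self.params.potentiation_factor


def gen_sltp_session(params: SltpSimParams) -> SltpSession:
    """Poisson pre/post spike counts with a known potentiation factor g.

    Counts in the response window are Poisson((rate + spont) * window)
    with the post-epoch evoked rate multiplied by g; per-trial baseline
    counts over ``baseline_window_s`` support spontaneous subtraction.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    pre_mu = (p.pre_rate + p.spont_rate) * p.window_s
    post_mu = (p.potentiation_factor * p.pre_rate + p.spont_rate) * p.window_s
    base_mu = p.spont_rate * p.baseline_window_s
    return SltpSession(
        pre_counts=rng.poisson(pre_mu, p.n_trials_pre),
        post_counts=rng.poisson(post_mu, p.n_trials_post),
        pre_baseline_counts=rng.poisson(base_mu, p.n_trials_pre),
        post_baseline_counts=rng.poisson(base_mu, p.n_trials_post),
        params=p,
    )
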