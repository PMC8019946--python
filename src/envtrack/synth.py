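"""Forward-model EEG simulator with known ground truth.

The generator emulates the study conditions of a two-competing-speaker
experiment: 49 scalp channels at 500 Hz in 10-minute blocks, two
speech-like envelope streams, ten embedded-name events per block obeying
the placement constraints (none in the first minute or last 30 s, at
least 30 s apart, control words at least 1.5 s from any name), EEG built
as lagged-kernel convolutions of both envelopes (attended response
peaking near 156 ms with a bilateral-temporal map, ignored near 50 ms
with a fronto-central map), a rectangular post-name gain window, an
injected posterior P3-like deflection near 760 ms, 1/f noise, and
optional stereotyped blinks.

Everything injected is recorded in a :class:`GroundTruth` object so the
downstream analyses can be validated against known parameters.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

from . import montage
from .containers import EegRecording, Envelope, make_event_table


class InfeasibleScheduleError(ValueError):
    """Raised when event-placement constraints cannot be satisfied."""


@dataclass
class GaborKernel:
    """Gaussian lag bump with a fixed scalp map: response = topo x bump(lag)."""

    peak_s: float
    width_s: float
    topography: np.ndarray | None = None  # unit-peak per-channel gain

    def lag_course(self, fs: float) -> np.ndarray:
        """Kernel sampled on the lag grid [0, peak + 4 widths]."""
        n = int(round((self.peak_s + 4 * self.width_s) * fs)) + 1
        lags = np.arange(n) / fs
        return np.exp(-0.5 * ((lags - self.peak_s) / self.width_s) ** 2)


@dataclass
class SimConfig:
    """Simulation parameters; defaults are the study conditions."""

    fs_eeg: float = 500.0
    n_channels: int = 49
    block_length: float = 600.0
    n_blocks: int = 5
    n_names_per_block: int = 10
    n_controls_per_block: int = 10
    min_gap: float = 30.0
    lead_exclusion: float = 60.0
    tail_exclusion: float = 30.0
    control_min_dist: float = 1.5
    kernel_att: GaborKernel = field(default_factory=lambda: GaborKernel(0.156, 0.05))
    kernel_ign: GaborKernel = field(default_factory=lambda: GaborKernel(0.050, 0.03))
    gain_att: float = 1.5
    gain_ign: float = 1.0
    post_event_gain_att: float = 1.2
    post_event_gain_ign: float = 1.3
    post_event_window: float = 5.6
    p3_latency: float = 0.760
    p3_amplitude: float = 5.0  # uV at the topography peak
    p3_rise: float = 0.080  # Gaussian SD of the rising flank, s
    p3_fall: float = 0.250  # exponential decay constant of the falling flank, s
    p3_topography: np.ndarray | None = None
    noise_rms: float = 20.0  # uV per channel
    noise_exponent: float = 1.0  # 1/f^alpha
    snr_db: float | None = None  # if set, overrides noise_rms to hit this SNR
    blink_rate: float = 0.0  # blinks per minute; adds two EOG channels when > 0
    blink_amplitude: float = 150.0  # uV at the EOG sites
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_eeg <= 0:
            raise ValueError("fs_eeg must be positive")
        if min(self.gain_att, self.gain_ign) < 0:
            raise ValueError("gains must be non-negative")
        if not 0 < self.p3_latency < 1.5:
            raise ValueError("p3_latency must lie in (0, 1.5) s")
        for topo in (self.kernel_att.topography, self.kernel_ign.topography, self.p3_topography):
            if topo is not None and len(topo) != self.n_channels:
                raise ValueError("topography length must equal n_channels")

    def channels(self) -> list[str]:
        return montage.default_channels(self.n_channels)

    def resolved_topographies(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        ch = self.channels()
        att = self.kernel_att.topography
        ign = self.kernel_ign.topography
        p3 = self.p3_topography
        if att is None:
            att = montage.temporal_topography(ch)
        if ign is None:
            ign = montage.frontocentral_topography(ch)
        if p3 is None:
            p3 = montage.posterior_topography(ch)
        return np.asarray(att, float), np.asarray(ign, float), np.asarray(p3, float)


@dataclass
class GroundTruth:
    """Everything the simulator injected, for validation of the analyses."""

    events: pd.DataFrame
    kernel_att: GaborKernel
    kernel_ign: GaborKernel
    gain_att_course: np.ndarray
    gain_ign_course: np.ndarray
    p3_latency: float
    p3_amplitude: float
    p3_topography: np.ndarray
    blink_course: np.ndarray | None = None
    seed: int = 0

    def to_json(self) -> str:
        def enc(o):
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, pd.DataFrame):
                return o.to_dict(orient="list")
            if dataclasses.is_dataclass(o):
                return dataclasses.asdict(o)
            raise TypeError(type(o))

        return json.dumps(dataclasses.asdict(self), default=enc)


def p3_waveform(t_rel: np.ndarray, rise: float, fall: float) -> np.ndarray:
    """Unit-peak P3-like deflection: Gaussian rise, exponential decay.

    ``t_rel`` is time relative to the peak. The classic P3 morphology is
    asymmetric — a fast build-up and a slow return to baseline.
    """
    t = np.asarray(t_rel, float)
    out = np.where(t <= 0, np.exp(-0.5 * (t / rise) ** 2), np.exp(-t / fall))
    return out


def pink_noise(
    n_channels: int, n_samples: int, fs: float, rms: float, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """Gaussian 1/f^alpha noise, per-channel RMS fixed to ``rms``."""
    from scipy import fft as sfft

    n_fft = sfft.next_fast_len(n_samples)
    white = rng.standard_normal((n_channels, n_fft))
    spec = sfft.rfft(white, axis=1)
    freqs = sfft.rfftfreq(n_fft, 1 / fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-exponent / 2)
    shaping[0] = 0.0  # no DC
    out = sfft.irfft(spec * shaping, n=n_fft, axis=1)[:, :n_samples]
    scale = rms / np.sqrt(np.mean(out**2, axis=1, keepdims=True))
    return out * scale


def gen_envelope_pair(
    duration: float, fs: float = 500.0, seed: int = 0
) -> tuple[Envelope, Envelope]:
    """Two mutually uncorrelated speech-like envelopes.

    Each is half-wave-rectified 1-8 Hz band noise, lightly smoothed, so the
    spectrum concentrates below 15 Hz with the syllable-rate emphasis of
    natural speech.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    n = int(round(duration * fs))
    rng = np.random.default_rng(seed)
    sos = signal.butter(4, [1.0, 8.0], btype="bandpass", fs=fs, output="sos")
    envs = []
    for _ in range(2):
        x = rng.standard_normal(n + int(4 * fs))
        x = signal.sosfiltfilt(sos, x)[int(2 * fs) : int(2 * fs) + n]
        x = np.maximum(x, 0.0)
        # light smoothing rounds the rectification corners (keeps power < 15 Hz)
        x = signal.sosfiltfilt(signal.butter(2, 12.0, fs=fs, output="sos"), x)
        envs.append(Envelope(np.maximum(x, 0.0), fs))
    return envs[0], envs[1]


def _place_with_gaps(
    n: int, low: float, high: float, min_gap: float, rng: np.random.Generator
) -> np.ndarray:
    """n sorted points in [low, high] with all pairwise gaps >= min_gap."""
    span = high - low
    slack = span - (n - 1) * min_gap
    if n < 0:
        raise ValueError("negative event count")
    if n == 0:
        return np.empty(0)
    if slack < 0:
        raise InfeasibleScheduleError(
            f"{n} events with {min_gap} s gaps do not fit in [{low}, {high}] s"
        )
    u = np.sort(rng.uniform(0, slack, size=n))
    return low + u + np.arange(n) * min_gap


def gen_event_schedule(
    block_length: float = 600.0,
    n_names: int = 10,
    min_gap: float = 30.0,
    lead_exclusion: float = 60.0,
    tail_exclusion: float = 30.0,
    seed: int = 0,
    n_controls: int = 0,
    control_min_dist: float = 1.5,
    fs: float = 500.0,
    block: int = 1,
    condition: str = "none",
) -> pd.DataFrame:
    """Name (and control-word) onsets satisfying the placement constraints.

    Names: none in the first ``lead_exclusion`` seconds or last
    ``tail_exclusion`` seconds of the block, pairwise at least ``min_gap``
    apart. Controls obey the same rules and additionally keep
    ``control_min_dist`` seconds away from every name. Infeasible requests
    raise :class:`InfeasibleScheduleError`.
    """
    rng = np.random.default_rng(seed)
    low, high = lead_exclusion, block_length - tail_exclusion
    if n_names > 0 and (high - low) < (n_names - 1) * min_gap:
        raise InfeasibleScheduleError(
            f"{n_names} names with {min_gap} s gaps do not fit in "
            f"[{low}, {high}] s of a {block_length} s block"
        )
    names = _place_with_gaps(n_names, low, high, min_gap, rng)

    controls = np.empty(0)
    if n_controls > 0:
        for _restart in range(100):
            placed: list[float] = []
            for _ in range(n_controls):
                for _try in range(2000):
                    cand = rng.uniform(low, high)
                    far_from_controls = all(abs(cand - c) >= min_gap for c in placed)
                    far_from_names = n_names == 0 or np.min(np.abs(names - cand)) >= control_min_dist
                    if far_from_controls and far_from_names:
                        placed.append(cand)
                        break
                else:
                    break  # dead end; restart the whole control set
            if len(placed) == n_controls:
                controls = np.sort(np.asarray(placed))
                break
        else:
            raise InfeasibleScheduleError("could not place control words away from names")

    onsets = np.concatenate([names, controls])
    types = ["name"] * len(names) + ["control"] * len(controls)
    order = np.argsort(onsets, kind="stable")
    return make_event_table(
        onsets[order], [types[i] for i in order], fs, block=block, condition=condition
    )


def simulate_eeg(
    env_att: Envelope, env_ign: Envelope, events: pd.DataFrame, cfg: SimConfig
) -> tuple[EegRecording, GroundTruth]:
    """Forward-model a block of EEG from the two envelopes and the events.

    Per channel c:  x_c(t) = topo_att[c] * g_att(t) * (k_att * env_att)(t)
                           + topo_ign[c] * g_ign(t) * (k_ign * env_ign)(t)
                           + P3 injections at name onsets + 1/f noise
    with g(t) the stream gain, multiplied by its post-event factor inside
    the rectangular window after each name onset.
    """
    if env_att.fs != cfg.fs_eeg or env_ign.fs != cfg.fs_eeg:
        raise ValueError("envelopes must be sampled at cfg.fs_eeg")
    if env_att.n_samples != env_ign.n_samples:
        raise ValueError("envelopes must have equal length")
    n = env_att.n_samples
    fs = cfg.fs_eeg
    rng = np.random.default_rng(cfg.seed)
    topo_att, topo_ign, topo_p3 = cfg.resolved_topographies()
    ch_names = cfg.channels()

    name_onsets = events.loc[events["type"] == "name", "onset_s"].to_numpy()
    g_att = np.full(n, cfg.gain_att)
    g_ign = np.full(n, cfg.gain_ign)
    for on in name_onsets:
        i0 = int(round(on * fs))
        i1 = min(n, int(round((on + cfg.post_event_window) * fs)))
        g_att[i0:i1] = cfg.gain_att * cfg.post_event_gain_att
        g_ign[i0:i1] = cfg.gain_ign * cfg.post_event_gain_ign

    sig_att = signal.fftconvolve(env_att.samples, cfg.kernel_att.lag_course(fs))[:n] * g_att
    sig_ign = signal.fftconvolve(env_ign.samples, cfg.kernel_ign.lag_course(fs))[:n] * g_ign
    data = topo_att[:, None] * sig_att[None, :] + topo_ign[:, None] * sig_ign[None, :]

    p3_course = np.zeros(n)
    if cfg.p3_amplitude != 0:
        t = np.arange(n) / fs
        for on in name_onsets:
            mu = on + cfg.p3_latency
            lo = max(0, int((mu - 9 * cfg.p3_rise) * fs))
            hi = min(n, int((mu + 26 * cfg.p3_fall) * fs) + 1)
            p3_course[lo:hi] += p3_waveform(t[lo:hi] - mu, cfg.p3_rise, cfg.p3_fall)
        data += cfg.p3_amplitude * topo_p3[:, None] * p3_course[None, :]

    if cfg.snr_db is not None:
        sig_rms = float(np.sqrt(np.mean(data**2)))
        noise_rms = sig_rms * 10 ** (-cfg.snr_db / 20) if sig_rms > 0 else cfg.noise_rms
    else:
        noise_rms = cfg.noise_rms

    blink_course = None
    if cfg.blink_rate > 0:
        ch_names = ch_names + montage.EOG_CHANNELS
        data = np.vstack([data, np.zeros((2, n))])
        blink_course = np.zeros(n)
        n_blinks = rng.poisson(cfg.blink_rate * (n / fs) / 60.0)
        width = int(round(0.300 * fs))
        template = 0.5 * (1 - np.cos(2 * np.pi * np.arange(width) / width))
        for start in np.sort(rng.integers(0, max(1, n - width), size=n_blinks)):
            blink_course[start : start + width] += template
        topo_blink = montage.frontal_topography(ch_names)
        data = data + cfg.blink_amplitude * topo_blink[:, None] * blink_course[None, :]

    if noise_rms > 0:
        data = data + pink_noise(len(ch_names), n, fs, noise_rms, cfg.noise_exponent, rng)

    rec = EegRecording(data=data, fs=fs, ch_names=ch_names, reference="nose", events=events)
    gt = GroundTruth(
        events=events,
        kernel_att=cfg.kernel_att,
        kernel_ign=cfg.kernel_ign,
        gain_att_course=g_att,
        gain_ign_course=g_ign,
        p3_latency=cfg.p3_latency,
        p3_amplitude=cfg.p3_amplitude,
        p3_topography=topo_p3,
        blink_course=blink_course,
        seed=cfg.seed,
    )
    return rec, gt


def simulate_block(
    cfg: SimConfig, block: int, condition: str, seed: int
) -> tuple[EegRecording, Envelope, Envelope, GroundTruth]:
    """One block: envelopes, schedule, and forward-modelled EEG.

    Block 1 carries no names (only a block_start marker), matching the
    familiarization block of the paradigm.
    """
    env_att, env_ign = gen_envelope_pair(cfg.block_length, cfg.fs_eeg, seed=seed)
    n_names = 0 if block == 1 else cfg.n_names_per_block
    n_controls = 0 if block == 1 else cfg.n_controls_per_block
    events = gen_event_schedule(
        cfg.block_length,
        n_names,
        cfg.min_gap,
        cfg.lead_exclusion,
        cfg.tail_exclusion,
        seed=seed + 1,
        n_controls=n_controls,
        control_min_dist=cfg.control_min_dist,
        fs=cfg.fs_eeg,
        block=block,
        condition=condition,
    )
    block_cfg = dataclasses.replace(cfg, seed=seed + 2)
    rec, gt = simulate_eeg(env_att, env_ign, events, block_cfg)
    return rec, env_att, env_ign, gt
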