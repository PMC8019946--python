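"""Stimulus audio processing.

Narrative preparation (silence shortening, RMS balancing), embedding of a
spoken name into the to-be-ignored narrative, and extraction of the speech
envelope that the tracking analysis correlates with the EEG.

The envelope chain is: absolute Hilbert transform -> 15 Hz low-pass ->
first derivative -> half-wave rectification -> anti-aliased resampling to
the EEG rate. The derivative accentuates word/syllable onsets; rectification
keeps rising slopes only, so the result is non-negative by construction.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np
from scipy import signal

from .containers import AudioTrack, Envelope
from .filters import design_fir, filtfilt_fir

#: silence criterion: short-time RMS in 10 ms hops below -40 dB re whole-track RMS
SILENCE_THRESHOLD_DB = -40.0
SILENCE_HOP_S = 0.010
SILENCE_MIN_DUR_S = 0.050


def detect_silences(
    audio: AudioTrack,
    threshold_db: float = SILENCE_THRESHOLD_DB,
    min_dur: float = SILENCE_MIN_DUR_S,
    hop: float = SILENCE_HOP_S,
) -> list[tuple[float, float]]:
    """Maximal intervals (seconds) where short-time RMS stays below threshold.

    Threshold is relative to the whole-track RMS. Frames are consecutive
    ``hop``-long windows; an interval must span at least ``min_dur``.
    """
    if min_dur <= 0:
        raise ValueError("min_dur must be positive")
    x = audio.samples
    if x.size == 0:
        return []
    hop_n = max(1, int(round(hop * audio.fs)))
    n_frames = x.size // hop_n
    track_rms = audio.rms()
    if track_rms == 0:
        return [(0.0, x.size / audio.fs)] if x.size / audio.fs >= min_dur else []
    frames = x[: n_frames * hop_n].reshape(n_frames, hop_n)
    frame_rms = np.sqrt(np.mean(frames**2, axis=1))
    quiet = frame_rms < track_rms * 10 ** (threshold_db / 20)
    # trailing partial frame counts as quiet only if its RMS is below threshold
    tail = x[n_frames * hop_n :]
    tail_quiet = tail.size > 0 and np.sqrt(np.mean(tail**2)) < track_rms * 10 ** (threshold_db / 20)

    intervals: list[tuple[float, float]] = []
    start = None
    flags = list(quiet) + ([tail_quiet] if tail.size else [])
    bounds = [i * hop_n for i in range(len(flags))] + [x.size]
    for i, q in enumerate(flags):
        if q and start is None:
            start = bounds[i]
        elif not q and start is not None:
            intervals.append((start, bounds[i]))
            start = None
    if start is not None:
        intervals.append((start, x.size))
    fs = audio.fs
    return [(a / fs, b / fs) for a, b in intervals if (b - a) / fs >= min_dur]


def shorten_silences(
    audio: AudioTrack,
    max_silence: float = 0.5,
    threshold_db: float = SILENCE_THRESHOLD_DB,
) -> AudioTrack:
    """Cut every silent interval longer than ``max_silence`` down to it."""
    silences = detect_silences(audio, threshold_db=threshold_db, min_dur=max_silence)
    keep = np.ones(audio.samples.size, dtype=bool)
    fs = audio.fs
    for a, b in silences:
        ia, ib = int(round(a * fs)), int(round(b * fs))
        excess = (ib - ia) - int(round(max_silence * fs))
        if excess > 0:
            # drop the middle of the silence, keeping its flanks intact
            mid = (ia + ib) // 2
            keep[mid - excess // 2 : mid - excess // 2 + excess] = False
    return AudioTrack(audio.samples[keep], fs)


def rms_balance(a: AudioTrack, b: AudioTrack) -> AudioTrack:
    """Scale ``b`` so its RMS matches that of ``a``."""
    rms_b = b.rms()
    if rms_b == 0:
        raise ValueError("cannot balance a silent track (zero RMS)")
    return AudioTrack(b.samples * (a.rms() / rms_b), b.fs)


def _silence_excluded_rms(audio: AudioTrack) -> float:
    """RMS after removing all detected silent periods (any length)."""
    silences = detect_silences(audio, min_dur=SILENCE_MIN_DUR_S)
    keep = np.ones(audio.samples.size, dtype=bool)
    fs = audio.fs
    for a, b in silences:
        keep[int(round(a * fs)) : int(round(b * fs))] = False
    voiced = audio.samples[keep]
    if voiced.size == 0:
        raise ValueError("window is entirely silent; no RMS reference for the name")
    return float(np.sqrt(np.mean(voiced**2)))


def embed_name(
    narrative: AudioTrack,
    name_clip: AudioTrack,
    onset: float,
    fade: float = 0.020,
    gap: float = 0.700,
    rms_window: float = 2.0,
) -> AudioTrack:
    """Replace a word in the narrative with the listener's name.

    The narrative fades out over 20 ms before ``onset``, is muted for the
    700 ms gap, and fades back in over 20 ms. The name clip is scaled to
    the silence-excluded RMS of the 2 s preceding the onset (so it blends
    into the local sound level) and inserted at the onset. Output length
    equals input length.
    """
    fs = narrative.fs
    if name_clip.fs != fs:
        raise ValueError("name clip and narrative must share a sampling rate")
    if name_clip.duration > gap:
        raise ValueError(
            f"name clip ({name_clip.duration:.3f} s) longer than mute gap ({gap} s)"
        )
    i_on = int(round(onset * fs))
    n_fade = int(round(fade * fs))
    n_gap = int(round(gap * fs))
    i_rms0 = int(round((onset - rms_window) * fs))
    if i_on - n_fade < 0 or i_rms0 < 0 or i_on + n_gap + n_fade > narrative.samples.size:
        raise ValueError("onset too close to the track edge for fade/gap/RMS window")

    target_rms = _silence_excluded_rms(AudioTrack(narrative.samples[i_rms0:i_on], fs))
    clip_rms = name_clip.rms()
    if clip_rms == 0:
        raise ValueError("name clip is silent")
    scaled_name = name_clip.samples * (target_rms / clip_rms)

    out = narrative.samples.copy()
    ramp = np.linspace(1.0, 0.0, n_fade, endpoint=False)
    out[i_on - n_fade : i_on] *= ramp
    out[i_on : i_on + n_gap] = 0.0
    out[i_on + n_gap : i_on + n_gap + n_fade] *= ramp[::-1]
    out[i_on : i_on + scaled_name.size] += scaled_name
    return AudioTrack(out, fs)


def extract_envelope(
    audio: AudioTrack, fs_out: float = 500.0, lp_edge: float = 15.0
) -> Envelope:
    """Speech envelope: |Hilbert| -> 15 Hz LP -> d/dt -> rectify -> resample."""
    if fs_out > audio.fs:
        raise ValueError("output rate above the audio rate")
    x = audio.samples
    env = np.abs(signal.hilbert(x))
    taps = design_fir(audio.fs, lp_edge, "lowpass")
    if env.size < taps.size:
        raise ValueError("audio shorter than the envelope low-pass filter")
    env = filtfilt_fir(taps, env)
    # first difference scaled to a derivative, zero-padded to preserve length
    env = np.diff(env, prepend=env[0]) * audio.fs
    env = np.maximum(env, 0.0)
    frac = Fraction(fs_out / audio.fs).limit_denominator(10000)
    env = signal.resample_poly(env, frac.numerator, frac.denominator)
    return Envelope(np.maximum(env, 0.0), fs_out)
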