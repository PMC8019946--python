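"""Speech-envelope tracking via lagged cross-correlation and global field power.

Each 5-s EEG segment is cross-correlated per channel with the matching
5-s envelope segment at lags from -1000 to +1000 ms (positive lag = EEG
follows the stimulus). The across-channel standard deviation of the
per-channel correlation values at each lag — a GFP-style magnitude —
yields a channel-selection-free tracking profile, summarized as the mean
magnitude over lags 0-500 ms. A mismatched control pairs envelope
segments with non-corresponding EEG segments to estimate chance level.

Name-locked analysis compares the 5-s segment ending at name onset
([-5, 0) s) with the one starting 0.6 s after it ([0.6, 5.6) s), the
0.6 s containing the name itself being cut out.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .containers import EegRecording, Envelope
from .filters import bandlimit

TRACK_LP_EDGE, TRACK_LP_ORDER = 15.0, 440
TRACK_HP_EDGE, TRACK_HP_ORDER = 1.0, 1650
SEG_LEN_S = 5.0
MAX_LAG_S = 1.0
SUMMARY_WINDOW_S = (0.0, 0.5)
AFTER_OFFSET_S = 0.6  # the segment after the name starts here (name cut out)
N_FLANK = 6


def prep_tracking(rec: EegRecording) -> EegRecording:
    """Common-average reference, then 15 Hz LP (order 440) and 1 Hz HP
    (order 1,650), zero-phase Hamming FIR."""
    if rec.n_channels < 2:
        raise ValueError("common-average reference needs at least 2 channels")
    data = rec.data - rec.data.mean(axis=0, keepdims=True)
    data = bandlimit(
        data, rec.fs,
        lp_edge=TRACK_LP_EDGE, lp_order=TRACK_LP_ORDER,
        hp_edge=TRACK_HP_EDGE, hp_order=TRACK_HP_ORDER,
    )
    return rec.copy_with(data=data, reference="common average")


@dataclass
class CrossCorrSet:
    """Per-channel cross-correlation values over the lag axis."""

    values: np.ndarray  # (n_channels, n_lags)
    lags: np.ndarray  # s, symmetric about 0
    role: str = "attended"  # attended | ignored | control
    n_segments: int = 1


@dataclass
class MagnitudeFunction:
    """SD-over-channels magnitude per lag plus its 0-500 ms summary."""

    magnitude: np.ndarray
    lags: np.ndarray
    summary: float
    role: str = "attended"


def segment_consecutive(
    rec: EegRecording, env_att: Envelope, env_ign: Envelope | None = None,
    seg_len: float = SEG_LEN_S,
) -> list[dict]:
    """Non-overlapping consecutive segments, EEG mean-subtracted per channel.

    Returns index-aligned dicts with keys ``eeg``, ``att`` (and ``ign``);
    the trailing partial segment is dropped.
    """
    n_seg_samples = int(round(seg_len * rec.fs))
    if rec.n_samples < n_seg_samples:
        raise ValueError("recording shorter than one segment")
    if env_att.n_samples != rec.n_samples or (
        env_ign is not None and env_ign.n_samples != rec.n_samples
    ):
        raise ValueError("envelope and recording must be aligned and equal length")
    n_seg = rec.n_samples // n_seg_samples
    out = []
    for k in range(n_seg):
        sl = slice(k * n_seg_samples, (k + 1) * n_seg_samples)
        eeg = rec.data[:, sl]
        seg = {"eeg": eeg - eeg.mean(axis=1, keepdims=True), "att": env_att.samples[sl]}
        if env_ign is not None:
            seg["ign"] = env_ign.samples[sl]
        out.append(seg)
    return out


def segment_event_locked(
    rec: EegRecording,
    env_att: Envelope,
    env_ign: Envelope,
    events: pd.DataFrame | None = None,
    seg_len: float = SEG_LEN_S,
    after_offset: float = AFTER_OFFSET_S,
    n_flank: int = N_FLANK,
) -> tuple[dict[int, list[dict]], list[dict]]:
    """Flanking 5-s segments around each name onset.

    Slot -k spans [-k*5, -(k-1)*5) s before the onset; slot +k spans
    [0.6+(k-1)*5, 0.6+k*5) s after it. Segments leaving the block are
    excluded with a log entry. Returns (slots, exclusion_log); each slot
    maps to per-event dicts with mean-subtracted EEG and both envelopes.
    """
    if events is None:
        events = rec.events
    names = events[events["type"] == "name"]
    if len(names) == 0:
        raise ValueError("no name events to lock to")
    n_seg = int(round(seg_len * rec.fs))
    n_off = int(round(after_offset * rec.fs))
    slots: dict[int, list[dict]] = {
        s: [] for s in list(range(-n_flank, 0)) + list(range(1, n_flank + 1))
    }
    excluded: list[dict] = []
    for _, row in names.iterrows():
        onset = int(row["sample"])
        for k in range(1, n_flank + 1):
            for slot, start in ((-k, onset - k * n_seg), (k, onset + n_off + (k - 1) * n_seg)):
                stop = start + n_seg
                if start < 0 or stop > rec.n_samples:
                    excluded.append(
                        {"onset_s": float(row["onset_s"]), "slot": slot,
                         "reason": "segment outside block"}
                    )
                    continue
                eeg = rec.data[:, start:stop]
                slots[slot].append(
                    {
                        "eeg": eeg - eeg.mean(axis=1, keepdims=True),
                        "att": env_att.samples[start:stop],
                        "ign": env_ign.samples[start:stop],
                    }
                )
    return slots, excluded


def xcorr_channels(
    eeg_seg: np.ndarray, env_seg: np.ndarray, fs: float, max_lag: float = MAX_LAG_S,
    role: str = "attended",
) -> CrossCorrSet:
    """Normalized lagged cross-correlation of every channel with the envelope.

    r(tau) = sum_t e~(t - tau) x~(t) / (||e~|| ||x~||), computed over the
    overlapping support with full-segment demeaning and norms (coefficient
    convention, so values lie in [-1, 1] and the profile is invariant to
    affine amplitude changes of either input). Positive tau means the EEG
    follows the envelope.
    """
    x = np.atleast_2d(np.asarray(eeg_seg, float))
    e = np.asarray(env_seg, float)
    n = e.size
    if x.shape[1] != n:
        raise ValueError("EEG segment and envelope segment must have equal length")
    lag_n = int(round(max_lag * fs))
    if lag_n >= n:
        raise ValueError("max_lag must be shorter than the segment")
    xt = x - x.mean(axis=1, keepdims=True)
    et = e - e.mean()
    norm_e = np.linalg.norm(et)
    norm_x = np.linalg.norm(xt, axis=1)
    if norm_e == 0:
        raise ValueError("zero-variance envelope segment")
    if np.any(norm_x == 0):
        bad = int(np.flatnonzero(norm_x == 0)[0])
        raise ValueError(f"zero-variance EEG segment in channel index {bad}")
    # full cross-correlation; index (n-1) + tau holds sum_s e(s) x(s+tau)
    full = signal.fftconvolve(xt, et[::-1][None, :], mode="full", axes=1)
    vals = full[:, n - 1 - lag_n : n + lag_n] / (norm_e * norm_x[:, None])
    lags = np.arange(-lag_n, lag_n + 1) / fs
    return CrossCorrSet(values=vals, lags=lags, role=role, n_segments=1)


def average_sets(sets: list[CrossCorrSet]) -> CrossCorrSet:
    """Element-wise mean of cross-correlation sets (equal axes required)."""
    if not sets:
        raise ValueError("cannot average an empty list of sets")
    first = sets[0]
    for s in sets[1:]:
        if s.values.shape != first.values.shape or not np.array_equal(s.lags, first.lags):
            raise ValueError("sets must share lag axis and channel count")
    vals = np.mean([s.values for s in sets], axis=0)
    return CrossCorrSet(
        values=vals, lags=first.lags.copy(), role=first.role,
        n_segments=sum(s.n_segments for s in sets),
    )


def gfp_magnitude(
    cc: CrossCorrSet, ddof: int = 1, summary_window: tuple[float, float] = SUMMARY_WINDOW_S
) -> MagnitudeFunction:
    """SD over channels at each lag; summary = mean over 0-500 ms lags."""
    if cc.values.shape[0] < 2:
        raise ValueError("GFP needs at least 2 channels")
    mag = cc.values.std(axis=0, ddof=ddof)
    return MagnitudeFunction(
        magnitude=mag, lags=cc.lags.copy(),
        summary=summary_score(mag, cc.lags, summary_window), role=cc.role,
    )


def summary_score(
    magnitude: np.ndarray, lags: np.ndarray, window: tuple[float, float] = SUMMARY_WINDOW_S
) -> float:
    sel = (lags >= window[0]) & (lags <= window[1])
    return float(magnitude[sel].mean())


def xcorr_over_segments(
    segments: list[dict], fs: float, stream: str, max_lag: float = MAX_LAG_S,
    role: str | None = None,
) -> CrossCorrSet:
    """Per-segment cross-correlation with the named envelope stream,
    averaged over segments."""
    role = role or ("attended" if stream == "att" else "ignored")
    sets = [xcorr_channels(s["eeg"], s[stream], fs, max_lag, role) for s in segments]
    return average_sets(sets)


def control_scores(
    segments: list[dict], fs: float, stream: str = "att", max_lag: float = MAX_LAG_S,
    shift: int = 1,
) -> MagnitudeFunction:
    """Mismatched control: envelope segment k against EEG segment k+shift
    (circular, fixed-point free), then the usual average/GFP chain."""
    if len(segments) < 2:
        raise ValueError("mismatched control needs at least 2 segments")
    if shift % len(segments) == 0:
        raise ValueError("shift must not map segments onto themselves")
    sets = []
    n = len(segments)
    for k in range(n):
        sets.append(
            xcorr_channels(
                segments[(k + shift) % n]["eeg"], segments[k][stream], fs, max_lag, "control"
            )
        )
    return gfp_magnitude(average_sets(sets))


def event_locked_scores(
    slots: dict[int, list[dict]], fs: float, max_lag: float = MAX_LAG_S
) -> dict[str, dict[int, float]]:
    """Summary score per slot and stream: cross-correlation sets averaged
    over events first, then GFP, then the 0-500 ms summary."""
    out: dict[str, dict[int, float]] = {"att": {}, "ign": {}}
    for stream in ("att", "ign"):
        for slot, segs in slots.items():
            if not segs:
                continue
            cc = xcorr_over_segments(segs, fs, stream, max_lag)
            out[stream][slot] = gfp_magnitude(cc).summary
    return out


def before_after_contrast(
    slots: dict[int, list[dict]], fs: float, max_lag: float = MAX_LAG_S
) -> dict[str, tuple[float, float]]:
    """Adjacent-pair scores: ([-5, 0) before, [0.6, 5.6) after) per stream."""
    if not slots.get(-1) or not slots.get(1):
        raise ValueError("no valid events with both adjacent segments")
    scores = {}
    for stream in ("att", "ign"):
        before = gfp_magnitude(xcorr_over_segments(slots[-1], fs, stream, max_lag)).summary
        after = gfp_magnitude(xcorr_over_segments(slots[1], fs, stream, max_lag)).summary
        scores[stream] = (before, after)
    return scores
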