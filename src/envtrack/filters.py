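"""Hamming-window FIR design and zero-phase application.

All band edges in this pipeline are *pass-band* edges, EEGLAB style: the
designed filter's 6 dB cutoff sits half a transition width beyond the
stated edge (below it for low-pass, above it for high-pass), so the
response at the edge itself stays within about 1 dB of unity. Transition
width follows the Hamming rule ``tw ~= 3.3 / N`` (normalized). Filters are
linear-phase type I (odd length), applied in a single FFT pass with exact
integer group-delay compensation, i.e. zero phase.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import signal

HAMMING_TW_FACTOR = 3.3  # normalized transition width ~ 3.3/numtaps


def transition_width_hz(order: int, fs: float) -> float:
    return HAMMING_TW_FACTOR * fs / (order + 1)


def default_order(edge_hz: float, fs: float, kind: str) -> int:
    """Order by the standard transition-width heuristic.

    Transition width: 25% of the pass-band edge, at least 2 Hz, and for
    high-pass never wider than the edge itself (keeps the stop band above
    0 Hz). Order is rounded up to even so the filter length is odd.
    """
    tw = max(0.25 * edge_hz, 2.0)
    if kind == "highpass":
        tw = min(tw, edge_hz)
    tw = min(tw, fs / 2 - edge_hz)
    order = int(math.ceil(HAMMING_TW_FACTOR * fs / tw))
    return order + order % 2


def design_fir(fs: float, edge_hz: float, kind: str, order: int | None = None) -> np.ndarray:
    """Hamming-window FIR taps for a low- or high-pass with a pass-band edge."""
    if kind not in ("lowpass", "highpass"):
        raise ValueError("kind must be 'lowpass' or 'highpass'")
    if not 0 < edge_hz < fs / 2:
        raise ValueError(f"edge {edge_hz} Hz outside (0, {fs / 2}) Hz")
    if order is None:
        order = default_order(edge_hz, fs, kind)
    if order % 2:
        order += 1  # force type I (odd length) for exact integer group delay
    numtaps = order + 1
    tw = transition_width_hz(order, fs)
    if kind == "lowpass":
        cutoff = min(edge_hz + tw / 2, fs / 2 * 0.999)
        return signal.firwin(numtaps, cutoff, window="hamming", pass_zero=True, fs=fs)
    # high-pass by spectral inversion of a unity-DC low-pass: the DC gain is
    # then exactly zero (offsets are fully removed)
    cutoff = max(edge_hz - tw / 2, 1e-9)
    lp = signal.firwin(numtaps, cutoff, window="hamming", pass_zero=True, fs=fs)
    hp = -lp
    hp[(numtaps - 1) // 2] += 1.0
    return hp


def filtfilt_fir(taps: np.ndarray, x: np.ndarray, axis: int = -1) -> np.ndarray:
    """Apply a linear-phase FIR at zero phase.

    Single FFT convolution pass with the (numtaps-1)/2-sample group delay
    removed; edges see implicit zero padding of half the filter length.
    """
    taps = np.asarray(taps, float)
    if taps.size % 2 == 0:
        raise ValueError("zero-phase application requires an odd-length (type I) FIR")
    n = x.shape[axis]
    if n < taps.size:
        raise ValueError(f"signal ({n} samples) shorter than filter ({taps.size} taps)")
    delay = (taps.size - 1) // 2
    shape = [1] * x.ndim
    shape[axis] = taps.size
    full = signal.fftconvolve(x, taps.reshape(shape), mode="full", axes=axis)
    sl = [slice(None)] * x.ndim
    sl[axis] = slice(delay, delay + n)
    return full[tuple(sl)]


def bandlimit(
    x: np.ndarray,
    fs: float,
    lp_edge: float | None = None,
    hp_edge: float | None = None,
    lp_order: int | None = None,
    hp_order: int | None = None,
    axis: int = -1,
) -> np.ndarray:
    """Low-pass then high-pass (the order every stage of this pipeline uses)."""
    out = x
    if lp_edge is not None:
        out = filtfilt_fir(design_fir(fs, lp_edge, "lowpass", lp_order), out, axis=axis)
    if hp_edge is not None:
        out = filtfilt_fir(design_fir(fs, hp_edge, "highpass", hp_order), out, axis=axis)
    return out


def attenuation_db(taps: np.ndarray, fs: float, freq_hz: float) -> float:
    """Magnitude response of the designed filter at one frequency, in dB."""
    w, h = signal.freqz(taps, worN=[freq_hz], fs=fs)
    return float(20 * np.log10(np.abs(h[0]) + 1e-300))
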