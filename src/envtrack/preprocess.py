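"""Continuous-EEG artifact correction.

Stages: marker-delay correction (the amplifier's event stream lags the
EEG by a constant 102 ms), 40 Hz low-pass / 2 Hz high-pass filtering for
decomposition, joint-probability rejection of atypical 1-s segments, and
linear ICA whose weights — fitted on the filtered, artifact-screened data
— are applied to the *raw* recording so only the artifact components are
removed from otherwise unfiltered data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .containers import EegRecording
from .filters import bandlimit

EVENT_DELAY_S = 0.102  # EEG leads the marker stream by this constant


def correct_event_delay(
    events: pd.DataFrame,
    delay: float = EVENT_DELAY_S,
    fs: float = 500.0,
    n_samples: int | None = None,
) -> pd.DataFrame:
    """Shift every marker onset by +delay onto true EEG time.

    The amplifier wrote markers ``delay`` seconds early relative to the
    data stream, so markers move *later*. Onsets that leave the recording
    are flagged in an ``in_range`` column, never dropped.
    """
    if not np.isfinite(delay):
        raise ValueError("delay must be finite")
    out = events.copy()
    out["onset_s"] = out["onset_s"] + delay
    out["sample"] = np.round(out["onset_s"] * fs).astype(int)
    if n_samples is not None:
        out["in_range"] = (out["sample"] >= 0) & (out["sample"] < n_samples)
    return out


def prefilter_for_ica(rec: EegRecording) -> EegRecording:
    """40 Hz low-pass then 2 Hz high-pass, both zero-phase Hamming FIR."""
    if rec.fs < 100:
        raise ValueError("sampling rate too low for the 40 Hz low-pass")
    data = bandlimit(rec.data, rec.fs, lp_edge=40.0, hp_edge=2.0, axis=-1)
    return rec.copy_with(data=data)


@dataclass
class SegmentMask:
    """Keep/reject flags for consecutive 1-s segments plus diagnostics."""

    keep: np.ndarray  # (n_segments,) bool
    stats: np.ndarray  # (n_channels, n_segments) z-scored improbability
    seg_len_samples: int

    @property
    def n_segments(self) -> int:
        return self.keep.size

    def kept_sample_mask(self, n_samples: int) -> np.ndarray:
        mask = np.zeros(n_samples, dtype=bool)
        for k in np.flatnonzero(self.keep):
            mask[k * self.seg_len_samples : (k + 1) * self.seg_len_samples] = True
        return mask


def mark_bad_segments(
    rec: EegRecording,
    seg_len: float = 1.0,
    local_z: float = 2.0,
    global_z: float = 2.0,
    n_bins: int = 100,
) -> SegmentMask:
    """Joint-probability screening of consecutive segments.

    Per channel, each segment's improbability is the negative mean log
    density of its samples under the channel's histogram-estimated
    amplitude distribution; z-scored over segments. A segment is rejected
    if any single channel exceeds ``local_z`` or the channel average
    exceeds ``global_z``.
    """
    seg_n_f = seg_len * rec.fs
    seg_n = int(round(seg_n_f))
    if abs(seg_n_f - seg_n) > 1e-9:
        raise ValueError("seg_len times sampling rate must be an integer")
    n_seg = rec.n_samples // seg_n
    if n_seg < 2:
        raise ValueError("need at least 2 segments for joint-probability screening")

    x = rec.data[:, : n_seg * seg_n]
    improb = np.empty((rec.n_channels, n_seg))
    for c in range(rec.n_channels):
        counts, edges = np.histogram(x[c], bins=n_bins)
        widths = np.diff(edges)
        dens = counts / (counts.sum() * widths)
        idx = np.clip(np.searchsorted(edges, x[c], side="right") - 1, 0, n_bins - 1)
        logp = np.log(dens[idx] + 1e-300)
        improb[c] = -logp.reshape(n_seg, seg_n).mean(axis=1)
    mu = improb.mean(axis=1, keepdims=True)
    sd = improb.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (improb - mu) / sd

    reject_local = np.any(z > local_z, axis=0)
    reject_global = z.mean(axis=0) > global_z
    keep = ~(reject_local | reject_global)
    return SegmentMask(keep=keep, stats=z, seg_len_samples=seg_n)


@dataclass
class IcaModel:
    """Linear decomposition: sources = unmixing @ x.

    The application path is purely linear (no mean handling), so zeroing
    no components reproduces the input exactly and zeroing all of them
    yields all-zero output. ``fit_mean`` records the channel means of the
    fitting data for reference only.
    """

    unmixing: np.ndarray  # (n_components, n_channels)
    mixing: np.ndarray  # (n_channels, n_components)
    fit_mean: np.ndarray  # (n_channels,)
    seed: int = 0

    @property
    def n_components(self) -> int:
        return self.unmixing.shape[0]

    def sources(self, data: np.ndarray) -> np.ndarray:
        return self.unmixing @ data


def fit_ica(
    filtered: EegRecording, mask: SegmentMask | None = None, seed: int = 0
) -> IcaModel:
    """Fit a converging linear ICA on filtered data restricted to kept segments."""
    from sklearn.decomposition import FastICA

    data = filtered.data
    if mask is not None:
        data = data[:, mask.kept_sample_mask(filtered.n_samples)]
    ica = FastICA(
        n_components=data.shape[0],
        whiten="unit-variance",
        random_state=seed,
        max_iter=2000,
        tol=1e-4,
    )
    ica.fit(data.T)
    return IcaModel(
        unmixing=ica.components_,
        mixing=ica.mixing_,
        fit_mean=ica.mean_,
        seed=seed,
    )


def auto_artifact_components(
    model: IcaModel, rec: EegRecording, eog_labels: tuple[str, ...] = ("EOG1", "EOG2"),
    corr_threshold: float = 0.8,
) -> list[int]:
    """Components whose |correlation| with an EOG channel exceeds threshold."""
    eog_idx = [rec.ch_names.index(l) for l in eog_labels if l in rec.ch_names]
    if not eog_idx:
        return []
    srcs = model.sources(rec.data)
    out = []
    for k in range(model.n_components):
        for e in eog_idx:
            r = np.corrcoef(srcs[k], rec.data[e])[0, 1]
            if abs(r) > corr_threshold:
                out.append(k)
                break
    return out


def ica_clean(
    raw: EegRecording, model: IcaModel, artifact_components: list[int]
) -> EegRecording:
    """Zero the listed components in the raw data and back-project the rest."""
    bad = list(artifact_components)
    if any(k < 0 or k >= model.n_components for k in bad):
        raise IndexError(f"component index out of range 0..{model.n_components - 1}")
    srcs = model.sources(raw.data)
    srcs[bad, :] = 0.0
    return raw.copy_with(data=model.mixing @ srcs)
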