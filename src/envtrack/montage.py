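"""Channel layout helpers: standard 10-10 positions, scalp topographies,
and nearest-neighbour interpolation weights.

The simulated cap is a 49-channel subset of the extended 10-10 system
(fronto-polar through parietal rows plus the temporal chains, no far
occipital ring), loosely matching a 64-channel cap recorded without the
most occipital and peri-aural sites. Positions come from the bundled
standard montage shipped with MNE.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

# 49 usable scalp sites, ordered front to back.
DEFAULT_49 = [
    "Fp1", "Fpz", "Fp2",
    "AF7", "AF3", "AFz", "AF4", "AF8",
    "F7", "F5", "F3", "F1", "Fz", "F2", "F4", "F6", "F8",
    "FC5", "FC3", "FC1", "FCz", "FC2", "FC4", "FC6",
    "T7", "C5", "C3", "C1", "Cz", "C2", "C4", "C6", "T8",
    "CP5", "CP3", "CP1", "CPz", "CP2", "CP4", "CP6",
    "P7", "P5", "P3", "P1", "Pz", "P2", "P4", "P6", "P8",
]

EOG_CHANNELS = ["EOG1", "EOG2"]


@lru_cache(maxsize=1)
def _standard_positions() -> dict[str, np.ndarray]:
    import mne

    for name in ("colin27_1020", "standard_1020"):
        try:
            m = mne.channels.make_standard_montage(name)
            break
        except Exception:  # pragma: no cover - montage naming across versions
            continue
    pos = m.get_positions()["ch_pos"]
    return {k: np.asarray(v, float) for k, v in pos.items()}


def default_channels(n: int = 49) -> list[str]:
    if n > len(DEFAULT_49):
        raise ValueError(f"at most {len(DEFAULT_49)} default channels available")
    labels = DEFAULT_49[:n]
    if "Pz" not in labels:  # keep the P3 quantification site in every layout
        labels = labels[: n - 1] + ["Pz"]
    return labels


def positions(ch_names: list[str]) -> np.ndarray:
    """3-D head positions (meters) for scalp labels; EOG sites get
    below-the-eye proxies."""
    table = _standard_positions()
    eog_proxy = {"EOG1": "Fp1", "EOG2": "Fp2"}
    out = np.empty((len(ch_names), 3))
    for i, ch in enumerate(ch_names):
        if ch in table:
            out[i] = table[ch]
        elif ch in eog_proxy:
            out[i] = table[eog_proxy[ch]] + np.array([0.0, 0.02, -0.04])
        else:
            raise KeyError(f"no standard position for channel {ch!r}")
    return out


def gaussian_topography(
    ch_names: list[str], centers: list[str], fwhm_m: float = 0.09
) -> np.ndarray:
    """Unit-peak scalp weight map: sum of Gaussians around center electrodes."""
    pos = positions(ch_names)
    sigma = fwhm_m / 2.3548
    w = np.zeros(len(ch_names))
    ctr_pos = positions(centers)
    for c in ctr_pos:
        d = np.linalg.norm(pos - c, axis=1)
        w += np.exp(-0.5 * (d / sigma) ** 2)
    return w / w.max()


def temporal_topography(ch_names: list[str]) -> np.ndarray:
    """Bilateral-temporal map (attended-stream tracking response)."""
    return gaussian_topography(ch_names, ["T7", "T8"])


def frontocentral_topography(ch_names: list[str]) -> np.ndarray:
    """Fronto-central map (ignored-stream tracking response)."""
    return gaussian_topography(ch_names, ["FCz"])


def posterior_topography(ch_names: list[str]) -> np.ndarray:
    """Posterior midline map (P3 response)."""
    return gaussian_topography(ch_names, ["Pz"])


def frontal_topography(ch_names: list[str]) -> np.ndarray:
    """Frontal map used for stereotyped blink artifacts."""
    w = gaussian_topography(ch_names, ["Fp1", "Fp2"], fwhm_m=0.07)
    for i, ch in enumerate(ch_names):
        if ch in EOG_CHANNELS:
            w[i] = 1.2  # EOG sees the blink stronger than any scalp site
    return w


def idw_weights(
    ch_names: list[str], target: str, usable: list[str], k: int = 4
) -> dict[str, float]:
    """Inverse-distance weights of the k nearest usable channels to target."""
    donors = [c for c in usable if c != target]
    if not donors:
        raise ValueError("no donor channels available for interpolation")
    pos = positions(ch_names)
    tpos = pos[ch_names.index(target)]
    dists = {c: float(np.linalg.norm(pos[ch_names.index(c)] - tpos)) for c in donors}
    nearest = sorted(dists, key=dists.get)[: min(k, len(donors))]
    inv = {c: 1.0 / max(dists[c], 1e-9) for c in nearest}
    total = sum(inv.values())
    return {c: v / total for c, v in inv.items()}
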