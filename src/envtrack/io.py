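"""File formats: BrainVision triplets, events TSV, envelope TSV, WAV.

Reading BrainVision goes through MNE; writing is done here (header,
marker, and multiplexed binary data files) in the IEEE_FLOAT_32 and
INT_16 dialects. Event tables travel as tab-separated text with the
columns ``onset_s, sample, type, block, condition`` (0-based samples,
times in seconds).
"""

from __future__ import annotations

import json
import re
from pathlib import Path

import numpy as np
import pandas as pd

from .containers import EegRecording, Envelope, EVENT_COLUMNS, validate_event_table

_VHDR_TEMPLATE = """\
BrainVision Data Exchange Header File Version 1.0

[Common Infos]
Codepage=UTF-8
DataFile={stem}.eeg
MarkerFile={stem}.vmrk
DataFormat=BINARY
DataOrientation=MULTIPLEXED
NumberOfChannels={n_channels}
SamplingInterval={sampling_interval}

[Binary Infos]
BinaryFormat={binary_format}

[Channel Infos]
{channel_lines}
"""


def write_brainvision(
    rec: EegRecording, path: str | Path, fmt: str = "float32", resolution: float = 0.1
) -> Path:
    """Write header/marker/data triplet; returns the .vhdr path.

    ``fmt`` is 'float32' (IEEE_FLOAT_32, data stored in uV) or 'int16'
    (INT_16 with the given resolution in uV per bit).
    """
    path = Path(path)
    if path.suffix == ".vhdr":
        path = path.with_suffix("")
    path.parent.mkdir(parents=True, exist_ok=True)
    stem = path.name
    if fmt == "float32":
        binary_format, res = "IEEE_FLOAT_32", 1.0
        payload = rec.data.T.astype("<f4")  # multiplexed: sample-major
    elif fmt == "int16":
        binary_format, res = "INT_16", resolution
        payload = np.round(rec.data.T / res).astype("<i2")
    else:
        raise ValueError("fmt must be 'float32' or 'int16'")

    channel_lines = "\n".join(
        f"Ch{i + 1}={name},,{res:g},µV" for i, name in enumerate(rec.ch_names)
    )
    vhdr = _VHDR_TEMPLATE.format(
        stem=stem,
        n_channels=rec.n_channels,
        sampling_interval=int(round(1e6 / rec.fs)),
        binary_format=binary_format,
        channel_lines=channel_lines,
    )
    path.with_suffix(".vhdr").write_text(vhdr)
    payload.tofile(path.with_suffix(".eeg"))

    lines = [
        "BrainVision Data Exchange Marker File, Version 1.0",
        "",
        "[Common Infos]",
        "Codepage=UTF-8",
        f"DataFile={stem}.eeg",
        "",
        "[Marker Infos]",
        "Mk1=New Segment,,1,1,0,0",
    ]
    for i, (_, row) in enumerate(rec.events.iterrows(), start=2):
        desc = f"{row['type']}:{row['condition']}:{row['block']}"
        # BrainVision marker positions are 1-based
        lines.append(f"Mk{i}=Stimulus,{desc},{int(row['sample']) + 1},1,0")
    path.with_suffix(".vmrk").write_text("\n".join(lines) + "\n")
    return path.with_suffix(".vhdr")


def _validate_vmrk(vmrk_path: Path) -> None:
    marker_re = re.compile(r"^Mk\d+=[^,]+,[^,]*,\d+,\d+,\d+")
    in_markers = False
    for lineno, line in enumerate(vmrk_path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if stripped.startswith("["):
            in_markers = stripped.lower() == "[marker infos]"
            continue
        if in_markers and stripped and not stripped.startswith(";"):
            if not marker_re.match(stripped):
                raise ValueError(
                    f"malformed marker in {vmrk_path.name} line {lineno}: {stripped!r}"
                )


def read_brainvision(path: str | Path) -> EegRecording:
    """Read a BrainVision triplet into an :class:`EegRecording` (uV)."""
    import mne

    path = Path(path)
    if path.suffix != ".vhdr":
        path = path.with_suffix(".vhdr")
    if not path.exists():
        raise FileNotFoundError(path)
    _validate_vmrk(path.with_suffix(".vmrk"))
    raw = mne.io.read_raw_brainvision(path, preload=True, verbose="error")
    data_uv = raw.get_data() * 1e6
    fs = float(raw.info["sfreq"])
    rows = []
    for ann in raw.annotations:
        desc = ann["description"]
        m = re.match(r"(?:Stimulus/)?(name|control|block_start):(\w+):(\d+)", desc)
        if not m:
            continue
        rows.append(
            {
                "onset_s": float(ann["onset"]),
                "sample": int(round(ann["onset"] * fs)),
                "type": m.group(1),
                "block": int(m.group(3)),
                "condition": m.group(2),
            }
        )
    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    return EegRecording(
        data=data_uv, fs=fs, ch_names=list(raw.ch_names), reference="nose", events=events
    )


def write_events_tsv(events: pd.DataFrame, path: str | Path) -> Path:
    validate_event_table(events)
    path = Path(path)
    events[EVENT_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_events_tsv(path: str | Path) -> pd.DataFrame:
    events = pd.read_csv(path, sep="\t")
    validate_event_table(events)
    return events


def write_envelope(env: Envelope, path: str | Path) -> Path:
    """Single-column TSV plus a JSON sidecar carrying the sampling rate."""
    path = Path(path)
    np.savetxt(path, env.samples, fmt="%.10g", header="envelope", comments="")
    path.with_suffix(".json").write_text(json.dumps({"fs": env.fs}))
    return path


def read_envelope(path: str | Path) -> Envelope:
    path = Path(path)
    samples = np.loadtxt(path, skiprows=1)
    meta = json.loads(path.with_suffix(".json").read_text())
    return Envelope(samples, float(meta["fs"]))


def write_wav(samples: np.ndarray, fs: int, path: str | Path, fmt: str = "float32") -> Path:
    from scipy.io import wavfile

    path = Path(path)
    if fmt == "float32":
        wavfile.write(path, fs, np.asarray(samples, dtype=np.float32))
    elif fmt == "int16":
        wavfile.write(path, fs, np.round(np.asarray(samples) * 32767).astype(np.int16))
    else:
        raise ValueError("fmt must be 'float32' or 'int16'")
    return path


def read_wav(path: str | Path) -> tuple[np.ndarray, int]:
    """Read a WAV file; integer PCM is scaled to full-scale float."""
    from scipy.io import wavfile

    fs, data = wavfile.read(path)
    if data.dtype == np.int16:
        data = data / 32768.0
    elif data.dtype == np.int32:
        data = data / 2147483648.0
    elif data.dtype == np.uint8:
        data = (data.astype(float) - 128) / 128.0
    return np.asarray(data, dtype=float), int(fs)
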