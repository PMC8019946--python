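"""Pipeline configuration: every stage constant in one serializable place."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All stage parameters with their published defaults."""

    # marker timing
    event_delay_s: float = 0.102
    # decomposition prefilter
    ica_lp_edge: float = 40.0
    ica_hp_edge: float = 2.0
    # joint-probability segment rejection
    seg_len_s: float = 1.0
    local_z: float = 2.0
    global_z: float = 2.0
    # ERP branch
    erp_lp_edge: float = 10.0
    erp_lp_order: int = 660
    erp_hp_edge: float = 0.1
    erp_hp_order: int = 16500
    epoch_window_s: tuple[float, float] = (-0.5, 1.5)
    baseline_s: tuple[float, float] = (-0.5, 0.0)
    tbt_threshold_uv: float = 150.0
    tbt_max_interp: int = 2
    tbt_chan_bad_fraction: float = 0.30
    smooth_s: float = 0.100
    p3_window_s: tuple[float, float] = (0.5, 1.2)
    p3_channel: str = "Pz"
    # tracking branch
    track_lp_edge: float = 15.0
    track_lp_order: int = 440
    track_hp_edge: float = 1.0
    track_hp_order: int = 1650
    track_seg_len_s: float = 5.0
    max_lag_s: float = 1.0
    summary_window_s: tuple[float, float] = (0.0, 0.5)
    after_offset_s: float = 0.6
    n_flank: int = 6
    gfp_ddof: int = 1
    # event placement
    n_names_per_block: int = 10
    min_gap_s: float = 30.0
    lead_exclusion_s: float = 60.0
    tail_exclusion_s: float = 30.0
    control_min_dist_s: float = 1.5
    # run control
    seed: int = 0
    input_dir: str = ""
    output_dir: str = "results"

    def to_yaml(self, path: str | Path | None = None) -> str:
        payload = dataclasses.asdict(self)
        for k, v in payload.items():
            if isinstance(v, tuple):
                payload[k] = list(v)
        text = yaml.safe_dump(payload, sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        text = str(source)
        if "\n" not in text and Path(text).exists():
            text = Path(text).read_text()
        payload = yaml.safe_load(text)
        known = {f.name: f for f in dataclasses.fields(cls)}
        unknown = set(payload) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for k, v in payload.items():
            if isinstance(v, list):
                payload[k] = tuple(v)
        return cls(**payload)
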