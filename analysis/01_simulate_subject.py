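#!/usr/bin/env python
"""Simulate one demo subject and write its raw data to disk.

Forward-models a reduced two-block recording (one block per name-
intelligibility condition) and writes the BrainVision triplet, the events
TSV, both envelope streams, and the ground-truth JSON under
results/sim/sub-01/. The marker stream is written 102 ms early, as the
acquisition hardware did, so the downstream scripts must delay-correct.
"""

import dataclasses
import json
from pathlib import Path

import numpy as np

from envtrack import io, pipeline, synth

OUT = Path("results/sim/sub-01")
SEED = 1

cfg = synth.SimConfig(
    n_channels=49, block_length=180.0, n_blocks=2, snr_db=0.0,
    n_names_per_block=4, n_controls_per_block=4,
    min_gap=20.0, lead_exclusion=20.0, tail_exclusion=15.0, seed=SEED,
)

for block, condition in [(2, "higher"), (3, "lower")]:
    block_cfg = dataclasses.replace(
        cfg, gain_ign=cfg.gain_ign * (0.6 if condition == "lower" else 1.0)
    )
    rec, env_att, env_ign, truth = synth.simulate_block(
        block_cfg, block, condition, SEED + 1000 * block
    )
    ev = rec.events.copy()
    ev["onset_s"] -= 0.102  # acquisition delay
    ev["sample"] = np.round(ev["onset_s"] * cfg.fs_eeg).astype(int)
    rec = rec.copy_with(events=ev)

    stem = OUT / f"block-{block:02d}"
    vhdr = io.write_brainvision(rec, stem, fmt="float32")
    io.write_events_tsv(rec.events, stem.with_suffix(".events.tsv"))
    io.write_envelope(env_att, stem.with_name(stem.name + "_env-attended.tsv"))
    io.write_envelope(env_ign, stem.with_name(stem.name + "_env-ignored.tsv"))
    stem.with_suffix(".truth.json").write_text(truth.to_json())
    print(f"block {block} ({condition}): wrote {vhdr} "
          f"({rec.n_channels} ch, {rec.duration:.0f} s, "
          f"{(rec.events['type'] == 'name').sum()} names)")

prov = {"seed": SEED, "config": {k: str(v) for k, v in dataclasses.asdict(cfg).items()}}
(OUT / "provenance.json").write_text(json.dumps(prov, indent=2))
print(f"provenance written to {OUT / 'provenance.json'}")
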