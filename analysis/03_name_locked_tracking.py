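#!/usr/bin/env python
"""Name-locked tracking contrast on a small simulated cohort.

Compares the tracking summary score of the 5-s segment ending at each
embedded-name onset with the 5-s segment starting 0.6 s after it (the
name itself cut out), for the attended and ignored streams separately.
The simulator applies post-name gain multipliers (1.2 attended, 1.3
ignored) inside a 5.6-s window, so both streams should show a
before < after increase. Writes per-subject pairs to results/.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from envtrack import pipeline, stats
from envtrack.synth import SimConfig

OUT = Path("results")
OUT.mkdir(exist_ok=True)
N_SUBJECTS = 8

cfg = SimConfig(
    n_channels=8, block_length=290.0, n_blocks=1, snr_db=0.0,
    gain_att=1.5, gain_ign=1.0, p3_amplitude=0.0,
    n_names_per_block=20, n_controls_per_block=0,
    min_gap=12.0, lead_exclusion=20.0, tail_exclusion=15.0,
)

rows = []
for seed, subj in pipeline.simulate_cohort(N_SUBJECTS, cfg, master_seed=2025,
                                           block_plan=[(2, "higher")]):
    el = pipeline.analyze_tracking_event_locked(subj)
    rows.append({
        "seed": seed,
        "att_before": el.before_after["att"][0],
        "att_after": el.before_after["att"][1],
        "ign_before": el.before_after["ign"][0],
        "ign_after": el.before_after["ign"][1],
    })

table = pd.DataFrame(rows)
table.to_csv(OUT / "event_locked_scores.tsv", sep="\t", index=False)

for stream in ("att", "ign"):
    d = table[f"{stream}_after"] - table[f"{stream}_before"]
    res = stats.wilcoxon_signed_rank(np.asarray(d), alternative="greater")
    label = "attended" if stream == "att" else "ignored"
    print(f"{label}: mean increase {d.mean():+.4f}, Z = {res.z:.2f}, p = {res.p:.2g}")
print(f"wrote {OUT / 'event_locked_scores.tsv'}")
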