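#!/usr/bin/env python
"""Consecutive-segment envelope tracking on a small simulated cohort.

For each subject, every name block is re-referenced to the common
average, band-limited to 1-15 Hz, cut into 5-s segments, and each
channel is cross-correlated with the attended and ignored envelopes at
lags -1000..1000 ms. The across-channel SD (GFP) gives one magnitude
function per stream, summarized over lags 0-500 ms; mismatched
envelope/EEG pairings give the chance level. Writes per-subject scores
and the group tests to results/.
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
    n_channels=16, block_length=120.0, n_blocks=1, snr_db=0.0,
    gain_att=1.5, gain_ign=1.0, p3_amplitude=0.0,
    n_names_per_block=0, n_controls_per_block=0,
)

rows, att_m, ign_m = [], [], []
for seed, subj in pipeline.simulate_cohort(N_SUBJECTS, cfg, master_seed=2024,
                                           block_plan=[(2, "higher")]):
    tr = pipeline.analyze_tracking_consecutive(subj)
    rows.append({"seed": seed, **tr.summaries})
    att_m.append(tr.att)
    ign_m.append(tr.ign)

table = pd.DataFrame(rows)
table.to_csv(OUT / "tracking_summaries.tsv", sep="\t", index=False)

ga_att = pipeline.grand_average_magnitude(att_m)
ga_ign = pipeline.grand_average_magnitude(ign_m)
z_ac = stats.wilcoxon_signed_rank(table["attended"], table["control"], "greater")
z_ic = stats.wilcoxon_signed_rank(table["ignored"], table["control"], "greater")
z_ai = stats.wilcoxon_signed_rank(table["attended"], table["ignored"], "greater")

print(f"n = {N_SUBJECTS} subjects, {cfg.block_length:.0f}-s blocks at 0 dB SNR")
print(f"grand-average peak lags: attended {1000 * pipeline.peak_lag_s(ga_att):.0f} ms, "
      f"ignored {1000 * pipeline.peak_lag_s(ga_ign):.0f} ms")
print(f"attended > control: Z = {z_ac.z:.2f}, p = {z_ac.p:.2g}")
print(f"ignored  > control: Z = {z_ic.z:.2f}, p = {z_ic.p:.2g}")
print(f"attended > ignored: Z = {z_ai.z:.2f}, p = {z_ai.p:.2g}")
print(f"wrote {OUT / 'tracking_summaries.tsv'}")
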