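# envtrack

EEG analysis of attention capture by one's own name in a two-competing-
speaker ("cocktail party") paradigm, plus a forward-model simulator that
makes the whole chain testable without the original recordings.

A listener attends one of two simultaneous narratives while their first
name is occasionally embedded in the to-be-ignored stream. Two neural
measures quantify what the name does:

- **P3**: the name evokes a late posterior positivity. Epochs
  (−500..1500 ms, baseline −500..0 ms, 10 Hz/0.1 Hz zero-phase FIR,
  ±150 µV trial-by-trial rejection with epoch-wise channel
  interpolation) are averaged, smoothed with a 100-ms moving average,
  and quantified at Pz by the mean amplitude over 500–1200 ms, the peak
  latency, and the amplitude at the individual latency ±50 ms.
- **Envelope tracking**: each EEG channel of a 5-s segment is
  cross-correlated with the speech envelope of each stream
  (|Hilbert| → 15 Hz LP → d/dt → half-wave rectification → 500 Hz) at
  lags τ ∈ [−1000, 1000] ms,

  r_c(τ) = Σ_t ẽ(t−τ) x̃_c(t) / (‖ẽ‖‖x̃_c‖),

  and the SD over channels of r_c(τ) — a global-field-power-style
  magnitude — gives a channel-selection-free tracking profile,
  summarized as its mean over τ ∈ [0, 500] ms. Mismatched envelope/EEG
  pairings estimate chance. The name-locked contrast compares the 5-s
  segment ending at the name onset ([−5, 0) s) with the segment starting
  0.6 s after it ([0.6, 5.6) s).

Group statistics are one-sided Wilcoxon signed-rank tests (exact for
n ≤ 25 without ties), plus Spearman/Pearson correlations and the
behavioral scoring rules for content questionnaires and retrospective
name-detection reports.

The simulator (`envtrack.synth`) forward-models all of this with known
ground truth: speech-like envelope pairs, event schedules obeying the
paradigm's placement constraints, EEG as lagged-kernel convolutions of
both envelopes (attended kernel peaking at 156 ms, bilateral-temporal
map; ignored at 50 ms, fronto-central map), rectangular post-name gain
modulation, an injected posterior P3 at 760 ms, 1/f noise, and optional
blinks. See `docs/methods.md` for the model and every default.

## Worked example

Recover the injected P3 from a simulated cohort (21 subjects, 40 name +
40 control epochs each, 5 µV deflection at 760 ms on 20 µV-RMS 1/f
noise):

```sh
$ python analysis/04_p3_erp.py
n = 21 subjects, injected P3: 5 uV at 760 ms on 20-uV 1/f noise
name vs control mean amplitude (500-1200 ms): Z = 2.33, p = 0.0088
grand-average P3 latency at Pz: 748 ms, amplitude at latency 3.93 uV
wrote results/p3_measures.tsv
```

The Z compares per-subject mean amplitudes (500–1200 ms) between name
and control epochs; the grand-average latency lands within a smoothing
step of the injected 760 ms, and the recovered amplitude sits below the
injected 5 µV peak because the 100-ms moving average rounds the peak
off and residual 1/f noise pulls the window mean around.

The other drivers work the same way: `02_envelope_tracking.py` recovers
the 156/50 ms tracking peaks and the attended > ignored > control
ordering, `03_name_locked_tracking.py` the before < after increase of
both streams, `05_behavior.py` the questionnaire scoring, and
`06_report.py` the figure set under `results/figures/`.

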