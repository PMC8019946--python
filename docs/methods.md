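# Methods

`envtrack` analyses EEG from a two-competing-speaker listening paradigm in
which a listener attends one of two simultaneous narratives while their own
first name is occasionally embedded in the to-be-ignored stream. Two
neural measures quantify what the name does to attention: the P3
event-related potential evoked by the name (did the listener detect it?)
and the envelope-tracking strength of each speech stream before versus
after the name (did attention shift?). Because the package must be
testable without the original recordings, it ships a forward-model
simulator whose injected structure the analyses are validated against.

## Speech envelopes

The envelope of a narrative is computed as |Hilbert transform| → 15 Hz
low-pass → first difference scaled to a derivative → half-wave
rectification → anti-aliased polyphase resampling to the EEG rate
(500 Hz). The derivative step accentuates word and syllable onsets; the
rectification keeps rising energy only, so envelopes are non-negative and
the whole chain is positively homogeneous (scaling the audio scales the
envelope). The derivative is a first difference with one-sample
zero-padding to preserve length — the simplest estimator consistent with
a discrete derivative.

All envelope/EEG filters in the package are Hamming-window FIR filters
applied at zero phase. Band edges are *pass-band* edges: the 6 dB cutoff
sits half a transition width beyond the stated edge (transition width
3.3/N normalized), so the response at the edge stays within ~1 dB of
unity. High-pass filters are built by spectral inversion of a unity-DC
low-pass, which makes the DC gain exactly zero. Filter lengths are forced
odd (type I), and zero phase is obtained in a single FFT pass by removing
the integer group delay; edges see implicit zero padding of half the
filter length. Zero-phase application was chosen because the
cross-correlation analysis is lag-sensitive; causal filtering would bias
every reported lag by the filter delay.

Where the analysis prescribes explicit orders they are used as given:
10 Hz low-pass of order 660 and 0.1 Hz high-pass of order 16,500 for the
ERP branch; 15 Hz (order 440) and 1 Hz (order 1,650) for the tracking
branch; the 40 Hz/2 Hz decomposition prefilter uses the standard
transition-width rule (25% of the edge, at least 2 Hz).

## Preprocessing

Event markers are shifted **later** by the constant 102 ms acquisition
delay between the EEG and the marker stream (the amplifier wrote markers
early relative to the data); onsets leaving the recording are flagged,
never dropped. For artifact screening, the 40/2 Hz-filtered data are cut
into consecutive 1-s segments and each segment's joint improbability is
computed per channel as the negative mean log density of its samples
under a 100-bin histogram estimate of the channel's amplitude
distribution, z-scored over segments; a segment is rejected when any
channel exceeds 2 SD (local) or the channel average exceeds 2 SD
(global). The histogram density is a pragmatic stand-in for the screening
routine's unspecified density model; the bin count is configurable.

ICA is a FastICA decomposition (fixed seed, as many components as
channels) fitted on the filtered, screened data. Cleaning applies the
unmixing to the **raw** recording, zeroes the listed artifact components,
and back-projects the rest; the application path is purely linear, so an
empty artifact list reproduces the input to numerical precision.
Component selection is by a manual index list, or — for testing against
simulated ground truth — an automatic proxy that flags components whose
absolute correlation with an EOG channel exceeds 0.8. The original
selection was visual and is not reproducible as an algorithm.

## P3 branch

Artifact-corrected data are filtered (10 Hz/0.1 Hz as above), epoched
−500..1500 ms around name and control-word onsets, and baseline-corrected
on −500..0 ms. Trial-by-trial rejection uses a ±150 µV threshold: up to
two exceeding channels are interpolated within the epoch, more rejects
the epoch, and a channel exceeding in more than 30% of epochs is
interpolated in all epochs (this channel-wide pass runs first).
Interpolation is inverse-distance weighting over the four nearest
neighbours on the standard 10-10 montage; a spherical-spline
interpolator would change interpolated waveforms slightly but none of
the keep/reject decisions. Averages (per event type, optionally per
condition) are smoothed with a centered 100-ms moving average —
centered, so the peak latency is unbiased. P3 measures at Pz: mean
amplitude over 500–1200 ms, latency of the window maximum (earliest
sample on ties), and mean amplitude over latency ±50 ms.

## Tracking branch

Data are re-referenced to the common average, filtered 1–15 Hz, and cut
into 5-s segments (consecutive, or name-locked). Each channel segment is
cross-correlated with the corresponding envelope segment at lags
−1000..+1000 ms; positive lag means the EEG follows the stimulus, which
is pinned down by a shifted-copy test. The correlation is normalized by
the full-segment norms after full-segment demeaning (coefficient
convention): values lie in [−1, 1], are invariant to affine amplitude
changes of either input, and the lag of the maximum is exactly the lag of
a shifted copy. Per-lag renormalization over the overlap was rejected
because it can displace the argmax near the segment edges; a
raw-covariance mode is available via the normalization hook in
`xcorr_channels` callers if needed.

Cross-correlation functions are averaged over segments (for name-locked
analysis: over events first, per subject), then the SD over channels at
each lag — a global-field-power-style magnitude — gives a
channel-selection-free tracking profile. The SD uses the sample (N−1)
denominator by default; classical GFP's population SD is a switch. The
summary score is the mean magnitude over lags 0–500 ms. The chance level
is estimated by pairing envelope segment k with EEG segment k+1
(circular — a fixed-point-free permutation). The name-locked contrast
compares the 5-s segment ending at the name onset with the one starting
0.6 s after it (the 0.6 s containing the name is cut out); up to six
flanking segments on each side give the score time course.

## Statistics and behavior

Group comparisons use the one-sided Wilcoxon signed-rank test: zero
differences dropped, ties mid-ranked, Z from the continuity-corrected
normal approximation, exact p for n ≤ 25 without ties (no
multiple-testing correction, matching the original analysis plan).
Spearman/Pearson correlations come from scipy with the stated-direction
alternative. Content questionnaires score "I don't know" as incorrect.
Retrospective name-detection reports map to per-condition estimates by
rule: name not noticed → both zero; condition difference not noticed →
the overall estimate for both; otherwise the per-condition values. A 0–10
per-block estimate maps to percent detected as ×10 (ten names per
block) — the scale-to-percent mapping is an assumption, documented here.

## The simulator

`synth.simulate_eeg` builds EEG as a linear forward model: each stream's
envelope is convolved with a lag kernel (Gaussian bump; attended peaking
at 156 ms, SD 50 ms; ignored at 50 ms, SD 30 ms) and projected through a
fixed scalp map (bilateral-temporal for attended, fronto-central for
ignored; Gaussian blobs on standard 10-10 electrode positions — the real
topographies are not numerically specified anywhere, so these are
qualitative stand-ins). Stream gains default to 1.5 (attended) vs 1.0
(ignored) and are multiplied by post-name factors (1.2/1.3) inside a
rectangular 5.6-s window starting at each name onset — rectangular
because that is the span the before/after analysis integrates over. Each
name also injects a P3-like deflection at Pz-centered posterior sites:
unit-peak waveform with a Gaussian rising flank (SD 80 ms) and an
exponential falling flank (τ = 250 ms) — the classic asymmetric P3
morphology — at 760 ms latency and 5 µV peak by default. Noise is
Gaussian 1/f^α (α = 1) scaled to a per-channel RMS (20 µV default) or to
a target SNR; optional stereotyped blinks (raised-cosine, 300 ms,
frontal + two EOG channels) exercise the ICA contract and are off by
default. Everything injected is returned as ground truth, and identical
configurations (including seed) give bit-identical output.

Event schedules obey the paradigm's constraints: ten names per 10-min
block, none in the first minute or last 30 s, pairwise at least 30 s
apart; control words follow the same rules and stay at least 1.5 s from
any name. Infeasible requests raise an error rather than truncating.

What the simulator does **not** emulate: real spectro-temporal response
functions (the kernels are single bumps, not multi-phase TRFs),
nonlinearities and adaptation, non-stationary noise, alpha rhythms,
heartbeat or muscle artifacts, and any coupling between the behavioral
generator and the EEG. Passing recovery tests therefore show that the
analysis chain correctly extracts what a linear tracking model puts in —
not that it would behave identically on real recordings.

## Validation scales

The validation suite runs cohorts that mirror the study design (21
subjects; 40 name events per subject; 40 name + 40 control epochs) while
shortening recordings and reducing channel counts so each check runs in
minutes on one core: tracking recovery uses 16-channel, 120-s blocks at
0 dB SNR; the name-locked contrast uses 8-channel, 520-s blocks holding
40 events with a 12-s minimum gap (enough to keep the ±5.6-s analysis
windows disjoint); P3 recovery uses 8-channel, 330-s blocks with 80
packed events. The acceptance script runs the full-scale geometry — 49
channels, two 600-s name blocks per subject (one per intelligibility
condition, scaled down from four) — for 21 subjects. Per-condition
simulation truth in that script: the ignored stream is attenuated
(gain ×0.6) in the lower-intelligibility condition, and the name's P3 is
weaker and later (4 µV/780 ms vs 6 µV/740 ms) — the qualitative pattern
the condition manipulation is known to produce, with the
condition-independent values (5 µV, 760 ms) as their means.

## Numerical choices and edge cases

- Cross-correlation of a zero-variance segment is an error naming the
  offending channel (it has no defined correlation).
- Epochs whose window leaves the recording are excluded with a logged
  reason; name-locked segments reaching outside a block likewise.
- Ties in peak picking resolve to the earliest latency (deterministic and
  conservative).
- The moving-average smoother uses nearest-edge padding; the FIR filters
  zero-pad. Both are visible only within half a window/filter length of
  the edges, which every analysis window stays clear of.
- Seeds: cohort seeds are drawn from one master seed via a PCG64
  generator and kept below 2^31; every stochastic stage (envelopes,
  schedules, noise, ICA) is seeded.

## Known limitations

Single-subject P3 **latency** is not a stable quantity at the simulated
noise level: 20 µV-RMS 1/f noise leaves ~14 µV per epoch inside the
0.1–10 Hz ERP band, so a 40-epoch average still carries ~2 µV of
structured noise against a 5 µV deflection with a flat top, and the
window-maximum latency of a single subject can wander by ±50 ms or more.
Latency recovery is therefore validated on cohort grand averages (as is
the name-vs-control amplitude test, mirroring the group statistics).
The behavioral generator is independent of the EEG generator, so
brain–behavior correlations are not meaningful in simulation and are not
reported. The beamformer that attenuated the ignored stream is modelled
only as a scalar gain.
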