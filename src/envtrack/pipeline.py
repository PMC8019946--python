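"""Cohort-level drivers tying the stages into the full analysis.

These functions reproduce the study's analysis path on simulated
subjects: forward-model each subject's blocks, correct the marker delay,
band-limit for tracking, run the consecutive-segment and name-locked
cross-correlation analyses, run the P3 branch, and aggregate with the
group statistics. Analysis scripts, the test suite, and the acceptance
script all come through here.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np

from . import erp, preprocess, stats, tracking
from .containers import EegRecording, Envelope
from .synth import GroundTruth, SimConfig, simulate_block

DEFAULT_BLOCK_PLAN = [
    (1, "none"), (2, "higher"), (3, "lower"), (4, "higher"), (5, "lower")
]


@dataclass
class BlockData:
    rec: EegRecording
    env_att: Envelope
    env_ign: Envelope
    truth: GroundTruth
    block: int
    condition: str


@dataclass
class SubjectData:
    blocks: list[BlockData]
    seed: int


def subject_seeds(master_seed: int, n: int) -> list[int]:
    rng = np.random.default_rng(master_seed)
    return [int(s) for s in rng.integers(0, 2**31 - 1, size=n)]


def simulate_subject(
    cfg: SimConfig,
    seed: int,
    block_plan: list[tuple[int, str]] | None = None,
    emulate_marker_delay: bool = False,
    delay: float = preprocess.EVENT_DELAY_S,
) -> SubjectData:
    """Forward-model one subject's blocks.

    With ``emulate_marker_delay`` the attached event table is shifted
    *earlier* by the acquisition delay, as the amplifier wrote it; the
    analysis side must then apply :func:`preprocess.correct_event_delay`.
    """
    plan = block_plan if block_plan is not None else DEFAULT_BLOCK_PLAN[: cfg.n_blocks]
    blocks = []
    for i, (block, condition) in enumerate(plan):
        rec, env_att, env_ign, gt = simulate_block(cfg, block, condition, seed + 1000 * i)
        if emulate_marker_delay:
            ev = rec.events.copy()
            ev["onset_s"] -= delay
            ev["sample"] = np.round(ev["onset_s"] * cfg.fs_eeg).astype(int)
            rec = rec.copy_with(events=ev)
        blocks.append(BlockData(rec, env_att, env_ign, gt, block, condition))
    return SubjectData(blocks=blocks, seed=seed)


def _analysis_blocks(subject: SubjectData, skip_first: bool = True) -> list[BlockData]:
    return [b for b in subject.blocks if not (skip_first and b.block == 1)]


@dataclass
class SubjectTracking:
    att: tracking.MagnitudeFunction
    ign: tracking.MagnitudeFunction
    control: tracking.MagnitudeFunction

    @property
    def summaries(self) -> dict[str, float]:
        return {
            "attended": self.att.summary,
            "ignored": self.ign.summary,
            "control": self.control.summary,
        }


def analyze_tracking_consecutive(
    subject: SubjectData, max_lag: float = tracking.MAX_LAG_S, skip_first: bool = True
) -> SubjectTracking:
    """Consecutive 5-s segment analysis of every name block."""
    segments: list[dict] = []
    for b in _analysis_blocks(subject, skip_first):
        prepped = tracking.prep_tracking(b.rec)
        segments.extend(tracking.segment_consecutive(prepped, b.env_att, b.env_ign))
    att = tracking.gfp_magnitude(
        tracking.xcorr_over_segments(segments, subject.blocks[0].rec.fs, "att", max_lag)
    )
    ign = tracking.gfp_magnitude(
        tracking.xcorr_over_segments(segments, subject.blocks[0].rec.fs, "ign", max_lag)
    )
    control = tracking.control_scores(segments, subject.blocks[0].rec.fs, "att", max_lag)
    return SubjectTracking(att=att, ign=ign, control=control)


@dataclass
class SubjectEventLocked:
    before_after: dict[str, tuple[float, float]]
    timecourse: dict[str, dict[int, float]] = field(default_factory=dict)


def analyze_tracking_event_locked(
    subject: SubjectData,
    max_lag: float = tracking.MAX_LAG_S,
    correct_delay: bool = False,
    with_timecourse: bool = False,
) -> SubjectEventLocked:
    """Name-locked before/after analysis pooled over a subject's blocks."""
    fs = subject.blocks[0].rec.fs
    slots: dict[int, list[dict]] = {}
    for b in _analysis_blocks(subject):
        events = b.rec.events
        if correct_delay:
            events = preprocess.correct_event_delay(events, fs=fs, n_samples=b.rec.n_samples)
        if not (events["type"] == "name").any():
            continue
        prepped = tracking.prep_tracking(b.rec)
        s, _ = tracking.segment_event_locked(prepped, b.env_att, b.env_ign, events)
        for slot, segs in s.items():
            slots.setdefault(slot, []).extend(segs)
    contrast = tracking.before_after_contrast(slots, fs, max_lag)
    timecourse = tracking.event_locked_scores(slots, fs, max_lag) if with_timecourse else {}
    return SubjectEventLocked(before_after=contrast, timecourse=timecourse)


@dataclass
class SubjectErp:
    waveforms: dict  # event type -> (n_channels, n_times) smoothed average
    times: np.ndarray
    ch_names: list[str]
    p3_name: erp.P3Measures
    p3_control: erp.P3Measures
    n_epochs: dict[str, int]
    p3_name_by_condition: dict[str, erp.P3Measures] = field(default_factory=dict)


def analyze_erp(
    subject: SubjectData,
    channel: str = "Pz",
    correct_delay: bool = False,
    by_condition: bool = False,
) -> SubjectErp:
    """P3 branch: filter, epoch, reject, average, smooth, quantify."""
    all_epochs: list[erp.ErpSet] = []
    for b in _analysis_blocks(subject):
        events = b.rec.events
        if correct_delay:
            events = preprocess.correct_event_delay(
                events, fs=b.rec.fs, n_samples=b.rec.n_samples
            )
        if not len(events):
            continue
        filtered = erp.filter_erp(b.rec)
        all_epochs.append(erp.epoch_and_baseline(filtered, events))
    if not all_epochs:
        raise ValueError("subject has no epochable events")
    merged = erp.ErpSet(
        epochs=np.concatenate([e.epochs for e in all_epochs]),
        times=all_epochs[0].times,
        ch_names=all_epochs[0].ch_names,
        event_type=np.concatenate([e.event_type for e in all_epochs]),
        condition=np.concatenate([e.condition for e in all_epochs]),
        fs=all_epochs[0].fs,
        log=sum((e.log for e in all_epochs), []),
    )
    surviving = erp.tbt_reject(merged)
    waveforms = erp.average_and_smooth(surviving)
    p3_name = erp.p3_quantify(
        waveforms["name"], surviving.times, surviving.ch_names, channel
    )
    p3_control = erp.p3_quantify(
        waveforms["control"], surviving.times, surviving.ch_names, channel
    )
    by_cond: dict[str, erp.P3Measures] = {}
    if by_condition:
        cond_waves = erp.average_and_smooth(surviving, by_condition=True)
        for (et, cond), wave in cond_waves.items():
            if et == "name":
                by_cond[cond] = erp.p3_quantify(
                    wave, surviving.times, surviving.ch_names, channel
                )
    return SubjectErp(
        waveforms=waveforms,
        times=surviving.times,
        ch_names=surviving.ch_names,
        p3_name=p3_name,
        p3_control=p3_control,
        p3_name_by_condition=by_cond,
        n_epochs={
            et: int((surviving.event_type == et).sum())
            for et in np.unique(surviving.event_type)
        },
    )


def simulate_cohort(
    n_subjects: int,
    cfg: SimConfig,
    master_seed: int,
    block_plan: list[tuple[int, str]] | None = None,
    emulate_marker_delay: bool = False,
):
    """Yield (seed, SubjectData) pairs; subjects differ only by seed."""
    for s in subject_seeds(master_seed, n_subjects):
        yield s, simulate_subject(
            dataclasses.replace(cfg, seed=s), s, block_plan, emulate_marker_delay
        )


def peak_lag_s(mag: tracking.MagnitudeFunction, window: tuple[float, float] = (0.0, 0.5)) -> float:
    """Lag of the magnitude maximum within a lag window."""
    sel = (mag.lags >= window[0]) & (mag.lags <= window[1])
    idx = np.flatnonzero(sel)
    return float(mag.lags[idx[np.argmax(mag.magnitude[sel])]])


def grand_average_magnitude(mags: list[tracking.MagnitudeFunction]) -> tracking.MagnitudeFunction:
    m = np.mean([x.magnitude for x in mags], axis=0)
    lags = mags[0].lags
    return tracking.MagnitudeFunction(
        magnitude=m, lags=lags, summary=tracking.summary_score(m, lags), role=mags[0].role
    )


def simulate_behavior(
    n_subjects: int,
    seed: int,
    p_detect_higher: float = 0.40,
    p_detect_lower: float = 0.30,
    p_notice_difference: float = 0.8,
    p_correct_content: float = 0.887,
    n_questions: int = 50,
    names_per_condition: int = 20,
) -> list[dict]:
    """Synthetic behavioral records consistent with the paradigm.

    Each subject detects each name independently (per-condition detection
    probabilities), reports per-block estimates on the questionnaire
    scales, and answers the content questions with a fixed accuracy.
    """
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_subjects):
        det_h = int(rng.binomial(names_per_condition, p_detect_higher))
        det_l = int(rng.binomial(names_per_condition, p_detect_lower))
        noticed = (det_h + det_l) > 0
        noticed_diff = bool(noticed and rng.random() < p_notice_difference)
        per_block_h = round(det_h / 2)  # two blocks per condition
        per_block_l = round(det_l / 2)
        report = stats.RetrospectiveReport(
            noticed_name=noticed,
            noticed_condition_difference=noticed_diff,
            overall_estimate=(
                min(10, max(1, round((det_h + det_l) / 4))) if noticed and not noticed_diff else None
            ),
            higher_estimate=min(10, per_block_h) if noticed_diff else None,
            lower_estimate=min(10, per_block_l) if noticed_diff else None,
        )
        answers = ["correct" if rng.random() < p_correct_content else
                   ("incorrect" if rng.random() < 0.5 else "dont_know")
                   for _ in range(n_questions)]
        out.append({"report": report, "content_answers": answers})
    return out
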