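"""Envelope tracking: referencing/filtering, segmentation, lagged
cross-correlation, GFP magnitude, mismatched control, name-locked contrast."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from envtrack import tracking
from envtrack.containers import EegRecording, Envelope, make_event_table
from envtrack.filters import attenuation_db, design_fir

FS = 500.0


def bruteforce_xcorr(x, e, max_lag_n):
    """Direct double-loop dot-product oracle (constant-norm convention)."""
    xt = x - x.mean()
    et = e - e.mean()
    denom = np.linalg.norm(et) * np.linalg.norm(xt)
    n = e.size
    out = np.empty(2 * max_lag_n + 1)
    for i, tau in enumerate(range(-max_lag_n, max_lag_n + 1)):
        acc = 0.0
        for t in range(n):
            s = t - tau
            if 0 <= s < n:
                acc += et[s] * xt[t]
        out[i] = acc / denom
    return out


class TestPrepTracking:
    def test_common_average_zeroes_channel_sum(self, rng):
        rec = EegRecording(rng.standard_normal((4, int(30 * FS))), FS, ["Fz", "Cz", "Pz", "Oz"])
        out = tracking.prep_tracking(rec)
        # re-reference then linear filtering preserves the zero channel sum
        assert np.abs(out.data.sum(axis=0)).max() < 1e-9

    def test_frequency_response_oracle(self):
        lp = design_fir(FS, 15.0, "lowpass", tracking.TRACK_LP_ORDER)
        hp = design_fir(FS, 1.0, "highpass", tracking.TRACK_HP_ORDER)
        assert lp.size == 441 and hp.size == 1651
        assert attenuation_db(hp, FS, 0.2) <= -20.0
        assert abs(attenuation_db(lp, FS, 8.0)) <= 1.0
        assert abs(attenuation_db(hp, FS, 8.0)) <= 1.0

    def test_single_channel_rejected(self, rng):
        rec = EegRecording(rng.standard_normal((1, int(30 * FS))), FS, ["Pz"])
        with pytest.raises(ValueError):
            tracking.prep_tracking(rec)


class TestSegmentConsecutive:
    def test_segment_count_arithmetic(self, rng):
        n = int(63 * FS)  # 63 s -> 12 full 5-s segments, partial dropped
        rec = EegRecording(rng.standard_normal((2, n)), FS, ["Fz", "Pz"])
        env = Envelope(np.abs(rng.standard_normal(n)), FS)
        segs = tracking.segment_consecutive(rec, env)
        assert len(segs) == 12

    def test_segments_mean_subtracted_and_index_aligned(self, rng):
        n = int(20 * FS)
        rec = EegRecording(rng.standard_normal((2, n)) + 5, FS, ["Fz", "Pz"])
        env = Envelope(np.arange(n, dtype=float), FS)
        segs = tracking.segment_consecutive(rec, env)
        for k, seg in enumerate(segs):
            assert np.abs(seg["eeg"].mean(axis=1)).max() < 1e-9
            # envelope segment k must span samples [k*2500, (k+1)*2500)
            assert seg["att"][0] == k * 2500
            assert seg["att"][-1] == (k + 1) * 2500 - 1

    def test_short_recording_rejected(self, rng):
        rec = EegRecording(rng.standard_normal((2, 100)), FS, ["Fz", "Pz"])
        env = Envelope(np.abs(rng.standard_normal(100)), FS)
        with pytest.raises(ValueError):
            tracking.segment_consecutive(rec, env)


class TestSegmentEventLocked:
    def make_block(self, rng, onset_s=60.0, n=int(120 * FS)):
        ev = make_event_table([onset_s], ["name"], FS)
        rec = EegRecording(rng.standard_normal((2, n)), FS, ["Fz", "Pz"], events=ev)
        env_a = Envelope(np.arange(n, dtype=float), FS)
        env_i = Envelope(np.arange(n, dtype=float) * 2, FS)
        return rec, env_a, env_i

    def test_adjacent_segment_index_oracle(self, rng):
        rec, env_a, env_i = self.make_block(rng)
        slots, excluded = tracking.segment_event_locked(rec, env_a, env_i)
        onset = 30000
        # before: [-2500, 0); after: [+300, +2800) samples relative to onset
        assert slots[-1][0]["att"][0] == onset - 2500
        assert slots[-1][0]["att"][-1] == onset - 1
        assert slots[1][0]["att"][0] == onset + 300
        assert slots[1][0]["att"][-1] == onset + 2799
        assert excluded == []

    def test_event_near_block_start_logged(self, rng):
        rec, env_a, env_i = self.make_block(rng, onset_s=4.0)
        slots, excluded = tracking.segment_event_locked(rec, env_a, env_i)
        assert len(slots[-1]) == 0
        assert any(e["slot"] == -1 for e in excluded)

    def test_no_events_rejected(self, rng):
        rec, env_a, env_i = self.make_block(rng)
        rec = rec.copy_with(events=make_event_table([], [], FS))
        with pytest.raises(ValueError):
            tracking.segment_event_locked(rec, env_a, env_i, rec.events)


class TestXcorrChannels:
    def test_matches_bruteforce_oracle(self, rng):
        n, lag_n = 500, 100
        e = np.abs(rng.standard_normal(n))
        x = rng.standard_normal((3, n))
        cc = tracking.xcorr_channels(x, e, FS, max_lag=lag_n / FS)
        for c in range(3):
            oracle = bruteforce_xcorr(x[c], e, lag_n)
            assert np.abs(cc.values[c] - oracle).max() < 1e-10

    def test_shifted_copy_peaks_at_shift(self, rng):
        n = int(5 * FS)
        e = np.abs(rng.standard_normal(n))
        x = np.zeros(n)
        x[50:] = e[:-50]  # EEG follows the envelope by 100 ms
        cc = tracking.xcorr_channels(x[None, :], e, FS)
        assert cc.lags[np.argmax(cc.values[0])] == pytest.approx(0.100)
        assert cc.values[0].max() > 0.95

    def test_white_noise_channel_within_null_bound(self, rng):
        n = int(5 * FS)
        e = np.abs(rng.standard_normal(n))
        x = rng.standard_normal(n)
        cc = tracking.xcorr_channels(x[None, :], e, FS)
        assert np.abs(cc.values).max() < 3 / np.sqrt(n - int(FS))

    def test_lag_axis_spans_plus_minus_one_second(self, rng):
        n = int(5 * FS)
        cc = tracking.xcorr_channels(
            rng.standard_normal((2, n)), np.abs(rng.standard_normal(n)), FS
        )
        assert cc.lags[0] == -1.0 and cc.lags[-1] == 1.0
        assert np.allclose(cc.lags, -cc.lags[::-1])

    def test_zero_variance_segment_rejected(self, rng):
        n = int(5 * FS)
        with pytest.raises(ValueError, match="channel"):
            tracking.xcorr_channels(np.zeros((1, n)), np.abs(rng.standard_normal(n)), FS)
        with pytest.raises(ValueError, match="envelope"):
            tracking.xcorr_channels(rng.standard_normal((1, n)), np.ones(n), FS)

    @settings(max_examples=20, deadline=None)
    @given(scale=st.floats(0.01, 100.0), offset=st.floats(-50.0, 50.0))
    def test_invariant_to_affine_amplitude_changes(self, scale, offset):
        rng = np.random.default_rng(3)
        n = 1000
        e = np.abs(rng.standard_normal(n))
        x = rng.standard_normal((2, n))
        base = tracking.xcorr_channels(x, e, FS, max_lag=0.2).values
        moved = tracking.xcorr_channels(scale * x + offset, e, FS, max_lag=0.2).values
        assert np.allclose(moved, base, atol=1e-9)


class TestAverageSets:
    def make_set(self, rng):
        vals = rng.standard_normal((3, 201))
        lags = np.arange(-100, 101) / FS
        return tracking.CrossCorrSet(vals, lags)

    def test_single_set_identity(self, rng):
        s = self.make_set(rng)
        out = tracking.average_sets([s])
        assert np.array_equal(out.values, s.values)

    def test_opposite_sets_cancel(self, rng):
        s = self.make_set(rng)
        neg = tracking.CrossCorrSet(-s.values, s.lags)
        assert np.allclose(tracking.average_sets([s, neg]).values, 0.0)

    def test_matches_manual_mean(self, rng):
        sets = [self.make_set(rng) for _ in range(5)]
        manual = sum(s.values for s in sets) / 5
        assert np.abs(tracking.average_sets(sets).values - manual).max() < 1e-12

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            tracking.average_sets([])


class TestGfpMagnitude:
    def test_identical_channels_zero_magnitude(self):
        lags = np.arange(-100, 101) / FS
        vals = np.tile(np.sin(lags * 5), (4, 1))
        mag = tracking.gfp_magnitude(tracking.CrossCorrSet(vals, lags))
        assert np.allclose(mag.magnitude, 0.0)

    def test_gain_factorization_closed_form(self):
        lags = np.arange(-100, 101) / FS
        f = np.sin(lags * 7) * np.exp(-np.abs(lags))
        gains = np.array([0.5, 1.0, 1.5, -0.3])
        vals = gains[:, None] * f[None, :]
        mag = tracking.gfp_magnitude(tracking.CrossCorrSet(vals, lags))
        expected = np.std(gains, ddof=1) * np.abs(f)
        assert np.abs(mag.magnitude - expected).max() < 1e-12

    def test_summary_window_is_0_to_500ms(self):
        lags = np.arange(-500, 501) / FS
        vals = np.vstack([lags, -lags])  # SD over 2 channels = |lags|*sqrt(2)
        mag = tracking.gfp_magnitude(tracking.CrossCorrSet(vals, lags))
        sel = (lags >= 0) & (lags <= 0.5)
        assert mag.summary == pytest.approx(np.sqrt(2) * np.abs(lags[sel]).mean())

    def test_single_channel_rejected(self):
        lags = np.arange(-10, 11) / FS
        with pytest.raises(ValueError):
            tracking.gfp_magnitude(tracking.CrossCorrSet(np.ones((1, 21)), lags))

    def test_invariant_to_common_additive_waveform_after_car(self, rng):
        """A waveform added to all channels is removed by the common-average
        reference, leaving the magnitude function unchanged."""
        n = int(30 * FS)
        base = rng.standard_normal((4, n)) * 10
        common = np.sin(2 * np.pi * 3 * np.arange(n) / FS) * 50
        env = Envelope(np.abs(rng.standard_normal(n)), FS)
        mags = []
        for data in (base, base + common):
            rec = EegRecording(data, FS, ["Fz", "Cz", "Pz", "Oz"])
            prepped = tracking.prep_tracking(rec)
            segs = tracking.segment_consecutive(prepped, env)
            cc = tracking.xcorr_over_segments(segs, FS, "att")
            mags.append(tracking.gfp_magnitude(cc).magnitude)
        assert np.allclose(mags[0], mags[1], atol=1e-9)


class TestControlAndContrast:
    def make_segments(self, rng, n_seg=12):
        n = int(5 * FS)
        segs = []
        for _ in range(n_seg):
            eeg = rng.standard_normal((3, n))
            segs.append({"eeg": eeg - eeg.mean(1, keepdims=True),
                         "att": np.abs(rng.standard_normal(n))})
        return segs

    def test_mismatch_pairing_is_derangement(self, rng):
        segs = self.make_segments(rng)
        with pytest.raises(ValueError):
            tracking.control_scores(segs, FS, shift=len(segs))
        with pytest.raises(ValueError):
            tracking.control_scores(segs[:1], FS)

    def test_white_noise_matched_and_control_indistinguishable(self, rng):
        """Without any true coupling, the matched score is just another draw
        from the mismatched-pairing null distribution."""
        segs = self.make_segments(rng, n_seg=12)
        matched = tracking.gfp_magnitude(
            tracking.xcorr_over_segments(segs, FS, "att")
        ).summary
        null = [
            tracking.control_scores(segs, FS, shift=k).summary
            for k in range(1, 12)
        ]
        lo, hi = np.min(null), np.max(null)
        spread = hi - lo
        assert lo - spread <= matched <= hi + spread

    def test_before_after_requires_adjacent_slots(self):
        with pytest.raises(ValueError):
            tracking.before_after_contrast({-1: [], 1: []}, FS)
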