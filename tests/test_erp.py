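"""P3 branch: ERP filtering, epoching/baseline, trial-by-trial rejection,
smoothing, and P3 quantification."""

import numpy as np
import pytest

from envtrack import erp
from envtrack.containers import EegRecording, make_event_table
from envtrack.filters import attenuation_db, design_fir

FS = 500.0
CH5 = ["Fz", "Cz", "Pz", "C3", "C4"]


class TestFilterErp:
    def test_frequency_response_oracle(self):
        lp = design_fir(FS, 10.0, "lowpass", erp.ERP_LP_ORDER)
        hp = design_fir(FS, 0.1, "highpass", erp.ERP_HP_ORDER)
        assert lp.size == 661 and hp.size == 16501
        assert attenuation_db(hp, FS, 0.01) <= -20.0
        assert abs(attenuation_db(lp, FS, 5.0)) <= 1.0
        assert abs(attenuation_db(hp, FS, 5.0)) <= 1.0

    def test_too_short_recording_rejected(self, rng):
        rec = EegRecording(rng.standard_normal((2, 1000)), FS, ["Fz", "Pz"])
        with pytest.raises(ValueError):
            erp.filter_erp(rec)


class TestEpochAndBaseline:
    def test_constant_offset_zeroed_by_baseline(self):
        data = np.full((2, 5000), 17.0)
        ev = make_event_table([5.0], ["name"], FS)
        rec = EegRecording(data, FS, ["Fz", "Pz"], events=ev)
        out = erp.epoch_and_baseline(rec)
        assert np.allclose(out.epochs, 0.0, atol=1e-9)

    def test_epoch_count_per_condition(self, rng):
        onsets = np.arange(40) * 3.0 + 5.0
        conds = ["higher"] * 20 + ["lower"] * 20
        ev = make_event_table(onsets, ["name"] * 40, FS, block=2, condition=conds)
        rec = EegRecording(rng.standard_normal((2, int(130 * FS))), FS, ["Fz", "Pz"], events=ev)
        out = erp.epoch_and_baseline(rec)
        assert out.n_epochs == 40
        assert (out.condition == "higher").sum() == 20
        assert (out.condition == "lower").sum() == 20

    def test_epoch_sample_index_arithmetic(self, rng):
        # epoch must span samples [-250, +750) around the event sample
        data = np.tile(np.arange(5000.0), (2, 1))
        ev = make_event_table([5.0], ["name"], FS)
        rec = EegRecording(data, FS, ["Fz", "Pz"], events=ev)
        out = erp.epoch_and_baseline(rec)
        assert out.epochs.shape[-1] == 1000
        ramp = np.arange(2500 - 250, 2500 + 750, dtype=float)
        assert np.allclose(out.epochs[0, 0], ramp - ramp[:250].mean())

    def test_event_near_edge_excluded_with_log(self, rng):
        ev = make_event_table([0.2, 5.0], ["name", "name"], FS)
        rec = EegRecording(rng.standard_normal((2, 5000)), FS, ["Fz", "Pz"], events=ev)
        out = erp.epoch_and_baseline(rec)
        assert out.n_epochs == 1
        assert out.log and out.log[0]["reason"] == "window outside recording"

    def test_empty_event_table_warns(self, rng):
        rec = EegRecording(rng.standard_normal((2, 5000)), FS, ["Fz", "Pz"])
        with pytest.warns(UserWarning):
            out = erp.epoch_and_baseline(rec)
        assert out.n_epochs == 0


def make_erpset(epochs):
    n_ep = epochs.shape[0]
    return erp.ErpSet(
        epochs=epochs,
        times=np.arange(-250, 750) / FS,
        ch_names=CH5,
        event_type=np.array(["name"] * n_ep, dtype=object),
        condition=np.array(["higher"] * n_ep, dtype=object),
        fs=FS,
    )


class TestTbtReject:
    def test_clean_epochs_untouched(self, rng):
        epochs = rng.standard_normal((6, 5, 1000)) * 20
        out = erp.tbt_reject(make_erpset(epochs.copy()))
        assert out.n_epochs == 6
        assert np.array_equal(out.epochs, epochs)
        assert out.log == []

    def test_decision_table_fixture(self, rng):
        """Hand-built 5-channel / 10-epoch decision table.

        Epoch 1: one channel above threshold -> interpolated, epoch kept.
        Epoch 2: two channels above -> both interpolated, epoch kept.
        Epoch 3: three channels above -> epoch rejected.
        """
        epochs = rng.standard_normal((10, 5, 1000)) * 10
        epochs[1, 0, 100] = 200.0
        epochs[2, 0, 50] = 200.0
        epochs[2, 1, 60] = -200.0
        epochs[3, 0, 10] = 200.0
        epochs[3, 1, 20] = 200.0
        epochs[3, 2, 30] = 200.0
        out = erp.tbt_reject(make_erpset(epochs.copy()))
        assert out.n_epochs == 9
        # interpolated channels no longer exceed threshold
        assert np.abs(out.epochs).max() < 150.0
        actions = {(e.get("epoch"), e["action"]) for e in out.log}
        assert (1, "interpolated") in actions
        assert (2, "interpolated") in actions
        assert (3, "rejected") in actions
        # non-flagged channels in kept epochs are untouched
        assert np.array_equal(out.epochs[0], epochs[0])
        assert np.array_equal(out.epochs[1][2:], epochs[1][2:])

    def test_chronically_bad_channel_interpolated_everywhere(self, rng):
        epochs = rng.standard_normal((10, 5, 1000)) * 10
        epochs[0:4, 3, 500] = 300.0  # bad in 40% > 30% of epochs
        out = erp.tbt_reject(make_erpset(epochs.copy()))
        assert out.n_epochs == 10
        assert any(
            e.get("action") == "interpolated_all_epochs" and e["channel"] == "C3"
            for e in out.log
        )
        # channel replaced in every epoch, not only the flagged ones
        assert not np.array_equal(out.epochs[5, 3], epochs[5, 3])

    def test_order_independence_across_epochs(self, rng):
        epochs = rng.standard_normal((8, 5, 1000)) * 10
        epochs[2, 0, 10] = 200.0
        epochs[5, 0, 10] = 200.0
        epochs[5, 1, 10] = 200.0
        epochs[5, 2, 10] = 200.0
        out1 = erp.tbt_reject(make_erpset(epochs.copy()))
        perm = np.array([5, 3, 1, 0, 2, 4, 7, 6])
        out2 = erp.tbt_reject(make_erpset(epochs[perm].copy()))
        # same epochs survive with the same data, independent of order
        kept1 = {e.tobytes() for e in out1.epochs}
        kept2 = {e.tobytes() for e in out2.epochs}
        assert kept1 == kept2

    def test_all_epochs_rejected_raises(self, rng):
        epochs = rng.standard_normal((3, 5, 1000)) * 10
        epochs[:, 0:4, 500] = 400.0
        # channel-wide rescue disabled so every epoch keeps >2 bad channels
        with pytest.raises(ValueError):
            erp.tbt_reject(make_erpset(epochs), chan_bad_fraction=1.1)


class TestAverageAndSmooth:
    def test_single_epoch_equals_smoothed_epoch(self, rng):
        from scipy.ndimage import uniform_filter1d

        epochs = rng.standard_normal((1, 5, 1000))
        out = erp.average_and_smooth(make_erpset(epochs))
        expected = uniform_filter1d(epochs[0], size=51, axis=1, mode="nearest")
        assert np.allclose(out["name"], expected)

    def test_identical_epochs_mean_idempotent(self, rng):
        one = rng.standard_normal((1, 5, 1000))
        many = np.repeat(one, 7, axis=0)
        assert np.allclose(
            erp.average_and_smooth(make_erpset(many))["name"],
            erp.average_and_smooth(make_erpset(one))["name"],
        )

    def test_white_noise_variance_reduced_by_window_factor(self, rng):
        epochs = rng.standard_normal((1, 2, 100000))
        smoothed = erp.average_and_smooth(
            erp.ErpSet(epochs, np.arange(100000) / FS, ["Fz", "Pz"],
                       np.array(["name"], dtype=object), np.array(["none"], dtype=object), FS)
        )["name"]
        ratio = smoothed.var() / epochs.var()
        assert ratio == pytest.approx(1 / 51, rel=0.2)


class TestP3Quantify:
    def test_all_zero_waveform(self):
        times = np.arange(-250, 750) / FS
        m = erp.p3_quantify(np.zeros(1000), times)
        assert m.mean_amp_window == 0.0
        assert m.latency == pytest.approx(0.5)
        assert m.amp_at_latency == 0.0

    def test_single_maximum_latency(self):
        times = np.arange(-250, 750) / FS
        wf = np.zeros(1000)
        wf[np.argmin(np.abs(times - 0.8))] = 1.0
        assert erp.p3_quantify(wf, times).latency == pytest.approx(0.8)

    def test_gaussian_bump_latency_and_windowed_amplitude_oracle(self):
        times = np.arange(-250, 750) / FS
        wf = 4.0 * np.exp(-0.5 * ((times - 0.76) / 0.1) ** 2)
        m = erp.p3_quantify(wf, times)
        assert abs(m.latency - 0.76) <= 1 / FS
        sel = (times >= m.latency - 0.05) & (times <= m.latency + 0.05)
        assert m.amp_at_latency == pytest.approx(wf[sel].sum() / sel.sum())

    def test_latency_invariant_to_positive_affine_scaling(self):
        times = np.arange(-250, 750) / FS
        wf = np.sin(times * 3) + 0.3 * np.cos(times * 11)
        base = erp.p3_quantify(wf, times).latency
        scaled = erp.p3_quantify(2.5 * wf + 7.0, times).latency
        assert scaled == base

    def test_missing_channel_rejected(self):
        times = np.arange(-250, 750) / FS
        with pytest.raises(KeyError):
            erp.p3_quantify(np.zeros((2, 1000)), times, ["Fz", "Cz"], channel="Pz")
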