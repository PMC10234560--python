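"""Spectral pipeline: filters, montages, Morlet maps, normalization,
epoching, contact selection, artifact removal."""

import numpy as np
import pytest

from stnadapt.spectral import (
    Epochs,
    NARROW_PAIRS,
    baseline_normalize,
    build_bipolar_montage,
    epoch_align,
    morlet_tfr,
    preprocess_signal,
    remove_stim_artifact,
    select_functional_contact,
)

RATE = 2048.0


class TestPreprocess:
    def test_dc_offset_strongly_attenuated(self):
        x = np.full(int(20 * RATE), 5.0)
        y, rate = preprocess_signal(x, RATE)
        mid = y[len(y) // 4 : -len(y) // 4]
        assert np.abs(mid).max() < 5.0 * 10 ** (-40 / 20)  # >= 40 dB down

    def test_mains_notch(self):
        t = np.arange(0, 20, 1 / RATE)
        x = np.sin(2 * np.pi * 50.0 * t)
        y, rate = preprocess_signal(x, RATE)
        mid = y[len(y) // 4 : -len(y) // 4]
        rms_in, rms_out = np.sqrt(np.mean(x**2)), np.sqrt(np.mean(mid**2))
        assert rms_out < rms_in * 10 ** (-20 / 20)  # >= 20 dB down

    def test_output_rate_and_passband(self):
        t = np.arange(0, 20, 1 / RATE)
        x = np.sin(2 * np.pi * 20.0 * t)
        y, rate = preprocess_signal(x, RATE)
        assert rate == 200.0
        assert y.size == int(20 * 200)
        mid = y[len(y) // 4 : -len(y) // 4]
        assert np.sqrt(np.mean(mid**2)) == pytest.approx(1 / np.sqrt(2), rel=0.05)

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            preprocess_signal(np.zeros(1000), 300.0)


class TestMontage:
    def test_narrow_gives_nine_channels(self, rng):
        sig, names = build_bipolar_montage(rng.normal(size=(8, 100)), "narrow")
        assert sig.shape[0] == 9 and len(names) == 9

    def test_wide_gives_two_channels(self, rng):
        sig, names = build_bipolar_montage(rng.normal(size=(8, 100)), "wide")
        assert sig.shape[0] == 2 and names == ["L3-L1", "L0-L2"]

    def test_common_mode_rejection(self, rng):
        common = rng.normal(size=100)
        contacts = np.tile(common, (8, 1))
        for mode in ("narrow", "wide"):
            sig, _ = build_bipolar_montage(contacts, mode)
            assert np.allclose(sig, 0.0)

    def test_narrow_matches_pair_list_oracle(self, rng):
        contacts = rng.normal(size=(8, 50))
        sig, _ = build_bipolar_montage(contacts, "narrow")
        # exhaustive expectation for the fixed 4-level directional lead
        expected_pairs = {
            (7, 4), (7, 5), (7, 6),  # dorsal ring vs dorsal directionals
            (4, 1), (5, 2), (6, 3),  # dorsal vs matching ventral directionals
            (1, 0), (2, 0), (3, 0),  # ventral directionals vs ventral ring
        }
        assert set(NARROW_PAIRS) == expected_pairs
        for row, (a, b) in zip(sig, NARROW_PAIRS):
            assert np.array_equal(row, contacts[a] - contacts[b])

    def test_missing_contacts_rejected(self, rng):
        with pytest.raises(ValueError):
            build_bipolar_montage(rng.normal(size=(6, 100)), "narrow")


class TestMorlet:
    def test_frequency_localization_and_power_scaling(self):
        rate = 200.0
        t = np.arange(0, 30, 1 / rate)
        x = np.sin(2 * np.pi * 20.0 * t)
        tfr = morlet_tfr(x, rate)
        assert tfr.freqs[0] == 2.0 and tfr.freqs[-1] == 100.0
        assert tfr.step == pytest.approx(0.02)
        prof = tfr.power[0].mean(axis=1)
        assert tfr.freqs[np.argmax(prof)] == 20.0
        tfr2 = morlet_tfr(2 * x, rate)
        mid = slice(tfr.times.size // 4, -tfr.times.size // 4)
        ratio = tfr2.power[0, 18, mid].mean() / tfr.power[0, 18, mid].mean()
        assert ratio == pytest.approx(4.0, rel=0.01)

    def test_short_recording_rejected(self):
        with pytest.raises(ValueError):
            morlet_tfr(np.zeros(100), 200.0)


class TestNormalization:
    def test_stationary_signal_maps_to_unity(self, rng):
        x = rng.normal(size=int(60 * 200))
        tfr = baseline_normalize(morlet_tfr(x, 200.0))
        mid = tfr.power[0, :, 100:-100]
        assert np.allclose(mid.mean(axis=1), 1.0, atol=0.1)

    def test_masked_artifact_excluded_from_mean(self, rng):
        x = rng.normal(size=int(60 * 200))
        tfr = morlet_tfr(x, 200.0)
        mask = np.zeros(tfr.times.size, dtype=bool)
        mask[1000:1500] = True
        tfr.power[..., mask] *= 100.0
        norm = baseline_normalize(tfr, mask)
        # each frequency row averages to exactly 1 over the retained samples
        assert np.allclose(norm.power[0][:, ~mask].mean(axis=1), 1.0)
        # and the masked artifact did not drag the normalization down
        assert norm.power[0][:, mask].mean() > 50.0

    def test_closed_form_doubled_epoch(self):
        # power 2 on one fifth of the recording, 1 elsewhere:
        # mean = 1.2, normalized doubled epoch = 2/1.2
        from stnadapt.spectral import TimeFrequencyMap

        power = np.ones((1, 3, 1000))
        power[..., :200] = 2.0
        tfr = TimeFrequencyMap(power, np.arange(3), np.arange(1000) * 0.02)
        norm = baseline_normalize(tfr)
        assert norm.power[0, 0, 0] == pytest.approx(2.0 / 1.2)
        assert norm.power[0, 0, 500] == pytest.approx(1.0 / 1.2)

    def test_double_normalization_rejected(self, rng):
        tfr = baseline_normalize(morlet_tfr(rng.normal(size=12000), 200.0))
        with pytest.raises(ValueError):
            baseline_normalize(tfr)


class TestEpoching:
    def test_bump_lands_at_time_zero(self):
        from stnadapt.spectral import TimeFrequencyMap

        times = np.arange(3000) * 0.02
        power = np.ones((1, 1, 3000))
        events = np.array([10.0, 25.0, 40.0])
        for ev in events:
            power[..., int(round(ev / 0.02))] = 9.0
        tfr = TimeFrequencyMap(power, np.array([20.0]), times)
        ep = epoch_align(tfr, events, (-1.0, 1.0))
        i0 = np.flatnonzero(np.isclose(ep.times, 0.0))[0]
        assert np.all(ep.power[:, 0, 0, i0] == 9.0)
        assert np.allclose(ep.times, np.arange(-1.0, 1.01, 0.02), atol=1e-9)

    def test_edge_epochs_flagged(self):
        from stnadapt.spectral import TimeFrequencyMap

        tfr = TimeFrequencyMap(np.ones((1, 1, 500)), np.array([20.0]),
                               np.arange(500) * 0.02)
        ep = epoch_align(tfr, np.array([0.5, 5.0]), (-1.0, 1.0))
        assert 0 in ep.flagged
        assert list(ep.trial_index) == [1]

    def test_epoch_average_equals_shifted_continuous_average(self, rng):
        from stnadapt.spectral import TimeFrequencyMap

        power = rng.random((1, 2, 2000))
        times = np.arange(2000) * 0.02
        tfr = TimeFrequencyMap(power, np.arange(2), times)
        events = np.array([10.0, 20.0, 30.0])
        ep = epoch_align(tfr, events, (-0.5, 0.5))
        idx = [int(round(ev / 0.02)) for ev in events]
        rel = np.arange(-25, 26)
        manual = np.mean([power[..., i + rel] for i in idx], axis=0)
        assert np.allclose(ep.power.mean(axis=0), manual)


class TestContactSelection:
    def _epochs(self, dips):
        # channels x trials with configurable beta dip during movement
        n_ch = len(dips)
        freqs = np.arange(13.0, 31.0)
        times = np.arange(-1.0, 0.51, 0.02)
        power = np.ones((20, n_ch, freqs.size, times.size))
        move = (times >= -0.5) & (times < 0.25)
        for ch, d in enumerate(dips):
            power[:, ch, :, move] *= 1.0 - d
        return Epochs(power, freqs, times, np.arange(20))

    def test_strongest_dip_selected(self):
        sel = select_functional_contact(self._epochs([0.05, 0.30, 0.05]))
        assert sel.channel == 1
        assert sel.reached_threshold
        assert sel.modulation == pytest.approx(0.30, abs=0.02)

    def test_all_weak_channels_flagged(self):
        sel = select_functional_contact(self._epochs([0.05, 0.08, 0.04]))
        assert not sel.reached_threshold


class TestArtifactRemoval:
    def test_clean_signal_passes_through(self, rng):
        t = np.arange(0, 30, 1 / RATE)
        x = 2.0 * np.sin(2 * np.pi * 20.0 * t) + 0.5 * rng.normal(size=t.size)
        y, rate, info = remove_stim_artifact(x, RATE)
        assert info["removed_fraction"] == 0.0
        assert rate == 200.0

    def test_isolated_spike_interpolated(self):
        t = np.arange(0, 30, 1 / RATE)
        x = np.sin(2 * np.pi * 10.0 * t)
        x[30000:30020] += 50.0  # 10 ms, 50 uV artifact burst
        y, rate, info = remove_stim_artifact(x, RATE)
        assert 0 < info["removed_fraction"] < 0.005
        # nothing suprathreshold survives and the signal far from the
        # artifact is untouched
        assert np.abs(y).max() <= 10.0
        clean, _, _ = remove_stim_artifact(np.sin(2 * np.pi * 10.0 * t), RATE)
        outer = np.r_[0:2500, 3500:6000]
        assert np.corrcoef(y[outer], clean[outer])[0, 1] > 0.999

    def test_idempotent_on_clean_signals(self, rng):
        t = np.arange(0, 20, 1 / RATE)
        x = np.sin(2 * np.pi * 15.0 * t) + 0.2 * rng.normal(size=t.size)
        y1, rate, _ = remove_stim_artifact(x, RATE)
        # feed the cleaned 200 Hz signal through again at its own rate
        y2, _, info2 = remove_stim_artifact(np.repeat(y1, 2), 400.0)
        assert info2["removed_fraction"] == 0.0

    def test_majority_removal_warns(self):
        x = np.full(int(10 * RATE), 50.0)
        x += np.sin(np.arange(x.size) * 0.1) * 30
        with pytest.warns(UserWarning):
            remove_stim_artifact(x, RATE)
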