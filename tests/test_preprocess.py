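"""Resampling, filtering, epoching, rejection and labeling rules."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal, stats

import bistream as bs
from bistream.preprocess import preswitch_discard_count


def _block(data, fs, stim=None, timeline=None):
    table = pd.DataFrame(
        {"site_id": np.arange(1, data.shape[0] + 1), "area": ["STG"] * data.shape[0]}
    )
    return bs.RecordingBlock(data=data, fs=fs, site_table=table, stim=stim, timeline=timeline)


def _tone(freq, fs, dur=30.0):
    t = np.arange(int(dur * fs)) / fs
    return np.sin(2 * np.pi * freq * t)


class TestResample:
    def test_tone_preserved_from_2khz(self):
        block = _block(_tone(10.0, 2000)[None, :], 2000)
        out = bs.resample_to_1khz(block)
        assert out.fs == 1000
        mid = out.data[0, 2000:-2000]  # ignore filter edges
        assert np.ptp(mid) / 2 == pytest.approx(1.0, rel=0.01)

    def test_identity_at_1khz(self):
        data = np.random.default_rng(0).standard_normal((2, 5000))
        out = bs.resample_to_1khz(_block(data, 1000))
        assert out.data is data

    def test_fractional_rate_length(self):
        n = 40_000
        block = _block(np.zeros((1, n)), 2034.5)
        out = bs.resample_to_1khz(block)
        expected = int(n * 1000 / 2034.5)
        assert abs(out.data.shape[1] - expected) <= 1

    def test_low_rate_rejected(self):
        with pytest.raises(ValueError):
            bs.resample_to_1khz(_block(np.zeros((1, 100)), 500))


class TestBandpass:
    @pytest.mark.parametrize(
        ("freq", "db_bound", "kind"),
        [(0.1, 20.0, "stop"), (30.0, 1.0, "pass"), (200.0, 40.0, "stop")],
    )
    def test_frequency_response(self, freq, db_bound, kind):
        """1.5-70 Hz band-pass: drift and high frequencies out, LFP band in."""
        fs = 1000.0
        out = bs.bandpass_lfp(_block(_tone(freq, fs, 60.0)[None, :], fs))
        mid = out.data[0, 5000:-5000]
        in_amp = 1.0
        out_amp = np.sqrt(2 * np.mean(mid**2))
        db = 20 * np.log10(max(out_amp, 1e-12) / in_amp)
        if kind == "stop":
            assert db <= -db_bound
        else:
            assert abs(db) <= db_bound


class TestNarrowband:
    def test_common_interference_removed(self):
        fs = 1000.0
        rng = np.random.default_rng(2)
        n = int(120 * fs)
        t = np.arange(n) / fs
        line = 5.0 * np.sin(2 * np.pi * 2.5 * t)
        data = line[None, :] + rng.standard_normal((6, n))
        out = bs.remove_narrowband(_block(data, fs), n_discard=5)

        def band_power(x):
            f, p = signal.welch(x, fs=fs, nperseg=8192)
            sel = (f >= 2.2) & (f <= 2.7)
            return p[sel].sum()

        assert band_power(out.data[0]) < 0.01 * band_power(data[0])

    def test_untouched_outside_stopband(self):
        """A signal with no 2.2-2.7 Hz energy passes essentially unchanged."""
        fs = 1000.0
        x = _tone(30.0, fs, 60.0)
        data = np.vstack([x, 0.5 * x, -x])
        out = bs.remove_narrowband(_block(data, fs), n_discard=2)
        mid = slice(5000, -5000)
        rel = np.abs(out.data[0, mid] - data[0, mid]).max() / np.abs(data[0, mid]).max()
        assert rel < 1e-3

    def test_component_cap_warns(self):
        data = np.random.default_rng(3).standard_normal((2, 20_000))
        with pytest.warns(UserWarning, match="n_discard"):
            bs.remove_narrowband(_block(data, 1000.0), n_discard=30)

    def test_single_site_rejected(self):
        with pytest.raises(ValueError):
            bs.remove_narrowband(_block(np.zeros((1, 1000)), 1000.0))


class TestEpoching:
    def _stim_block(self, n_triplets=50, n_sites=2, seed=0):
        stim = bs.TripletStimulus(n_triplets=n_triplets)
        n = int(stim.total_dur * 1000)
        data = np.random.default_rng(seed).standard_normal((n_sites, n))
        return _block(data, 1000.0, stim=stim), stim

    def test_plain_window_counts(self):
        block, stim = self._stim_block(50)
        ep = bs.epoch_triplets(block)
        assert ep.trials.shape == (50, 2, 600)
        assert np.allclose(ep.trial_onsets, stim.triplet_onsets())

    def test_embedding_window_drops_edges(self):
        block, _ = self._stim_block(50)
        ep = bs.epoch_triplets(block, window=(700.0, 600.0, 700.0))
        assert ep.n_time == 2000
        assert ep.n_trials == 46  # two triplets at each edge lack context
        assert ep.trial_onsets[0] == pytest.approx(1.2)

    def test_epoching_is_lossless(self):
        """Concatenating (0,600,0) trials reproduces the continuous data."""
        block, _ = self._stim_block(10)
        ep = bs.epoch_triplets(block)
        recon = np.concatenate([ep.trials[i] for i in range(ep.n_trials)], axis=1)
        assert np.array_equal(recon, block.data[:, : recon.shape[1]])

    def test_missing_stimulus_errors(self):
        with pytest.raises(ValueError):
            bs.epoch_triplets(_block(np.zeros((1, 1000)), 1000.0))


class TestRejection:
    def _epochs(self, data):
        n_trials, n_sites, n_time = data.shape
        return bs.LabeledEpochs(
            trials=data,
            labels=np.zeros(n_trials, dtype=int),
            kept=np.ones((n_trials, n_sites), dtype=bool),
            trial_onsets=np.arange(n_trials) * 0.6,
            window=(0.0, n_time * 1.0, 0.0),
            fs=1000.0,
            site_table=pd.DataFrame({"site_id": np.arange(1, n_sites + 1), "area": ["STG"] * n_sites}),
        )

    def test_spike_masked(self):
        rng = np.random.default_rng(0)
        data = rng.standard_normal((100, 1, 600))
        data[17, 0, 300] = 10.0 * data.std()
        ep = bs.reject_trials(self._epochs(data))
        assert not ep.kept[17, 0]

    def test_gaussian_rejection_rate(self):
        """Rejection rate on pure Gaussian data matches the 4-SD tail bound."""
        rng = np.random.default_rng(5)
        data = rng.standard_normal((500, 1, 600))
        ep = bs.reject_trials(self._epochs(data))
        n_rej = int((~ep.kept[:, 0]).sum())
        p_trial = 1 - (1 - 2 * stats.norm.sf(4.0)) ** 600
        expected = 500 * p_trial
        sd = np.sqrt(500 * p_trial * (1 - p_trial))
        assert abs(n_rej - expected) <= 3.5 * sd

    def test_constant_block_no_rejection(self):
        ep = bs.reject_trials(self._epochs(np.full((20, 1, 600), 3.0)))
        assert ep.kept.all()

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        ep0 = self._epochs(rng.standard_normal((200, 2, 600)))
        once = bs.reject_trials(ep0)
        twice = bs.reject_trials(once)
        assert np.array_equal(once.kept, twice.kept)


class TestLabeling:
    @pytest.mark.parametrize(
        ("rt", "k"), [(0.6, 2), (1.34, 3), (2.0, 4), (3.22, 6), (0.0, 2)]
    )
    def test_preswitch_discard_count(self, rt, k):
        assert preswitch_discard_count(rt) == k

    def _epochs(self, n_triplets=50):
        data = np.zeros((n_triplets, 1, 600))
        return bs.LabeledEpochs(
            trials=data,
            labels=np.zeros(n_triplets, dtype=int),
            kept=np.ones((n_triplets, 1), dtype=bool),
            trial_onsets=np.arange(n_triplets) * 0.6,
            window=(0.0, 600.0, 0.0),
            fs=1000.0,
            site_table=pd.DataFrame({"site_id": [1], "area": ["STG"]}),
        )

    def test_labels_and_exclusions(self):
        tl = bs.PerceptTimeline(np.array([3.0, 15.0]), np.array([1, 2]), 30.0)
        ep = bs.label_and_filter(self._epochs(), tl, rt=0.6)  # k = 2
        onsets = ep.trial_onsets
        # before the first press: unlabeled
        assert np.all(ep.labels[onsets < 3.0] == 0)
        # k=2 epochs before each press excluded
        for p in tl.press_times:
            sel = (onsets >= p - 1.2) & (onsets < p)
            assert np.all(ep.labels[sel] == 0)
        # mid-dominance trials carry the reported percept
        assert ep.labels[np.searchsorted(onsets, 6.0)] == 1
        assert ep.labels[np.searchsorted(onsets, 20.0)] == 2

    def test_never_labels_before_first_press(self):
        tl = bs.PerceptTimeline(np.array([7.3]), np.array([2]), 30.0)
        ep = bs.label_and_filter(self._epochs(), tl, rt=0.0)
        assert np.all(ep.trial_onsets[ep.labels != 0] >= 7.3)

    def test_control_block_change_to_response_excluded(self):
        tl = bs.PerceptTimeline(
            np.array([1.0, 12.4]),
            np.array([1, 2]),
            30.0,
            stim_changes=np.array([10.0]),
        )
        ep = bs.label_and_filter(self._epochs(), tl, rt=0.0)
        sel = (ep.trial_onsets >= 10.0) & (ep.trial_onsets < 12.4)
        assert np.all(ep.labels[sel] == 0)

    @pytest.mark.parametrize(
        ("press", "expected_onset"), [(10.0, 9.0), (10.2, 9.6), (0.65, 0.0)]
    )
    def test_preswitch_trial_selection(self, press, expected_onset):
        tl = bs.PerceptTimeline(np.array([press]), np.array([2]), 30.0)
        out = bs.select_preswitch_trials(self._epochs(), tl)
        assert out.n_trials == 1
        assert out.trial_onsets[0] == pytest.approx(expected_onset)
        assert out.labels[0] == 2  # labeled by the percept switched into

    def test_preswitch_press_too_early(self):
        tl = bs.PerceptTimeline(np.array([0.3]), np.array([1]), 30.0)
        out = bs.select_preswitch_trials(self._epochs(), tl)
        assert out.n_trials == 0

    def test_preswitch_no_presses(self):
        tl = bs.PerceptTimeline(np.array([]), np.array([]), 30.0)
        out = bs.select_preswitch_trials(self._epochs(), tl)
        assert out.n_trials == 0


def test_full_chain_on_synthetic(small_epochs):
    """End-to-end preprocessing yields labeled 600 ms trials."""
    assert small_epochs.n_time == 600
    assert set(np.unique(small_epochs.labels)) <= {0, 1, 2}
    assert (small_epochs.labels == 1).sum() > 5
    assert (small_epochs.labels == 2).sum() > 5
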