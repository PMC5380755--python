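import numpy as np
import pytest
from hypothesis import given, strategies as st

from nirsload.preprocessing import (BeerLambertConstants, build_sample_set,
                                    channel_qc, design_lowpass_fir,
                                    intensity_to_od, lowpass_filter,
                                    mbll_convert, HemoTimeSeries)
from nirsload.synthetic import ForwardModelConfig, generate_design, generate_fnirs

from conftest import preprocess_recording


class TestOpticalDensity:
    def test_constant_intensity_gives_zero(self):
        od = intensity_to_od({760: np.full((2, 50), 3.0)})
        assert np.allclose(od.od[760], 0.0)

    def test_decade_drop_gives_unit_od(self):
        x = np.full(100, 10.0)
        x[40] = 1.0
        od = intensity_to_od({760: x[None, :]},
                             reference={760: np.array([10.0])})
        assert od.od[760][0, 40] == pytest.approx(1.0)

    def test_zero_mean_per_channel_with_default_reference(self):
        rng = np.random.default_rng(0)
        x = np.exp(rng.normal(0, 0.1, (4, 200)))
        od = intensity_to_od({850: x})
        assert np.allclose((10.0 ** -od.od[850]).mean(axis=1), 1.0, atol=1e-12)

    def test_nonpositive_intensity_names_location(self):
        x = np.ones((3, 10))
        x[2, 4] = 0.0
        with pytest.raises(ValueError, match="channel index 2, sample 4"):
            intensity_to_od({760: x})


class TestBeerLambert:
    def test_printed_default_constants(self):
        c = BeerLambertConstants()
        assert np.allclose(c.epsilon, [[1486.59, 3843.71],
                                       [2526.39, 1798.64]])
        assert c.dpf == (7.25, 6.38)

    def test_zero_od_gives_zero_concentrations(self):
        c = BeerLambertConstants(distance_cm=np.array([3.5]))
        od = intensity_to_od({760: np.ones((1, 20)), 850: np.ones((1, 20))})
        hemo = mbll_convert(od, c, 1.955)
        assert np.allclose(hemo.hbo, 0) and np.allclose(hemo.hbr, 0)

    def test_invert_forward_known_concentrations(self):
        """Forward-model (1, -0.5) uM at 3.5 cm, recover to <=1e-9."""
        hbo_t, hbr_t = 1e-6, -0.5e-6
        c = BeerLambertConstants(distance_cm=np.array([3.5]))
        od = {}
        for i, wl in enumerate(c.wavelengths_nm):
            eps = c.epsilon[i]
            od[wl] = np.full((1, 10),
                             3.5 * c.dpf[i] * (eps[0] * hbo_t + eps[1] * hbr_t))
        hemo = mbll_convert(
            type("OD", (), {"od": od, "reference_intensity": {}})(), c, 1.955)
        assert hemo.hbo[0, 0] == pytest.approx(hbo_t, rel=1e-9)
        assert hemo.hbr[0, 0] == pytest.approx(hbr_t, rel=1e-9)

    def test_generator_round_trip_exact(self):
        """Beer-Lambert inversion is the left-inverse of the forward model
        on mean-centered concentrations (artifacts live in concentration
        space; bad channels excluded, noise included)."""
        design = generate_design(1, 5, 1, seed=4)
        rec = generate_fnirs(design, ForwardModelConfig(seed=4))
        od = intensity_to_od(rec.raw_intensity)
        hemo = mbll_convert(od, rec.config.constants, rec.sampling_rate)
        good = np.ones(rec.n_channels, bool)
        good[rec.config.montage.subset_indices(rec.config.bad_channel_ids)] = False
        for truth, recov in ((rec.truth_hbr, hemo.hbr),
                             (rec.truth_hbo, hemo.hbo)):
            ct = (truth - truth.mean(1, keepdims=True))[good]
            cr = (recov - recov.mean(1, keepdims=True))[good]
            assert np.max(np.abs(cr - ct)) <= 1e-9 * np.max(np.abs(ct))

    def test_singular_epsilon_rejected(self):
        with pytest.raises(ValueError, match="singular"):
            BeerLambertConstants(epsilon=np.ones((2, 2)))


class TestLowpass:
    fs = 1.955

    def test_dc_preserved(self):
        h = design_lowpass_fir(0.1, self.fs)
        assert abs(h.sum() - 1.0) < 1e-3
        x = np.full(600, 2.5)
        assert np.allclose(lowpass_filter(x, 0.1, self.fs), 2.5, atol=1e-6)

    @pytest.mark.parametrize("freq, check", [
        (0.05, "pass"), (0.5, "stop")])
    def test_band_behavior(self, freq, check):
        t = np.arange(4000) / self.fs
        x = np.sin(2 * np.pi * freq * t)
        y = lowpass_filter(x, 0.1, self.fs)
        core = slice(500, -500)
        gain = np.ptp(y[core]) / np.ptp(x[core])
        if check == "pass":
            assert gain == pytest.approx(1.0, abs=0.05)
        else:
            assert gain < 10 ** (-20 / 20)   # >= 20 dB attenuation

    def test_output_time_aligned(self):
        """Group delay is compensated: a slow feature stays in place."""
        t = np.arange(2000) / self.fs
        x = np.exp(-((t - 500) ** 2) / (2 * 30**2))
        y = lowpass_filter(x, 0.1, self.fs)
        assert abs(np.argmax(y) - np.argmax(x)) <= 2

    def test_filter_epoch_commutes_on_interior(self):
        rng = np.random.default_rng(1)
        x = rng.normal(0, 1, 1200)
        full = lowpass_filter(x, 0.1, self.fs, numtaps=31)
        seg = slice(400, 600)
        epoch = lowpass_filter(x[seg], 0.1, self.fs, numtaps=31)
        interior = slice(16, -16)
        assert np.allclose(full[seg][interior], epoch[interior], atol=1e-6)

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(ValueError, match="cutoff"):
            lowpass_filter(np.ones(100), 1.0, self.fs)


class TestChannelQC:
    def test_constant_channel_retained(self):
        rep = channel_qc({760: np.full((1, 50), 5.0)})
        assert rep.cv_percent[760][0] == 0.0
        assert rep.rejected_ids == []

    def test_cv_formula_and_threshold(self):
        x = np.tile([125.0, 75.0], 1000)   # mu 100, sd 25
        rep = channel_qc({760: x[None, :]})
        assert rep.cv_percent[760][0] == pytest.approx(25.0, rel=1e-6)
        assert rep.rejected_ids == [1]

    def test_zero_mean_channel_flagged_not_raised(self):
        x = np.concatenate([np.ones(10), -np.ones(10)])
        rep = channel_qc({760: x[None, :]})
        assert np.isinf(rep.cv_percent[760][0])
        assert rep.rejected_ids == [1]

    @given(st.floats(min_value=1e-3, max_value=1e3))
    def test_scale_invariance(self, scale):
        rng = np.random.default_rng(42)
        x = np.exp(rng.normal(0, 0.3, (1, 300)))
        a = channel_qc({760: x}).cv_percent[760][0]
        b = channel_qc({760: scale * x}).cv_percent[760][0]
        assert b == pytest.approx(a, rel=1e-9)

    def test_injected_bad_channels_rejected_exactly(self, default_design):
        rec = generate_fnirs(default_design, ForwardModelConfig(
            seed=5, bad_channel_ids=(7, 40, 66)))
        rep = channel_qc(rec.raw_intensity)
        assert rep.rejected_ids == [7, 40, 66]


class TestSampleSet:
    def _hemo(self, design, n_ch=3, fs=1.955):
        n = int(np.ceil((design.duration + 10) * fs))
        rng = np.random.default_rng(0)
        x = rng.normal(0, 1, (n_ch, n))
        return HemoTimeSeries(x.copy(), x, fs, list(range(1, n_ch + 1)))

    def test_zero_exclusion_keeps_every_in_trial_sample(self):
        design = generate_design(2, 5, 1, seed=0, p_correct_by_level=None)
        hemo = self._hemo(design)
        ss = build_sample_set(hemo, design, transition_exclusion=0.0)
        expected = sum(
            int(np.ceil((t.sign_onset + t.duration) * 1.955))
            - int(np.ceil(t.sign_onset * 1.955)) for t in design.trials)
        assert len(ss) == expected
        assert ss.excluded["transition"] == 0

    def test_incorrect_trial_dropped(self):
        design = generate_design(1, 10, 1, seed=0, p_correct_by_level=None)
        object.__setattr__(design.trials[3], "correct", False)
        hemo = self._hemo(design)
        ss = build_sample_set(hemo, design, transition_exclusion=0.0)
        assert 3 not in set(ss.trial_id)
        assert set(ss.trial_id) == set(range(10)) - {3}
        assert ss.excluded["incorrect_trial"] > 0

    def test_transition_guard_sample_count(self):
        """20 s trial at 1.955 Hz with +-3 s guard -> ~27 samples/trial."""
        design = generate_design(1, 10, 1, seed=1, p_correct_by_level=None)
        ss = build_sample_set(self._hemo(design), design, 3.0)
        per_trial = np.bincount(ss.trial_id)
        assert np.all((per_trial >= 26) & (per_trial <= 28))

    def test_labels_match_trial_levels(self, default_design):
        ss = build_sample_set(self._hemo(default_design), default_design)
        level_of = {t.index: t.nback_level for t in default_design.trials}
        assert all(level_of[tid] == lab
                   for tid, lab in zip(ss.trial_id, ss.labels))

    def test_channel_shuffle_permutes_features(self, default_design):
        hemo = self._hemo(default_design, n_ch=4)
        ss = build_sample_set(hemo, default_design)
        perm = [2, 0, 3, 1]
        hemo2 = HemoTimeSeries(hemo.hbo[perm], hemo.hbr[perm],
                               hemo.sampling_rate,
                               [hemo.channel_ids[i] for i in perm])
        ss2 = build_sample_set(hemo2, default_design)
        assert np.array_equal(ss2.features, ss.features[:, perm])
        assert np.array_equal(ss2.labels, ss.labels)

    def test_no_surviving_samples_raises(self):
        design = generate_design(1, 2, 1, seed=0)
        with pytest.raises(ValueError, match="no samples"):
            build_sample_set(self._hemo(design), design,
                             transition_exclusion=10.0)

    def test_pipeline_chain_runs(self, default_design):
        rec = generate_fnirs(default_design)
        ss = preprocess_recording(rec)
        assert ss.features.shape[1] == 76   # two bad channels rejected
        assert set(np.unique(ss.labels)) <= {0, 1, 2, 3, 4}
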