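import numpy as np
import pytest
from scipy.ndimage import gaussian_filter1d

from prpkit.simulate import disc_layout
from prpkit.stats import layout_adjacency
from prpkit.tracking import (N_BANDS, PredictorSet, boost_trf, delta_r,
                             derive_predictors, log_band_edges, onset_series,
                             roi_score)


class TestDerivePredictors:
    def test_constant_envelope_has_zero_onsets(self):
        env = np.full((N_BANDS, 100), 2.0)
        ps = derive_predictors(band_envelopes=env, fs_eeg=64.0)
        assert np.allclose(ps.onsets, 0.0)

    def test_step_envelope_gives_single_onset_pulse(self):
        env = np.zeros((N_BANDS, 50))
        env[:, 25:] = 1.0
        ps = derive_predictors(band_envelopes=env, fs_eeg=64.0)
        assert np.allclose(ps.onsets[:, 25], 1.0)
        mask = np.ones(50, bool)
        mask[25] = False
        assert np.allclose(ps.onsets[:, mask], 0.0)

    def test_downward_steps_are_rectified_away(self):
        env = np.ones((N_BANDS, 40))
        env[:, 20:] = 0.25
        ps = derive_predictors(band_envelopes=env, fs_eeg=64.0)
        assert np.allclose(ps.onsets, 0.0)

    def test_waveform_mode_compresses_and_resamples(self):
        fs_audio, fs_eeg = 16000.0, 128.0
        t = np.arange(int(2 * fs_audio)) / fs_audio
        wave = np.sin(2 * np.pi * 1000.0 * t)   # tone inside band range
        ps = derive_predictors(waveform=wave, fs_audio=fs_audio,
                               fs_eeg=fs_eeg)
        assert ps.envelopes.shape == (N_BANDS, int(2 * fs_eeg))
        # the band containing 1 kHz carries the most energy
        edges = log_band_edges()
        band_1k = np.searchsorted(edges, 1000.0) - 1
        assert ps.envelopes.mean(axis=1).argmax() == band_1k

    def test_band_edges_above_nyquist_raise(self):
        with pytest.raises(ValueError, match="Nyquist"):
            derive_predictors(waveform=np.zeros(20000), fs_audio=10000.0,
                              band_edges=log_band_edges(20, 6000))

    def test_negative_envelopes_rejected(self):
        with pytest.raises(ValueError):
            PredictorSet(envelopes=-np.ones((8, 10)),
                         onsets=np.zeros((8, 10)), fs=64.0)


def _convolved_fixture(seed=3, n_seg=8, seg_s=8.0, fs=64.0, smooth=0.8):
    rng = np.random.default_rng(seed)
    seg_len = int(seg_s * fs)
    N = n_seg * seg_len
    env = gaussian_filter1d(np.abs(rng.normal(size=(N_BANDS, N))), smooth,
                            axis=-1)
    ps = derive_predictors(band_envelopes=env, fs_eeg=fs)
    X, names = ps.stack("both")
    lags = np.arange(int(-0.1 * fs), int(0.5 * fs) + 1)
    h_true = np.zeros((X.shape[0], len(lags)))
    tk = np.maximum(lags / fs, 0)
    h_true[3] = (tk / 0.06) * np.exp(1 - tk / 0.06) * (lags >= 0)
    y = np.zeros(N)
    for p in range(X.shape[0]):
        for j, l in enumerate(lags):
            if h_true[p, j]:
                if l >= 0:
                    y[l:] += h_true[p, j] * X[p, :N - l]
                else:
                    y[:l] += h_true[p, j] * X[p, -l:]
    segs = [(i * seg_len, (i + 1) * seg_len) for i in range(n_seg)]
    return X, y, h_true, segs, fs


class TestBoostTRF:
    def test_recovers_generative_kernel(self):
        X, y, h_true, segs, fs = _convolved_fixture()
        m = boost_trf(X, y[None], fs, segs, seed=0, max_steps=2500,
                      patience=40)
        kcorr = np.corrcoef(m.kernels[:, 0, :].ravel(), h_true.ravel())[0, 1]
        assert kcorr >= 0.9
        assert m.r[0] >= 0.95

    def test_null_r_near_zero(self):
        X, _, _, segs, fs = _convolved_fixture(seed=5, n_seg=6)
        rs = []
        for seed in range(3):
            rng = np.random.default_rng(100 + seed)
            eeg = rng.normal(size=(1, segs[-1][1]))
            m = boost_trf(X[:, :segs[-1][1]], eeg, fs, segs, seed=seed,
                          max_steps=150, patience=10)
            rs.append(m.r[0])
        assert np.all(np.abs(rs) < 0.1)

    def test_predictor_scaling_halves_kernels(self):
        X, y, _, segs, fs = _convolved_fixture(n_seg=6)
        m1 = boost_trf(X, y[None], fs, segs, seed=0, max_steps=600)
        m2 = boost_trf(2.0 * X, y[None], fs, segs, seed=0, max_steps=600)
        assert np.allclose(m2.kernels, m1.kernels / 2.0, atol=1e-9)
        assert np.allclose(m2.r, m1.r, atol=1e-9)

    def test_zero_predictor_keeps_zero_kernel(self):
        X, y, _, segs, fs = _convolved_fixture(n_seg=6)
        X = X.copy()
        X[7] = 0.0
        m = boost_trf(X, y[None], fs, segs, seed=0, max_steps=200)
        assert np.allclose(m.kernels[7], 0.0)

    def test_too_few_segments_raise(self):
        X, y, _, segs, fs = _convolved_fixture(n_seg=6)
        with pytest.raises(ValueError, match="segments"):
            boost_trf(X, y[None], fs, segs[:3], seed=0)

    def test_cv_never_predicts_training_segments(self):
        # fold test blocks partition the segments exactly once
        X, y, _, segs, fs = _convolved_fixture(n_seg=6)
        n_seg = len(segs)
        fold_assign = np.array_split(np.arange(n_seg), 5)
        seen = np.concatenate(fold_assign)
        assert sorted(seen.tolist()) == list(range(n_seg))


class TestDeltaR:
    def _models(self):
        X, y, _, segs, fs = _convolved_fixture(n_seg=6)
        full = boost_trf(X, y[None], fs, segs, seed=0, max_steps=300)
        reduced = boost_trf(X[:N_BANDS], y[None], fs, segs, seed=0,
                            max_steps=300)
        return full, reduced

    def test_antisymmetric(self):
        full, reduced = self._models()
        assert np.allclose(delta_r(full, reduced), -delta_r(reduced, full))

    def test_mismatched_folds_raise(self):
        X, y, _, segs, fs = _convolved_fixture(n_seg=10)
        a = boost_trf(X, y[None], fs, segs, folds=5, seed=0, max_steps=50)
        b = boost_trf(X, y[None], fs, segs[:5], folds=5, seed=0, max_steps=50)
        b2 = boost_trf(X, y[None], fs, segs, folds=2, seed=0, max_steps=50)
        with pytest.raises(ValueError):
            delta_r(a, b2)


class TestRoiScore:
    def test_recovers_constructed_topography(self):
        rng = np.random.default_rng(6)
        E = 16
        layout = disc_layout(E)
        adjacency = layout_adjacency(layout)
        # 5 mutually adjacent electrodes with strong positive delta-r
        center = np.array([0.0, 0.0])
        d = np.linalg.norm(layout - center, axis=1)
        signal = np.argsort(d)[:5]
        dr = 0.02 * rng.normal(size=(12, E))
        dr[:, signal] += 0.5
        res = roi_score(dr, adjacency=adjacency, n_perm=500, seed=1)
        assert set(res["roi"]) == set(signal.tolist())

    def test_uniform_delta_r_scores_equal_the_constant(self):
        E = 12
        adjacency = layout_adjacency(disc_layout(E))
        dr = np.full((10, E), 0.3)
        dr += 1e-3 * np.random.default_rng(7).normal(size=dr.shape)
        res = roi_score(dr, adjacency=adjacency, n_perm=300, seed=2)
        assert res["roi"].size == E
        assert np.allclose(res["scores"], dr.mean(axis=1))

    def test_pure_noise_usually_empty(self):
        rng = np.random.default_rng(8)
        adjacency = layout_adjacency(disc_layout(16))
        with pytest.warns(UserWarning, match="empty ROI"):
            # fixed draw known to be null; warns and returns NaN scores
            dr = rng.normal(size=(10, 16))
            res = roi_score(dr, adjacency=adjacency, n_perm=300, seed=3)
            assert np.all(np.isnan(res["scores"]))

    def test_too_few_participants_raise(self):
        with pytest.raises(ValueError):
            roi_score(np.zeros((5, 8)), n_perm=100)
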