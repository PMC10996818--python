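"""Preprocessing chain: QC, trimming, filtering, PCA, MBLL, z-scoring."""

import numpy as np
import pandas as pd
import pytest
from scipy import signal as sps

import neurosync as ns
from neurosync.preprocess import optical_density, qcod

from conftest import hemodynamic_like

FS = 7.8


def _raw(hbo, hbr, **kw):
    return ns.simulate_raw_intensity(hbo, hbr, sampling_rate=kw.pop("fs", FS), **kw)


class TestQC:
    def test_white_noise_channel_flagged(self):
        T = 4096
        hbo = hemodynamic_like(2, T, FS, seed=1)
        hbr = hemodynamic_like(2, T, FS, seed=2)
        raw = _raw(hbo, hbr, white_noise_channels=[1], seed=3)
        report = ns.qc_channels(raw)
        assert report.reason == ["ok", "white_noise"]
        assert report.qcod[1] < 0.1 <= report.qcod[0]
        assert not report.usable[1] and report.usable[0]

    def test_oscillation_dominated_channel_usable(self):
        T = 4096
        t = np.arange(T) / FS
        rng = np.random.default_rng(0)
        x = np.sin(2 * np.pi * 0.1 * t) + 0.05 * rng.standard_normal(T)
        f, psd = sps.welch(x, fs=FS, nperseg=32, window="boxcar")
        assert qcod(psd[f > 0]) >= 0.1  # direct-computation oracle
        hbo = 1e-6 * np.vstack([x, x])
        raw = _raw(hbo, np.zeros_like(hbo))
        report = ns.qc_channels(raw)
        assert report.usable.all()

    def test_saturation_boundary_exactly_two_seconds(self):
        # fs = 8 Hz so 2.0 s is exactly 16 samples: 2.0 s is allowed,
        # one extra sample is "more than 2 seconds" and flags the channel
        fs, T = 8.0, 2048
        hbo = hemodynamic_like(2, T, fs, seed=5)
        hbr = hemodynamic_like(2, T, fs, seed=6)
        raw = _raw(
            hbo,
            hbr,
            fs=fs,
            saturation_segments=[(0, 10.0, 2.0), (1, 10.0, 2.0 + 1 / fs)],
            adc_ceiling=10.0,
        )
        report = ns.qc_channels(raw)
        assert report.reason[0] == "ok"
        assert report.reason[1] == "saturation"
        assert report.max_saturation_run_s[1] > 2.0 >= report.max_saturation_run_s[0]

    def test_qc_does_not_modify_data(self):
        hbo = hemodynamic_like(2, 1024, FS, seed=7)
        raw = _raw(hbo, np.zeros_like(hbo))
        before = raw.intensity.copy()
        ns.qc_channels(raw)
        np.testing.assert_array_equal(raw.intensity, before)


class TestTrimConcatenate:
    events = pd.DataFrame(
        {
            "onset_s": [1.0, 5.0, 10.0],
            "duration_s": [2.0, 3.0, 2.0],
            "condition": ["political", "neutral", "political"],
        }
    )

    def test_length_additivity(self):
        rec = np.arange(2 * 200, dtype=float).reshape(2, 200)
        out = ns.trim_concatenate(rec, self.events, "political", sampling_rate=10.0)
        assert out.shape == (2, 20 + 20)

    def test_segments_in_event_order(self):
        rec = np.zeros((1, 200))
        rec[0, 10:30] = 1.0  # event 1 (political)
        rec[0, 100:120] = 3.0  # event 3 (political)
        out = ns.trim_concatenate(rec, self.events, "political", sampling_rate=10.0)
        assert np.all(out[0, :20] == 1.0) and np.all(out[0, 20:] == 3.0)

    def test_no_matching_events_raises(self):
        with pytest.raises(ns.types.EmptyConditionError):
            ns.trim_concatenate(
                np.zeros((1, 200)), self.events, "missing", sampling_rate=10.0
            )

    def test_out_of_bounds_event_raises(self):
        with pytest.raises(ns.types.InvalidEventsError):
            ns.trim_concatenate(
                np.zeros((1, 50)), self.events, "political", sampling_rate=10.0
            )


class TestBandpass:
    def test_dc_removed(self):
        out = ns.bandpass(np.full(4000, 5.0), sampling_rate=FS)
        assert np.abs(out.mean()) < 1e-6 * 5.0

    def test_passband_gain_near_unity(self):
        # oracle: the filter's own frequency response at 0.1 Hz
        nyq = FS / 2
        sos = sps.butter(3, [0.005 / nyq, 0.5 / nyq], btype="band", output="sos")
        w, h = sps.sosfreqz(sos, worN=[0.1 / nyq * np.pi])
        expected_gain = np.abs(h[0]) ** 2  # applied forward and backward
        # the 0.005 Hz high-pass pole rings for minutes; trim generously
        t = np.arange(30000) / FS
        x = np.sin(2 * np.pi * 0.1 * t)
        out = ns.bandpass(x, sampling_rate=FS)
        measured = np.abs(out[10000:-10000]).max()
        assert measured == pytest.approx(expected_gain, abs=0.02)
        assert 0.95 <= measured <= 1.05

    def test_stopband_attenuation(self):
        t = np.arange(8000) / FS
        x = np.sin(2 * np.pi * 2.0 * t)
        out = ns.bandpass(x, sampling_rate=FS)
        assert np.abs(out[2000:-2000]).max() <= 0.1

    def test_invalid_band_rejected(self):
        with pytest.raises(ns.types.InvalidBandError):
            ns.bandpass(np.zeros(100), low=0.5, high=5.0, sampling_rate=FS)


class TestPCAMotionCorrect:
    def test_zero_fraction_is_identity(self):
        X = np.random.default_rng(0).standard_normal((5, 300))
        np.testing.assert_array_equal(ns.pca_motion_correct(X, 0.0), X)

    def test_shared_spike_suppressed(self):
        rng = np.random.default_rng(1)
        X = rng.standard_normal((8, 500))
        X[:, 250] += 30.0
        out = ns.pca_motion_correct(X, 0.8)
        assert np.abs(out[:, 250]).mean() <= 0.5 * 30.0

    def test_residual_variance_monotone_in_removal(self):
        X = np.random.default_rng(2).standard_normal((6, 400))
        res = [
            np.var(ns.pca_motion_correct(X, f)) for f in (0.0, 0.3, 0.6, 0.99)
        ]
        assert all(a >= b for a, b in zip(res, res[1:]))

    def test_single_channel_warns_and_passes_through(self):
        X = np.random.default_rng(3).standard_normal((1, 100))
        with pytest.warns(UserWarning):
            out = ns.pca_motion_correct(X, 0.8)
        np.testing.assert_array_equal(out, X)


class TestMBLL:
    def test_baseline_intensity_gives_zero_concentration(self):
        raw = _raw(np.zeros((2, 50)), np.zeros((2, 50)))
        hbo, hbr = ns.mbll(raw)
        assert np.abs(hbo).max() < 1e-15 and np.abs(hbr).max() < 1e-15

    def test_forward_inverse_round_trip(self):
        rng = np.random.default_rng(0)
        hbo = 1e-6 * rng.standard_normal((3, 400))
        hbr = 1e-6 * rng.standard_normal((3, 400))
        raw = _raw(hbo, hbr)
        rec_o, rec_r = ns.mbll(raw)
        assert np.abs(rec_o - hbo).max() < 1e-9
        assert np.abs(rec_r - hbr).max() < 1e-9

    def test_distance_scaling(self):
        rng = np.random.default_rng(1)
        hbo = 1e-6 * rng.standard_normal((2, 200))
        hbr = 1e-6 * rng.standard_normal((2, 200))
        raw = _raw(hbo, hbr)
        o1, r1 = ns.mbll(raw, distance_cm=3.0)
        o2, r2 = ns.mbll(raw, distance_cm=6.0)
        np.testing.assert_allclose(o2, o1 / 2, rtol=1e-10)
        np.testing.assert_allclose(r2, r1 / 2, rtol=1e-10)

    def test_nonpositive_intensity_flagged_missing(self):
        raw = _raw(np.zeros((1, 50)), np.zeros((1, 50)))
        raw.intensity[0, 0, 10] = -1.0
        raw.baseline_intensity = None
        with pytest.warns(UserWarning, match="nonpositive"):
            od = optical_density(raw)
        assert np.isnan(od[0, 0, 10]) and np.isfinite(od[0, 0, 11])


class TestTotalHb:
    def test_zscore_properties(self):
        rng = np.random.default_rng(0)
        total = ns.total_hb_signal(rng.standard_normal((4, 500)), rng.standard_normal((4, 500)))
        assert np.abs(total.mean(axis=1)).max() < 1e-10
        assert np.abs(total.std(axis=1) - 1).max() < 1e-10

    def test_equal_hbo_hbr_degenerate(self):
        x = np.random.default_rng(1).standard_normal((2, 100))
        with pytest.raises(ns.DegenerateInputError):
            ns.total_hb_signal(x, x)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        hbo = rng.standard_normal((3, 200))
        hbr = rng.standard_normal((3, 200))
        a = ns.total_hb_signal(hbo, hbr)
        b = ns.total_hb_signal(3.5 * hbo + 2.0, 3.5 * hbr + 2.0)
        np.testing.assert_allclose(a, b, atol=1e-10)


class TestFullChain:
    def test_provenance_order_and_determinism(self):
        T = 2048
        hbo = hemodynamic_like(4, T, FS, seed=10)
        hbr = hemodynamic_like(4, T, FS, seed=11)
        raw = _raw(hbo, hbr)
        events = pd.DataFrame(
            {"onset_s": [10.0, 100.0], "duration_s": [60.0, 60.0],
             "condition": ["political", "political"]}
        )
        tc1, rep1 = ns.preprocess_raw(raw, events=events, condition="political")
        tc2, rep2 = ns.preprocess_raw(raw, events=events, condition="political")
        assert tc1.provenance == [
            "trim_concatenate", "qc_channels", "bandpass",
            "pca_motion_correct", "mbll", "total_hb_zscore",
        ]
        np.testing.assert_array_equal(tc1.total, tc2.total)
        assert rep1.usable.all()
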