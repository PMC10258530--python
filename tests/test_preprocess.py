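"""fNIRS preprocessing: optical density, wavelet motion correction,
Beer-Lambert conversion, heartbeat QC, PCA scalp filtering."""

import numpy as np
import pytest

from dyadsync.design import RawNIRS
from dyadsync.preprocess import (
    QC_NO_HEARTBEAT,
    QC_OK,
    HemoSeries,
    ODSeries,
    beer_lambert,
    detect_heartbeat,
    intensity_to_od,
    pca_spatial_filter,
    qc_channels,
    wavelet_motion_correct,
)
from dyadsync.simulate import (
    NIRSSimConfig,
    concentration_to_intensity,
    simulate_dyad_nirs,
)

FS = 10.0


def _od(series_2d, fs=FS, ids=None):
    arr = np.asarray(series_2d)[None, None, :].repeat(2, axis=1)
    return ODSeries(arr, fs, ids or ["ch1"])


class TestIntensityToOD:
    def test_constant_intensity_zero_od(self):
        raw = RawNIRS("p", FS, np.full((2, 2, 100), 3.7))
        assert np.all(intensity_to_od(raw).od == 0)

    def test_log10_arithmetic(self):
        i = np.ones((1, 2, 1000))
        i[0, :, 500] = 0.1  # ~mean/10 at one sample
        od = intensity_to_od(RawNIRS("p", FS, i))
        expected = np.log10(i.mean(axis=2)[0, 0] / 0.1)
        assert od.od[0, 0, 500] == pytest.approx(expected, rel=1e-6)

    def test_gain_invariance(self):
        rng = np.random.default_rng(0)
        i = np.exp(rng.normal(0, 0.01, (2, 2, 200)))
        od1 = intensity_to_od(RawNIRS("p", FS, i))
        od2 = intensity_to_od(RawNIRS("p", FS, 7.3 * i))
        np.testing.assert_allclose(od1.od, od2.od, atol=1e-12)


class TestWaveletMotionCorrect:
    def test_smooth_signal_preserved(self):
        t = np.arange(1200) / FS
        sig = np.sin(2 * np.pi * 0.05 * t)
        out = wavelet_motion_correct(_od(sig))
        assert np.abs(out.od[0, 0] - sig).max() < 0.01  # < 1% of amplitude

    def test_spike_suppressed_carrier_intact(self):
        t = np.arange(1200) / FS
        sig = np.sin(2 * np.pi * 0.05 * t)
        spiky = sig.copy()
        spiky[600] += 10.0
        out = wavelet_motion_correct(_od(spiky))
        resid = out.od[0, 0] - sig
        assert np.abs(resid).max() <= 0.2 * 10.0  # >= 80% peak reduction
        away = np.abs(np.arange(1200) - 600) > 20
        rms_dev = np.sqrt(np.mean(resid[away] ** 2))
        assert rms_dev <= 0.05 * np.sqrt(np.mean(sig[away] ** 2))

    def test_all_zero_stays_zero(self):
        out = wavelet_motion_correct(_od(np.zeros(256)))
        assert np.all(out.od == 0)

    def test_idempotent_within_tolerance(self):
        from dyadsync.simulate import band_limited_noise

        rng = np.random.default_rng(3)
        t = np.arange(1200) / FS
        sig = (
            0.01 * band_limited_noise(1200, FS, 0.015, 0.15, rng)
            + 0.003 * np.sin(2 * np.pi * 1.2 * t)
        )
        once = wavelet_motion_correct(_od(sig))
        twice = wavelet_motion_correct(once)
        rms = np.sqrt(np.mean(once.od[0, 0] ** 2))
        change = np.sqrt(np.mean((twice.od[0, 0] - once.od[0, 0]) ** 2))
        assert change < 0.01 * rms

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            wavelet_motion_correct(_od(np.zeros(8)))


class TestBeerLambert:
    def test_zero_od_zero_concentration(self, small_layout):
        od = ODSeries(np.zeros((6, 2, 50)), FS, small_layout.channel_ids)
        hemo = beer_lambert(od, small_layout)
        assert np.all(hemo.hbo == 0) and np.all(hemo.hbr == 0)

    def test_inverse_operator_round_trip(self, small_layout):
        rng = np.random.default_rng(1)
        hbo = rng.standard_normal((6, 200))
        hbr = rng.standard_normal((6, 200))
        sep = np.array([c.separation_cm for c in small_layout.channels])
        # direct forward operator (no mean-normalization step)
        intensity = concentration_to_intensity(hbo, hbr, sep)
        od = ODSeries(
            -np.log10(intensity), FS, small_layout.channel_ids
        )
        hemo = beer_lambert(od, small_layout)
        np.testing.assert_allclose(hemo.hbo, hbo, atol=1e-10)
        np.testing.assert_allclose(hemo.hbr, hbr, atol=1e-10)

    def test_doubling_dpf_halves_concentrations(self, small_layout):
        rng = np.random.default_rng(2)
        od = ODSeries(
            rng.normal(0, 0.01, (6, 2, 100)), FS, small_layout.channel_ids
        )
        h1 = beer_lambert(od, small_layout, dpf={760.0: 6.0, 850.0: 6.0})
        h2 = beer_lambert(od, small_layout, dpf={760.0: 12.0, 850.0: 12.0})
        np.testing.assert_allclose(h2.hbo, h1.hbo / 2, atol=1e-12)

    def test_singular_extinction_rejected(self, small_layout):
        od = ODSeries(np.zeros((6, 2, 50)), FS, small_layout.channel_ids)
        with pytest.raises(ValueError, match="singular"):
            beer_lambert(od, small_layout, extinction=np.ones((2, 2)))

    def test_full_simulated_round_trip(self, small_layout):
        """Noise-free simulation -> OD -> Beer-Lambert recovers the
        ground-truth concentration changes (relative RMS < 1e-8)."""
        cfg = NIRSSimConfig(
            cardiac_amp=0, resp_amp=0, mayer_amp=0, scalp_amp=0, seed=11
        )
        raw, _, truth = simulate_dyad_nirs(cfg, small_layout)
        hemo = beer_lambert(intensity_to_od(raw), small_layout)
        gt = truth["hbo"]["A"]
        # intensities are defined up to detector gain, so concentration
        # changes are recovered up to each channel's temporal mean
        rec = hemo.hbo - hemo.hbo.mean(axis=1, keepdims=True)
        gtc = gt - gt.mean(axis=1, keepdims=True)
        rel = np.sqrt(np.mean((rec - gtc) ** 2) / np.mean(gtc**2))
        assert rel < 1e-8


class TestHeartbeat:
    def test_cardiac_sinusoid_detected(self):
        rng = np.random.default_rng(0)
        t = np.arange(1200) / FS
        noise = rng.standard_normal(1200)
        sig = 5 * noise.std() * np.sin(2 * np.pi * 1.2 * t) + noise
        assert detect_heartbeat(sig, FS)

    def test_white_noise_rejected(self):
        rng = np.random.default_rng(1)
        hits = sum(
            detect_heartbeat(rng.standard_normal(1200), FS)
            for _ in range(200)
        )
        assert hits <= 10  # false-positive rate <= 5%

    def test_pure_hemodynamic_rejected(self):
        t = np.arange(1200) / FS
        assert not detect_heartbeat(np.sin(2 * np.pi * 0.05 * t), FS)

    def test_too_short_raises(self):
        with pytest.raises(ValueError):
            detect_heartbeat(np.zeros(100), FS)

    def test_qc_flags_and_exclusion(self, small_layout):
        rng = np.random.default_rng(2)
        t = np.arange(1200) / FS
        hbo = 0.1 * rng.standard_normal((6, 1200))
        hbo[:3] += np.sin(2 * np.pi * 1.2 * t)  # cardiac on first 3 only
        hemo = HemoSeries("p", hbo, np.zeros_like(hbo), FS,
                          small_layout.channel_ids)
        out = qc_channels(hemo)
        assert out.qc[:3] == [QC_OK] * 3
        assert set(out.qc[3:]) == {QC_NO_HEARTBEAT}
        assert list(out.ok_indices()) == [0, 1, 2]


class TestPCASpatialFilter:
    def test_global_component_removed(self, grid_layout):
        rng = np.random.default_rng(0)
        g = rng.standard_normal(1200)
        local = 0.5 * rng.standard_normal((16, 1200))
        hemo = HemoSeries("p", local + g, np.zeros((16, 1200)), FS,
                          grid_layout.channel_ids)
        out = pca_spatial_filter(hemo, grid_layout, 3.5)
        pre = np.mean([abs(np.corrcoef(hemo.hbo[i], g)[0, 1]) for i in range(16)])
        post = np.mean([abs(np.corrcoef(out.hbo[i], g)[0, 1]) for i in range(16)])
        assert post <= 0.5 * pre

    def test_focal_alternating_signal_preserved(self, grid_layout):
        rng = np.random.default_rng(1)
        sign = np.array([(-1) ** (i + j) for i in range(4) for j in range(4)])
        focal = np.outer(sign, rng.standard_normal(1200))
        hemo = HemoSeries("p", focal.copy(), np.zeros_like(focal), FS,
                          grid_layout.channel_ids)
        out = pca_spatial_filter(hemo, grid_layout, 3.5)
        rel = np.sqrt(np.mean((out.hbo - focal) ** 2) / np.mean(focal**2))
        assert rel < 0.10

    def test_sigma_zero_is_identity(self, grid_layout):
        rng = np.random.default_rng(2)
        hbo = rng.standard_normal((16, 300))
        hemo = HemoSeries("p", hbo.copy(), np.zeros_like(hbo), FS,
                          grid_layout.channel_ids)
        out = pca_spatial_filter(hemo, grid_layout, 0.0)
        np.testing.assert_allclose(out.hbo, hbo, atol=1e-10)

    def test_shapes_and_exclusions_preserved(self, grid_layout):
        rng = np.random.default_rng(3)
        hbo = rng.standard_normal((16, 300))
        qc = [QC_OK] * 16
        qc[5] = QC_NO_HEARTBEAT
        hemo = HemoSeries("p", hbo.copy(), np.zeros_like(hbo), FS,
                          grid_layout.channel_ids, qc=qc)
        out = pca_spatial_filter(hemo, grid_layout, 3.5)
        assert out.hbo.shape == hemo.hbo.shape
        assert out.qc == qc
        np.testing.assert_array_equal(out.hbo[5], hbo[5])  # untouched
        np.testing.assert_array_equal(out.hbr, hemo.hbr)   # HHb passthrough

    def test_too_few_channels_raises(self, grid_layout):
        hbo = np.random.default_rng(4).standard_normal((16, 100))
        qc = [QC_NO_HEARTBEAT] * 16
        qc[0] = qc[1] = QC_OK
        hemo = HemoSeries("p", hbo, np.zeros_like(hbo), FS,
                          grid_layout.channel_ids, qc=qc)
        with pytest.raises(ValueError, match="3 ok channels"):
            pca_spatial_filter(hemo, grid_layout, 3.5)

    def test_scalp_injection_recovery(self, grid_layout):
        """Injected global scalp process: channel correlations with it drop
        by >= 50% after filtering (simulator + pipeline end to end)."""
        cfg = NIRSSimConfig(scalp_amp=1.0, cardiac_amp=0.3, seed=5)
        raw, _, truth = simulate_dyad_nirs(cfg, grid_layout)
        hemo = beer_lambert(intensity_to_od(raw), grid_layout)
        out = pca_spatial_filter(hemo, grid_layout, 3.5)
        scalp = truth["scalp"]["A"]
        pre = np.mean([abs(np.corrcoef(hemo.hbo[i], scalp)[0, 1])
                       for i in range(16)])
        post = np.mean([abs(np.corrcoef(out.hbo[i], scalp)[0, 1])
                        for i in range(16)])
        assert post <= 0.5 * pre
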