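"""Morlet CWT, wavelet transform coherence, band averaging, ROI coupling."""

import numpy as np
import pytest

from dyadsync.coherence import (
    WTCResult,
    band_average,
    coi_max_scale,
    cwt_morlet,
    morlet_scales,
    pseudo_coupling,
    records_to_frame,
    roi_pair_coupling,
    scale_to_freq,
    wtc,
)
from dyadsync.design import ConditionBlock
from dyadsync.preprocess import HemoSeries
from dyadsync.simulate import NIRSSimConfig, band_limited_noise, simulate_dyad_nirs

FS = 10.0


class TestCWT:
    def test_sinusoid_localized_at_its_frequency(self):
        t = np.arange(2048) / FS
        for f0 in (0.05, 0.1, 0.3):
            x = np.sin(2 * np.pi * f0 * t)
            scales = morlet_scales(FS)
            w = cwt_morlet(x, FS, scales)
            freqs = scale_to_freq(scales)
            peak = freqs[np.argmax(np.mean(np.abs(w) ** 2, axis=1))]
            assert abs(np.log2(peak / f0)) < 1.5 / 12  # within ~1.5 voices

    def test_linearity_in_amplitude(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal(512)
        scales = morlet_scales(FS)
        w1 = cwt_morlet(x, FS, scales)
        w3 = cwt_morlet(3.0 * x, FS, scales)
        np.testing.assert_allclose(w3, 3.0 * w1, atol=1e-9)

    def test_energy_conservation(self):
        """Scale-integrated |W|^2 tracks signal variance (Parseval-type
        identity for the Morlet frame, numerical-integration oracle)."""
        rng = np.random.default_rng(1)
        x = band_limited_noise(4096, FS, 0.05, 0.3, rng)
        voices = 12
        scales = morlet_scales(FS, f_min=0.01, f_max=2.0, voices=voices)
        w = cwt_morlet(x, FS, scales)
        dj = 1.0 / voices
        dt = 1.0 / FS
        # reconstruction-energy constant for Morlet (omega0=6): C_delta=0.776
        est = (
            dj * dt / (0.776 * 1.033) *
            np.sum(np.abs(w) ** 2 / scales[:, None]) / x.size
        )
        assert est == pytest.approx(np.var(x), rel=0.05)

    def test_nan_rejected(self):
        x = np.ones(64)
        x[3] = np.nan
        with pytest.raises(ValueError):
            cwt_morlet(x, FS, morlet_scales(FS))


class TestWTC:
    def test_self_coherence_is_one_inside_coi(self):
        rng = np.random.default_rng(2)
        x = rng.standard_normal(1200).cumsum()
        res = wtc(x, x, FS)
        assert res.R2[res.valid_mask()].min() > 1.0 - 1e-6

    def test_without_smoothing_r2_is_identically_one(self):
        """Regression proof that the smoothing operator is what makes
        coherence informative: with S = identity, R2 == 1 for ANY pair."""
        rng = np.random.default_rng(3)
        x = rng.standard_normal(600)
        y = rng.standard_normal(600)
        res = wtc(x, y, FS, smoothing=False)
        np.testing.assert_allclose(res.R2, 1.0, atol=1e-9)
        # and with smoothing the same pair is far from 1
        assert wtc(x, y, FS).R2.mean() < 0.9

    def test_symmetric_in_arguments(self):
        rng = np.random.default_rng(4)
        x, y = rng.standard_normal((2, 600))
        r1 = wtc(x, y, FS)
        r2 = wtc(y, x, FS)
        np.testing.assert_allclose(r1.R2, r2.R2, atol=1e-12)

    def test_amplitude_scaling_invariant(self):
        rng = np.random.default_rng(5)
        x, y = rng.standard_normal((2, 600))
        r1 = wtc(x, y, FS)
        r2 = wtc(5.0 * x, 0.2 * y, FS)
        np.testing.assert_allclose(r1.R2, r2.R2, atol=1e-6)

    def test_phase_locked_sinusoids_high_coherence(self):
        t = np.arange(2400) / FS
        rng = np.random.default_rng(6)
        f0 = 0.1
        x = np.sin(2 * np.pi * f0 * t) + 0.1 * rng.standard_normal(t.size)
        y = np.sin(2 * np.pi * f0 * t + 1.0) + 0.1 * rng.standard_normal(t.size)
        res = wtc(x, y, FS)
        sel = (res.freqs > f0 / 1.3) & (res.freqs < f0 * 1.3)
        band = res.R2[:, sel][res.valid_mask()[:, sel]]
        assert band.mean() > 0.9

    def test_independent_noise_below_permutation_null(self):
        """Mean in-band coherence of an independent pair sits below the 95th
        percentile of a circular-shift permutation null."""
        rng = np.random.default_rng(7)
        x = band_limited_noise(1200, FS, 0.015, 0.15, rng)
        y = band_limited_noise(1200, FS, 0.015, 0.15, rng)
        obs = band_average(wtc(x, y, FS))["band_mean_r2"]
        null = []
        for _ in range(50):
            shift = rng.integers(100, 1100)
            null.append(
                band_average(wtc(x, np.roll(y, shift), FS))["band_mean_r2"]
            )
        assert obs <= np.quantile(null, 0.95) + 0.05

    def test_mismatched_or_flat_series_rejected(self):
        with pytest.raises(ValueError):
            wtc(np.zeros(100) + 1.0, np.ones(100), FS)
        with pytest.raises(ValueError):
            wtc(np.arange(100.0), np.arange(99.0), FS)

    def test_coherence_monotone_in_rho(self):
        """Band coherence recovers the planned shared-variance ordering."""
        means = []
        for rho in (0.0, 0.3, 0.6, 0.9):
            zs = []
            for seed in range(10):
                rng = np.random.default_rng(1000 + seed)
                sh = band_limited_noise(1200, FS, 0.015, 0.15, rng)
                x = np.sqrt(rho) * sh + np.sqrt(1 - rho) * band_limited_noise(
                    1200, FS, 0.015, 0.15, rng)
                y = np.sqrt(rho) * sh + np.sqrt(1 - rho) * band_limited_noise(
                    1200, FS, 0.015, 0.15, rng)
                zs.append(band_average(wtc(x, y, FS))["band_mean_z"])
            means.append(np.mean(zs))
        assert all(b > a for a, b in zip(means, means[1:]))


class TestBandAverage:
    def _flat_result(self, c=0.42, n=1200):
        scales = morlet_scales(FS)
        freqs = scale_to_freq(scales)
        coi_s = coi_max_scale(n, FS)
        coi_freq = np.where(coi_s > 0, 6.0 / (2 * np.pi * np.maximum(coi_s, 1e-300)), np.inf)
        return WTCResult(
            freqs=freqs, times=np.arange(n) / FS,
            R2=np.full((n, freqs.size), c), coi_freq=coi_freq,
            scales=scales, fs=FS,
        )

    def test_constant_surface_mean_is_constant(self):
        ba = band_average(self._flat_result(0.42))
        assert ba["band_mean_r2"] == pytest.approx(0.42)
        assert ba["band_mean_z"] == pytest.approx(np.arctanh(np.sqrt(0.42)))

    def test_effective_band_floor_reported(self):
        """120 s at 10 Hz: the COI keeps the lowest usable frequency above
        the nominal 0.015 Hz band edge."""
        ba = band_average(self._flat_result(n=1200))
        assert ba["effective_band_floor_hz"] > 0.015

    def test_band_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            band_average(self._flat_result(), f_lo=2.0, f_hi=4.0)

    def test_no_valid_cells_rejected(self):
        res = self._flat_result(n=100)  # 10 s: all low-band cells in COI
        with pytest.raises(ValueError):
            band_average(res, f_lo=0.015, f_hi=0.02)


def _hemo_pair(small_layout, rho_plan, seed=0, duration=120.0):
    cfg = NIRSSimConfig(
        duration_s=duration, cardiac_amp=0, resp_amp=0, mayer_amp=0,
        scalp_amp=0, seed=seed,
    )
    rawA, rawB, _ = simulate_dyad_nirs(cfg, small_layout, rho_plan)
    def to_hemo(raw):
        from dyadsync.preprocess import beer_lambert, intensity_to_od
        return beer_lambert(intensity_to_od(raw), small_layout,
                            participant_id=raw.participant_id)
    return to_hemo(rawA), to_hemo(rawB)


class TestROICoupling:
    def test_channel_pair_counting(self, small_layout):
        ha, hb = _hemo_pair(small_layout, {}, seed=1)
        recs = roi_pair_coupling(
            ha, small_layout, hb, small_layout, scope="between",
            unit_id="d1",
        )
        frame = records_to_frame(recs)
        same = frame[frame.roi_pair == "L.IFG-L.IFG"]
        assert int(same.n_channel_pairs.iloc[0]) == 4  # 2x2 channels
        cross = frame[frame.roi_pair == "L.IFG-dmPFC"]
        assert int(cross.n_channel_pairs.iloc[0]) == 8  # both orientations

    def test_planned_pair_dominates(self, small_layout):
        # rho=1 on the two L.IFG channel pairs only
        plan = {("ch1", "ch1"): 1.0, ("ch2", "ch2"): 1.0}
        ha, hb = _hemo_pair(small_layout, plan, seed=2)
        recs = records_to_frame(
            roi_pair_coupling(ha, small_layout, hb, small_layout,
                              scope="between", unit_id="d1")
        )
        target = recs[recs.roi_pair == "L.IFG-L.IFG"].wtc_z.iloc[0]
        others = recs[recs.roi_pair != "L.IFG-L.IFG"].wtc_z
        assert target > others.max()

    def test_within_scope_never_self_pairs(self, small_layout):
        ha, _ = _hemo_pair(small_layout, {}, seed=3)
        recs = records_to_frame(
            roi_pair_coupling(ha, small_layout, scope="within", unit_id="p1")
        )
        assert set(recs.scope) == {"within"}
        assert all("-" in rp for rp in recs.roi_pair)
        # 3 cross-ROI pairs, 2x2 channel pairs each
        assert (recs.n_channel_pairs == 4).all()
        assert not any(
            a == b for a, b in (rp.split("-", 1) for rp in recs.roi_pair)
        )

    def test_condition_blocks_partition_time(self, small_layout):
        ha, hb = _hemo_pair(small_layout, {}, seed=4, duration=240.0)
        blocks = (
            ConditionBlock("FM", 0.0, 120.0),
            ConditionBlock("IS", 120.0, 120.0),
        )
        recs = records_to_frame(
            roi_pair_coupling(ha, small_layout, hb, small_layout,
                              scope="between", blocks=blocks, unit_id="d1")
        )
        assert set(recs.condition) == {"FM", "IS"}

    def test_excluded_roi_dropped_with_warning(self, small_layout):
        ha, hb = _hemo_pair(small_layout, {}, seed=5)
        ha.qc[0] = ha.qc[1] = "no_heartbeat"  # kill L.IFG on A
        with pytest.warns(UserWarning, match="no usable channel pairs"):
            recs = records_to_frame(
                roi_pair_coupling(ha, small_layout, hb, small_layout,
                                  scope="between", unit_id="d1")
            )
        assert "L.IFG-L.IFG" not in set(recs.roi_pair)


class TestPseudoCoupling:
    def _dyads(self, small_layout, n=3):
        out = []
        for d in range(n):
            ha, hb = _hemo_pair(small_layout, {("ch1", "ch1"): 0.8},
                                seed=100 + d, duration=60.0)
            out.append((f"d{d}", (ha, small_layout), (hb, small_layout)))
        return out

    def test_counts_match_real(self, small_layout):
        dyads = self._dyads(small_layout)
        pseudo = pseudo_coupling(dyads, seed=1)
        real = []
        for did, (ha, la), (hb, lb) in dyads:
            real += roi_pair_coupling(ha, la, hb, lb, scope="between",
                                      unit_id=did)
        pf, rf = records_to_frame(pseudo), records_to_frame(real)
        assert set(pf.group) == {"pseudo"}
        counts_p = pf.groupby(["roi_pair", "condition"]).size()
        counts_r = rf.groupby(["roi_pair", "condition"]).size()
        assert counts_p.equals(counts_r)

    def test_seed_deterministic(self, small_layout):
        dyads = self._dyads(small_layout, n=3)
        p1 = records_to_frame(pseudo_coupling(dyads, seed=9))
        p2 = records_to_frame(pseudo_coupling(dyads, seed=9))
        assert p1.equals(p2)
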