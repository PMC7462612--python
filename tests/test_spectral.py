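"""Welch spectra, beta-baseline interpolation, STA of the LFP, shift predictor."""

import numpy as np
import pytest

from mersuite.metrics import SpikeTrain
from mersuite.sorting import RecordingSegment
from mersuite.spectral import (
    PSDEstimate,
    STAResult,
    beta_power,
    lfp_psd,
    mua_psd,
    shift_predictor,
    sta_lfp,
    sta_psd,
    znorm,
)
from mersuite.synth import (
    LockingParams,
    UnitSpec,
    gen_spike_train,
    lock_spikes_to_lfp,
    render_extracellular,
    synth_lfp,
)

FS_LFP = 1375.0


def narrowband_lfp(duration, fs, freq, seed, amp=1.0, noise_exponent=1.0):
    """1/f background plus a finite-coherence (filtered-noise) oscillation.

    A narrowband oscillation, unlike a pure tone, loses phase coherence over a
    few cycles, so the STA of locked spikes decays away from lag 0 and has a
    unique global maximum there.
    """
    from scipy import signal as sps

    rng = np.random.default_rng(seed)
    x = synth_lfp(duration, fs, [], noise_exponent, rng)
    sos = sps.butter(2, [freq - 2.0, freq + 2.0], btype="bandpass", fs=fs,
                     output="sos")
    nb = sps.sosfiltfilt(sos, rng.standard_normal(x.size))
    return x + amp * nb / nb.std()


@pytest.fixture(scope="module")
def locked_fixture():
    """100 s LFP with a narrowband 20 Hz oscillation and strongly locked spikes."""
    lfp = narrowband_lfp(100.0, FS_LFP, 20.0, seed=21)
    spikes = lock_spikes_to_lfp(lfp, FS_LFP, 8.0, 5.0, 0.0, seed=22, freq=20.0)
    return RecordingSegment(lfp, FS_LFP, "LFP"), SpikeTrain(spikes, 100.0)


class TestZnorm:
    def test_normalizes(self, rng):
        x = znorm(5.0 + 2.0 * rng.standard_normal(10_000))
        assert abs(x.mean()) < 1e-12
        assert x.std() == pytest.approx(1.0)

    def test_idempotent_and_affine_invariant(self, rng):
        x = rng.standard_normal(1000)
        z = znorm(x)
        np.testing.assert_allclose(znorm(z), z, atol=1e-12)
        np.testing.assert_allclose(znorm(3.2 * x - 7.0), z, atol=1e-10)

    def test_constant_rejected(self):
        with pytest.raises(ValueError):
            znorm(np.ones(100))


class TestMuaPsd:
    def test_envelope_modulation_detected(self):
        # spiking locked to a 20 Hz rhythm -> rectified-MUA PSD peak at 20 Hz
        units = [UnitSpec(rate=40.0, peak_amp=1.0,
                          locking=LockingParams(20.0, 5.0, 0.0))]
        rec = render_extracellular(units, 30.0, 20_000.0, noise_sd=0.1, seed=4,
                                   lfp_components=[(20.0, 1.0)])
        psd = mua_psd(RecordingSegment(rec.mua_signal, rec.fs_mua, "MUA"))
        bp = beta_power(psd)
        i20 = int(np.argmin(np.abs(psd.freqs - 20.0)))
        assert psd.power[i20] > psd.power[i20 - 3]
        assert psd.power[i20] > psd.power[i20 + 3]
        assert bp.excess > 0

    def test_rectification_is_necessary(self):
        # without the absolute-value step the envelope stays invisible
        units = [UnitSpec(rate=40.0, peak_amp=1.0,
                          locking=LockingParams(20.0, 5.0, 0.0))]
        rec = render_extracellular(units, 30.0, 20_000.0, noise_sd=0.1, seed=5,
                                   lfp_components=[(20.0, 1.0)])
        seg = RecordingSegment(rec.mua_signal, rec.fs_mua, "MUA")
        rect = mua_psd(seg)
        from mersuite.spectral import _welch_1hz
        f, p_raw, _ = _welch_1hz(znorm(seg.samples), seg.fs)
        raw = PSDEstimate(f, p_raw, "MUA", 1)
        assert beta_power(rect).excess > 10 * abs(beta_power(raw).excess)

    def test_unmodulated_null_no_beta_excess(self):
        excesses = []
        for s in range(20):
            rec = render_extracellular([UnitSpec(rate=30.0)], 20.0, 20_000.0,
                                       noise_sd=0.1, seed=400 + s)
            psd = mua_psd(RecordingSegment(rec.mua_signal, rec.fs_mua, "MUA"))
            excesses.append(beta_power(psd).excess)
        m = np.mean(excesses)
        se = np.std(excesses, ddof=1) / np.sqrt(len(excesses))
        assert abs(m) < 2 * se + 1e-12

    def test_wrong_kind_rejected(self):
        with pytest.raises(ValueError):
            mua_psd(RecordingSegment(np.random.default_rng(0).standard_normal(5000),
                                     1375.0, "LFP"))


class TestBetaPower:
    def _psd(self, power):
        freqs = np.arange(0.0, 51.0)
        return PSDEstimate(freqs, np.asarray(power, float), "LFP", 1)

    def test_flat_psd_zero_excess(self):
        bp = beta_power(self._psd(np.full(51, 3.7)))
        assert bp.observed == pytest.approx(3.7)
        assert bp.baseline == pytest.approx(3.7)
        assert bp.excess == pytest.approx(0.0)

    def test_triangular_bump_arithmetic(self):
        # symmetric triangle over 13..30 peaking +1 at 21.5 Hz on a flat PSD of 1
        freqs = np.arange(0.0, 51.0)
        bump = np.clip(1.0 - np.abs(freqs - 21.5) / 8.5, 0.0, None)
        bp = beta_power(self._psd(1.0 + bump))
        in_band = (freqs >= 13) & (freqs <= 30)
        assert bp.baseline == pytest.approx(1.0)
        assert bp.observed == pytest.approx(1.0 + bump[in_band].mean())

    def test_out_of_band_bump_ignored(self):
        freqs = np.arange(0.0, 51.0)
        bump = np.clip(1.0 - np.abs(freqs - 40.0) / 4.0, 0.0, None)
        bp = beta_power(self._psd(1.0 + bump))
        assert bp.excess == pytest.approx(0.0)

    def test_missing_flank_rejected(self):
        psd = PSDEstimate(np.arange(14.0, 29.0), np.ones(15), "LFP", 1)
        with pytest.raises(ValueError):
            beta_power(psd)


class TestLfpPsd:
    def test_tone_peak_bin(self):
        x = synth_lfp(60.0, FS_LFP, [(21.0, 2.0)], seed=0)
        psd = lfp_psd(RecordingSegment(x, FS_LFP, "LFP"))
        assert psd.freqs[np.argmax(psd.power)] == pytest.approx(21.0)

    def test_white_noise_flat(self, rng):
        x = rng.standard_normal(int(120 * FS_LFP))
        psd = lfp_psd(RecordingSegment(x, FS_LFP, "LFP"))
        sel = (psd.freqs > 5) & (psd.freqs < 600)
        slope = np.polyfit(psd.freqs[sel], np.log(psd.power[sel]), 1)[0]
        assert abs(slope) < 1e-3

    def test_parseval(self, rng):
        x = rng.standard_normal(int(60 * FS_LFP))
        psd = lfp_psd(RecordingSegment(x, FS_LFP, "LFP"))
        total = np.sum(psd.power) * 1.0  # df = 1 Hz; one-sided spectrum
        assert total == pytest.approx(1.0, rel=0.02)


class TestSta:
    def test_locked_sta_peaks_at_zero_lag(self, locked_fixture):
        lseg, train = locked_fixture
        sta = sta_lfp(train, lseg, (13.0, 30.0))
        assert sta.lags[np.argmax(sta.average)] == pytest.approx(0.0, abs=1e-12)
        # the STA oscillates at ~20 Hz: next peak ~50 ms away
        i0 = int(np.argmax(sta.average))
        period = np.argmax(sta.average[i0 + 10 : i0 + 90]) + 10
        assert 0.040 < period / FS_LFP < 0.060

    def test_independent_spikes_average_out(self):
        lfp = synth_lfp(100.0, FS_LFP, [(20.0, 1.0)], seed=31)
        lseg = RecordingSegment(lfp, FS_LFP, "LFP")
        spikes = gen_spike_train(UnitSpec(rate=8.0), 100.0, seed=32)
        sta = sta_lfp(SpikeTrain(spikes, 100.0), lseg, (13.0, 30.0))
        band_sd = 1.0  # z-normed LFP has SD 1; band-passed less
        assert np.max(np.abs(sta.average)) < 3.5 / np.sqrt(sta.n_spikes) * band_sd

    def test_zero_lfp_zero_curve(self):
        lseg = RecordingSegment(np.zeros(int(10 * FS_LFP)), FS_LFP, "LFP")
        train = SpikeTrain(np.linspace(1, 9, 20), 10.0)
        sta = sta_lfp(train, lseg, (13.0, 30.0))
        np.testing.assert_array_equal(sta.average, 0.0)

    def test_edge_spikes_dropped_and_counted(self, locked_fixture):
        lseg, train = locked_fixture
        t = np.sort(np.concatenate([[0.1], train.timestamps, [99.95]]))
        sta = sta_lfp(SpikeTrain(t, 100.0), lseg, (13.0, 30.0))
        expected = int(np.sum((t < 0.5) | (t > 99.5)))
        assert sta.n_dropped == expected >= 2


class TestShiftPredictor:
    def test_destroys_locking(self, locked_fixture):
        lseg, train = locked_fixture
        assert train.n_spikes >= 500
        sta = sta_lfp(train, lseg, (13.0, 30.0))
        pred = shift_predictor(train, lseg, (13.0, 30.0), seed=7)
        assert np.max(np.abs(pred.average)) < 0.2 * np.max(np.abs(sta.average))

    def test_null_case_predictor_matches_sta(self):
        lfp = synth_lfp(100.0, FS_LFP, [(20.0, 1.0)], seed=41)
        lseg = RecordingSegment(lfp, FS_LFP, "LFP")
        spikes = gen_spike_train(UnitSpec(rate=10.0), 100.0, seed=42)
        train = SpikeTrain(spikes, 100.0)
        sta = sta_lfp(train, lseg, (13.0, 30.0))
        pred = shift_predictor(train, lseg, (13.0, 30.0), seed=43)
        bound = 5.0 / np.sqrt(train.n_spikes)
        assert np.max(np.abs(sta.average)) < bound
        assert np.max(np.abs(pred.average)) < bound

    def test_reproducible(self, locked_fixture):
        lseg, train = locked_fixture
        a = shift_predictor(train, lseg, (13.0, 30.0), seed=9)
        b = shift_predictor(train, lseg, (13.0, 30.0), seed=9)
        np.testing.assert_array_equal(a.average, b.average)


class TestStaPsd:
    def test_locked_beta_dominates_predictor(self, locked_fixture):
        lseg, train = locked_fixture
        sta = sta_lfp(train, lseg, (13.0, 30.0))
        pred = shift_predictor(train, lseg, (13.0, 30.0), seed=11)
        b_sta = beta_power(sta_psd(sta, FS_LFP)).observed
        b_pred = beta_power(sta_psd(pred, FS_LFP)).observed
        assert b_sta > 20 * b_pred

    def test_pure_sine_concentrated(self):
        lags = np.arange(-688, 689) / FS_LFP
        curve = np.sin(2 * np.pi * 20.0 * lags)
        sta = STAResult(lags, curve, (13.0, 30.0), 100)
        psd = sta_psd(sta, FS_LFP)
        assert psd.freqs[np.argmax(psd.power)] == pytest.approx(20.0)
        # all power inside the taper mainlobe around 20 Hz
        away = np.abs(psd.freqs - 20.0) > 2.0
        assert psd.power[away].max() < 1e-3 * psd.power.max()
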