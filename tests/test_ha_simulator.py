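import numpy as np
import pytest

from oprars.audio import CalibratedSignal, band_limit
from oprars.gain_constraints import HAConfiguration
from oprars.ha_simulator import (CompressorParams, UndersampledError, amplify,
                                 compress_channel, filterbank_split,
                                 static_gain_db)
from oprars.prescription import ChannelBank, Prescription

FS = 16000


def _tone(freq, level_db_spl, dur=1.0, fs=FS):
    t = np.arange(int(dur * fs)) / fs
    x = np.sin(2 * np.pi * freq * t)
    return CalibratedSignal(x, fs).scaled_to(level_db_spl)


def _settled_level(sig, skip=0.5):
    n = int(skip * sig.sample_rate_hz)
    tail = CalibratedSignal(sig.samples[n:], sig.sample_rate_hz,
                            sig.full_scale_db_spl)
    return tail.level_db_spl()


class TestFilterbank:
    def test_tone_lands_in_its_channel(self, bank):
        tone = _tone(1000.0, 65.0)
        chans = filterbank_split(tone, bank)
        energies = [np.sum(c.samples**2) for c in chans]
        assert energies[1] / sum(energies) >= 0.95

    def test_reconstruction_of_white_noise(self, bank):
        rng = np.random.default_rng(0)
        x = CalibratedSignal(rng.standard_normal(FS), FS)
        ref = band_limit(x.samples, FS, 100.0, 8000.0)
        total = sum(c.samples for c in filterbank_split(x, bank))
        resid = np.sum((total - ref)**2)
        assert 10 * np.log10(resid / np.sum(ref**2)) <= -30.0

    def test_silence(self, bank):
        chans = filterbank_split(CalibratedSignal(np.zeros(FS), FS), bank)
        assert all(np.allclose(c.samples, 0.0) for c in chans)

    def test_low_sample_rate_rejected(self, bank):
        with pytest.raises(UndersampledError):
            filterbank_split(CalibratedSignal(np.zeros(8000), 8000), bank)


class TestCompressor:
    def test_below_threshold_applies_linear_gain(self):
        p = CompressorParams(ct_db_spl=60.0, cr=3.0, gain_db=20.0,
                             attack_ms=50, release_ms=200)
        out = compress_channel(_tone(1000, 50.0, dur=2.0), p)
        assert _settled_level(out, 1.0) == pytest.approx(70.0, abs=0.5)

    def test_above_threshold_follows_ratio(self):
        p = CompressorParams(ct_db_spl=50.0, cr=2.0, gain_db=20.0,
                             attack_ms=50, release_ms=200)
        out = compress_channel(_tone(1000, 70.0, dur=2.0), p)
        # ct + gain + (in - ct)/cr = 50 + 20 + 10
        assert _settled_level(out, 1.0) == pytest.approx(80.0, abs=0.5)

    def test_unity_ratio_is_pure_gain(self):
        p = CompressorParams(ct_db_spl=40.0, cr=1.0, gain_db=12.0,
                             attack_ms=50, release_ms=200)
        for lvl in (30.0, 55.0, 80.0):
            out = compress_channel(_tone(500, lvl, dur=1.0), p)
            assert _settled_level(out) == pytest.approx(lvl + 12.0, abs=0.5)

    def test_static_curve_continuous_at_threshold(self):
        p = CompressorParams(ct_db_spl=45.0, cr=8.0, gain_db=15.0)
        below = static_gain_db(45.0 - 1e-9, p)
        above = static_gain_db(45.0 + 1e-9, p)
        assert abs(below - above) < 0.1

    def test_monotone_output_level(self):
        p = CompressorParams(ct_db_spl=40.0, cr=5.0, gain_db=25.0,
                             attack_ms=20, release_ms=100)
        levels = [_settled_level(compress_channel(_tone(1000, lv, dur=1.0), p))
                  for lv in np.arange(20.0, 95.0, 5.0)]
        assert np.all(np.diff(levels) >= -1e-6)


def _config(ig65, ig85, ct=35.0):
    p = Prescription(ig_sp65=np.full(11, float(ig65)),
                     ig_sp85=np.full(11, float(ig85)),
                     ct_db_spl=np.full(5, float(ct)))
    return HAConfiguration(np.full(5, float(ct)), np.zeros(5), resolved=p)


class TestAmplify:
    def test_transparent_configuration(self, bank):
        rng = np.random.default_rng(2)
        x = CalibratedSignal(rng.standard_normal(FS), FS).scaled_to(65.0)
        ref = band_limit(x.samples, FS, 100.0, 8000.0)
        ref_level = CalibratedSignal(ref, FS).level_db_spl()
        out = amplify(x, _config(0.0, 0.0), bank)
        assert out.level_db_spl() == pytest.approx(ref_level, abs=1.0)

    def test_flat_linear_gain_on_speech_noise(self, bank):
        rng = np.random.default_rng(3)
        x = CalibratedSignal(rng.standard_normal(2 * FS), FS)
        x = CalibratedSignal(band_limit(x.samples, FS, 100, 8000), FS).scaled_to(65.0)
        out = amplify(x, _config(20.0, 20.0), bank)  # CR = 1
        assert out.level_db_spl() == pytest.approx(85.0, abs=1.0)

    def test_compression_slope_between_65_and_85(self, bank):
        # modest gains keep the output clear of the 100-dB limiter
        cfg = _config(10.0, 0.0, ct=30.0)  # CR = 2 everywhere
        rng = np.random.default_rng(4)
        base = band_limit(rng.standard_normal(2 * FS), FS, 100, 8000)
        lo = amplify(CalibratedSignal(base, FS).scaled_to(65.0), cfg, bank)
        hi = amplify(CalibratedSignal(base, FS).scaled_to(85.0), cfg, bank)
        growth = _settled_level(hi) - _settled_level(lo)
        assert growth == pytest.approx(10.0, abs=1.0)

    def test_linear_configs_superpose(self, bank):
        """With CR=1 and the limiter out of reach, amplification is linear."""
        cfg = _config(10.0, 10.0)
        rng = np.random.default_rng(5)
        a = CalibratedSignal(rng.standard_normal(FS), FS).scaled_to(60.0)
        b = CalibratedSignal(np.sin(2 * np.pi * 700 * np.arange(FS) / FS),
                             FS).scaled_to(60.0)
        ya = amplify(a, cfg, bank).samples
        yb = amplify(b, cfg, bank).samples
        yab = amplify(CalibratedSignal(a.samples + b.samples, FS), cfg, bank).samples
        assert np.allclose(yab, ya + yb, atol=1e-6 * np.max(np.abs(ya + yb)))

    def test_unresolved_config_rejected(self, bank):
        with pytest.raises(ValueError):
            amplify(_tone(1000, 65.0), HAConfiguration(), bank)

    def test_infeasible_cr_rejected(self, bank):
        cfg = _config(30.0, 0.0)  # denominator -10: CR out of range
        with pytest.raises(ValueError):
            amplify(_tone(1000, 65.0, dur=0.2), cfg, bank)
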