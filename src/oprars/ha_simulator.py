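"""Five-channel hearing-aid simulator.

Each channel runs two dynamic-range compressors in series: a slow main
compressor realizing the prescribed gain/CR, and a fast output limiter.
The band split uses zero-phase brick-wall masks at the channel edges, so
the recombined channels reconstruct the band-limited input exactly; the
level detectors smooth signal power with separate attack/release time
constants (see :mod:`oprars.audio`).

Static behaviour of one compressor (input level L, threshold CT, ratio
CR, linear gain G, all dB):

    out = L + G                      for L <= CT
    out = CT + G + (L - CT) / CR     for L >  CT

The main compressor's gain is anchored so that 65-dB-SPL input receives
exactly the prescribed IGSP65; its CR comes from the two-level gains at
the channel center frequency and is guaranteed in [1, 10] by the
constraint pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .audio import CalibratedSignal, band_split, envelope_db
from .gain_constraints import HAConfiguration, compression_ratio
from .prescription import ChannelBank, channel_center_frequency

#: slow main-compressor time constants per channel (ms)
ATTACK_MS = (200.0, 100.0, 100.0, 100.0, 100.0)
RELEASE_MS = (2000.0, 1500.0, 1200.0, 1000.0, 1000.0)

#: conventional output-limiter defaults (configurable)
LIMITER_CT_DB_SPL = 100.0
LIMITER_CR = 10.0
LIMITER_ATTACK_MS = 5.0
LIMITER_RELEASE_MS = 50.0

OPERATING_LEVEL_DB_SPL = 65.0
MIN_SAMPLE_RATE_HZ = 16000


class UndersampledError(ValueError):
    """Sample rate too low for the 5.6–8 kHz channel."""


@dataclass
class CompressorParams:
    """Static curve and detector ballistics of one compressor."""

    ct_db_spl: float
    cr: float
    gain_db: float = 0.0
    attack_ms: float = 100.0
    release_ms: float = 1000.0

    def __post_init__(self) -> None:
        if self.cr < 1.0:
            raise ValueError("compression ratio must be >= 1")
        if self.attack_ms <= 0 or self.release_ms <= 0:
            raise ValueError("time constants must be positive")


def static_gain_db(level_db_spl, p: CompressorParams):
    """Gain (dB) applied at a given detected level, per the static curve."""
    level = np.asarray(level_db_spl, dtype=float)
    over = np.maximum(level - p.ct_db_spl, 0.0)
    return p.gain_db - over * (1.0 - 1.0 / p.cr)


def _check_rate(x: CalibratedSignal) -> None:
    if x.sample_rate_hz < MIN_SAMPLE_RATE_HZ:
        raise UndersampledError(
            f"sample rate {x.sample_rate_hz} Hz < {MIN_SAMPLE_RATE_HZ} Hz")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def filterbank_split(x: CalibratedSignal, bank: ChannelBank) -> list[CalibratedSignal]:
    """Split into the bank's 5 channels (zero-phase, exactly complementary)."""
    _check_rate(x)
    bands = band_split(x.samples, x.sample_rate_hz, bank.edges_hz)
    return [replace(x, samples=b) for b in bands]


def compress_channel(x: CalibratedSignal, p: CompressorParams) -> CalibratedSignal:
    """Apply one dynamic-range compressor to a channel signal."""
    level = envelope_db(x.samples, x.sample_rate_hz, p.attack_ms, p.release_ms,
                        x.full_scale_db_spl)
    gain = static_gain_db(level, p)
    return replace(x, samples=x.samples * 10.0 ** (gain / 20.0))


def channel_compressors(config: HAConfiguration, bank: ChannelBank,
                        limiter: CompressorParams | None = None
                        ) -> list[tuple[CompressorParams, CompressorParams]]:
    """Main-compressor/limiter pair per channel for a resolved configuration.

    CR per channel comes from the resolved IGSP65/IGSP85 at the channel
    center; the below-threshold gain is set so the 65-dB operating point
    receives IGSP65: G = IG65 + max(0, 65 − CT)·(1 − 1/CR).
    """
    if config.resolved is None:
        raise ValueError("configuration must be resolved (run the constraint pipeline)")
    pairs = []
    for ch in range(1, bank.n_channels + 1):
        fc = channel_center_frequency(bank, ch)
        ig65 = config.resolved.gain_at(fc, 65)
        ig85 = config.resolved.gain_at(fc, 85)
        cr = compression_ratio(ig65, ig85)
        if not (1.0 - 1e-6 <= cr <= bank.max_cr + 1e-6):
            raise ValueError(
                f"channel {ch}: CR {cr:.3g} outside [1, {bank.max_cr}]; "
                "enforce_cr_bounds was not applied")
        cr = float(np.clip(cr, 1.0, bank.max_cr))
        ct = float(config.ct_db_spl[ch - 1])
        gain = ig65 + max(0.0, OPERATING_LEVEL_DB_SPL - ct) * (1.0 - 1.0 / cr)
        main = CompressorParams(ct, cr, gain, ATTACK_MS[ch - 1], RELEASE_MS[ch - 1])
        lim = limiter if limiter is not None else CompressorParams(
            LIMITER_CT_DB_SPL, LIMITER_CR, 0.0, LIMITER_ATTACK_MS, LIMITER_RELEASE_MS)
        pairs.append((main, lim))
    return pairs


def amplify(x: CalibratedSignal, config: HAConfiguration, bank: ChannelBank,
            limiter: CompressorParams | None = None) -> CalibratedSignal:
    """Amplify a calibrated signal with a resolved configuration.

    Band-split → per-channel main compressor then limiter → sum.  The
    output keeps the input calibration.
    """
    _check_rate(x)
    channels = filterbank_split(x, bank)
    pairs = channel_compressors(config, bank, limiter)
    out = np.zeros_like(x.samples)
    for sig, (main, lim) in zip(channels, pairs):
        y = compress_channel(sig, main)
        y = compress_channel(y, lim)
        out += y.samples
    return replace(x, samples=out)


def transparent_configuration(bank: ChannelBank) -> HAConfiguration:
    """Zero-gain linear setting (useful as a null reference)."""
    from .prescription import Prescription
    p = Prescription()  # zero gains, default CTs
    cfg = HAConfiguration(resolved=p)
    return cfg
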