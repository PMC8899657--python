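"""Speech Intelligibility Index from band-audibility, ANSI S3.5 style.

The index is an importance-weighted sum of per-band audibilities, where a
band's audibility grows linearly from 0 to 1 as the speech level rises
from 15 dB below to 15 dB above the listener's effective threshold in
that band.  Masking spread and high-level distortion factors are not
modelled: the package targets speech in quiet at a single presentation
level, where audibility dominates.

Two band schemes ship as packaged tables: the 6 octave bands 250–8000 Hz
(default, matching audiogram granularity) and 18 third-octave bands
160–8000 Hz.  Importance weights sum to 1 in each scheme; hearing levels
(dB HL) are converted to band sound pressure levels with tabulated
reference-equivalent threshold offsets.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd

from .audio import CalibratedSignal
from .audiograms import Audiogram


@lru_cache(maxsize=None)
def _load_table(name: str) -> pd.DataFrame:
    with importlib.resources.files("oprars.data").joinpath(name).open() as fh:
        return pd.read_csv(fh)


def band_centers(scheme: str = "octave") -> np.ndarray:
    return _band_table(scheme)["center_hz"].to_numpy(float)


def band_importance(scheme: str = "octave") -> np.ndarray:
    return _band_table(scheme)["importance"].to_numpy(float)


def _band_table(scheme: str) -> pd.DataFrame:
    if scheme == "octave":
        return _load_table("octave_bands.csv")
    if scheme == "third-octave":
        return _load_table("third_octave_bands.csv")
    raise ValueError(f"unknown band scheme: {scheme!r}")


def retspl_db(centers_hz) -> np.ndarray:
    """dB HL → dB SPL conversion offsets, interpolated on log2 frequency."""
    tab = _load_table("octave_bands.csv")
    return np.interp(np.log2(np.asarray(centers_hz, float)),
                     np.log2(tab["center_hz"].to_numpy(float)),
                     tab["retspl_db"].to_numpy(float))


@dataclass
class BandSpectrum:
    """Per-band levels (dB SPL) under a named band scheme."""

    band_center_hz: np.ndarray
    level_db_spl: np.ndarray
    scheme: str = "octave"

    def __post_init__(self) -> None:
        self.band_center_hz = np.asarray(self.band_center_hz, dtype=float)
        self.level_db_spl = np.asarray(self.level_db_spl, dtype=float)
        if self.band_center_hz.shape != self.level_db_spl.shape:
            raise ValueError("band centers and levels must align")
        if np.any(np.isnan(self.level_db_spl)):
            raise ValueError("band levels must not be NaN")

    def shifted(self, offset_db: float) -> "BandSpectrum":
        return BandSpectrum(self.band_center_hz, self.level_db_spl + offset_db,
                            self.scheme)


def _check_compatible(a: BandSpectrum, b: BandSpectrum) -> None:
    if a.scheme != b.scheme or a.band_center_hz.shape != b.band_center_hz.shape \
            or not np.allclose(a.band_center_hz, b.band_center_hz):
        raise ValueError("incompatible band schemes")


# ---------------------------------------------------------------------------
# Core index
# ---------------------------------------------------------------------------

def band_audibility(speech: BandSpectrum, threshold: BandSpectrum) -> np.ndarray:
    """Per-band audibility: clip((speech − threshold + 15) / 30, 0, 1)."""
    _check_compatible(speech, threshold)
    # -inf speech (silence) is legitimately fully inaudible
    with np.errstate(invalid="ignore"):
        a = (speech.level_db_spl - threshold.level_db_spl + 15.0) / 30.0
    return np.clip(np.nan_to_num(a, nan=0.0, neginf=0.0, posinf=1.0), 0.0, 1.0)


def threshold_spectrum(a: Audiogram, scheme: str = "octave") -> BandSpectrum:
    """Audiogram converted to effective band thresholds in dB SPL."""
    centers = band_centers(scheme)
    hl = a.interpolated_at(centers)
    return BandSpectrum(centers, hl + retspl_db(centers), scheme)


def sii_value(speech: BandSpectrum, a: Audiogram) -> float:
    """Importance-weighted audibility in [0, 1]."""
    disturbance = threshold_spectrum(a, speech.scheme)
    aud = band_audibility(speech, disturbance)
    w = band_importance(speech.scheme)
    return float(np.dot(w / w.sum(), aud))


# ---------------------------------------------------------------------------
# Spectra from calibrated signals
# ---------------------------------------------------------------------------

def spectrum_of_signal(x: CalibratedSignal, scheme: str = "octave") -> BandSpectrum:
    """Long-term RMS band levels (dB SPL) of a calibrated waveform.

    Band powers are accumulated from the magnitude spectrum (Parseval),
    with band edges a factor of 2^(1/2) (octave) or 2^(1/6) (third-octave)
    around each center.  Digital silence yields −inf levels.
    """
    if x.samples.size == 0:
        raise ValueError("empty signal")
    centers = band_centers(scheme)
    half_width = 2.0 ** (0.5 if scheme == "octave" else 1.0 / 6.0)
    n = x.samples.size
    spec = np.fft.rfft(x.samples)
    freqs = np.fft.rfftfreq(n, 1.0 / x.sample_rate_hz)
    # mean-square contribution of each bin (one-sided spectrum)
    psd = np.abs(spec) ** 2 / n**2
    if n % 2 == 0:
        psd[1:-1] *= 2.0
    else:
        psd[1:] *= 2.0
    levels = np.empty(centers.size)
    for i, c in enumerate(centers):
        lo, hi = c / half_width, c * half_width
        p = psd[(freqs >= lo) & (freqs < hi)].sum()
        levels[i] = (x.full_scale_db_spl + 10.0 * np.log10(p)) if p > 0 else -np.inf
    return BandSpectrum(centers, levels, scheme)


def amplified_speech_spectrum(base: BandSpectrum, prescription,
                              level: int = 65) -> BandSpectrum:
    """Speech spectrum with a prescription's insertion gains applied.

    Gains are the prescription's IG values interpolated (log2-frequency)
    at the band centers — the quasi-static spectral image of amplifying
    65-dB-SPL speech, used by the SII-equalization loop.
    """
    g = prescription.ig_sp65 if level == 65 else prescription.ig_sp85
    gains = np.interp(np.log2(base.band_center_hz),
                      np.log2(prescription.frequencies_hz), g)
    return BandSpectrum(base.band_center_hz, base.level_db_spl + gains, base.scheme)
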