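"""Calibrated audio containers and shared signal primitives.

All levels in the package are referred to a fixed digital full-scale
calibration: a signal with unit RMS is defined to be at
``FULL_SCALE_DB_SPL`` (100 dB SPL by default).  Everything downstream —
compression thresholds, SII band levels, recruitment ceilings — is
expressed on this common dB SPL scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.io import wavfile

FULL_SCALE_DB_SPL = 100.0

#: floor used when converting (possibly zero) powers to dB
_POWER_FLOOR = 1e-20


@dataclass
class CalibratedSignal:
    """A mono waveform with a dB SPL calibration attached.

    Parameters
    ----------
    samples : ndarray
        Mono float samples.
    sample_rate_hz : int
        Sampling rate; processing stages covering the 5.6–8 kHz channel
        require at least 16 kHz.
    full_scale_db_spl : float
        Sound pressure level of a unit-RMS signal.
    """

    samples: np.ndarray
    sample_rate_hz: int
    full_scale_db_spl: float = FULL_SCALE_DB_SPL

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("CalibratedSignal is mono: expected a 1-D array")
        if not np.isfinite(self.full_scale_db_spl):
            raise ValueError("full-scale reference must be finite")

    # -- levels ----------------------------------------------------------
    def rms(self) -> float:
        if self.samples.size == 0:
            return 0.0
        return float(np.sqrt(np.mean(np.square(self.samples))))

    def level_db_spl(self) -> float:
        """Long-term RMS level in dB SPL (−inf for digital silence)."""
        r = self.rms()
        if r <= 0.0:
            return -np.inf
        return self.full_scale_db_spl + 20.0 * np.log10(r)

    def scaled_to(self, level_db_spl: float) -> "CalibratedSignal":
        """Return a copy rescaled to the requested long-term level."""
        current = self.level_db_spl()
        if not np.isfinite(current):
            raise ValueError("cannot rescale a silent signal")
        g = 10.0 ** ((level_db_spl - current) / 20.0)
        return replace(self, samples=self.samples * g)

    def copy(self) -> "CalibratedSignal":
        return replace(self, samples=self.samples.copy())


# ---------------------------------------------------------------------------
# WAV I/O (16-bit PCM or float); calibration is a package convention, the
# file itself carries none.
# ---------------------------------------------------------------------------

def read_wav(path, full_scale_db_spl: float = FULL_SCALE_DB_SPL) -> CalibratedSignal:
    fs, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim == 2:  # take first channel of multichannel files
        data = data[:, 0]
    if data.dtype == np.int16:
        x = data.astype(float) / 32768.0
    elif data.dtype == np.int32:
        x = data.astype(float) / 2147483648.0
    elif data.dtype == np.uint8:
        x = (data.astype(float) - 128.0) / 128.0
    else:
        x = data.astype(float)
    return CalibratedSignal(x, int(fs), full_scale_db_spl)


def write_wav(path, signal: CalibratedSignal, subtype: str = "float") -> None:
    if subtype == "int16":
        peak = np.max(np.abs(signal.samples)) if signal.samples.size else 0.0
        if peak > 1.0:
            raise ValueError("samples exceed full scale; rescale before 16-bit export")
        wavfile.write(path, signal.sample_rate_hz,
                      (signal.samples * 32767.0).astype(np.int16))
    else:
        wavfile.write(path, signal.sample_rate_hz,
                      signal.samples.astype(np.float32))


# ---------------------------------------------------------------------------
# Band splitting.  Zero-phase brick-wall masks in the frequency domain: the
# channels tile their passbands exactly, so the sum of channels equals the
# band-limited input to numerical precision.
# ---------------------------------------------------------------------------

def band_split(x: np.ndarray, fs: int, edges_hz) -> list[np.ndarray]:
    """Split ``x`` into ``len(edges)-1`` contiguous bands.

    Band b keeps frequency bins f with ``edges[b] <= f < edges[b+1]``;
    the final band is closed above.  Bins outside ``[edges[0], edges[-1]]``
    are discarded.
    """
    edges = np.asarray(edges_hz, dtype=float)
    if np.any(np.diff(edges) <= 0):
        raise ValueError("band edges must be strictly increasing")
    n = x.size
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    out = []
    for b in range(edges.size - 1):
        lo, hi = edges[b], edges[b + 1]
        if b == edges.size - 2:
            mask = (freqs >= lo) & (freqs <= hi)
        else:
            mask = (freqs >= lo) & (freqs < hi)
        out.append(np.fft.irfft(spec * mask, n))
    return out


def band_limit(x: np.ndarray, fs: int, lo_hz: float, hi_hz: float) -> np.ndarray:
    """Zero-phase brick-wall band-pass of ``x`` to [lo, hi] Hz."""
    n = x.size
    spec = np.fft.rfft(x)
    freqs = np.fft.rfftfreq(n, 1.0 / fs)
    mask = (freqs >= lo_hz) & (freqs <= hi_hz)
    return np.fft.irfft(spec * mask, n)


# ---------------------------------------------------------------------------
# Level detectors.
# ---------------------------------------------------------------------------

def smoothing_coeff(tau_ms: float, fs: int) -> float:
    """Per-sample update coefficient of a one-pole smoother."""
    if tau_ms <= 0:
        raise ValueError("time constant must be positive")
    return 1.0 - float(np.exp(-1000.0 / (tau_ms * fs)))


def envelope_db(x: np.ndarray, fs: int, attack_ms: float, release_ms: float,
                full_scale_db_spl: float = FULL_SCALE_DB_SPL) -> np.ndarray:
    """Smoothed level trajectory in dB SPL.

    The instantaneous power ``x**2`` is tracked by a one-pole smoother with
    separate attack (rising) and release (falling) time constants, then
    converted to dB.  For a steady tone the detector settles on the tone's
    RMS level, so static input/output curves are RMS-referred with no
    crest-factor correction.
    """
    ca = smoothing_coeff(attack_ms, fs)
    cr = smoothing_coeff(release_ms, fs)
    p = np.square(x)
    # short symmetric pre-smoothing removes the 2f ripple of narrowband
    # content, which would otherwise bias the asymmetric ballistics upward
    pre_ms = min(2.0, attack_ms, release_ms)
    c_pre = smoothing_coeff(pre_ms, fs)
    p = _smooth_power(p, c_pre, c_pre)
    if attack_ms != release_ms or attack_ms > pre_ms:
        p = _smooth_power(p, ca, cr)
    return full_scale_db_spl + 10.0 * np.log10(np.maximum(p, _POWER_FLOOR))


def _smooth_power(p_in: np.ndarray, coeff_attack: float, coeff_release: float) -> np.ndarray:
    from scipy.signal import lfilter

    if coeff_attack == coeff_release:
        # symmetric case reduces to a linear one-pole filter
        c = coeff_attack
        zi = np.array([(1.0 - c) * p_in[0]]) if p_in.size else np.zeros(1)
        y, _ = lfilter([c], [1.0, -(1.0 - c)], p_in, zi=zi)
        return y
    out = np.empty_like(p_in)
    state = p_in[0] if p_in.size else 0.0
    ca, cr = coeff_attack, coeff_release
    for i in range(p_in.size):
        v = p_in[i]
        c = ca if v > state else cr
        state += c * (v - state)
        out[i] = state
    return out


def frame_energies(x: np.ndarray, frame_len: int) -> np.ndarray:
    """Energy of consecutive non-overlapping frames (trailing rest dropped)."""
    n_frames = x.size // frame_len
    if n_frames == 0:
        raise ValueError("signal shorter than one frame")
    return np.square(x[: n_frames * frame_len]).reshape(n_frames, frame_len).sum(axis=1)
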