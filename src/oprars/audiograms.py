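"""Audiograms: representation, CSV I/O, completion, summary, synthesis.

An audiogram stores pure-tone hearing thresholds (dB HL) at the 11
audiometric frequencies used throughout the package.  Missing thresholds
are completed with a degree-3 least-squares polynomial fitted on a
log-frequency axis, and severity is summarized by the pure-tone average
over 0.5–4 kHz.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: the 11 audiometric frequencies (Hz) carried by every audiogram
AUDIOMETRIC_FREQUENCIES_HZ = (
    125.0, 250.0, 500.0, 750.0, 1000.0, 1500.0,
    2000.0, 3000.0, 4000.0, 6000.0, 8000.0,
)

#: frequencies entering the pure-tone average (Hz)
PTA_FREQUENCIES_HZ = (500.0, 750.0, 1000.0, 1500.0, 2000.0, 3000.0, 4000.0)

THRESHOLD_MIN_DB_HL = -10.0
THRESHOLD_MAX_DB_HL = 120.0


class IncompleteAudiogramError(ValueError):
    """Raised when an operation needs thresholds that are missing."""


@dataclass
class Audiogram:
    """Hearing thresholds in dB HL as a function of frequency.

    ``thresholds_db_hl`` may contain NaN for missing values.  Frequencies
    must be strictly increasing; present thresholds must be finite and lie
    in [−10, 120] dB HL.
    """

    frequencies_hz: np.ndarray = field(
        default_factory=lambda: np.array(AUDIOMETRIC_FREQUENCIES_HZ))
    thresholds_db_hl: np.ndarray = field(
        default_factory=lambda: np.zeros(len(AUDIOMETRIC_FREQUENCIES_HZ)))
    label: str = ""

    def __post_init__(self) -> None:
        self.frequencies_hz = np.asarray(self.frequencies_hz, dtype=float)
        self.thresholds_db_hl = np.asarray(self.thresholds_db_hl, dtype=float)
        if self.frequencies_hz.shape != self.thresholds_db_hl.shape:
            raise ValueError("frequencies and thresholds must align")
        if np.any(self.frequencies_hz <= 0):
            raise ValueError("frequencies must be positive")
        if np.any(np.diff(self.frequencies_hz) <= 0):
            raise ValueError("frequencies must be strictly increasing")
        present = self.thresholds_db_hl[~np.isnan(self.thresholds_db_hl)]
        if np.any(~np.isfinite(present)):
            raise ValueError("present thresholds must be finite")
        if np.any(present < THRESHOLD_MIN_DB_HL) or np.any(present > THRESHOLD_MAX_DB_HL):
            raise ValueError("thresholds outside [-10, 120] dB HL")

    # -- helpers ---------------------------------------------------------
    @property
    def present_mask(self) -> np.ndarray:
        return ~np.isnan(self.thresholds_db_hl)

    def is_complete(self) -> bool:
        return bool(self.present_mask.all())

    def threshold_at(self, frequency_hz: float) -> float:
        idx = np.nonzero(np.isclose(self.frequencies_hz, frequency_hz))[0]
        if idx.size == 0:
            raise KeyError(f"no threshold stored at {frequency_hz} Hz")
        return float(self.thresholds_db_hl[idx[0]])

    def interpolated_at(self, frequencies_hz) -> np.ndarray:
        """Thresholds linearly interpolated on a log2-frequency axis."""
        if not self.is_complete():
            raise IncompleteAudiogramError("interpolate_missing_thresholds first")
        return np.interp(np.log2(np.asarray(frequencies_hz, dtype=float)),
                         np.log2(self.frequencies_hz), self.thresholds_db_hl)

    # -- CSV -------------------------------------------------------------
    @classmethod
    def from_csv(cls, path, label: str = "") -> "Audiogram":
        df = pd.read_csv(path)
        if not {"frequency_hz", "threshold_db_hl"} <= set(df.columns):
            raise ValueError("audiogram CSV needs columns frequency_hz,threshold_db_hl")
        return cls(df["frequency_hz"].to_numpy(float),
                   df["threshold_db_hl"].to_numpy(float),
                   label=label or str(path))

    def to_csv(self, path) -> None:
        pd.DataFrame({"frequency_hz": self.frequencies_hz,
                      "threshold_db_hl": self.thresholds_db_hl}
                     ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------

def interpolate_missing_thresholds(a: Audiogram) -> Audiogram:
    """Fill missing thresholds with a cubic least-squares fit in log2(f).

    Present values are left untouched; filled values are clamped to the
    audiometric range [−10, 120] dB HL.  At least 4 present thresholds are
    required for the degree-3 fit to be determined.
    """
    mask = a.present_mask
    n_present = int(mask.sum())
    if n_present < 4:
        raise IncompleteAudiogramError(
            f"degree-3 fit needs >= 4 present thresholds, got {n_present}")
    if mask.all():
        return Audiogram(a.frequencies_hz.copy(), a.thresholds_db_hl.copy(), a.label)
    x = np.log2(a.frequencies_hz)
    coeffs = np.polynomial.polynomial.polyfit(x[mask], a.thresholds_db_hl[mask], 3)
    filled = a.thresholds_db_hl.copy()
    missing = ~mask
    fit = np.polynomial.polynomial.polyval(x[missing], coeffs)
    filled[missing] = np.clip(fit, THRESHOLD_MIN_DB_HL, THRESHOLD_MAX_DB_HL)
    return Audiogram(a.frequencies_hz.copy(), filled, a.label)


def pta(a: Audiogram) -> float:
    """Pure-tone average over 0.5, 0.75, 1, 1.5, 2, 3, and 4 kHz (dB HL)."""
    values = []
    for f in PTA_FREQUENCIES_HZ:
        idx = np.nonzero(np.isclose(a.frequencies_hz, f))[0]
        if idx.size == 0 or np.isnan(a.thresholds_db_hl[idx[0]]):
            raise IncompleteAudiogramError(f"PTA frequency {f} Hz missing")
        values.append(a.thresholds_db_hl[idx[0]])
    return float(np.mean(values))


# Base sloping-loss profiles by severity level (dB HL at the 11 audiometric
# frequencies).  Levels 4–7 index increasing severity of age-related loss:
# mild low-frequency thresholds with a monotonic high-frequency decline.
_SEVERITY_BASE = {
    4: np.array([15, 15, 20, 22, 25, 30, 35, 45, 55, 60, 65], float),
    5: np.array([20, 22, 28, 32, 35, 42, 48, 58, 66, 72, 76], float),
    6: np.array([28, 30, 36, 42, 48, 55, 62, 70, 78, 84, 88], float),
    7: np.array([38, 42, 50, 56, 62, 70, 78, 86, 92, 98, 102], float),
}


def synth_audiogram(severity: int, seed: int, jitter: float = 0.0) -> Audiogram:
    """Synthesize a sloping-loss audiogram for a severity level in 4..7.

    The deterministic part (``jitter=0``) is the severity's base profile
    with a seeded overall shift and slope scaling, and is non-decreasing
    across frequency.  ``jitter > 0`` adds independent per-frequency
    perturbations (dB standard deviation), producing the more erratic
    shapes of individual clinical audiograms.
    """
    if severity not in _SEVERITY_BASE:
        raise ValueError(f"severity must be one of 4..7, got {severity}")
    rng = np.random.default_rng(np.random.SeedSequence([severity, int(seed)]))
    base = _SEVERITY_BASE[severity]
    shift = rng.uniform(-4.0, 4.0)
    slope_scale = rng.uniform(0.9, 1.1)  # >= 0 keeps monotonicity
    thr = base[0] + (base - base[0]) * slope_scale + shift
    if jitter > 0:
        thr = thr + rng.normal(0.0, jitter, size=thr.size)
    thr = np.clip(np.round(thr, 1), THRESHOLD_MIN_DB_HL, 110.0)
    return Audiogram(np.array(AUDIOMETRIC_FREQUENCIES_HZ), thr,
                     label=f"synthetic-L{severity}-seed{seed}")
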