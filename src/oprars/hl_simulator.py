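"""Hearing-loss simulation: threshold elevation with loudness recruitment.

Amplified speech is degraded per band by expanding its envelope in the dB
domain: a level at the listener's elevated threshold maps to 0 dB SPL
(normal threshold) while a fixed ceiling level maps to itself, i.e. the
envelope is raised to the power n = ceiling / (ceiling − HL).  This
realizes both threshold elevation and the abnormally steep loudness
growth (recruitment) of cochlear loss.  Loss of frequency selectivity is
deliberately not simulated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .audio import CalibratedSignal, band_split, envelope_db
from .audiograms import Audiogram
from .ha_simulator import MIN_SAMPLE_RATE_HZ, UndersampledError

DEFAULT_CEILING_DB_SPL = 100.0
ENVELOPE_TAU_MS = 1.0

#: audiometric octave bands used for the per-band expansion (edges, Hz)
OCTAVE_BAND_EDGES_HZ = (88.4, 176.8, 353.6, 707.1, 1414.2, 2828.4, 5656.9, 8000.0)
OCTAVE_BAND_CENTERS_HZ = (125.0, 250.0, 500.0, 1000.0, 2000.0, 4000.0, 8000.0)


class UnsimulatableLossError(ValueError):
    """Hearing loss at or above the recruitment ceiling."""


@dataclass
class RecruitmentParams:
    """Per-band losses and the self-mapped ceiling level."""

    hl_db: np.ndarray
    band_edges_hz: np.ndarray = field(
        default_factory=lambda: np.array(OCTAVE_BAND_EDGES_HZ))
    ceiling_db_spl: float = DEFAULT_CEILING_DB_SPL

    def __post_init__(self) -> None:
        self.hl_db = np.asarray(self.hl_db, dtype=float)
        self.band_edges_hz = np.asarray(self.band_edges_hz, dtype=float)
        if self.hl_db.size != self.band_edges_hz.size - 1:
            raise ValueError("need one loss value per band")
        if np.any(self.hl_db < 0):
            raise ValueError("losses must be non-negative")
        if np.any(self.hl_db >= self.ceiling_db_spl):
            raise UnsimulatableLossError("loss at or above the recruitment ceiling")


def recruitment_map(level_db_spl, hl_db: float,
                    ceiling_db_spl: float = DEFAULT_CEILING_DB_SPL):
    """Expansive dB-domain map sending hl → 0 and ceiling → ceiling.

    mapped = (level − hl) · ceiling / (ceiling − hl); the slope
    ceiling/(ceiling−hl) ≥ 1 equals the envelope exponent n.
    """
    if hl_db >= ceiling_db_spl:
        raise UnsimulatableLossError(
            f"hl {hl_db} dB >= ceiling {ceiling_db_spl} dB SPL")
    level = np.asarray(level_db_spl, dtype=float)
    return (level - hl_db) * ceiling_db_spl / (ceiling_db_spl - hl_db)


def params_from_audiogram(a: Audiogram,
                          ceiling_db_spl: float = DEFAULT_CEILING_DB_SPL,
                          band_edges_hz=OCTAVE_BAND_EDGES_HZ,
                          band_centers_hz=OCTAVE_BAND_CENTERS_HZ) -> RecruitmentParams:
    """Band losses from an audiogram, interpolated at the band centers.

    Hearing levels are used directly as dB SPL threshold elevations in
    each band (negative thresholds clip to zero loss).
    """
    hl = np.maximum(a.interpolated_at(np.asarray(band_centers_hz, float)), 0.0)
    return RecruitmentParams(hl, np.asarray(band_edges_hz, float), ceiling_db_spl)


def simulate_loss(x: CalibratedSignal, a: Audiogram,
                  ceiling_db_spl: float = DEFAULT_CEILING_DB_SPL,
                  params: RecruitmentParams | None = None) -> CalibratedSignal:
    """Degrade a calibrated signal according to an audiogram.

    Per band: the envelope level (1-ms smoothed power, dB SPL) is mapped
    through the recruitment expansion; the band waveform is rescaled
    sample-by-sample so its envelope follows the mapped trajectory while
    the fine structure is preserved; bands are then recombined.
    """
    if x.sample_rate_hz < MIN_SAMPLE_RATE_HZ:
        raise UndersampledError(
            f"sample rate {x.sample_rate_hz} Hz < {MIN_SAMPLE_RATE_HZ} Hz")
    if params is None:
        params = params_from_audiogram(a, ceiling_db_spl)
    edges = params.band_edges_hz
    bands = band_split(x.samples, x.sample_rate_hz, edges)
    out = np.zeros_like(x.samples)
    for b, hl in zip(bands, params.hl_db):
        if hl == 0.0:
            out += b
            continue
        level = envelope_db(b, x.sample_rate_hz, ENVELOPE_TAU_MS, ENVELOPE_TAU_MS,
                            x.full_scale_db_spl)
        gain = recruitment_map(level, hl, params.ceiling_db_spl) - level
        out += b * 10.0 ** (gain / 20.0)
    return replace(x, samples=out)
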