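"""Compression-ratio bounds and SII-based audibility equalization.

Each candidate hearing-aid setting passes through a fixed pipeline before
it is auditioned:

1. per-channel insertion-gain offsets are applied to the baseline
   prescription;
2. the compression ratio implied by the two-level gains at each channel
   center, ``CR = 20 / (20 + IG85 − IG65)``, is forced into [1, 10] by
   repeated 0.5-dB gain corrections;
3. a uniform gain offset in 0.1-dB quanta equalizes the candidate's SII
   to the baseline prescription's SII, so the search cannot trade
   audibility for spectral shape;
4. a final bounds pass guards the rare interaction between the uniform
   shift and the gain caps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audiograms import Audiogram
from .prescription import (GAIN_MAX_DB, GAIN_MIN_DB, ChannelBank, Prescription,
                           channel_center_frequency, map_frequencies_to_channels)
from . import sii as sii_mod

CR_MIN = 1.0
CR_MAX = 10.0
CR_STEP_DB = 0.5
SII_STEP_DB = 0.1
_TOL = 1e-9


@dataclass
class HAConfiguration:
    """A searchable hearing-aid setting: per-channel CTs and IG offsets.

    ``ct_db_spl`` are the five compression thresholds; ``dig`` the five
    insertion-gain offsets (dB, applied to both IGSP65 and IGSP85 of every
    frequency in the channel).  ``resolved`` holds the prescription after
    offsets and all adjustments; ``provenance`` counts the adjustment
    steps applied.
    """

    ct_db_spl: np.ndarray = field(default_factory=lambda: np.full(5, 35.0))
    dig: np.ndarray = field(default_factory=lambda: np.zeros(5))
    resolved: Prescription | None = None
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ct_db_spl = np.asarray(self.ct_db_spl, dtype=float)
        self.dig = np.asarray(self.dig, dtype=float)
        if self.ct_db_spl.size != self.dig.size:
            raise ValueError("ct and dig must have one value per channel")

    def params(self) -> np.ndarray:
        """Flat parameter vector (ct_1..5, dig_1..5)."""
        return np.concatenate([self.ct_db_spl, self.dig])

    def copy(self) -> "HAConfiguration":
        return HAConfiguration(self.ct_db_spl.copy(), self.dig.copy(),
                               self.resolved.copy() if self.resolved else None,
                               dict(self.provenance))


# ---------------------------------------------------------------------------
# Eq.-style compression ratio and the 0.5-dB correction loop
# ---------------------------------------------------------------------------

def compression_ratio(ig65: float, ig85: float) -> float:
    """CR implied by the gains at 65/85 dB SPL: 20 / (20 + ig85 − ig65).

    A zero denominator (output level independent of input) returns +inf.
    """
    den = 20.0 + ig85 - ig65
    if den == 0.0:
        return np.inf
    return 20.0 / den


def enforce_cr_bounds(ig65: float, ig85: float) -> tuple[float, float, int]:
    """Force the implied CR into [1, 10] by 0.5-dB gain corrections.

    Rules, re-evaluated after every step until CR ∈ [1, 10]:
    CR < 0 → raise ig85; 0 ≤ CR < 1 → raise ig65; CR > 10 (including the
    singular zero-denominator case) → lower ig65.  Returns the adjusted
    gains and the number of steps taken.
    """
    g65, g85 = float(ig65), float(ig85)
    steps = 0
    while True:
        den = 20.0 + g85 - g65
        if 2.0 - _TOL <= den <= 20.0 + _TOL:  # CR in [1, 10]
            return g65, g85, steps
        if den < 0.0:  # CR < 0
            g85 += CR_STEP_DB
        elif den > 20.0:  # 0 <= CR < 1
            g65 += CR_STEP_DB
        else:  # 0 <= den < 2: CR > 10 or infinite
            g65 -= CR_STEP_DB
        steps += 1
        if steps > 100000:  # unreachable for finite inputs; defensive
            raise RuntimeError("CR adjustment failed to terminate")


def enforce_cr_bounds_prescription(p: Prescription, bank: ChannelBank) -> tuple[Prescription, int]:
    """Apply the CR loop at each channel center, correcting the whole channel.

    The gain corrections found at the channel center frequency are added
    to every frequency of that channel (both levels), keeping the
    within-channel gain shape intact.  Corrected gains are clipped to the
    representable range.
    """
    out = p.copy()
    assignment = map_frequencies_to_channels(bank, p.frequencies_hz)
    total_steps = 0
    for ch in range(1, bank.n_channels + 1):
        fc = channel_center_frequency(bank, ch)
        i_fc = int(np.argmin(np.abs(p.frequencies_hz - fc)))
        g65, g85, steps = enforce_cr_bounds(out.ig_sp65[i_fc], out.ig_sp85[i_fc])
        d65 = g65 - out.ig_sp65[i_fc]
        d85 = g85 - out.ig_sp85[i_fc]
        members = assignment == ch
        out.ig_sp65[members] += d65
        out.ig_sp85[members] += d85
        total_steps += steps
    out.ig_sp65 = np.clip(out.ig_sp65, GAIN_MIN_DB, GAIN_MAX_DB)
    out.ig_sp85 = np.clip(out.ig_sp85, GAIN_MIN_DB, GAIN_MAX_DB)
    return out, total_steps


# ---------------------------------------------------------------------------
# SII equalization
# ---------------------------------------------------------------------------

def sii_equalize(candidate: Prescription, baseline: Prescription, a: Audiogram,
                 speech_spectrum: sii_mod.BandSpectrum,
                 max_steps: int = 2000) -> tuple[Prescription, dict]:
    """Equalize a candidate's SII to the baseline's by uniform 0.1-dB shifts.

    Both IGSP65 and IGSP85 are shifted identically.  Each step moves in
    the direction of sign(SII_baseline − SII_candidate) and is kept only
    if it reduces |ΔSII|; the first non-improving step is reverted and the
    loop stops.  Returns the shifted prescription and a provenance dict
    with ``sii_steps``, ``sii_offset_db`` and ``sii_delta_final``.
    """
    def delta(offset: float) -> float:
        shifted = sii_mod.amplified_speech_spectrum(speech_spectrum, candidate).shifted(offset)
        v = sii_mod.sii_value(shifted, a)
        if not np.isfinite(v):
            raise ArithmeticError("SII computation returned a non-finite value")
        return sii_base - v

    base_spec = sii_mod.amplified_speech_spectrum(speech_spectrum, baseline)
    sii_base = sii_mod.sii_value(base_spec, a)
    if not np.isfinite(sii_base):
        raise ArithmeticError("SII computation returned a non-finite value")

    offset = 0.0
    d = delta(0.0)
    steps = 0
    while steps < max_steps and d != 0.0:
        trial = offset + np.sign(d) * SII_STEP_DB
        d_trial = delta(trial)
        if abs(d_trial) < abs(d):
            offset, d = trial, d_trial
            steps += 1
        else:
            break
    offset = round(offset / SII_STEP_DB) * SII_STEP_DB  # exact 0.1 quanta
    out = candidate.copy()
    out.ig_sp65 = np.clip(out.ig_sp65 + offset, GAIN_MIN_DB, GAIN_MAX_DB)
    out.ig_sp85 = np.clip(out.ig_sp85 + offset, GAIN_MIN_DB, GAIN_MAX_DB)
    return out, {"sii_steps": steps, "sii_offset_db": offset,
                 "sii_delta_final": d}


# ---------------------------------------------------------------------------
# Candidate resolution pipeline
# ---------------------------------------------------------------------------

def resolve_configuration(config: HAConfiguration, baseline: Prescription,
                          bank: ChannelBank, a: Audiogram | None = None,
                          speech_spectrum: sii_mod.BandSpectrum | None = None
                          ) -> HAConfiguration:
    """Offsets → CR bounds → SII equalization → final CR pass.

    The SII step runs only when an audiogram and a speech spectrum are
    supplied (the surrogate objectives do; the synthetic optimizer test
    objective operates on raw parameters and skips it).
    """
    p = baseline.copy()
    assignment = map_frequencies_to_channels(bank, p.frequencies_hz)
    for ch in range(1, bank.n_channels + 1):
        members = assignment == ch
        p.ig_sp65[members] += config.dig[ch - 1]
        p.ig_sp85[members] += config.dig[ch - 1]
    p.ig_sp65 = np.clip(p.ig_sp65, GAIN_MIN_DB, GAIN_MAX_DB)
    p.ig_sp85 = np.clip(p.ig_sp85, GAIN_MIN_DB, GAIN_MAX_DB)
    p.ct_db_spl = np.asarray(config.ct_db_spl, dtype=float).copy()

    p, cr_steps = enforce_cr_bounds_prescription(p, bank)
    prov = {"cr_steps": cr_steps, "sii_steps": 0, "sii_offset_db": 0.0,
            "sii_delta_final": 0.0, "offset_out_of_bounds": False}
    if a is not None and speech_spectrum is not None:
        p, sii_prov = sii_equalize(p, baseline, a, speech_spectrum)
        prov.update(sii_prov)
        # the uniform shift may push effective offsets past the +/-10 dB
        # search range; permitted, but flagged
        if np.any(np.abs(config.dig + sii_prov["sii_offset_db"]) > 10.0 + _TOL):
            prov["offset_out_of_bounds"] = True
        p, extra = enforce_cr_bounds_prescription(p, bank)
        prov["cr_steps"] += extra
    return HAConfiguration(config.ct_db_spl.copy(), config.dig.copy(), p, prov)
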