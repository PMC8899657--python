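"""Baseline insertion-gain prescriptions and the 5-channel structure.

The searchable hearing aid has five channels (100–700, 700–1400,
1400–2800, 2800–5600, 5600–8000 Hz).  A prescription rule maps an
audiogram to insertion gains for 65- and 85-dB-SPL speech (IGSP65,
IGSP85) at 11 audiometric frequencies, plus per-channel compression
thresholds.  The default rule is a simple documented linear-in-HL
stand-in; an "external" rule accepts tabulated gains (e.g. from
commercial fitting software) so real prescriptions can be plugged in.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .audiograms import AUDIOMETRIC_FREQUENCIES_HZ, Audiogram

GAIN_MIN_DB = -10.0
GAIN_MAX_DB = 80.0
CT_MIN_DB_SPL = 20.0
CT_MAX_DB_SPL = 50.0
DEFAULT_CT_DB_SPL = 35.0  # midpoint of the searchable 20–50 dB SPL range


@dataclass
class ChannelBank:
    """Six band edges defining five compression channels."""

    edges_hz: np.ndarray = field(
        default_factory=lambda: np.array([100.0, 700.0, 1400.0, 2800.0, 5600.0, 8000.0]))
    max_cr: float = 10.0

    def __post_init__(self) -> None:
        self.edges_hz = np.asarray(self.edges_hz, dtype=float)
        if self.edges_hz.size != 6:
            raise ValueError("a ChannelBank has exactly 6 edges (5 channels)")
        if np.any(np.diff(self.edges_hz) <= 0):
            raise ValueError("edges must be strictly increasing")

    @property
    def n_channels(self) -> int:
        return self.edges_hz.size - 1

    def channel_edges(self, channel: int) -> tuple[float, float]:
        if not 1 <= channel <= self.n_channels:
            raise IndexError(f"channel must be in 1..{self.n_channels}")
        return float(self.edges_hz[channel - 1]), float(self.edges_hz[channel])


@dataclass
class Prescription:
    """Two-level insertion gains at 11 frequencies plus per-channel CTs."""

    frequencies_hz: np.ndarray = field(
        default_factory=lambda: np.array(AUDIOMETRIC_FREQUENCIES_HZ))
    ig_sp65: np.ndarray = field(default_factory=lambda: np.zeros(11))
    ig_sp85: np.ndarray = field(default_factory=lambda: np.zeros(11))
    ct_db_spl: np.ndarray = field(default_factory=lambda: np.full(5, DEFAULT_CT_DB_SPL))

    def __post_init__(self) -> None:
        self.frequencies_hz = np.asarray(self.frequencies_hz, dtype=float)
        self.ig_sp65 = np.asarray(self.ig_sp65, dtype=float)
        self.ig_sp85 = np.asarray(self.ig_sp85, dtype=float)
        self.ct_db_spl = np.asarray(self.ct_db_spl, dtype=float)
        for g in (self.ig_sp65, self.ig_sp85):
            if g.shape != self.frequencies_hz.shape:
                raise ValueError("gain vectors must align with frequencies")
            if np.any(~np.isfinite(g)):
                raise ValueError("gains must be finite")
            if np.any(g < GAIN_MIN_DB) or np.any(g > GAIN_MAX_DB):
                raise ValueError(f"gains outside [{GAIN_MIN_DB}, {GAIN_MAX_DB}] dB")
        if np.any(self.ct_db_spl < CT_MIN_DB_SPL) or np.any(self.ct_db_spl > CT_MAX_DB_SPL):
            raise ValueError("compression thresholds outside [20, 50] dB SPL")

    def copy(self) -> "Prescription":
        return Prescription(self.frequencies_hz.copy(), self.ig_sp65.copy(),
                            self.ig_sp85.copy(), self.ct_db_spl.copy())

    def gain_at(self, frequency_hz: float, level: int = 65) -> float:
        idx = np.nonzero(np.isclose(self.frequencies_hz, frequency_hz))[0]
        if idx.size == 0:
            raise KeyError(f"no gain stored at {frequency_hz} Hz")
        g = self.ig_sp65 if level == 65 else self.ig_sp85
        return float(g[idx[0]])

    # -- JSON ------------------------------------------------------------
    def to_json(self, path=None):
        obj = {"frequencies_hz": self.frequencies_hz.tolist(),
               "ig_sp65": self.ig_sp65.tolist(),
               "ig_sp85": self.ig_sp85.tolist(),
               "ct_db_spl": self.ct_db_spl.tolist()}
        if path is None:
            return obj
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=1)
        return obj

    @classmethod
    def from_json(cls, path) -> "Prescription":
        with open(path) as fh:
            obj = json.load(fh)
        return cls(np.array(obj["frequencies_hz"]), np.array(obj["ig_sp65"]),
                   np.array(obj["ig_sp85"]), np.array(obj["ct_db_spl"]))


# ---------------------------------------------------------------------------
# Channel geometry
# ---------------------------------------------------------------------------

def channel_center_frequency(bank: ChannelBank, channel: int) -> float:
    """Geometric-mean channel center snapped to an audiometric frequency."""
    lo, hi = bank.channel_edges(channel)
    center = float(np.sqrt(lo * hi))
    freqs = np.asarray(AUDIOMETRIC_FREQUENCIES_HZ)
    return float(freqs[np.argmin(np.abs(freqs - center))])


def map_frequencies_to_channels(bank: ChannelBank,
                                frequencies_hz=AUDIOMETRIC_FREQUENCIES_HZ) -> np.ndarray:
    """Assign each frequency to the channel whose half-open band holds it.

    Frequencies below the lowest edge join channel 1; the top edge is
    closed, so 8000 Hz belongs to channel 5.  Returns 1-based channel
    indices.
    """
    freqs = np.asarray(frequencies_hz, dtype=float)
    idx = np.searchsorted(bank.edges_hz, freqs, side="right")
    idx = np.clip(idx, 1, bank.n_channels)
    return idx.astype(int)


# ---------------------------------------------------------------------------
# Prescription rules
# ---------------------------------------------------------------------------

def _rule_linear(a: Audiogram, bank: ChannelBank, *, r65: float = 0.45,
                 r85: float = 0.30, cap_db: float = 55.0, **_) -> Prescription:
    """Linear-in-HL stand-in rule: IGSP65 = 0.45·HL, IGSP85 = 0.30·HL.

    Monotone in hearing loss and compressive (IGSP85 < IGSP65 whenever
    HL > 0), capped at 55 dB.
    """
    hl = np.maximum(a.thresholds_db_hl, 0.0)
    return Prescription(a.frequencies_hz.copy(),
                        np.minimum(r65 * hl, cap_db),
                        np.minimum(r85 * hl, cap_db))


def _rule_external(a: Audiogram, bank: ChannelBank, *, table=None, **_) -> Prescription:
    """Pass-through rule echoing a user-supplied gain table.

    ``table`` is a DataFrame or CSV path with columns
    ``frequency_hz,ig_sp65,ig_sp85`` covering the audiogram frequencies.
    """
    if table is None:
        raise ValueError("external rule requires a gain table")
    df = table if isinstance(table, pd.DataFrame) else pd.read_csv(table)
    df = df.sort_values("frequency_hz")
    f = df["frequency_hz"].to_numpy(float)
    if f.shape != a.frequencies_hz.shape or not np.allclose(f, a.frequencies_hz):
        raise ValueError("external table must cover the audiogram frequencies")
    return Prescription(a.frequencies_hz.copy(),
                        df["ig_sp65"].to_numpy(float),
                        df["ig_sp85"].to_numpy(float))


RULES: dict = {"linear": _rule_linear, "external": _rule_external}


def register_rule(name: str, fn) -> None:
    """Register a prescription rule callable(a, bank, **kw) -> Prescription."""
    RULES[name] = fn


def baseline_prescription(a: Audiogram, bank: ChannelBank | None = None,
                          rule: str = "linear", **kwargs) -> Prescription:
    """Compute the baseline (pre-search) prescription for an audiogram."""
    if bank is None:
        bank = ChannelBank()
    if not a.is_complete():
        raise ValueError("baseline prescription requires a complete audiogram")
    if rule not in RULES:
        raise KeyError(f"unregistered prescription rule: {rule!r}")
    return RULES[rule](a, bank, **kwargs)
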