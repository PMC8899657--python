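"""Intelligibility objectives for the random search.

Three interchangeable objectives are provided, all returning an
:class:`IntelligibilityResult` (a percent-correct score quantized to the
token-count granularity, plus a continuous likelihood used to break score
ties):

* a deterministic envelope-correlation surrogate (STOI-flavoured) scored
  against clean references, with a recognition threshold standing in for
  a recognizer's top-5 decision rule;
* a quadratic test objective with a hidden optimum, used to validate the
  optimizers;
* an adapter that shells out to an external ASR system following a small
  file contract, restoring the exact top-5 rule when a recognizer is
  available.
"""

from __future__ import annotations

import csv
import json
import subprocess
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .audio import CalibratedSignal, band_split, frame_energies, write_wav
from .gain_constraints import HAConfiguration
from .prescription import ChannelBank

DEFAULT_THRESHOLD = 0.5
FRAME_MS = 32.0
#: band level below which a frame counts as inaudible (dB SPL).  Log
#: energies are clipped here before correlation: envelope structure that
#: falls under the normal-hearing threshold carries no intelligibility,
#: which is what makes the metric sensitive to audibility at all (a pure
#: correlation would be invariant to the affine dB mapping of recruitment).
AUDIBILITY_FLOOR_DB_SPL = 0.0


def _log_energy_floor(full_scale_db_spl: float, frame_len: int) -> float:
    """Frame log-energy corresponding to the audibility floor."""
    return (AUDIBILITY_FLOOR_DB_SPL - full_scale_db_spl
            + 10.0 * np.log10(frame_len))


@dataclass
class IntelligibilityResult:
    """Percent-correct score with a continuous tie-breaking likelihood."""

    score_percent: float
    likelihood: float
    per_token: list = field(default_factory=list)

    def key(self) -> tuple[float, float]:
        return (self.score_percent, self.likelihood)


# ---------------------------------------------------------------------------
# Surrogate token metric
# ---------------------------------------------------------------------------

def _band_frame_log_energies(x: CalibratedSignal, bank: ChannelBank,
                             frame_len: int) -> np.ndarray:
    floor = 10.0 ** (_log_energy_floor(x.full_scale_db_spl, frame_len) / 10.0)
    bands = band_split(x.samples, x.sample_rate_hz, bank.edges_hz)
    rows = [10.0 * np.log10(np.maximum(frame_energies(b, frame_len), floor))
            for b in bands]
    return np.vstack(rows)  # (n_bands, n_frames)


def _clipped_pattern_correlation(ref_log: np.ndarray, proc_log: np.ndarray) -> float:
    """Non-negative correlation of the joint (band × frame) log-energy patterns.

    Each pattern is centered by its own global mean only — the analogue of
    a recognizer front-end normalizing overall input level — so relative
    band levels (spectral shape) and envelope trajectories both count.
    """
    ref_c = ref_log.ravel() - ref_log.mean()
    proc_c = proc_log.ravel() - proc_log.mean()
    denom = np.linalg.norm(ref_c) * np.linalg.norm(proc_c)
    r = float(ref_c @ proc_c / denom) if denom > 0 else 0.0
    return max(r, 0.0)


def token_metric(processed: CalibratedSignal, clean_reference: CalibratedSignal,
                 bank: ChannelBank | None = None,
                 max_length_mismatch: float = 0.05) -> float:
    """Envelope-correlation intelligibility metric in [0, 1].

    Short-time (32-ms frames) log band energies of the processed token,
    clipped at the audibility floor, are correlated with those of the
    clean reference as one joint (band × frame) pattern; a negative
    correlation clips to zero.  Subtracting each pattern's global mean
    makes the metric invariant to overall gain — mirroring a recognizer
    front-end's level normalization — while leaving it sensitive to
    changes of spectral shape, which is what actually degrades
    recognition.
    """
    if processed.sample_rate_hz != clean_reference.sample_rate_hz:
        raise ValueError("sample rates differ")
    n_p, n_r = processed.samples.size, clean_reference.samples.size
    if abs(n_p - n_r) > max_length_mismatch * max(n_p, n_r):
        raise ValueError(f"token lengths differ by more than "
                         f"{max_length_mismatch:.0%}: {n_p} vs {n_r} samples")
    n = min(n_p, n_r)
    if bank is None:
        bank = ChannelBank()
    frame_len = int(round(FRAME_MS * 1e-3 * processed.sample_rate_hz))
    ref = CalibratedSignal(clean_reference.samples[:n], clean_reference.sample_rate_hz,
                           clean_reference.full_scale_db_spl)
    proc = CalibratedSignal(processed.samples[:n], processed.sample_rate_hz,
                            processed.full_scale_db_spl)
    return _clipped_pattern_correlation(
        _band_frame_log_energies(ref, bank, frame_len),
        _band_frame_log_energies(proc, bank, frame_len))


def score_tokens(processed: list, references: list,
                 threshold: float = DEFAULT_THRESHOLD,
                 bank: ChannelBank | None = None) -> IntelligibilityResult:
    """Score matched token pairs: recognized iff metric >= threshold.

    The likelihood is the mean metric over recognized tokens (over all
    tokens when none is recognized, keeping the tie-breaker total).
    """
    if len(processed) == 0 or len(processed) != len(references):
        raise ValueError("need at least one matched token pair")
    metrics = [token_metric(p, r, bank) for p, r in zip(processed, references)]
    return result_from_metrics(np.asarray(metrics), threshold)


def result_from_metrics(metrics: np.ndarray, threshold: float = DEFAULT_THRESHOLD
                        ) -> IntelligibilityResult:
    metrics = np.asarray(metrics, dtype=float)
    recognized = metrics >= threshold
    n = metrics.size
    score = 100.0 * recognized.sum() / n
    pool = metrics[recognized] if recognized.any() else metrics
    return IntelligibilityResult(float(score), float(pool.mean()),
                                 per_token=[{"recognized": bool(r), "metric": float(m)}
                                            for r, m in zip(recognized, metrics)])


# ---------------------------------------------------------------------------
# Quadratic optimizer-validation objective
# ---------------------------------------------------------------------------

def quantize_score(value: float, n_tokens: int) -> float:
    """Floor-quantize a percent value to the n-token granularity."""
    step = 100.0 / n_tokens
    return float(np.floor(value / step + 1e-12) * step)


@dataclass
class QuadraticTestObjective:
    """Deterministic objective with a hidden optimum in parameter space.

    Parameters are normalized by their search resolution (CT in 1-dB
    steps, IG offsets in 0.1-dB steps), so every coordinate of the
    distance is measured in grid steps; the score is
    ``quantize(100·exp(−d²/τ))`` with d the Euclidean distance to the
    hidden optimum, and the likelihood is −d.  The 100/n_tokens score
    granularity emulates an N-word recognition test.
    """

    hidden_optimum: np.ndarray
    tau: float = 50.0
    n_tokens: int = 50
    mask: np.ndarray | None = None  # restrict distance to a parameter subset

    def __post_init__(self) -> None:
        self.hidden_optimum = np.asarray(self.hidden_optimum, dtype=float)

    @staticmethod
    def normalize(params: np.ndarray) -> np.ndarray:
        params = np.asarray(params, dtype=float)
        n_ch = params.size // 2
        ct = params[:n_ch] / 1.0  # CT stepsize: 1 dB
        dig = params[n_ch:] / 0.1  # IG stepsize: 0.1 dB
        return np.concatenate([ct, dig])

    def __call__(self, config: HAConfiguration) -> IntelligibilityResult:
        p = self.normalize(config.params())
        o = self.normalize(self.hidden_optimum)
        diff = p - o
        if self.mask is not None:
            diff = diff[np.asarray(self.mask, bool)]
        d = float(np.linalg.norm(diff))
        raw = 100.0 * np.exp(-d * d / self.tau)
        return IntelligibilityResult(quantize_score(raw, self.n_tokens), -d)


# ---------------------------------------------------------------------------
# External-ASR adapter
# ---------------------------------------------------------------------------

@dataclass
class ExternalASRAdapter:
    """File contract for scoring tokens with a user-supplied recognizer.

    For each evaluation the adapter writes the processed tokens as WAV
    files plus ``manifest.csv`` (token_id, target_word) into a work
    directory, invokes ``command`` (a list; the work directory path is
    appended), and reads back ``results.csv`` with columns
    ``token_id,recognized,log_likelihood``.  A nonzero exit status or a
    timeout raises RuntimeError.
    """

    command: list
    workdir: Path
    timeout_s: float = 600.0

    def score(self, processed: list, token_ids: list, target_words: list
              ) -> IntelligibilityResult:
        work = Path(self.workdir)
        work.mkdir(parents=True, exist_ok=True)
        with open(work / "manifest.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["token_id", "target_word", "wav"])
            for sig, tid, word in zip(processed, token_ids, target_words):
                wav = work / f"{tid}.wav"
                write_wav(wav, sig)
                w.writerow([tid, word, wav.name])
        try:
            proc = subprocess.run([*self.command, str(work)], timeout=self.timeout_s,
                                  capture_output=True, text=True)
        except subprocess.TimeoutExpired as e:
            raise RuntimeError(f"external ASR timed out after {self.timeout_s}s") from e
        if proc.returncode != 0:
            raise RuntimeError(f"external ASR failed (exit {proc.returncode}): "
                               f"{proc.stderr.strip()[:500]}")
        rows = {}
        with open(work / "results.csv", newline="") as fh:
            for row in csv.DictReader(fh):
                rows[row["token_id"]] = (int(row["recognized"]),
                                         float(row["log_likelihood"]))
        missing = [t for t in token_ids if str(t) not in rows]
        if missing:
            raise RuntimeError(f"external ASR omitted tokens: {missing[:5]}")
        rec = np.array([rows[str(t)][0] for t in token_ids], bool)
        ll = np.array([rows[str(t)][1] for t in token_ids], float)
        score = 100.0 * rec.sum() / rec.size
        pool = ll[rec] if rec.any() else ll
        return IntelligibilityResult(float(score), float(pool.mean()),
                                     per_token=[{"recognized": bool(r), "metric": float(v)}
                                                for r, v in zip(rec, ll)])
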