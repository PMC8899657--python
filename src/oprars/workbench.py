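"""Fixtures and orchestration: synthetic speech tokens, full-chain
objectives, batch experiments, and repetition comparison.

The token generator produces abstract speech-like items (harmonic source,
two per-token formant targets, a fricative-like noise burst) calibrated
to 65 dB SPL.  They are not words in any language: the surrogate
objective only needs matched clean/processed pairs and pairwise
distinctness.

Two full-chain objectives wrap amplification → hearing-loss simulation →
envelope-correlation scoring:

* :class:`ChainObjective` composes the public simulator functions
  literally (used for spot checks and small runs);
* :class:`SurrogateChainObjective` exploits that the clean token set is
  fixed across a search: the channel band signals and detector level
  trajectories are precomputed once, and each candidate only applies its
  (slowly varying) gain trajectories in the dB domain.  This quasi-static
  fast path is what makes desk-scale batch experiments tractable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.signal import lfilter, sawtooth

from . import sii as sii_mod
from .audio import CalibratedSignal, band_limit, band_split, envelope_db, frame_energies
from .audiograms import Audiogram, interpolate_missing_thresholds
from .gain_constraints import HAConfiguration, compression_ratio, resolve_configuration
from .ha_simulator import (ATTACK_MS, LIMITER_ATTACK_MS, LIMITER_CR,
                           LIMITER_CT_DB_SPL, LIMITER_RELEASE_MS,
                           OPERATING_LEVEL_DB_SPL, RELEASE_MS, amplify)
from .hl_simulator import DEFAULT_CEILING_DB_SPL, RecruitmentParams, simulate_loss
from .objective import (DEFAULT_THRESHOLD, FRAME_MS, IntelligibilityResult,
                        _log_energy_floor, result_from_metrics, token_metric)
from .prescription import (ChannelBank, Prescription, baseline_prescription,
                           channel_center_frequency)
from .random_search import run_algorithm

TOKEN_LEVEL_DB_SPL = 65.0


# ---------------------------------------------------------------------------
# Token generation
# ---------------------------------------------------------------------------

@dataclass
class TokenSet:
    """Distinct speech-like tokens calibrated to 65 dB SPL."""

    tokens: list
    ids: list
    sample_rate_hz: int
    seed: int

    def __len__(self) -> int:
        return len(self.tokens)


def _resonator(x: np.ndarray, fs: int, f_hz: float, bw_hz: float) -> np.ndarray:
    """Second-order all-pole resonance (formant) filter."""
    r = np.exp(-np.pi * bw_hz / fs)
    theta = 2.0 * np.pi * f_hz / fs
    a = [1.0, -2.0 * r * np.cos(theta), r * r]
    # unity gain at the resonance frequency
    w = np.exp(1j * theta)
    g = abs(1.0 + a[1] * w**-1 + a[2] * w**-2)
    return lfilter([g], a, x)


def _syllable(rng: np.random.Generator, fs: int, n_samp: int, f0: float) -> np.ndarray:
    phase = 2.0 * np.pi * np.cumsum(
        np.linspace(f0, f0 * rng.uniform(0.8, 0.95), n_samp)) / fs
    src = sawtooth(phase)
    formants = (rng.uniform(300.0, 800.0), rng.uniform(900.0, 2200.0),
                rng.uniform(2300.0, 3200.0))
    bws = (80.0, 120.0, 180.0)
    y = src
    for f, bw in zip(formants, bws):
        y = _resonator(y, fs, f, bw)
    # raised-cosine rise/fall keeps syllables separated in the envelope
    rise = min(int(0.03 * fs), n_samp // 3)
    fall = min(int(0.05 * fs), n_samp // 3)
    env = np.ones(n_samp)
    env[:rise] = 0.5 * (1 - np.cos(np.pi * np.arange(rise) / rise))
    env[n_samp - fall:] = 0.5 * (1 + np.cos(np.pi * np.arange(fall) / fall))
    return y * env


def generate_tokens(n: int, seed: int, sample_rate: int = 16000) -> TokenSet:
    """Generate ``n`` distinct two-syllable speech-like tokens (0.4–0.8 s).

    Deterministic for a fixed seed; each token gets its own fundamental,
    formant targets and a band-limited noise burst at the second-syllable
    onset.  Long-term level is 65 dB SPL under the package calibration.
    """
    if n < 1:
        raise ValueError("need at least one token")
    rng = np.random.default_rng(np.random.SeedSequence([0x0A17, int(seed)]))
    tokens = []
    for i in range(n):
        dur = rng.uniform(0.4, 0.8)
        n_samp = int(dur * sample_rate)
        split = int(n_samp * rng.uniform(0.4, 0.6))
        f0 = rng.uniform(100.0, 140.0)
        syl1 = _syllable(rng, sample_rate, split, f0)
        syl2 = _syllable(rng, sample_rate, n_samp - split, f0 * rng.uniform(0.9, 1.1))
        x = np.concatenate([syl1, 0.9 * syl2])
        # fricative-like burst at the second-syllable onset
        burst_len = min(int(0.06 * sample_rate), n_samp - split)
        noise = rng.standard_normal(burst_len)
        noise = band_limit(noise, sample_rate, 2000.0, 6000.0)
        x[split:split + burst_len] += 0.4 * noise * np.std(x)
        x = band_limit(x, sample_rate, 80.0, min(7900.0, sample_rate / 2 * 0.99))
        sig = CalibratedSignal(x, sample_rate).scaled_to(TOKEN_LEVEL_DB_SPL)
        tokens.append(sig)
    return TokenSet(tokens, [f"tok{i:03d}" for i in range(n)], sample_rate, seed)


# ---------------------------------------------------------------------------
# Full-chain objectives
# ---------------------------------------------------------------------------

class ChainObjective:
    """Literal composition amplify → simulate_loss → token metric.

    Exact but slow; prefer :class:`SurrogateChainObjective` for searches.
    """

    def __init__(self, tokens: TokenSet, audiogram: Audiogram,
                 baseline: Prescription, bank: ChannelBank | None = None,
                 threshold: float = DEFAULT_THRESHOLD,
                 hl_params: RecruitmentParams | None = None):
        self.tokens = tokens
        self.audiogram = audiogram
        self.baseline = baseline
        self.bank = bank or ChannelBank()
        self.threshold = threshold
        self.hl_params = hl_params
        concat = np.concatenate([t.samples for t in tokens.tokens])
        self.speech_spectrum = sii_mod.spectrum_of_signal(
            CalibratedSignal(concat, tokens.sample_rate_hz,
                             tokens.tokens[0].full_scale_db_spl))

    def resolve(self, config: HAConfiguration) -> HAConfiguration:
        return resolve_configuration(config, self.baseline, self.bank,
                                     self.audiogram, self.speech_spectrum)

    def __call__(self, config: HAConfiguration) -> IntelligibilityResult:
        resolved = self.resolve(config)
        metrics = []
        for tok in self.tokens.tokens:
            y = amplify(tok, resolved, self.bank)
            z = simulate_loss(y, self.audiogram, params=self.hl_params)
            metrics.append(token_metric(z, tok, self.bank))
        return result_from_metrics(np.asarray(metrics), self.threshold)


class TokenChannelFeatures:
    """Candidate-independent precomputation over a fixed clean token set.

    Each token is processed independently (matching how the literal chain
    amplifies recordings one by one): its 5-channel band split and the
    main-compressor, limiter and recruitment detector level trajectories
    are computed per token and concatenated, along with normalized clean
    log-energy frames and the long-term octave speech spectrum.  One
    features object can serve every audiogram in a batch.
    """

    def __init__(self, tokens: TokenSet, bank: ChannelBank | None = None):
        self.tokens = tokens
        self.bank = bank or ChannelBank()
        fs = tokens.sample_rate_hz
        self.fs = fs
        self.full_scale = tokens.tokens[0].full_scale_db_spl
        concat = np.concatenate([t.samples for t in tokens.tokens])
        self.speech_spectrum = sii_mod.spectrum_of_signal(
            CalibratedSignal(concat, fs, self.full_scale))

        nch = self.bank.n_channels
        self.centers = [channel_center_frequency(self.bank, c + 1) for c in range(nch)]
        per_tok_bands = [band_split(t.samples, fs, self.bank.edges_hz)
                         for t in tokens.tokens]
        self.x, self.x_sq = [], []
        self.level_main, self.level_lim, self.level_env = [], [], []
        for c in range(nch):
            xs = [tb[c] for tb in per_tok_bands]
            self.x.append(np.concatenate(xs).astype(np.float32))
            self.x_sq.append(np.square(self.x[-1]))
            self.level_main.append(np.concatenate(
                [envelope_db(b, fs, ATTACK_MS[c], RELEASE_MS[c], self.full_scale)
                 for b in xs]).astype(np.float32))
            self.level_lim.append(np.concatenate(
                [envelope_db(b, fs, LIMITER_ATTACK_MS, LIMITER_RELEASE_MS,
                             self.full_scale) for b in xs]).astype(np.float32))
            self.level_env.append(np.concatenate(
                [envelope_db(b, fs, 1.0, 1.0, self.full_scale)
                 for b in xs]).astype(np.float32))

        # per-token frame bookkeeping and normalized clean log-energy frames
        frame_len = int(round(FRAME_MS * 1e-3 * fs))
        self.frame_len = frame_len
        self.le_floor = _log_energy_floor(self.full_scale, frame_len)
        self.e_floor = 10.0 ** (self.le_floor / 10.0)
        self.token_slices = []
        start = 0
        for t in tokens.tokens:
            n_frames = t.samples.size // frame_len
            self.token_slices.append((start, start + n_frames * frame_len, n_frames))
            start += t.samples.size
        # [token] unit-norm globally-centered (channel × frame) log-energy
        # patterns of the clean tokens — the metric's reference side
        self.ref_norm = []
        for (s, e, nf) in self.token_slices:
            mat = np.empty((nch, nf))
            for c in range(nch):
                mat[c] = 10.0 * np.log10(np.maximum(
                    frame_energies(self.x[c][s:e].astype(float), frame_len),
                    self.e_floor))
            flat = mat.ravel() - mat.mean()
            norm = np.linalg.norm(flat)
            self.ref_norm.append((flat / norm if norm > 0 else flat, norm > 0))


class SurrogateChainObjective:
    """Fast full-chain objective over a fixed token set.

    Per candidate, the channel gain trajectory is evaluated in the dB
    domain from the precomputed clean detector levels (quasi-static: gain
    variations are slow relative to the detector time constants, so
    detector levels of processed signals are the clean levels shifted by
    the running gain).  Recruitment bands coincide with the hearing-aid
    channels here, which keeps the whole evaluation in vectorized
    per-channel arithmetic.
    """

    def __init__(self, tokens: TokenSet, audiogram: Audiogram,
                 baseline: Prescription, bank: ChannelBank | None = None,
                 threshold: float = DEFAULT_THRESHOLD,
                 ceiling_db_spl: float = DEFAULT_CEILING_DB_SPL,
                 features: TokenChannelFeatures | None = None):
        self.tokens = tokens
        self.audiogram = audiogram
        self.baseline = baseline
        self.bank = bank or ChannelBank()
        self.threshold = threshold
        self.ceiling = ceiling_db_spl
        f = features if features is not None else TokenChannelFeatures(tokens, self.bank)
        self.features = f
        self.fs = f.fs
        self.full_scale = f.full_scale
        self.speech_spectrum = f.speech_spectrum
        self.centers = f.centers
        self.hl = np.maximum(self.audiogram.interpolated_at(self.centers), 0.0)
        self.x, self.x_sq = f.x, f.x_sq
        self.level_main, self.level_lim, self.level_env = \
            f.level_main, f.level_lim, f.level_env
        self.token_slices = f.token_slices
        self.frame_len = f.frame_len
        self.ref_norm = f.ref_norm

    # -- candidate resolution -------------------------------------------
    def resolve(self, config: HAConfiguration) -> HAConfiguration:
        return resolve_configuration(config, self.baseline, self.bank,
                                     self.audiogram, self.speech_spectrum)

    def _channel_gain_db(self, resolved: HAConfiguration, c: int) -> np.ndarray:
        fc = self.centers[c]
        ig65 = resolved.resolved.gain_at(fc, 65)
        ig85 = resolved.resolved.gain_at(fc, 85)
        cr = float(np.clip(compression_ratio(ig65, ig85), 1.0, self.bank.max_cr))
        ct = float(resolved.ct_db_spl[c])
        g0 = ig65 + max(0.0, OPERATING_LEVEL_DB_SPL - ct) * (1.0 - 1.0 / cr)
        g_main = g0 - np.maximum(self.level_main[c] - ct, 0.0) * (1.0 - 1.0 / cr)
        g_lim = -np.maximum(self.level_lim[c] + g_main - LIMITER_CT_DB_SPL, 0.0) \
            * (1.0 - 1.0 / LIMITER_CR)
        g = g_main + g_lim
        hl = self.hl[c]
        if hl >= self.ceiling - 0.5:
            # loss at the recruitment ceiling: the band is effectively dead
            return np.full_like(g, -400.0)
        if hl > 0.0:
            level = self.level_env[c] + g
            g = g + (level - hl) * (self.ceiling / (self.ceiling - hl)) - level
        return np.clip(g, -400.0, 200.0)  # float32-safe after squaring

    def metrics_exact(self, config: HAConfiguration) -> np.ndarray:
        """Per-token metrics with exact (non-quasi-static) detectors.

        Same channel-wise structure as :meth:`metrics`, but the limiter
        and recruitment detectors smooth the actually modulated signals
        token by token instead of shifting precomputed clean levels.
        Slow; used to validate the quasi-static approximation.
        """
        resolved = self.resolve(config)
        nch = self.bank.n_channels
        n_tok = len(self.tokens)
        mats = [np.empty((nch, nf)) for (_, _, nf) in self.token_slices]
        for c in range(nch):
            fc = self.centers[c]
            ig65 = resolved.resolved.gain_at(fc, 65)
            ig85 = resolved.resolved.gain_at(fc, 85)
            cr = float(np.clip(compression_ratio(ig65, ig85), 1.0, self.bank.max_cr))
            ct = float(resolved.ct_db_spl[c])
            g0 = ig65 + max(0.0, OPERATING_LEVEL_DB_SPL - ct) * (1.0 - 1.0 / cr)
            hl = self.hl[c]
            pos = 0
            for k, tok in enumerate(self.tokens.tokens):
                n = tok.samples.size
                xk = self.x[c][pos:pos + n].astype(float)
                lm = self.level_main[c][pos:pos + n].astype(float)
                g_main = g0 - np.maximum(lm - ct, 0.0) * (1.0 - 1.0 / cr)
                y = xk * 10.0 ** (g_main / 20.0)
                l_lim = envelope_db(y, self.fs, LIMITER_ATTACK_MS,
                                    LIMITER_RELEASE_MS, self.full_scale)
                y = y * 10.0 ** (-np.maximum(l_lim - LIMITER_CT_DB_SPL, 0.0)
                                 * (1.0 - 1.0 / LIMITER_CR) / 20.0)
                if hl >= self.ceiling - 0.5:
                    y = np.zeros_like(y)  # dead band
                elif hl > 0.0:
                    le = envelope_db(y, self.fs, 1.0, 1.0, self.full_scale)
                    g_hl = (le - hl) * (self.ceiling / (self.ceiling - hl)) - le
                    y = y * 10.0 ** (g_hl / 20.0)
                s, e, nf = self.token_slices[k]
                seg = np.square(y[: nf * self.frame_len])
                mats[k][c] = 10.0 * np.log10(np.maximum(
                    seg.reshape(nf, self.frame_len).sum(axis=1),
                    self.features.e_floor))
                pos += n
        return self._pattern_correlations(mats)

    def _pattern_correlations(self, mats: list) -> np.ndarray:
        """Clipped correlation of each token's (channel × frame) pattern
        with its precomputed clean reference pattern."""
        out = np.zeros(len(mats))
        for k, mat in enumerate(mats):
            ref, ok = self.ref_norm[k]
            if not ok:
                continue
            flat = mat.ravel() - mat.mean()
            norm = np.linalg.norm(flat)
            r = float(ref @ flat / norm) if norm > 0 else 0.0
            out[k] = max(r, 0.0)
        return out

    def metrics(self, config: HAConfiguration) -> np.ndarray:
        resolved = self.resolve(config)
        nch = self.bank.n_channels
        mats = [np.empty((nch, nf)) for (_, _, nf) in self.token_slices]
        for c in range(nch):
            g = self._channel_gain_db(resolved, c)
            z_sq = self.x_sq[c] * np.square(10.0 ** (g / 20.0)).astype(np.float32)
            for k, (s, e, nf) in enumerate(self.token_slices):
                mats[k][c] = 10.0 * np.log10(np.maximum(
                    z_sq[s:e].reshape(nf, self.frame_len).sum(axis=1),
                    self.features.e_floor))
        return self._pattern_correlations(mats)

    def __call__(self, config: HAConfiguration) -> IntelligibilityResult:
        return result_from_metrics(self.metrics(config), self.threshold)


# ---------------------------------------------------------------------------
# Batch experiments
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    """Summary table plus per-run prescriptions, states and errors."""

    summary: pd.DataFrame
    prescriptions: dict = field(default_factory=dict)  # (audiogram idx, rep) -> Prescription
    states: dict = field(default_factory=dict)
    errors: list = field(default_factory=list)


def _run_seed(base_seed: int, *parts: int) -> int:
    return int(np.random.SeedSequence([int(base_seed), *map(int, parts)])
               .generate_state(1)[0] % (2**31))


def run_experiment(audiograms: list, algorithm: str = "gen1",
                   repetitions: int = 2, base_seed: int = 0,
                   iterations: int = 75, threads: int = 4,
                   n_tokens: int = 50, sample_rate: int = 16000,
                   threshold: float = DEFAULT_THRESHOLD,
                   rule: str = "linear", bank: ChannelBank | None = None,
                   out_dir=None) -> ExperimentResult:
    """Optimize settings for a batch of audiograms, several repetitions each.

    Tokens are generated once per experiment; every (audiogram,
    repetition) run gets an independent seed derived from ``base_seed``.
    Failures are recorded per audiogram and the batch continues.  The
    baseline score is the objective at the unsearched configuration
    (offsets 0, default CTs).
    """
    bank = bank or ChannelBank()
    tokens = generate_tokens(n_tokens, seed=base_seed, sample_rate=sample_rate)
    features = TokenChannelFeatures(tokens, bank)
    rows, result = [], ExperimentResult(pd.DataFrame())
    for idx, a in enumerate(audiograms):
        try:
            if not a.is_complete():
                a = interpolate_missing_thresholds(a)
            baseline = baseline_prescription(a, bank, rule=rule)
            obj = SurrogateChainObjective(tokens, a, baseline, bank, threshold,
                                          features=features)
            base_cfg = HAConfiguration(np.full(bank.n_channels, 35.0),
                                       np.zeros(bank.n_channels))
            base_res = obj(base_cfg)
            for rep in range(repetitions):
                seed = _run_seed(base_seed, idx, rep)
                state = run_algorithm(algorithm, obj, iterations=iterations,
                                      threads=threads, seed=seed)
                resolved = obj.resolve(state.best_config)
                row = {"audiogram": idx, "label": a.label, "repetition": rep,
                       "algorithm": algorithm, "seed": seed,
                       "baseline_score": base_res.score_percent,
                       "optimized_score": state.best_result.score_percent,
                       "optimized_likelihood": state.best_result.likelihood}
                for c in range(bank.n_channels):
                    row[f"ct_{c + 1}"] = resolved.ct_db_spl[c]
                    row[f"dig_{c + 1}"] = resolved.dig[c]
                rows.append(row)
                result.prescriptions[(idx, rep)] = resolved.resolved
                result.states[(idx, rep)] = state
                if out_dir is not None:
                    from pathlib import Path
                    d = Path(out_dir)
                    d.mkdir(parents=True, exist_ok=True)
                    resolved.resolved.to_json(d / f"settings_a{idx}_r{rep}.json")
                    state.trace_frame().to_csv(
                        d / f"trace_a{idx}_r{rep}.csv", index=False)
        except Exception as e:  # noqa: BLE001 - batch robustness by contract
            result.errors.append({"audiogram": idx, "label": getattr(a, "label", ""),
                                  "error": repr(e)})
    result.summary = pd.DataFrame(rows)
    if out_dir is not None and len(rows):
        from pathlib import Path
        result.summary.to_csv(Path(out_dir) / "summary.csv", index=False)
    return result


def compare_repetitions(prescriptions_rep1: list, prescriptions_rep2: list
                        ) -> tuple[pd.DataFrame, dict]:
    """Reproducibility of two repetitions over matched audiograms.

    Per audiogram: Pearson r between the two 11-point IGSP65 functions
    and per-channel |ΔCT|.  Returns the per-audiogram table and a summary
    with min/max/mean r.
    """
    if len(prescriptions_rep1) != len(prescriptions_rep2) or not prescriptions_rep1:
        raise ValueError("repetition sets must be non-empty and matched")
    rows = []
    for i, (p1, p2) in enumerate(zip(prescriptions_rep1, prescriptions_rep2)):
        if not np.allclose(p1.frequencies_hz, p2.frequencies_hz):
            raise ValueError(f"audiogram {i}: frequency grids differ")
        g1, g2 = p1.ig_sp65, p2.ig_sp65
        if np.std(g1) == 0 or np.std(g2) == 0:
            r = 1.0 if np.std(g1) == np.std(g2) else 0.0
        else:
            r = float(np.corrcoef(g1, g2)[0, 1])
        row = {"audiogram": i, "pearson_r": r}
        for c, (c1, c2) in enumerate(zip(p1.ct_db_spl, p2.ct_db_spl)):
            row[f"abs_dct_{c + 1}"] = abs(float(c1) - float(c2))
        rows.append(row)
    df = pd.DataFrame(rows)
    summary = {"r_min": float(df["pearson_r"].min()),
               "r_max": float(df["pearson_r"].max()),
               "r_mean": float(df["pearson_r"].mean())}
    return df, summary
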