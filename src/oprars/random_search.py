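"""Genetic random-search optimizers for hearing-aid settings.

Three variants share the same ingredients — seeded four-thread search,
uniform perturbations inside a per-parameter range that decays over 750
iterations, and rollback acceptance with a likelihood tie-break:

* GEN1: four independent threads each perturb all ten parameters
  (5 compression thresholds + 5 insertion-gain offsets) every iteration;
  the range decays by a constant per-iteration decrement down to the
  parameter stepsize.
* GEN2: one channel at a time (150 iterations each); the four threads are
  resynchronized to the cross-thread best after every iteration; the
  range decays linearly to zero over the global iteration index.
* GEN3: first all compression thresholds (250 iterations, gains pinned to
  the baseline), then all gain offsets (500 iterations); thread
  synchronization and decay as in GEN2.

Parameters live on a discrete grid: thresholds 20–50 dB SPL in 1-dB
steps, offsets ±10 dB in 0.1-dB steps (6000 settings per channel, hence
6000^5 ≈ 7.78·10^18 configurations over five channels).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .gain_constraints import HAConfiguration
from .objective import IntelligibilityResult
from .prescription import ChannelBank

CT_RANGE_DB_SPL = (20.0, 50.0)
CT_STEP_DB = 1.0
IG_OFFSET_RANGE_DB = (-10.0, 10.0)
IG_STEP_DB = 0.1
DEFAULT_ITERATIONS = 750
DEFAULT_THREADS = 4


# ---------------------------------------------------------------------------
# Decay schedules
# ---------------------------------------------------------------------------

@dataclass
class DecaySchedule:
    """Search half-range trajectory for one parameter kind.

    ``mode='eq2'`` applies a constant per-iteration decrement from
    ``initial_delta`` down to ``stepsize`` (reached exactly at the final
    iteration); ``mode='eq3'`` shrinks linearly from ``half_range`` to
    zero as a function of the iteration index.
    """

    initial_delta: float = 10.0
    stepsize: float = 0.1
    total_iterations: int = DEFAULT_ITERATIONS
    mode: str = "eq2"
    half_range: float = 10.0

    def __post_init__(self) -> None:
        if self.mode not in ("eq2", "eq3"):
            raise ValueError("mode must be 'eq2' or 'eq3'")
        if self.total_iterations < 1:
            raise ValueError("total_iterations must be >= 1")
        if self.mode == "eq2" and not self.initial_delta > self.stepsize > 0:
            raise ValueError("need initial_delta > stepsize > 0")

    def delta(self, i: int) -> float:
        """Half-range used at iteration ``i`` (1-based)."""
        if self.mode == "eq2":
            return eq2_delta(self, i - 1)
        return eq3_delta(self, i)


def eq2_delta(schedule: DecaySchedule, steps_applied: int) -> float:
    """Half-range after applying the constant decrement ``steps_applied`` times.

    Δ_0 = initial_delta; Δ_{k+1} = Δ_k − (initial_delta − stepsize)/N, so
    after N steps the half-range equals the stepsize exactly (floored
    there, making the 'during' and 'after' readings of the final
    iteration coincide).
    """
    dec = (schedule.initial_delta - schedule.stepsize) / schedule.total_iterations
    return max(schedule.stepsize, schedule.initial_delta - steps_applied * dec)


def eq3_delta(schedule: DecaySchedule, i: int) -> float:
    """Linearly shrinking half-range (N − i − 1)·half_range/N, floored at 0."""
    n = schedule.total_iterations
    if not 1 <= i <= n:
        raise IndexError(f"iteration index {i} outside 1..{n}")
    return max(0.0, (n - i - 1) * schedule.half_range / n)


def default_schedules(mode: str = "eq2",
                      total_iterations: int = DEFAULT_ITERATIONS) -> dict:
    """CT and IG schedules at the study search ranges and stepsizes."""
    return {
        "ct": DecaySchedule(initial_delta=15.0, stepsize=CT_STEP_DB,
                            total_iterations=total_iterations, mode=mode,
                            half_range=15.0),
        "ig": DecaySchedule(initial_delta=10.0, stepsize=IG_STEP_DB,
                            total_iterations=total_iterations, mode=mode,
                            half_range=10.0),
    }


# ---------------------------------------------------------------------------
# Acceptance
# ---------------------------------------------------------------------------

def accept_candidate(incumbent: tuple, candidate: tuple) -> bool:
    """Accept iff the candidate scores strictly higher, or ties on score
    with a strictly higher likelihood; otherwise roll back."""
    i_score, i_lik = incumbent
    c_score, c_lik = candidate
    return c_score > i_score or (c_score == i_score and c_lik > i_lik)


def _better(a: IntelligibilityResult, b: IntelligibilityResult) -> bool:
    return accept_candidate(b.key(), a.key())


# ---------------------------------------------------------------------------
# Search state and helpers
# ---------------------------------------------------------------------------

@dataclass
class ThreadState:
    config: HAConfiguration
    result: IntelligibilityResult


@dataclass
class SearchState:
    """Outcome of one optimizer run (best setting, threads, full trace)."""

    algorithm: str
    best_config: HAConfiguration
    best_result: IntelligibilityResult
    iteration: int
    thread_states: list
    trace: list = field(default_factory=list)
    seed: int | None = None

    def trace_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.trace)


def _round_ct(v: np.ndarray) -> np.ndarray:
    lo, hi = CT_RANGE_DB_SPL
    return np.clip(np.round(v / CT_STEP_DB) * CT_STEP_DB, lo, hi)


def _round_dig(v: np.ndarray) -> np.ndarray:
    lo, hi = IG_OFFSET_RANGE_DB
    return np.clip(np.round(v / IG_STEP_DB) * IG_STEP_DB, lo, hi)


def _random_config(rng: np.random.Generator, n_channels: int) -> HAConfiguration:
    ct = _round_ct(rng.uniform(*CT_RANGE_DB_SPL, size=n_channels))
    dig = _round_dig(rng.uniform(*IG_OFFSET_RANGE_DB, size=n_channels))
    return HAConfiguration(ct, dig)


def _perturb(rng: np.random.Generator, base: HAConfiguration,
             delta_ct: float, delta_ig: float,
             ct_mask: np.ndarray, dig_mask: np.ndarray) -> HAConfiguration:
    """Uniform perturbation within ±Δ on the masked parameters."""
    n = base.ct_db_spl.size
    ct = base.ct_db_spl + np.where(ct_mask, rng.uniform(-delta_ct, delta_ct, n), 0.0)
    dig = base.dig + np.where(dig_mask, rng.uniform(-delta_ig, delta_ig, n), 0.0)
    return HAConfiguration(_round_ct(ct), _round_dig(dig))


def _trace_row(algorithm, thread, iteration, phase, cfg, res, accepted):
    row = {"algorithm": algorithm, "thread": thread, "iteration": iteration,
           "channel_phase": phase, "score": res.score_percent,
           "likelihood": res.likelihood, "accepted": bool(accepted)}
    for c in range(cfg.ct_db_spl.size):
        row[f"ct_{c + 1}"] = cfg.ct_db_spl[c]
        row[f"dig_{c + 1}"] = cfg.dig[c]
    return row


class ObjectiveError(RuntimeError):
    """Objective evaluation failed; carries the offending configuration."""


def _evaluate(objective, cfg: HAConfiguration) -> IntelligibilityResult:
    try:
        return objective(cfg)
    except Exception as e:  # noqa: BLE001 - re-raise with search context
        raise ObjectiveError(f"objective failed at ct={cfg.ct_db_spl.tolist()}, "
                             f"dig={cfg.dig.tolist()}: {e}") from e


# ---------------------------------------------------------------------------
# GEN1: independent threads, all parameters at once, eq2 decay
# ---------------------------------------------------------------------------

def gen1_run(objective, budget: int = DEFAULT_ITERATIONS,
             threads: int = DEFAULT_THREADS, seed: int = 0,
             n_channels: int = 5, schedules: dict | None = None) -> SearchState:
    """Run GEN1 and return the best configuration across threads.

    Each thread starts from its own uniform-random configuration (the
    initial evaluation is the thread's baseline and is not counted
    against the iteration budget), then perturbs all parameters each
    iteration with the eq2 half-range decay, keeping improvements and
    rolling back otherwise.  Fully reproducible from ``seed``.
    """
    if schedules is None:
        schedules = default_schedules("eq2", budget)
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(seed).spawn(threads)]
    all_mask = np.ones(n_channels, bool)
    trace = []
    states = []
    for t, rng in enumerate(streams):
        cfg = _random_config(rng, n_channels)
        res = _evaluate(objective, cfg)
        states.append(ThreadState(cfg, res))
        trace.append(_trace_row("gen1", t, 0, 0, cfg, res, True))
    for i in range(1, budget + 1):
        d_ct = schedules["ct"].delta(i)
        d_ig = schedules["ig"].delta(i)
        for t, rng in enumerate(streams):
            st = states[t]
            cand = _perturb(rng, st.config, d_ct, d_ig, all_mask, all_mask)
            res = _evaluate(objective, cand)
            ok = accept_candidate(st.result.key(), res.key())
            if ok:
                states[t] = ThreadState(cand, res)
            trace.append(_trace_row("gen1", t, i, 0, cand, res, ok))
    best = states[0]
    for st in states[1:]:
        if _better(st.result, best.result):
            best = st
    return SearchState("gen1", best.config, best.result, budget, states, trace, seed)


# ---------------------------------------------------------------------------
# Synchronized-thread step shared by GEN2/GEN3
# ---------------------------------------------------------------------------

def _synchronized_step(objective, streams, incumbent_cfg, incumbent_res,
                       d_ct, d_ig, ct_mask, dig_mask, algorithm, iteration,
                       phase, trace):
    """All threads perturb the shared incumbent; the best challenger (ties
    to the lowest thread index) replaces it if strictly better."""
    challenger_cfg, challenger_res = None, None
    for t, rng in enumerate(streams):
        cand = _perturb(rng, incumbent_cfg, d_ct, d_ig, ct_mask, dig_mask)
        res = _evaluate(objective, cand)
        if challenger_res is None or _better(res, challenger_res):
            challenger_cfg, challenger_res = cand, res
        trace.append(_trace_row(algorithm, t, iteration, phase, cand, res, False))
    ok = accept_candidate(incumbent_res.key(), challenger_res.key())
    if ok:
        incumbent_cfg, incumbent_res = challenger_cfg, challenger_res
        # annotate the winning row for the run log
        for row in trace[-len(streams):]:
            if (row["score"] == challenger_res.score_percent
                    and row["likelihood"] == challenger_res.likelihood):
                row["accepted"] = True
                break
    return incumbent_cfg, incumbent_res


def _phase_random_init(objective, streams, incumbent_cfg, incumbent_res,
                       ct_mask, dig_mask, algorithm, phase, trace,
                       randomize_dig: bool = True):
    """Full-range random draws on the masked parameters (one per thread),
    competing against the incumbent.  Not counted against the budget."""
    n = incumbent_cfg.ct_db_spl.size
    challenger_cfg, challenger_res = None, None
    for t, rng in enumerate(streams):
        rand = _random_config(rng, n)
        ct = np.where(ct_mask, rand.ct_db_spl, incumbent_cfg.ct_db_spl)
        dig = np.where(dig_mask if randomize_dig else np.zeros(n, bool),
                       rand.dig, incumbent_cfg.dig)
        cand = HAConfiguration(ct, dig)
        res = _evaluate(objective, cand)
        if challenger_res is None or _better(res, challenger_res):
            challenger_cfg, challenger_res = cand, res
        trace.append(_trace_row(algorithm, t, 0, phase, cand, res, False))
    if accept_candidate(incumbent_res.key(), challenger_res.key()):
        for row in trace[-len(streams):]:
            if (row["score"] == challenger_res.score_percent
                    and row["likelihood"] == challenger_res.likelihood):
                row["accepted"] = True
                break
        return challenger_cfg, challenger_res
    return incumbent_cfg, incumbent_res


# ---------------------------------------------------------------------------
# GEN2: channel by channel, synchronized threads, eq3 decay (global index)
# ---------------------------------------------------------------------------

def gen2_run(objective, per_channel_budget: int = 150,
             threads: int = DEFAULT_THREADS, seed: int = 0,
             n_channels: int = 5, baseline_config: HAConfiguration | None = None,
             schedules: dict | None = None) -> SearchState:
    """Run GEN2: tune (CT, IG offset) of channels 1→5 in turn.

    Untuned channels sit at the baseline configuration (offset 0, default
    CT); previously tuned channels stay frozen at their best values.  The
    eq3 half-range decay uses the global iteration index 1..750 across
    phases.  Each channel phase opens with one full-range random draw per
    thread (not counted against the budget).
    """
    total = per_channel_budget * n_channels
    if schedules is None:
        schedules = default_schedules("eq3", total)
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(seed).spawn(threads)]
    trace = []
    incumbent_cfg = baseline_config.copy() if baseline_config else HAConfiguration(
        np.full(n_channels, 35.0), np.zeros(n_channels))
    incumbent_res = _evaluate(objective, incumbent_cfg)
    trace.append(_trace_row("gen2", -1, 0, 0, incumbent_cfg, incumbent_res, True))
    i = 0
    for ch in range(1, n_channels + 1):
        mask = np.zeros(n_channels, bool)
        mask[ch - 1] = True
        incumbent_cfg, incumbent_res = _phase_random_init(
            objective, streams, incumbent_cfg, incumbent_res, mask, mask,
            "gen2", ch, trace)
        for _ in range(per_channel_budget):
            i += 1
            incumbent_cfg, incumbent_res = _synchronized_step(
                objective, streams, incumbent_cfg, incumbent_res,
                schedules["ct"].delta(i), schedules["ig"].delta(i),
                mask, mask, "gen2", i, ch, trace)
    states = [ThreadState(incumbent_cfg, incumbent_res)]
    return SearchState("gen2", incumbent_cfg, incumbent_res, i, states, trace, seed)


# ---------------------------------------------------------------------------
# GEN3: thresholds first (gains pinned), then gains; eq3 decay
# ---------------------------------------------------------------------------

def gen3_run(objective, ct_budget: int = 250, ig_budget: int = 500,
             threads: int = DEFAULT_THREADS, seed: int = 0,
             n_channels: int = 5, baseline_config: HAConfiguration | None = None,
             schedules: dict | None = None) -> SearchState:
    """Run GEN3: 250 iterations over all CTs (IG offsets pinned to the
    baseline), then 500 over all IG offsets (CTs frozen at their best)."""
    total = ct_budget + ig_budget
    if schedules is None:
        schedules = default_schedules("eq3", total)
    streams = [np.random.default_rng(s)
               for s in np.random.SeedSequence(seed).spawn(threads)]
    trace = []
    incumbent_cfg = baseline_config.copy() if baseline_config else HAConfiguration(
        np.full(n_channels, 35.0), np.zeros(n_channels))
    incumbent_res = _evaluate(objective, incumbent_cfg)
    trace.append(_trace_row("gen3", -1, 0, 0, incumbent_cfg, incumbent_res, True))
    all_mask = np.ones(n_channels, bool)
    none_mask = np.zeros(n_channels, bool)
    # phase 1: random CT draws then CT-only tuning
    incumbent_cfg, incumbent_res = _phase_random_init(
        objective, streams, incumbent_cfg, incumbent_res, all_mask, none_mask,
        "gen3", 1, trace, randomize_dig=False)
    i = 0
    for _ in range(ct_budget):
        i += 1
        incumbent_cfg, incumbent_res = _synchronized_step(
            objective, streams, incumbent_cfg, incumbent_res,
            schedules["ct"].delta(i), 0.0, all_mask, none_mask,
            "gen3", i, 1, trace)
    for _ in range(ig_budget):
        i += 1
        incumbent_cfg, incumbent_res = _synchronized_step(
            objective, streams, incumbent_cfg, incumbent_res,
            0.0, schedules["ig"].delta(i), none_mask, all_mask,
            "gen3", i, 2, trace)
    states = [ThreadState(incumbent_cfg, incumbent_res)]
    return SearchState("gen3", incumbent_cfg, incumbent_res, i, states, trace, seed)


ALGORITHMS = {"gen1": gen1_run, "gen2": gen2_run, "gen3": gen3_run}


def run_algorithm(name: str, objective, iterations: int = DEFAULT_ITERATIONS,
                  threads: int = DEFAULT_THREADS, seed: int = 0,
                  n_channels: int = 5, **kwargs) -> SearchState:
    """Dispatch by algorithm name with a single total-iteration budget.

    GEN2 splits the budget evenly over channels; GEN3 spends one third on
    thresholds and the rest on gains (250/500 at the full 750)."""
    if name == "gen1":
        return gen1_run(objective, budget=iterations, threads=threads, seed=seed,
                        n_channels=n_channels, **kwargs)
    if name == "gen2":
        return gen2_run(objective, per_channel_budget=max(1, iterations // n_channels),
                        threads=threads, seed=seed, n_channels=n_channels, **kwargs)
    if name == "gen3":
        ct_budget = max(1, iterations // 3)
        return gen3_run(objective, ct_budget=ct_budget,
                        ig_budget=max(1, iterations - ct_budget), threads=threads,
                        seed=seed, n_channels=n_channels, **kwargs)
    raise KeyError(f"unknown algorithm: {name!r}")


# ---------------------------------------------------------------------------
# Search-space accounting
# ---------------------------------------------------------------------------

def count_search_space(bank: ChannelBank | None = None,
                       ig_span: float = 20.0, ig_step: float = IG_STEP_DB,
                       ct_span: float = 30.0, ct_step: float = CT_STEP_DB) -> float:
    """Number of grid configurations: ((ig_span/ig_step)·(ct_span/ct_step))^C.

    Ranges are counted half-open, which with the study values gives
    (200·30)^5 = 6000^5 ≈ 7.78·10^18.
    """
    n_channels = bank.n_channels if bank is not None else 5
    counts = []
    for span, step in ((ig_span, ig_step), (ct_span, ct_step)):
        if span <= 0 or step <= 0:
            raise ValueError("spans and steps must be positive")
        ratio = span / step
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(f"span {span} is not a multiple of step {step}")
        counts.append(round(ratio))
    return float((counts[0] * counts[1]) ** n_channels)
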