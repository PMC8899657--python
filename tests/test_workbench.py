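import numpy as np
import pandas as pd
import pytest

from oprars.audiograms import synth_audiogram
from oprars.gain_constraints import HAConfiguration
from oprars.objective import token_metric
from oprars.prescription import ChannelBank, Prescription, baseline_prescription
from oprars.workbench import (SurrogateChainObjective, TokenChannelFeatures,
                              compare_repetitions, generate_tokens,
                              run_experiment)


class TestTokenGeneration:
    def test_seeded_determinism(self):
        a = generate_tokens(5, seed=1)
        b = generate_tokens(5, seed=1)
        for x, y in zip(a.tokens, b.tokens):
            assert np.array_equal(x.samples, y.samples)

    def test_calibrated_to_65_db_spl(self, small_tokens):
        for t in small_tokens.tokens:
            assert t.level_db_spl() == pytest.approx(65.0, abs=0.5)

    def test_pairwise_distinctness(self, small_tokens):
        """A token matches itself perfectly and other tokens less well."""
        toks = small_tokens.tokens
        from oprars.audio import CalibratedSignal
        for i in (0, 3):
            self_m = token_metric(toks[i], toks[i])
            assert self_m == pytest.approx(1.0)
            for j in range(len(toks)):
                if j == i:
                    continue
                n = min(toks[i].samples.size, toks[j].samples.size)
                cross = token_metric(
                    CalibratedSignal(toks[i].samples[:n], toks[i].sample_rate_hz),
                    CalibratedSignal(toks[j].samples[:n], toks[j].sample_rate_hz),
                    max_length_mismatch=1.0)
                assert cross < self_m


class TestSurrogateObjective:
    def test_quasi_static_matches_exact_detectors(self, small_tokens, bank):
        """The precomputed-level fast path reproduces the per-channel chain
        with exact detector smoothing to within 0.02 per token."""
        a = synth_audiogram(6, 2)
        base = baseline_prescription(a, bank)
        obj = SurrogateChainObjective(small_tokens, a, base, bank)
        rng = np.random.default_rng(0)
        for _ in range(2):
            cfg = HAConfiguration(np.round(rng.uniform(20, 50, 5)),
                                  np.round(rng.uniform(-10, 10, 5), 1))
            diff = np.abs(obj.metrics(cfg) - obj.metrics_exact(cfg))
            assert diff.max() <= 0.02

    def test_shared_features_give_identical_results(self, small_tokens, bank):
        a = synth_audiogram(5, 4)
        base = baseline_prescription(a, bank)
        feats = TokenChannelFeatures(small_tokens, bank)
        o1 = SurrogateChainObjective(small_tokens, a, base, bank, features=feats)
        o2 = SurrogateChainObjective(small_tokens, a, base, bank)
        cfg = HAConfiguration(np.full(5, 30.0), np.full(5, 4.0))
        assert np.allclose(o1.metrics(cfg), o2.metrics(cfg))

    def test_amplification_helps_a_moderate_flat_loss(self, small_tokens, bank):
        """Baseline amplification never scores below no amplification."""
        from oprars.audiograms import Audiogram
        a = Audiogram(thresholds_db_hl=np.full(11, 45.0))
        base = baseline_prescription(a, bank)
        obj = SurrogateChainObjective(small_tokens, a, base, bank)
        amplified = obj(HAConfiguration())
        none = SurrogateChainObjective(
            small_tokens, a,
            Prescription(),  # zero-gain prescription
            bank)(HAConfiguration())
        assert amplified.key() >= none.key()

    def test_dead_band_handled(self, small_tokens, bank):
        """Loss at the recruitment ceiling silences the band instead of
        blowing up the expansion."""
        from oprars.audiograms import Audiogram
        thr = np.full(11, 30.0)
        thr[-3:] = 105.0  # top channel beyond the 100-dB ceiling
        a = Audiogram(thresholds_db_hl=thr)
        base = baseline_prescription(a, bank)
        obj = SurrogateChainObjective(small_tokens, a, base, bank)
        res = obj(HAConfiguration())
        assert np.isfinite(res.likelihood)


@pytest.fixture(scope="module")
def small_experiment():
    auds = [synth_audiogram(4, 1), synth_audiogram(6, 2, jitter=4.0)]
    return run_experiment(auds, algorithm="gen1", repetitions=2,
                          base_seed=3, iterations=8, n_tokens=6)


class TestExperiment:
    def test_bookkeeping(self, small_experiment):
        df = small_experiment.summary
        assert len(df) == 4  # 2 audiograms x 2 repetitions
        assert not small_experiment.errors
        assert set(small_experiment.prescriptions) == {(0, 0), (0, 1),
                                                       (1, 0), (1, 1)}

    def test_optimized_at_least_baseline(self, small_experiment):
        df = small_experiment.summary
        assert (df.optimized_score >= df.baseline_score).all()

    def test_rerun_is_identical(self, small_experiment):
        auds = [synth_audiogram(4, 1), synth_audiogram(6, 2, jitter=4.0)]
        again = run_experiment(auds, algorithm="gen1", repetitions=2,
                               base_seed=3, iterations=8, n_tokens=6)
        pd.testing.assert_frame_equal(small_experiment.summary, again.summary)

    def test_partial_failure_recorded_not_raised(self):
        class Broken:
            label = "broken"

            def is_complete(self):
                raise RuntimeError("bad audiogram object")

        res = run_experiment([Broken(), synth_audiogram(4, 9)], algorithm="gen1",
                             repetitions=1, base_seed=1, iterations=4,
                             n_tokens=4)
        assert len(res.errors) == 1
        assert len(res.summary) == 1


class TestCompareRepetitions:
    def _prescription(self, gains, cts=None):
        return Prescription(ig_sp65=np.asarray(gains, float),
                            ig_sp85=np.asarray(gains, float) * 0.7,
                            ct_db_spl=np.asarray(cts if cts is not None
                                                 else np.full(5, 35.0), float))

    def test_identical_repetitions(self):
        p = self._prescription(np.linspace(5, 40, 11))
        df, summ = compare_repetitions([p], [p])
        assert summ["r_mean"] == pytest.approx(1.0)
        assert (df.filter(like="abs_dct").to_numpy() == 0).all()

    def test_constant_offset_preserves_correlation(self):
        g = np.linspace(5, 40, 11)
        df, summ = compare_repetitions([self._prescription(g)],
                                       [self._prescription(g + 4.0)])
        assert summ["r_mean"] == pytest.approx(1.0)

    def test_matches_textbook_pearson_formula(self):
        rng = np.random.default_rng(3)
        g1, g2 = rng.uniform(0, 50, 11), rng.uniform(0, 50, 11)
        df, _ = compare_repetitions([self._prescription(g1)],
                                    [self._prescription(g2)])
        n = 11
        num = n * (g1 * g2).sum() - g1.sum() * g2.sum()
        den = np.sqrt(n * (g1**2).sum() - g1.sum()**2) * \
            np.sqrt(n * (g2**2).sum() - g2.sum()**2)
        assert df.pearson_r[0] == pytest.approx(num / den)

    def test_ct_differences(self):
        p1 = self._prescription(np.linspace(5, 40, 11), [20, 30, 40, 50, 25])
        p2 = self._prescription(np.linspace(5, 40, 11), [25, 30, 35, 20, 45])
        df, _ = compare_repetitions([p1], [p2])
        assert df[[f"abs_dct_{c}" for c in range(1, 6)]].iloc[0].tolist() == \
            [5.0, 0.0, 5.0, 30.0, 20.0]

    def test_mismatched_sets_rejected(self):
        p = self._prescription(np.linspace(5, 40, 11))
        with pytest.raises(ValueError):
            compare_repetitions([p, p], [p])
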