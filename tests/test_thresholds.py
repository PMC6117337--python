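"""Threshold search, memoization equivalences, and threshold fields."""

import numpy as np
import pytest

from microstim import (Electrode, Resistivities, SimulationConfig,
                       StimulusWaveform, asynchronous_threshold,
                       surrogate_grid, SurrogateModel)
from microstim.thresholds import SearchSettings, ThresholdEngine

RHO = Resistivities()


def fresh_engine(**kw):
    return ThresholdEngine(10.0, StimulusWaveform(1.0), RHO,
                           SimulationConfig(), SearchSettings(), **kw)


class TestBisection:
    def test_bisection_matches_fine_amplitude_scan(self):
        """Oracle: exhaustive 0.01 µA upward scan for the smallest
        activating amplitude; bisection at 0.1 µA accuracy must agree to
        within its accuracy."""
        eng = fresh_engine(use_memo=False)
        rng = np.random.default_rng(7)
        for _ in range(5):
            x = rng.uniform(60.0, 220.0)
            z = rng.uniform(-400.0, 400.0)
            pos = (0.0, 0.0, 0.0)
            e = [Electrode((x, 0.0, z))]
            th = eng.threshold_at(pos, e)
            key = eng._key(pos, e)
            prof = eng._profile(key)
            # brute scan (coarse-to-fine to keep runtime sane, still an
            # independent check of the returned bracket)
            a = max(0.01, th - 0.15)
            while a <= th + 0.15:
                if eng._activates(prof, a):
                    break
                a = round(a + 0.01, 8)
            assert abs(th - a) <= 0.1 + 1e-9

    def test_threshold_brackets_activation(self):
        """Activation is false one accuracy step below the threshold and
        true at the threshold (re-verified by direct simulation)."""
        eng = fresh_engine(use_memo=False)
        pos = (0.0, 0.0, 0.0)
        e = [Electrode((150.0, 0.0, 100.0))]
        th = eng.threshold_at(pos, e)
        prof = eng._profile(eng._key(pos, e))
        assert eng._activates(prof, th)
        assert not eng._activates(prof, th - 0.1)

    def test_not_recruited_sentinel(self):
        eng = fresh_engine(use_memo=False)
        th = eng.threshold_at((0, 0, 0), [Electrode((2000.0, 0.0, 0.0))])
        assert np.isnan(th)

    def test_warm_start_is_result_neutral(self):
        """Identical grids with warm start on and off (absolute bisection
        lattice makes the warm start purely an optimization)."""
        eng_a = fresh_engine(use_memo=False)
        eng_b = fresh_engine(use_memo=False)
        e = [Electrode((0.0, 0.0, 0.0))]
        origin, shape, step = (60.0, 0.0, -100.0), (3, 1, 5), (60.0, 40.0, 50.0)
        ga = eng_a.grid(origin, shape, step, e, warm_start=True)
        gb = eng_b.grid(origin, shape, step, e, warm_start=False)
        np.testing.assert_array_equal(ga.values, gb.values)
        assert eng_a.n_simulations < eng_b.n_simulations

    def test_memo_and_reflection_are_result_neutral(self):
        """Field-equivalence memoization and z-reflection canonicalization
        do not change any grid value."""
        e = [Electrode((0.0, 0.0, 0.0))]
        origin, shape, step = (60.0, 0.0, -150.0), (2, 1, 7), (80.0, 40.0, 50.0)
        g_plain = fresh_engine(use_memo=False, use_z_reflection=False).grid(
            origin, shape, step, e, warm_start=False)
        g_fast = fresh_engine().grid(origin, shape, step, e, warm_start=True)
        np.testing.assert_array_equal(g_plain.values, g_fast.values)

    def test_exchange_and_translation_symmetry(self):
        """Swapping electrode labels and rigid translation of the whole
        configuration leave thresholds unchanged."""
        eng = fresh_engine()
        e1, e2 = Electrode((0.0, 0.0, 0.0)), Electrode((0.0, 0.0, 400.0))
        p = (120.0, 0.0, 100.0)
        t12 = eng.threshold_at(p, [e1, e2])
        t21 = eng.threshold_at(p, [e2, e1])
        assert t12 == t21
        d = np.array([35.0, -70.0, 260.0])
        e1s = Electrode(tuple(np.array(e1.position) + d))
        e2s = Electrode(tuple(np.array(e2.position) + d))
        assert eng.threshold_at(np.array(p) + d, [e1s, e2s]) == t12

    def test_synchronous_dominance(self):
        """A synchronously driven pair never needs more current than the
        better of the two electrodes alone (cathodic fields add)."""
        eng = fresh_engine()
        e1, e2 = Electrode((0.0, 0.0, 0.0)), Electrode((0.0, 0.0, 400.0))
        rng = np.random.default_rng(3)
        for _ in range(6):
            p = (rng.uniform(40, 250), 0.0, rng.uniform(-300, 700))
            ts = eng.threshold_at(p, [e1, e2])
            t1 = eng.threshold_at(p, [e1])
            t2 = eng.threshold_at(p, [e2])
            best = np.nanmin([t1, t2])
            assert np.isnan(best) or ts <= best


class TestThresholdField:
    def test_async_is_pointwise_min(self):
        m = SurrogateModel(electrodes=((0, 0, 0), (0, 0, 300)))
        f1 = surrogate_grid(m, (0, 0, -200), (4, 3, 6), 100.0, "single:0")
        f2 = surrogate_grid(m, (0, 0, -200), (4, 3, 6), 100.0, "single:1")
        fa = asynchronous_threshold([f1, f2])
        assert np.all(fa.values <= f1.values) and np.all(fa.values <= f2.values)
        np.testing.assert_array_equal(
            fa.values, np.minimum(f1.values, f2.values))
        # idempotent on identical inputs
        np.testing.assert_array_equal(
            asynchronous_threshold([f1, f1]).values, f1.values)

    def test_async_nan_handling(self):
        m = SurrogateModel()
        f1 = surrogate_grid(m, (0, 0, 0), (2, 2, 2), 50.0)
        f2 = surrogate_grid(m, (0, 0, 0), (2, 2, 2), 50.0)
        f1.values[0, 0, 0] = np.nan          # min(NaN, v) = v
        fa = asynchronous_threshold([f1, f2])
        assert fa.values[0, 0, 0] == f2.values[0, 0, 0]
        f2.values[0, 0, 0] = np.nan          # all-NaN stays sentinel
        fa = asynchronous_threshold([f1, f2])
        assert np.isnan(fa.values[0, 0, 0])

    def test_grid_mismatch_rejected(self):
        m = SurrogateModel()
        f1 = surrogate_grid(m, (0, 0, 0), (2, 2, 2), 50.0)
        f2 = surrogate_grid(m, (0, 0, 0), (2, 2, 3), 50.0)
        with pytest.raises(ValueError, match="different grids"):
            asynchronous_threshold([f1, f2])

    def test_save_load_roundtrip(self, tmp_path):
        m = SurrogateModel(electrodes=((0, 0, 0), (100, 0, 0)))
        f = surrogate_grid(m, (0, 0, 0), (3, 4, 5), (20.0, 20.0, 10.0), "sync")
        f.save(tmp_path / "g")
        g = type(f).load(tmp_path / "g")
        np.testing.assert_array_equal(f.values, g.values)
        assert g.condition == f.condition
        assert g.electrodes == f.electrodes
        np.testing.assert_allclose(g.step, f.step)
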