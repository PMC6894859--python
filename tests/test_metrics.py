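"""Cycle detection and the four gait parameters."""

import numpy as np
import pytest

import scrunchkit as sk
from scrunchkit.metrics import (Cycle, InsufficientOscillation, round_half_up,
                                select_window, smooth, summarize)
from scrunchkit.trace import LengthTrace
from conftest import scrunch_params


def make_trace(lengths, fps=10.0):
    lengths = np.asarray(lengths, dtype=float)
    return LengthTrace(times=np.arange(len(lengths)) / fps, lengths=lengths, fps=fps)


def make_cycle(t_start, t_peak, t_end, peak=2.0, trough=1.0, fps=10.0):
    return Cycle(t_start=t_start, t_peak=t_peak, t_end=t_end, L_peak=peak,
                 L_trough_low=trough, L_trough_mean=trough,
                 i_start=int(t_start * fps), i_peak=int(t_peak * fps),
                 i_end=int(t_end * fps))


class TestSmooth:
    def test_constant_unchanged(self):
        tr = make_trace(np.full(40, 7.0))
        assert np.array_equal(smooth(tr).lengths, tr.lengths)

    def test_noise_variance_reduced(self):
        rng = np.random.default_rng(0)
        tr = make_trace(100 + rng.normal(0, 5, 200))
        assert smooth(tr, 0.5).lengths.var() < tr.lengths.var()

    def test_boxcar_attenuation_matches_closed_form(self):
        # 3-sample boxcar on a 0.5 Hz sinusoid at 10 fps attenuates the
        # amplitude by (1 + 2 cos(2 pi f dt)) / 3
        f, fps = 0.5, 10.0
        t = np.arange(400) / fps
        tr = make_trace(100 + 10 * np.sin(2 * np.pi * f * t), fps=fps)
        out = smooth(tr, 0.3).lengths[50:-50] - 100
        expected = 10 * (1 + 2 * np.cos(2 * np.pi * f / fps)) / 3
        assert np.max(out) == pytest.approx(expected, rel=0.02)

    def test_window_too_small_rejected(self):
        with pytest.raises(ValueError):
            smooth(make_trace(np.ones(30) * 5), window_s=0.1)


class TestDetectCycles:
    def test_constant_trace_no_cycles(self):
        assert sk.detect_cycles(make_trace(np.full(100, 50.0))) == []

    def test_noise_free_five_cycles_with_true_boundaries(self):
        trace, truth = sk.generate_length_trace(scrunch_params())
        cycles = sk.detect_cycles(trace)
        assert len(cycles) == 5
        starts = [c.t_start for c in cycles] + [cycles[-1].t_end]
        np.testing.assert_allclose(starts, truth.true_cycle_boundaries, atol=0.1)

    def test_noisy_count_matches_truth_in_95_percent_of_seeds(self):
        hits = 0
        for seed in range(100):
            trace, truth = sk.generate_length_trace(
                scrunch_params(noise_sd=0.02, seed=seed))
            hits += len(sk.detect_cycles(trace)) == len(truth.true_cycle_boundaries) - 1
        assert hits >= 95

    def test_subthreshold_oscillation_ignored(self):
        t = np.arange(200) / 10
        tr = make_trace(100 + 2 * np.sin(2 * np.pi * 0.5 * t))  # 2% amplitude
        assert sk.detect_cycles(tr) == []


class TestSelectWindow:
    def test_six_clean_cycles_all_selected(self):
        cycles = [make_cycle(2 * k, 2 * k + 1.2, 2 * k + 2) for k in range(6)]
        window, chosen = select_window(cycles)
        assert window == (0.0, 12.0) and len(chosen) == 6

    def test_three_cycles_insufficient(self):
        cycles = [make_cycle(2 * k, 2 * k + 1.2, 2 * k + 2) for k in range(3)]
        assert isinstance(select_window(cycles), InsufficientOscillation)

    def test_bend_gap_shifts_window_to_later_run(self):
        early = [make_cycle(2 * k, 2 * k + 1.2, 2 * k + 2) for k in range(2)]
        bent = [make_cycle(4.0, 5.2, 6.0)]
        late = [make_cycle(6 + 2 * k, 6 + 2 * k + 1.2, 6 + 2 * k + 2) for k in range(5)]
        window, chosen = select_window(early + bent + late,
                                       bend_spans=[(4.5, 5.5)])
        assert window == (6.0, 16.0) and len(chosen) == 5


class TestSummarize:
    def test_formulas_on_constructed_cycles(self):
        cycles = [make_cycle(2 * k, 2 * k + 1.2, 2 * k + 2) for k in range(5)]
        tr = make_trace(np.full(101, 1.5))
        s = summarize(tr, cycles)
        assert s.frequency == pytest.approx(0.5)
        assert s.max_elongation == pytest.approx(0.5)   # (2-1)/2
        assert s.asymmetry == pytest.approx(0.6)
        assert s.speed == pytest.approx(s.frequency * s.max_elongation, abs=1e-15)

    def test_published_speed_product(self):
        # frequency 0.72 x elongation 0.52 -> printed speed 0.37
        assert round_half_up(0.72 * 0.52) == 0.37

    def test_symmetric_triangle_wave_asymmetry_half(self):
        one = np.concatenate([np.linspace(1, 2, 11), np.linspace(2, 1, 11)[1:]])
        tr = make_trace(np.concatenate([one[:-1]] * 6 + [one[-1:]]))
        s = sk.quantify_trace(tr, smooth_window_s=None)
        assert s.asymmetry == pytest.approx(0.5, abs=0.05)

    def test_empty_cycles_rejected(self):
        with pytest.raises(ValueError):
            summarize(make_trace(np.ones(10) * 4), [])


class TestCountScrunches:
    def test_constant_trace_zero(self):
        assert sk.count_scrunches(make_trace(np.full(100, 9.0))) == 0

    def test_pure_contraction_zero(self):
        assert sk.count_scrunches(make_trace(np.linspace(200, 100, 100))) == 0

    def test_contraction_then_cycles_counted(self):
        p = scrunch_params(duration_s=16.2, gliding_prelude_s=3.0)
        trace, truth = sk.generate_length_trace(p)
        expected = len(truth.true_cycle_boundaries) - 1
        assert sk.count_scrunches(trace) == expected == 7


class TestBatch:
    def test_single_worm_flagged_sd(self):
        s = sk.GaitSummary(frequency=0.5, max_elongation=0.4, speed=0.2,
                           asymmetry=0.6, n_cycles=5, window=(0, 10))
        df = sk.batch_summarize([s])
        assert (df["sd"] == 0).all() and not df["sd_defined"].any()
        assert df.set_index("parameter").loc["speed", "mean"] == 0.2

    def test_population_speed_is_mean_of_worm_speeds(self):
        mk = lambda f, A: sk.GaitSummary(frequency=f, max_elongation=A, speed=f * A,
                                         asymmetry=0.6, n_cycles=5, window=(0, 10))
        df = sk.batch_summarize([mk(1.0, 0.3), mk(1.0, 0.5)])
        assert df.set_index("parameter").loc["speed", "mean"] == pytest.approx(0.4)

    def test_population_recovery_from_sampled_worms(self):
        rng = np.random.default_rng(42)
        summaries = []
        for i in range(9):
            f = rng.normal(0.72, 0.08)
            trace, _ = sk.generate_length_trace(
                scrunch_params(frequency_hz=f, max_elongation=0.52, asymmetry=0.59,
                               duration_s=30.0, noise_sd=0.01, seed=int(i)))
            summaries.append(sk.quantify_trace(trace))
        df = sk.batch_summarize(summaries).set_index("parameter")
        se = 0.08 / np.sqrt(9)
        assert abs(df.loc["frequency", "mean"] - 0.72) < 2 * se + 0.01


class TestInvariants:
    def test_speed_identity_exact(self):
        for seed in range(5):
            trace, _ = sk.generate_length_trace(
                scrunch_params(duration_s=30.0, noise_sd=0.02, seed=seed))
            s = sk.quantify_trace(trace)
            assert s.speed == s.frequency * s.max_elongation

    def test_time_shift_invariance(self):
        base = scrunch_params(frequency_hz=0.72, max_elongation=0.52,
                              asymmetry=0.59, duration_s=30.0)
        shifted = scrunch_params(frequency_hz=0.72, max_elongation=0.52,
                                 asymmetry=0.59, duration_s=30.0,
                                 gliding_prelude_s=5.0)
        s1 = sk.quantify_trace(sk.generate_length_trace(base)[0])
        s2 = sk.quantify_trace(sk.generate_length_trace(shifted)[0])
        assert s2.frequency == pytest.approx(s1.frequency, rel=0.01)
        assert s2.max_elongation == pytest.approx(s1.max_elongation, abs=0.01)
        assert s2.asymmetry == pytest.approx(s1.asymmetry, abs=0.01)


def test_round_half_up_ties_away_from_zero():
    assert round_half_up(0.375) == 0.38
    assert round_half_up(0.365) == 0.37
    assert round_half_up(0.08399999, 2) == 0.08
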