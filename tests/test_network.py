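"""Interactive-activation dynamics, GLA and multiple read-out decisions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mromgla import (
    ActivationTrace,
    InteractiveActivationModel,
    Lexicon,
    ModelParams,
    activation_step,
    global_lexical_activity,
    simulate_lexical_decision,
    z_transform,
)

from _oracles import naive_word_trace


class TestNetworkStructure:
    def test_unit_counts_and_connectivity(self, toy_lexicon):
        m = InteractiveActivationModel(toy_lexicon)
        assert m._E.shape[0] == 4
        # "cat" excited exactly by c@1, a@2, t@3
        wi = toy_lexicon.words.index("cat")
        on = np.flatnonzero(m._E[wi])
        K = len(m.alphabet)
        assert [(i // K, m.alphabet[i % K]) for i in on] == [(0, "c"), (1, "a"), (2, "t")]

    def test_equal_log_frequency_gives_equal_rest(self):
        lex = Lexicon.from_entries([("cat", 5.0), ("dog", 5.0), ("pig", 50.0)])
        m = InteractiveActivationModel(lex)
        r = dict(zip(lex.words, m.rest))
        assert r["cat"] == r["dog"] < r["pig"] == 0.0

    def test_single_word_rests_at_top_of_range(self):
        m = InteractiveActivationModel(Lexicon.from_entries([("work", 3.0)]))
        assert m.rest[0] == 0.0

    def test_empty_lexicon_rejected(self):
        with pytest.raises(Exception):
            InteractiveActivationModel(Lexicon.from_entries([]))


class TestRunTrial:
    def test_cycle_zero_is_resting_state(self, toy_lexicon):
        m = InteractiveActivationModel(toy_lexicon)
        tr = m.run_trial("cat", 5)
        assert np.array_equal(tr.words[0], m.resting_state)
        assert np.all(tr.letters[0] == 0)

    def test_matching_word_rises_monotonically(self):
        m = InteractiveActivationModel(Lexicon.from_entries([("work", 10.0)]))
        tr = m.run_trial("work", 7)
        acts = tr.words[1:, 0]
        assert np.all(np.diff(acts) > 0)
        assert acts[-1] > 0.5

    def test_disjoint_stimulus_keeps_words_nonpositive(self, micro):
        lexicon, _, params = micro
        m = InteractiveActivationModel(lexicon, params)
        tr = m.run_trial("gost", 10)  # shares no letter-at-position with any word
        assert np.all(tr.words <= 0)

    def test_zero_cycles_rejected(self, toy_lexicon):
        m = InteractiveActivationModel(toy_lexicon)
        with pytest.raises(ValueError):
            m.run_trial("cat", 0)

    def test_overlong_stimulus_rejected(self, toy_lexicon):
        m = InteractiveActivationModel(toy_lexicon)
        with pytest.raises(ValueError, match="position channels"):
            m.run_trial("catdog", 3)

    def test_resting_state_is_fixed_point_without_stimulus(self, micro):
        lexicon, _, params = micro
        m = InteractiveActivationModel(lexicon, params)
        tr = m.run_trial("", 10)
        for c in range(11):
            assert np.allclose(tr.words[c], m.resting_state, atol=1e-12)
            assert np.allclose(tr.letters[c], 0.0, atol=1e-12)

    def test_determinism_bit_identical(self, micro):
        lexicon, _, params = micro
        m1 = InteractiveActivationModel(lexicon, params)
        m2 = InteractiveActivationModel(lexicon, params)
        t1, t2 = m1.run_trial("lamp", 15), m2.run_trial("lamp", 15)
        assert np.array_equal(t1.words, t2.words)
        assert np.array_equal(t1.letters, t2.letters)

    def test_matches_naive_recomputation(self, micro):
        lexicon, stimuli, params = micro
        m = InteractiveActivationModel(lexicon, params)
        for stim, _ in stimuli:
            tr = m.run_trial(stim, 12)
            hist = naive_word_trace(lexicon.entries, lexicon.alphabet, params, stim, 12)
            for c in range(1, 13):
                mine = dict(zip(tr.word_labels, tr.words[c]))
                for w, a in hist[c - 1].items():
                    assert abs(mine[w] - a) < 1e-10

    def test_boundedness_under_random_parameters(self):
        rng = np.random.default_rng(5)
        lex = Lexicon.from_entries([("cat", 50.0), ("cot", 5.0), ("dog", 1.0)])
        for _ in range(5):
            p = ModelParams(
                excite_letter_word=float(rng.uniform(0, 0.5)),
                inhibit_letter_word=float(rng.uniform(0, 0.5)),
                inhibit_word_word=float(rng.uniform(0, 0.5)),
                feedback_word_letter=float(rng.uniform(0, 0.5)),
                decay=float(rng.uniform(0, 0.3)),
                input_clamp=float(rng.uniform(0, 2.0)),
            )
            m = InteractiveActivationModel(lex, p)
            tr = m.run_trial("cat", 2000)
            assert tr.words.min() >= p.a_min - 1e-12
            assert tr.words.max() <= p.a_max + 1e-12
            assert tr.letters.min() >= p.a_min - 1e-12
            assert tr.letters.max() <= p.a_max + 1e-12


class TestActivationStep:
    @pytest.mark.parametrize("net", [0.05, 0.2, 0.6])
    @pytest.mark.parametrize("decay", [0.03, 0.07, 0.2])
    @pytest.mark.parametrize("rest", [-0.2, -0.1, 0.0])  # fixed point must lie in bounds
    def test_isolated_unit_converges_to_closed_form(self, net, decay, rest):
        p = ModelParams(decay=decay)
        a = rest
        for _ in range(3000):
            a = float(activation_step(a, net, rest, p))
        expected = (net * p.a_max + decay * rest) / (net + decay)
        assert abs(a - expected) < 1e-8


class TestGLA:
    def test_zero_when_all_word_activity_nonpositive(self, micro):
        lexicon, _, params = micro
        m = InteractiveActivationModel(lexicon, params)
        assert m.gla("gost") == 0.0

    def test_arithmetic_mean_of_summed_positive(self):
        p = ModelParams()
        trace = ActivationTrace(
            stimulus="x",
            letters=np.zeros((4, 1, 1)),
            words=np.array([[0.0], [0.1], [0.2], [0.3]]),
            word_labels=("w",),
            params=p,
        )
        assert global_lexical_activity(trace, 3) == pytest.approx(0.2)

    def test_window_exceeding_trace_rejected(self, toy_lexicon):
        m = InteractiveActivationModel(toy_lexicon)
        tr = m.run_trial("cat", 5)
        with pytest.raises(ValueError, match="window"):
            global_lexical_activity(tr, 6)

    def test_extra_neighbor_raises_gla_without_lateral_inhibition(self):
        p = ModelParams(inhibit_word_word=0.0)
        small = Lexicon.from_entries([("lamp", 10.0), ("damp", 10.0)])
        large = Lexicon.from_entries([("lamp", 10.0), ("damp", 10.0), ("ramp", 10.0)])
        g_small = InteractiveActivationModel(small, p).gla("lamp")
        g_large = InteractiveActivationModel(large, p).gla("lamp")
        assert g_large > g_small


class TestZTransform:
    def test_three_point_example(self):
        assert np.allclose(z_transform([1, 2, 3]), [-1, 0, 1])

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            z_transform([2.0, 2.0, 2.0])

    @settings(derandomize=True, max_examples=30)
    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=3, max_size=40).filter(
            lambda xs: max(xs) - min(xs) > 1e-6
        )
    )
    def test_output_standardized(self, xs):
        z = z_transform(xs)
        assert abs(z.mean()) < 1e-9
        assert abs(z.std(ddof=1) - 1) < 1e-9


class TestLexicalDecision:
    def test_own_word_identified_before_deadline(self):
        m = InteractiveActivationModel(Lexicon.from_entries([("work", 10.0)]))
        d = m.decide("work")
        assert d.response == "YES"
        assert d.criterion in ("M", "S")
        assert d.rt_cycles < m.params.t_base

    def test_disjoint_stimulus_times_out_at_base_deadline(self, micro):
        lexicon, _, params = micro
        m = InteractiveActivationModel(lexicon, params)
        d = m.decide("gost")
        assert (d.response, d.criterion) == ("NO", "T")
        assert d.rt_cycles == params.t_base  # g = 0 at adjustment: no shift
        assert d.gla_at_adjust == 0.0

    def test_high_overlap_nonword_delays_deadline(self, micro):
        lexicon, _, params = micro
        m = InteractiveActivationModel(lexicon, params)
        dense = m.decide("lanp")
        sparse = m.decide("gost")
        assert dense.gla_at_adjust > sparse.gla_at_adjust
        if dense.criterion == "T":
            assert dense.rt_cycles > sparse.rt_cycles

    def test_params_override_rebuilds_readout(self, micro):
        lexicon, _, params = micro
        m = InteractiveActivationModel(lexicon, params)
        from dataclasses import replace

        strict = replace(params, m_criterion=0.99, s_base=99.0, t_base=5)
        d = simulate_lexical_decision("lamp", m, strict)
        assert (d.response, d.criterion, d.rt_cycles) == ("NO", "T", 5 + round(strict.t_gain * d.gla_at_adjust))


class TestModelParamsIO:
    def test_roundtrip_through_config_file(self, tmp_path):
        p = ModelParams(decay=0.11, t_base=33, rest_range=(-0.5, 0.0))
        path = tmp_path / "params.cfg"
        p.to_file(path)
        assert ModelParams.from_file(path) == p

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(a_min=0.1)
        with pytest.raises(ValueError):
            ModelParams(decay=-0.1)
        with pytest.raises(ValueError):
            ModelParams(gla_cycles=0)
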