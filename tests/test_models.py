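import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from recatmem import (
    ExemplarStore,
    ModelParams,
    SequenceContext,
    exemplar_predict,
    forgetting_predict,
    make_uniform_sequence,
    memory_strength,
    mixture_predict,
    predict_sequence,
    prototype_predict,
)
from recatmem.models import store_at_trial

EQUAL_W = np.full(6, 1 / 6)


def loop_prototype(features, w, c, prototypes):
    """Plain-python oracle for the prototype choice rule."""
    d_a = sum(wi * abs(x - p) for wi, x, p in zip(w, features, prototypes[0]))
    d_b = sum(wi * abs(x - p) for wi, x, p in zip(w, features, prototypes[1]))
    s_a, s_b = math.exp(-c * d_a), math.exp(-c * d_b)
    return s_a / (s_a + s_b)


def loop_exemplar(features, w, c, store, beta=0.0, current_trial=None):
    """Plain-python oracle: token-by-token summed similarity, optional decay."""
    s_a = s_b = 0.0
    for tok, cat, at in zip(store.features, store.categories, store.stored_at):
        d = sum(wi * abs(x - y) for wi, x, y in zip(w, features, tok))
        sim = math.exp(-c * d)
        if beta:
            sim *= (current_trial - at) ** (-beta)
        if cat == "A":
            s_a += sim
        else:
            s_b += sim
    total = s_a + s_b
    return 0.5 if total == 0 else s_a / total


def random_store(rng, n_tokens, m=6, max_trial=100):
    feats = rng.integers(0, 2, size=(n_tokens, m)).astype(float)
    cats = np.where(rng.random(n_tokens) < 0.5, "A", "B")
    at = np.sort(rng.choice(np.arange(1, max_trial), size=n_tokens, replace=False))
    return ExemplarStore(feats, cats, at)


class TestHandValues:
    def test_prototype_at_own_prototype(self, structure):
        p = prototype_predict((0,) * 6, EQUAL_W, 1.0, structure.prototype_matrix)
        assert p == pytest.approx(1 / (1 + math.exp(-1)), abs=1e-12)

    def test_prototype_misclassifies_exception(self, structure):
        exc = next(
            s for s in structure.stimuli
            if s.role == "exception" and s.category == "A"
        )
        p = prototype_predict(exc.features, EQUAL_W, 1.0, structure.prototype_matrix)
        assert p == pytest.approx(1 / (1 + math.exp(4 / 6)), abs=1e-12)
        assert p < 0.5

    def test_zero_sensitivity_is_chance(self, structure, rng):
        feats = rng.integers(0, 2, 6)
        assert prototype_predict(
            feats, EQUAL_W, 0.0, structure.prototype_matrix
        ) == pytest.approx(0.5)

    def test_exemplar_two_prototype_store(self, structure):
        store = ExemplarStore(
            structure.prototype_matrix, np.array(["A", "B"]), np.array([1, 2])
        )
        p = exemplar_predict((0,) * 6, EQUAL_W, 1.0, store)
        assert p == pytest.approx(1 / (1 + math.exp(-1)), abs=1e-12)

    @pytest.mark.parametrize(
        "delay,beta,expected",
        [(1, 0.7, 1.0), (5, 0.0, 1.0), (2, 0.7, 2 ** -0.7)],
    )
    def test_memory_strength(self, delay, beta, expected):
        assert memory_strength(delay, beta) == pytest.approx(expected, abs=1e-12)

    def test_memory_strength_rejects_zero_delay(self):
        with pytest.raises(ValueError):
            memory_strength(0, 0.7)

    def test_forgetting_recency_dominates(self):
        # identical features: similarities cancel, only trace strengths matter
        store = ExemplarStore(
            np.zeros((2, 6)), np.array(["B", "A"]), np.array([1, 100])
        )
        p = forgetting_predict((0,) * 6, EQUAL_W, 3.0, 0.7, store, 101)
        assert p == pytest.approx(1 / (1 + 100 ** -0.7), abs=1e-12)

    def test_forgetting_rejects_future_tokens(self):
        store = ExemplarStore(np.zeros((1, 6)), np.array(["A"]), np.array([5]))
        with pytest.raises(ValueError):
            forgetting_predict((0,) * 6, EQUAL_W, 1.0, 0.7, store, 5)


class TestStoreBehaviour:
    def test_empty_store_is_chance(self):
        store = ExemplarStore.empty(6)
        assert exemplar_predict((1,) * 6, EQUAL_W, 5.0, store) == 0.5

    def test_one_sided_store(self):
        store = ExemplarStore(np.zeros((3, 6)), np.array(["A"] * 3), np.arange(1, 4))
        assert exemplar_predict((0,) * 6, EQUAL_W, 2.0, store) == 1.0

    def test_duplicated_store_invariance(self, rng):
        store = random_store(rng, 8)
        k3 = ExemplarStore(
            np.tile(store.features, (3, 1)),
            np.tile(store.categories, 3),
            np.repeat(store.stored_at, 3),  # keep sorted
        )
        probe = rng.integers(0, 2, 6)
        assert exemplar_predict(probe, EQUAL_W, 4.0, k3) == pytest.approx(
            exemplar_predict(probe, EQUAL_W, 4.0, store), abs=1e-12
        )


class TestNesting:
    def test_beta_zero_equals_exemplar(self, rng):
        for _ in range(20):
            store = random_store(rng, 12)
            probe = rng.integers(0, 2, 6)
            c = rng.uniform(0, 10)
            assert forgetting_predict(
                probe, EQUAL_W, c, 0.0, store, 101
            ) == pytest.approx(exemplar_predict(probe, EQUAL_W, c, store), abs=1e-12)

    def test_equal_delays_equal_exemplar(self, rng):
        feats = rng.integers(0, 2, size=(6, 6)).astype(float)
        cats = np.array(["A", "B", "A", "B", "B", "A"])
        store = ExemplarStore(feats, cats, np.full(6, 40))
        probe = rng.integers(0, 2, 6)
        assert forgetting_predict(
            probe, EQUAL_W, 3.0, 1.3, store, 50
        ) == pytest.approx(exemplar_predict(probe, EQUAL_W, 3.0, store), abs=1e-12)

    @pytest.mark.parametrize("alpha", [0.0, 1.0])
    def test_mixture_endpoints(self, structure, rng, alpha):
        store = random_store(rng, 10)
        probe = rng.integers(0, 2, 6)
        p = mixture_predict(
            probe, EQUAL_W, 2.0, 4.0, alpha, store, structure.prototype_matrix
        )
        expected = (
            prototype_predict(probe, EQUAL_W, 2.0, structure.prototype_matrix)
            if alpha == 1.0
            else exemplar_predict(probe, EQUAL_W, 4.0, store)
        )
        assert p == pytest.approx(expected, abs=1e-12)

    def test_mixture_midpoint_arithmetic(self, structure, rng):
        store = random_store(rng, 10)
        probe = rng.integers(0, 2, 6)
        p = mixture_predict(
            probe, EQUAL_W, 2.0, 4.0, 0.5, store, structure.prototype_matrix
        )
        p_p = prototype_predict(probe, EQUAL_W, 2.0, structure.prototype_matrix)
        p_e = exemplar_predict(probe, EQUAL_W, 4.0, store)
        assert p == pytest.approx(0.5 * p_p + 0.5 * p_e, abs=1e-12)

    def test_response_scaling_gamma_one_special_case(self, rng):
        # a response-scaled rule sum(s)^g / (sum(s)^g + sum(s)^g) reduces to
        # the implemented rule at g = 1
        store = random_store(rng, 9)
        probe = rng.integers(0, 2, 6)
        c = 3.0
        s_a = s_b = 0.0
        for tok, cat in zip(store.features, store.categories):
            sim = math.exp(-c * sum(EQUAL_W * np.abs(probe - tok)))
            if cat == "A":
                s_a += sim
            else:
                s_b += sim
        g = 1.0
        scaled = s_a**g / (s_a**g + s_b**g)
        assert exemplar_predict(probe, EQUAL_W, c, store) == pytest.approx(
            scaled, abs=1e-12
        )


class TestOracleEquivalence:
    def test_vectorized_equals_loop(self, structure, rng):
        protos = structure.prototype_matrix
        for _ in range(100):
            n_tok = int(rng.integers(1, 20))
            store = random_store(rng, n_tok)
            probe = rng.integers(0, 2, 6)
            w = rng.dirichlet(np.ones(6))
            c = float(rng.uniform(0, 12))
            beta = float(rng.uniform(0, 2))
            assert prototype_predict(probe, w, c, protos) == pytest.approx(
                loop_prototype(probe, w, c, protos), abs=1e-12
            )
            assert exemplar_predict(probe, w, c, store) == pytest.approx(
                loop_exemplar(probe, w, c, store), abs=1e-12
            )
            assert forgetting_predict(
                probe, w, c, beta, store, 101
            ) == pytest.approx(
                loop_exemplar(probe, w, c, store, beta, 101), abs=1e-12
            )

    def test_sequence_trace_equals_per_trial_loop(self, structure):
        seq = make_uniform_sequence(structure, 5, 3)  # 70 trials
        params = ModelParams("exemplar_forgetting", EQUAL_W, c=6.0, beta=0.7)
        trace = predict_sequence(params, seq, structure)
        by_id = {s.id: s for s in structure.stimuli}
        for t in range(1, seq.n_trials + 1):
            store = store_at_trial(seq, structure, t)
            probe = by_id[int(seq.stimulus_ids[t - 1])].features
            expected = loop_exemplar(probe, EQUAL_W, 6.0, store, 0.7, t)
            assert trace[t - 1] == pytest.approx(expected, abs=1e-12)

    def test_exemplar_trace_drifts_with_history(self, structure):
        seq = make_uniform_sequence(structure, 10, 4)
        params = ModelParams("exemplar", EQUAL_W, c=6.0)
        trace = predict_sequence(params, seq, structure)
        sid = seq.stimulus_ids
        reps = trace[sid == sid[0]]
        assert len(np.unique(np.round(reps, 12))) > 1


class TestSequenceTrace:
    def test_first_trial_is_chance(self, structure, uniform_seq):
        params = ModelParams("exemplar", EQUAL_W, c=8.0)
        trace = predict_sequence(params, uniform_seq, structure)
        assert trace[0] == 0.5

    def test_trace_bounds(self, structure, uniform_seq):
        params = ModelParams("exemplar_forgetting", EQUAL_W, c=9.0, beta=1.0)
        trace = predict_sequence(params, uniform_seq, structure)
        assert np.all(trace >= 0) and np.all(trace <= 1)

    def test_prototype_trace_history_free(self, structure, uniform_seq):
        params = ModelParams("prototype", EQUAL_W, c=3.0)
        trace = predict_sequence(params, uniform_seq, structure)
        sid = uniform_seq.stimulus_ids
        for s in np.unique(sid):
            assert len(np.unique(trace[sid == s])) == 1

    def test_per_trial_c_matches_scalar_when_constant(self, structure, uniform_seq):
        ctx = SequenceContext(uniform_seq, structure)
        a = ctx.exemplar_trace(EQUAL_W, 7.0, 0.5)
        b = ctx.exemplar_trace(EQUAL_W, np.full(616, 7.0), 0.5)
        assert np.allclose(a, b, atol=1e-14)


class TestProperties:
    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_forgetting_monotone_in_opposite_delay(self, seed):
        # aging only the opposite-category tokens raises P(own category)
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        store = random_store(rng, n, max_trial=50)
        if len(set(store.categories)) < 2:
            return
        probe = rng.integers(0, 2, 6)
        w = rng.dirichlet(np.ones(6))
        c = float(rng.uniform(0, 8))
        shift = int(rng.integers(5, 40))
        aged_at = np.where(
            store.categories == "B", store.stored_at - shift, store.stored_at
        )
        order = np.argsort(aged_at, kind="stable")
        aged = ExemplarStore(
            store.features[order], store.categories[order], aged_at[order]
        )
        p0 = forgetting_predict(probe, w, c, 0.8, store, 60)
        p1 = forgetting_predict(probe, w, c, 0.8, aged, 60)
        assert p1 >= p0 - 1e-12

    def test_free_parameter_counts(self):
        w = EQUAL_W
        assert ModelParams("prototype", w, c=1.0).n_free == 6
        assert ModelParams("exemplar", w, c=1.0).n_free == 6
        assert ModelParams("exemplar_forgetting", w, c=1.0, beta=0.5).n_free == 7
        assert (
            ModelParams("mixture", w, c_proto=1.0, c_exem=1.0, alpha=0.5).n_free == 8
        )
        assert (
            ModelParams(
                "mixture", w, c_proto=1.0, c_exem=1.0, alpha=np.full(11, 0.5)
            ).n_free
            == 18
        )

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ModelParams("prototype", np.full(6, 0.5), c=1.0)  # not a simplex
        with pytest.raises(ValueError):
            ModelParams("exemplar", EQUAL_W, c=-1.0)
        with pytest.raises(ValueError):
            ModelParams("mixture", EQUAL_W, c_proto=1.0, c_exem=1.0, alpha=1.5)
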