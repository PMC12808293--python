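import numpy as np
import pytest

from recatmem import (
    FitSpec,
    ModelParams,
    SequenceContext,
    SimulationProtocol,
    fit,
    fit_condition,
    fit_nested,
    mse_objective,
    predict_sequence,
    simulate_cohort,
    sse_objective,
)
from recatmem.fitting import results_to_frame

EQUAL_W = np.full(6, 1 / 6)


class TestObjectives:
    def test_sse_zero_on_perfect_match(self):
        sid = np.array([0, 0, 1, 1, 2])
        resp = np.array([1, 0, 1, 1, 0], float)
        # per-stimulus predictions equal to observed proportions
        trace = np.array([0.5, 0.5, 1.0, 1.0, 0.0])
        assert sse_objective(trace, resp, sid) == pytest.approx(0.0, abs=1e-15)

    def test_sse_single_off_by_half(self):
        sid = np.array([0, 1])
        resp = np.array([1.0, 1.0])
        trace = np.array([0.5, 1.0])
        assert sse_objective(trace, resp, sid) == pytest.approx(0.25)

    def test_sse_three_stimulus_hand_sum(self):
        # hand-summed: (0.8-1)^2 + (0.3-0)^2 + (0.6-0.5)^2
        sid = np.array([0, 1, 2, 2])
        resp = np.array([1.0, 0.0, 1.0, 0.0])
        trace = np.array([0.8, 0.3, 0.6, 0.6])
        expected = 0.04 + 0.09 + 0.01
        assert sse_objective(trace, resp, sid) == pytest.approx(expected, abs=1e-12)

    def test_sse_order_invariant_within_segment(self, rng):
        sid = rng.integers(0, 5, 40)
        resp = rng.integers(0, 2, 40).astype(float)
        trace = rng.random(40)
        perm = rng.permutation(40)
        assert sse_objective(trace, resp, sid) == pytest.approx(
            sse_objective(trace[perm], resp[perm], sid[perm]), abs=1e-12
        )

    def test_sse_empty_segment_rejected(self):
        with pytest.raises(ValueError):
            sse_objective(np.array([0.5]), np.array([1.0]), np.array([0]), trials=[])

    def test_mse_perfect_and_chance(self):
        resp = np.array([1, 0, 1, 1], float)
        assert mse_objective(resp, resp) == 0.0
        assert mse_objective(np.full(4, 0.5), resp) == pytest.approx(0.25)

    def test_mse_hand_computed(self, rng):
        trace = rng.random(10)
        resp = rng.integers(0, 2, 10).astype(float)
        expected = sum((p - r) ** 2 for p, r in zip(trace, resp)) / 10
        assert mse_objective(trace, resp) == pytest.approx(expected, abs=1e-12)

    def test_mse_permutation_invariant(self, rng):
        trace, resp = rng.random(30), rng.integers(0, 2, 30).astype(float)
        perm = rng.permutation(30)
        assert mse_objective(trace, resp) == pytest.approx(
            mse_objective(trace[perm], resp[perm]), abs=1e-12
        )


class TestFit:
    def test_prototype_recovery_from_noiseless_proportions(self, structure):
        # responses given as exact per-trial probabilities: at the generating
        # parameters the segment proportions match exactly, so SSE -> 0
        from recatmem import make_uniform_sequence

        seq = make_uniform_sequence(structure, 8, 11)
        truth = ModelParams("prototype", EQUAL_W, c=3.0)
        trace = predict_sequence(truth, seq, structure)
        spec = FitSpec(objective="sse_segment", n_restarts=6, seed=0)
        res = fit("prototype", trace, seq, structure, spec)
        assert res.objective_value < 1e-6
        assert res.params.c == pytest.approx(3.0, abs=0.3)
        assert np.allclose(res.params.w, EQUAL_W, atol=0.05)

    def test_weights_on_simplex(self, structure, small_cohort):
        resp = small_cohort.response_a("control", 0)
        seq = small_cohort.sequences[("control", 0)]
        spec = FitSpec(objective="mse_trials", n_restarts=3, seed=1)
        res = fit("exemplar", resp, seq, structure, spec)
        assert res.params.w.sum() == pytest.approx(1.0, abs=1e-6)
        assert res.objective_value >= 0

    def test_fixed_beta_zero_equals_exemplar_fit(self, structure, small_cohort):
        resp = small_cohort.response_a("control", 0)
        seq = small_cohort.sequences[("control", 0)]
        spec = FitSpec(objective="mse_trials", n_restarts=3, seed=2)
        base = fit("exemplar", resp, seq, structure, spec)
        spec0 = FitSpec(objective="mse_trials", n_restarts=3, seed=2, fix_beta=0.0)
        forg = fit("exemplar_forgetting", resp, seq, structure, spec0)
        assert forg.objective_value == pytest.approx(
            base.objective_value, abs=1e-12
        )

    def test_nested_families_never_fit_worse(self, structure, small_cohort):
        resp = small_cohort.response_a("control", 0)
        seq = small_cohort.sequences[("control", 0)]
        spec = FitSpec(objective="mse_trials", n_restarts=3, seed=3)
        ctx = SequenceContext(seq, structure)
        base = fit("exemplar", resp, seq, structure, spec, ctx=ctx)
        proto = fit("prototype", resp, seq, structure, spec, ctx=ctx)
        forg = fit_nested("exemplar_forgetting", resp, seq, structure, spec, ctx=ctx)
        mix = fit_nested("mixture", resp, seq, structure, spec, ctx=ctx)
        assert forg.objective_value <= base.objective_value + 1e-9
        assert mix.objective_value <= min(
            base.objective_value, proto.objective_value
        ) + 1e-9


class TestFitCondition:
    def test_control_sse_yields_one_fit_per_segment(self, small_cohort):
        spec = FitSpec(objective="sse_segment", n_restarts=2, seed=4)
        res = fit_condition(small_cohort, "control", "prototype", spec)
        n_p = len(small_cohort.participants("control"))
        assert len(res) == 11 * n_p
        assert {r.segment for r in res} == set(range(1, 12))

    def test_experimental_fits_whole_experiment(self, small_cohort):
        spec = FitSpec(objective="mse_trials", n_restarts=2, seed=4)
        res = fit_condition(small_cohort, "experimental", "prototype", spec)
        assert len(res) == len(small_cohort.participants("experimental"))
        assert all(r.segment is None for r in res)

    def test_experimental_mixture_alpha_vector(self, small_cohort):
        spec = FitSpec(objective="mse_trials", n_restarts=1, seed=4)
        res = fit_condition(
            small_cohort, "experimental", "mixture", spec, nested=False
        )
        alpha = np.atleast_1d(np.asarray(res[0].params.alpha))
        assert alpha.shape == (11,)
        assert res[0].params.n_free == 18

    def test_absent_condition_gives_empty_list(self, small_cohort_control_only):
        spec = FitSpec(objective="mse_trials", n_restarts=1, seed=0)
        res = fit_condition(
            small_cohort_control_only, "experimental", "exemplar", spec
        )
        assert res == []

    def test_results_frame_schema(self, small_cohort):
        spec = FitSpec(objective="mse_trials", n_restarts=1, seed=4)
        res = fit_condition(small_cohort, "control", "exemplar", spec)
        df = results_to_frame(res)
        assert {"participant", "condition", "family", "value", "c"} <= set(
            df.columns
        )
        assert len(df) == len(res)


@pytest.fixture(scope="module")
def small_cohort():
    protocol = SimulationProtocol(n_participants=2, seed=42)
    return simulate_cohort(protocol)


@pytest.fixture(scope="module")
def small_cohort_control_only():
    protocol = SimulationProtocol(
        n_participants=2, seed=42, conditions=("control",)
    )
    return simulate_cohort(protocol)
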