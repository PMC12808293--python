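"""Constrained model fitting under the two fit statistics.

Two objectives are supported, matching how the learning curves are analysed:

* **SSE** over a trial segment: for each stimulus shown in the segment,
  compare the model's mean predicted P(A) with the observed proportion of A
  responses, and sum the squared differences over stimuli. Stimuli absent
  from the segment contribute no term.
* **MSE** over a trial set: mean squared difference between the per-trial
  predicted P(A) and the 0/1 response, so trial-level recency structure is
  not aggregated away.

Optimization uses SLSQP (scipy) under bound constraints plus the equality
constraint that the attention weights sum to 1, from multiple seeded starts
(weights drawn uniformly on the simplex, scalars uniform within bounds). A
nested-start policy is available: when fitting a model that nests a simpler
one (forgetting nests exemplar at beta = 0; the mixture nests both components
at alpha in {0, 1}), the restricted optimum is supplied as an extra start so
the richer model can never fit worse than its restriction.

Fitting policy per condition (mirroring the original analyses): control-
condition SSE fits are per sequential segment with all parameters free per
segment; control MSE fits and all power-law-condition fits are per
participant over the whole experiment, with only the mixture's alpha allowed
to vary across power-law segments.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .models import ModelParams, SequenceContext, validate_weights
from .schedules import SegmentAssignment, TrialSequence
from .stimuli import CategoryStructure

OBJECTIVES = ("sse_segment", "mse_trials")


def sse_objective(trace, response_a, stimulus_ids, trials=None) -> float:
    """Sum over stimuli of squared (predicted - observed) A-response proportions.

    ``trace`` and ``response_a`` are per-trial arrays aligned with
    ``stimulus_ids``; ``trials`` optionally restricts to a segment (0-based
    indices). The model's predicted proportion for a stimulus is the mean of
    its per-trial predictions within the segment.
    """
    trace = np.asarray(trace, dtype=float)
    resp = np.asarray(response_a, dtype=float)
    sid = np.asarray(stimulus_ids)
    if trials is not None:
        trials = np.asarray(trials)
        if len(trials) == 0:
            raise ValueError("empty segment")
        if len(trace) == len(trials) and len(trace) != len(sid):
            # trace already restricted to the segment rows
            resp, sid = resp[trials], sid[trials]
        else:
            trace, resp, sid = trace[trials], resp[trials], sid[trials]
    if len(trace) == 0:
        raise ValueError("empty segment")
    sse = 0.0
    for s in np.unique(sid):
        m = sid == s
        sse += (trace[m].mean() - resp[m].mean()) ** 2
    return float(sse)


def mse_objective(trace, response_a, trials=None) -> float:
    """Mean squared per-trial error between predicted P(A) and 0/1 responses."""
    trace = np.asarray(trace, dtype=float)
    resp = np.asarray(response_a, dtype=float)
    if trials is not None:
        trials = np.asarray(trials)
        if len(trials) == 0:
            raise ValueError("empty trial set")
        if len(trace) != len(trials):
            trace = trace[trials]
        resp = resp[trials]
    if len(trace) == 0:
        raise ValueError("empty trial set")
    return float(np.mean((trace - resp) ** 2))


@dataclass
class FitSpec:
    """Configuration of one fitting run."""

    objective: str = "mse_trials"
    scope: str = "whole_experiment"  # or "per_sequential_segment"
    n_restarts: int = 10
    seed: int | None = None
    c_max: float = 30.0
    beta_max: float = 5.0
    fix_beta: float | None = None
    alpha_by_segment: bool = False
    maxiter: int = 200

    def __post_init__(self) -> None:
        if self.objective not in OBJECTIVES:
            raise ValueError(f"unknown objective {self.objective!r}")


@dataclass
class FitResult:
    params: ModelParams
    objective_value: float
    converged: bool
    restarts_used: int
    family: str
    objective: str
    participant: int | str | None = None
    condition: str | None = None
    segment: int | None = None


def _pack_layout(family: str, m: int, n_alpha: int, spec: FitSpec):
    """Return (names, bounds) for the free-parameter vector of a family."""
    names = [f"w{i}" for i in range(m)]
    bounds = [(0.0, 1.0)] * m
    if family in ("prototype", "exemplar"):
        names += ["c"]
        bounds += [(0.0, spec.c_max)]
    elif family == "exemplar_forgetting":
        names += ["c"]
        bounds += [(0.0, spec.c_max)]
        if spec.fix_beta is None:
            names += ["beta"]
            bounds += [(0.0, spec.beta_max)]
    elif family == "mixture":
        names += ["c_proto", "c_exem"] + [f"alpha{j}" for j in range(n_alpha)]
        bounds += [(0.0, spec.c_max)] * 2 + [(0.0, 1.0)] * n_alpha
    return names, bounds


def _unpack(x, family, m, n_alpha, spec: FitSpec) -> ModelParams:
    w = np.clip(np.asarray(x[:m], dtype=float), 0.0, 1.0)
    w = w / w.sum()
    if family == "mixture":
        c_p, c_e = float(x[m]), float(x[m + 1])
        alpha = np.clip(np.asarray(x[m + 2 : m + 2 + n_alpha], dtype=float), 0, 1)
        if n_alpha == 1:
            alpha = float(alpha[0])
        return ModelParams(
            "mixture", w, c_proto=max(c_p, 0.0), c_exem=max(c_e, 0.0), alpha=alpha
        )
    c = max(float(x[m]), 0.0)
    if family == "exemplar_forgetting":
        beta = spec.fix_beta if spec.fix_beta is not None else max(float(x[m + 1]), 0.0)
        return ModelParams("exemplar_forgetting", w, c=c, beta=float(beta))
    return ModelParams(family, w, c=c)


def _params_to_vector(p: ModelParams, family, m, n_alpha, spec: FitSpec) -> np.ndarray:
    x = list(np.asarray(p.w, dtype=float))
    if family == "mixture":
        a = np.atleast_1d(np.asarray(p.alpha, dtype=float))
        if a.size == 1:
            a = np.repeat(a, n_alpha)
        x += [p.c_proto, p.c_exem, *a]
    else:
        x += [p.c]
        if family == "exemplar_forgetting" and spec.fix_beta is None:
            x += [p.beta]
    return np.asarray(x, dtype=float)


def _random_start(rng, family, m, n_alpha, spec: FitSpec) -> np.ndarray:
    w = rng.dirichlet(np.ones(m))
    if family == "mixture":
        return np.concatenate(
            [w, rng.uniform(0, spec.c_max, 2), rng.uniform(0, 1, n_alpha)]
        )
    scalars = [rng.uniform(0, spec.c_max)]
    if family == "exemplar_forgetting" and spec.fix_beta is None:
        scalars.append(rng.uniform(0, spec.beta_max))
    return np.concatenate([w, scalars])


def _default_start(family, m, n_alpha, spec: FitSpec) -> np.ndarray:
    w = np.full(m, 1.0 / m)
    if family == "mixture":
        return np.concatenate([w, [spec.c_max / 6] * 2, [0.5] * n_alpha])
    scalars = [spec.c_max / 6]
    if family == "exemplar_forgetting" and spec.fix_beta is None:
        scalars.append(0.5)
    return np.concatenate([w, scalars])


def fit(
    family: str,
    response_a,
    seq: TrialSequence,
    structure: CategoryStructure,
    spec: FitSpec,
    trials=None,
    assignment: SegmentAssignment | None = None,
    ctx: SequenceContext | None = None,
    extra_starts: list[ModelParams] | None = None,
    participant=None,
    condition: str | None = None,
    segment: int | None = None,
) -> FitResult:
    """Fit one model family to one participant's responses.

    ``trials`` (0-based indices) restricts the objective to a segment; the
    prediction at each of those trials still conditions on the full earlier
    history. ``assignment`` is required when ``spec.alpha_by_segment`` (the
    mixture's alpha becomes one value per segment of that assignment).
    The best parameters over all starts — including the raw start points
    themselves — are returned, so supplying a restricted model's optimum via
    ``extra_starts`` guarantees the nested-model inequality.
    """
    if ctx is None:
        ctx = SequenceContext(seq, structure)
    response_a = np.asarray(response_a, dtype=float)
    m = structure.n_features
    n_alpha = 1
    alpha_per_trial_of = None
    if family == "mixture" and spec.alpha_by_segment:
        if assignment is None:
            raise ValueError("alpha_by_segment requires a segment assignment")
        n_alpha = assignment.n_segments
        seg0 = assignment.segment_of_trial - 1

        def alpha_per_trial_of(alpha_vec, rows):
            return np.asarray(alpha_vec)[seg0 if rows is None else seg0[rows]]

    rows = None if trials is None else np.asarray(trials)
    sid = ctx.stim if rows is None else ctx.stim[rows]
    resp = response_a if rows is None else response_a[rows]

    def objective(x: np.ndarray) -> float:
        p = _unpack(x, family, m, n_alpha, spec)
        if family == "mixture":
            a = p.alpha
            apt = alpha_per_trial_of(a, rows) if alpha_per_trial_of else a
            trace = ctx.mixture_trace(p.w, p.c_proto, p.c_exem, apt, rows)
        elif family == "prototype":
            trace = ctx.prototype_trace(p.w, p.c, rows)
        else:
            beta = p.beta if family == "exemplar_forgetting" else 0.0
            trace = ctx.exemplar_trace(p.w, p.c, beta, rows)
        if spec.objective == "sse_segment":
            return sse_objective(trace, resp, sid)
        return mse_objective(trace, resp)

    names, bounds = _pack_layout(family, m, n_alpha, spec)
    constraints = [{"type": "eq", "fun": lambda x: x[:m].sum() - 1.0}]
    rng = np.random.default_rng(spec.seed)

    starts = [_default_start(family, m, n_alpha, spec)]
    starts += [
        _random_start(rng, family, m, n_alpha, spec)
        for _ in range(max(spec.n_restarts - 1, 0))
    ]
    for p in extra_starts or []:
        starts.append(_params_to_vector(p, family, m, n_alpha, spec))

    best_x, best_val, converged = None, np.inf, False
    for x0 in starts:
        v0 = objective(x0)
        if v0 < best_val:
            best_x, best_val = x0, v0
        try:
            res = minimize(
                objective,
                x0,
                method="SLSQP",
                bounds=bounds,
                constraints=constraints,
                options={"maxiter": spec.maxiter, "ftol": 1e-9},
            )
        except Exception:  # optimizer blew up on this start; keep going
            continue
        val = objective(res.x)  # re-evaluate: res.fun can be stale on failure
        if np.isfinite(val) and val < best_val:
            best_x, best_val = res.x, val
        converged = converged or bool(res.success)

    params = _unpack(best_x, family, m, n_alpha, spec)
    validate_weights(params.w)
    return FitResult(
        params=params,
        objective_value=float(best_val),
        converged=converged,
        restarts_used=len(starts),
        family=family,
        objective=spec.objective,
        participant=participant,
        condition=condition,
        segment=segment,
    )


def fit_nested(
    family: str,
    response_a,
    seq,
    structure,
    spec: FitSpec,
    **kwargs,
) -> FitResult:
    """Fit with the nested-start policy.

    For ``exemplar_forgetting``, first fits the base exemplar model and seeds
    the forgetting fit with that optimum at beta = 0. For ``mixture``, fits
    both components and seeds with (alpha=1, component=prototype) and
    (alpha=0, component=exemplar). Other families fall through to ``fit``.
    """
    kwargs.setdefault("ctx", SequenceContext(seq, structure))
    if family == "exemplar_forgetting":
        base = fit("exemplar", response_a, seq, structure, spec, **kwargs)
        seeded = ModelParams(
            "exemplar_forgetting", base.params.w, c=base.params.c, beta=0.0
        )
        return fit(
            family, response_a, seq, structure, spec,
            extra_starts=[seeded], **kwargs,
        )
    if family == "mixture":
        proto = fit("prototype", response_a, seq, structure, spec, **kwargs)
        exem = fit("exemplar", response_a, seq, structure, spec, **kwargs)
        seeds = [
            ModelParams(
                "mixture", proto.params.w,
                c_proto=proto.params.c, c_exem=proto.params.c, alpha=1.0,
            ),
            ModelParams(
                "mixture", exem.params.w,
                c_proto=exem.params.c, c_exem=exem.params.c, alpha=0.0,
            ),
        ]
        return fit(
            family, response_a, seq, structure, spec,
            extra_starts=seeds, **kwargs,
        )
    return fit(family, response_a, seq, structure, spec, **kwargs)


def fit_condition(
    cohort,
    condition: str,
    family: str,
    spec: FitSpec,
    nested: bool = True,
) -> list[FitResult]:
    """Fit every participant of one condition under the condition's policy.

    control + sse_segment -> one FitResult per participant x sequential
    segment (all parameters free per segment). Everything else -> one
    FitResult per participant over all trials; in the power-law condition the
    mixture's alpha varies by power-law segment while all other parameters
    are shared.
    """
    from .simulate import Cohort  # local import to avoid a cycle

    assert isinstance(cohort, Cohort)
    results: list[FitResult] = []
    fitter = fit_nested if nested else fit
    for participant in cohort.participants(condition):
        seq = cohort.sequences[(condition, participant)]
        assignment = cohort.assignments[(condition, participant)]
        resp = cohort.response_a(condition, participant)
        ctx = SequenceContext(seq, cohort.structure)
        if condition == "control" and spec.objective == "sse_segment":
            for s in range(1, assignment.n_segments + 1):
                results.append(
                    fitter(
                        family, resp, seq, cohort.structure,
                        replace(spec, alpha_by_segment=False),
                        trials=assignment.trials_in(s), ctx=ctx,
                        participant=participant, condition=condition, segment=s,
                    )
                )
        else:
            use_spec = spec
            if family == "mixture" and condition == "experimental":
                use_spec = replace(spec, alpha_by_segment=True)
            results.append(
                fitter(
                    family, resp, seq, cohort.structure, use_spec,
                    assignment=assignment, ctx=ctx,
                    participant=participant, condition=condition,
                )
            )
    return results


def results_to_frame(results: list[FitResult]) -> pd.DataFrame:
    """Flatten FitResults to a tidy table (one row per fit)."""
    rows = []
    for r in results:
        row = {
            "participant": r.participant,
            "condition": r.condition,
            "segment": r.segment,
            "family": r.family,
            "objective": r.objective,
            "value": r.objective_value,
            "converged": r.converged,
        }
        p = r.params
        for i, wi in enumerate(p.w):
            row[f"w{i + 1}"] = wi
        for name in ("c", "beta", "c_proto", "c_exem"):
            row[name] = getattr(p, name)
        if p.alpha is not None:
            a = np.atleast_1d(np.asarray(p.alpha, dtype=float))
            if a.size == 1:
                row["alpha"] = float(a[0])
            else:
                for j, aj in enumerate(a):
                    row[f"alpha{j + 1}"] = float(aj)
        rows.append(row)
    return pd.DataFrame(rows)
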