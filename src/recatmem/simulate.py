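"""Response simulation: synthetic participant cohorts from any model family.

The default protocol is the demonstration protocol of the exemplar-forgetting
account: equal attention weights of 1/6, a sensitivity parameter that rises
across segments from 5.5 to 10.5 in steps of 0.5 (capturing learning), and a
power-law forgetting rate of beta = 0.7 — the same values in both conditions.
Sensitivity is indexed by the trial's *sequential* segment in the control
condition and by its *power-law* segment in the experimental condition, so
the parameterization follows each condition's own notion of task progress.

For every trial the model's P(A) is computed conditional on the full
feedback-labelled history, and the response is a Bernoulli sample of it.
Simulated participants receive independent seeded sequences (a shared
sequence can be requested), and the whole cohort is reproducible from one
integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .models import ModelParams, SequenceContext
from .schedules import (
    SegmentAssignment,
    TrialSequence,
    assign_segments,
    make_powerlaw_sequence,
    make_uniform_sequence,
    sequence_from_ids,
)
from .stimuli import CategoryStructure, make_rule_plus_exception


def _default_c_schedule() -> np.ndarray:
    return np.arange(5.5, 10.51, 0.5)


@dataclass
class SimulationProtocol:
    """Generating model and cohort design for a simulated experiment.

    Defaults reproduce the demonstration settings: exemplar-forgetting
    generator, equal weights, c rising 5.5 -> 10.5 by 0.5 across the 11
    segments, beta = 0.7; 616 trials as 44 uniform blocks (control) or
    introductions every 35 trials followed by power-law-spaced reappearances
    (experimental).
    """

    family: str = "exemplar_forgetting"
    weights: np.ndarray | None = None  # None -> equal 1/M
    c_schedule: np.ndarray = field(default_factory=_default_c_schedule)
    beta: float = 0.7
    alpha: float = 0.5  # mixture generator only
    c_proto: float | None = None  # mixture generator only
    c_exem: float | None = None
    n_participants: int = 30
    conditions: tuple[str, ...] = ("control", "experimental")
    n_blocks: int = 44
    total_trials: int = 616
    intro_interval: int = 35
    decay_gamma: float = 2.0
    quota_exponent: float = 0.4
    n_segments: int = 11
    shared_sequences: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        self.c_schedule = np.asarray(self.c_schedule, dtype=float)
        if len(self.c_schedule) != self.n_segments:
            raise ValueError("c_schedule length must equal n_segments")
        if np.any(self.c_schedule < 0):
            raise ValueError("sensitivities must be >= 0")


def paper_protocol(**overrides) -> SimulationProtocol:
    """The demonstration protocol (all defaults), with optional overrides."""
    return SimulationProtocol(**overrides)


@dataclass
class Cohort:
    """A simulated (or imported) response cohort plus its provenance.

    ``data`` has one row per trial: participant, condition, trial,
    stimulus_id, presentation_index, delay, segment (condition-appropriate
    scheme), p_A (the sampling probability, retained for tests), response
    ("A"/"B"), response_a (0/1) and correct (0/1).
    """

    data: pd.DataFrame
    sequences: dict[tuple[str, int], TrialSequence]
    assignments: dict[tuple[str, int], SegmentAssignment]
    structure: CategoryStructure
    protocol: SimulationProtocol | None = None

    def participants(self, condition: str) -> list[int]:
        mask = self.data["condition"] == condition
        return sorted(self.data.loc[mask, "participant"].unique())

    def rows(self, condition: str, participant) -> pd.DataFrame:
        d = self.data
        sel = (d["condition"] == condition) & (d["participant"] == participant)
        return d.loc[sel].sort_values("trial")

    def response_a(self, condition: str, participant) -> np.ndarray:
        return self.rows(condition, participant)["response_a"].to_numpy(dtype=float)

    def to_csv(self, path) -> None:
        self.data.to_csv(path, index=False)


def _sequence_for(protocol: SimulationProtocol, structure, condition, participant):
    cond_i = ("control", "experimental").index(condition)
    p = 0 if protocol.shared_sequences else participant + 1
    ss = np.random.SeedSequence(protocol.seed, spawn_key=(cond_i, p, 0))
    if condition == "control":
        return make_uniform_sequence(structure, protocol.n_blocks, ss)
    return make_powerlaw_sequence(
        structure,
        protocol.total_trials,
        protocol.intro_interval,
        protocol.decay_gamma,
        ss,
        quota_exponent=protocol.quota_exponent,
    )


def _generator_params(protocol: SimulationProtocol, m: int) -> ModelParams:
    w = (
        np.full(m, 1.0 / m)
        if protocol.weights is None
        else np.asarray(protocol.weights, dtype=float)
    )
    fam = protocol.family
    if fam == "mixture":
        c_p = protocol.c_proto if protocol.c_proto is not None else 8.0
        c_e = protocol.c_exem if protocol.c_exem is not None else 8.0
        return ModelParams("mixture", w, c_proto=c_p, c_exem=c_e, alpha=protocol.alpha)
    c0 = float(protocol.c_schedule[0])
    if fam == "exemplar_forgetting":
        return ModelParams(fam, w, c=c0, beta=protocol.beta)
    return ModelParams(fam, w, c=c0)


def _trace_for(
    protocol: SimulationProtocol,
    structure: CategoryStructure,
    seq: TrialSequence,
    assignment: SegmentAssignment,
) -> np.ndarray:
    params = _generator_params(protocol, structure.n_features)
    ctx = SequenceContext(seq, structure)
    c_per_trial = protocol.c_schedule[assignment.segment_of_trial - 1]
    if params.family == "mixture":
        return ctx.mixture_trace(
            params.w, params.c_proto, params.c_exem, protocol.alpha
        )
    return ctx.trace(params, c_per_trial=c_per_trial)


def simulate_trace_only(
    protocol: SimulationProtocol,
    structure: CategoryStructure,
    seq: TrialSequence,
    assignment: SegmentAssignment | None = None,
) -> np.ndarray:
    """Noiseless per-trial P(A) under the protocol's generating model."""
    if assignment is None:
        scheme = "sequential" if seq.condition == "control" else "power_law"
        assignment = assign_segments(seq, scheme, protocol.n_segments)
    return _trace_for(protocol, structure, seq, assignment)


def simulate_cohort(
    protocol: SimulationProtocol, structure: CategoryStructure | None = None
) -> Cohort:
    """Simulate a full cohort of Bernoulli responders under the protocol."""
    if structure is None:
        structure = make_rule_plus_exception()
    truth = {int(s.id): s.category for s in structure.stimuli}
    frames = []
    sequences: dict[tuple[str, int], TrialSequence] = {}
    assignments: dict[tuple[str, int], SegmentAssignment] = {}
    for condition in protocol.conditions:
        cond_i = ("control", "experimental").index(condition)
        scheme = "sequential" if condition == "control" else "power_law"
        for participant in range(protocol.n_participants):
            seq = _sequence_for(protocol, structure, condition, participant)
            assignment = assign_segments(seq, scheme, protocol.n_segments)
            p_a = _trace_for(protocol, structure, seq, assignment)
            rng = np.random.default_rng(
                np.random.SeedSequence(
                    protocol.seed, spawn_key=(cond_i, participant + 1, 1)
                )
            )
            resp_a = (rng.random(seq.n_trials) < p_a).astype(int)
            cats = np.array([truth[int(s)] for s in seq.stimulus_ids])
            response = np.where(resp_a == 1, "A", "B")
            frames.append(
                pd.DataFrame(
                    {
                        "participant": participant,
                        "condition": condition,
                        "trial": seq.trials,
                        "stimulus_id": seq.stimulus_ids,
                        "presentation_index": seq.presentation_index,
                        "delay": seq.delay,
                        "segment": assignment.segment_of_trial,
                        "p_A": p_a,
                        "response": response,
                        "response_a": resp_a,
                        "correct": (response == cats).astype(int),
                    }
                )
            )
            sequences[(condition, participant)] = seq
            assignments[(condition, participant)] = assignment
    data = pd.concat(frames, ignore_index=True)
    return Cohort(data, sequences, assignments, structure, protocol)


def read_cohort(path, structure: CategoryStructure | None = None) -> Cohort:
    """Rebuild a Cohort (sequences and segment assignments included) from CSV."""
    if structure is None:
        structure = make_rule_plus_exception()
    data = pd.read_csv(path)
    return cohort_from_frame(data, structure)


def cohort_from_frame(data: pd.DataFrame, structure: CategoryStructure) -> Cohort:
    sequences: dict[tuple[str, int], TrialSequence] = {}
    assignments: dict[tuple[str, int], SegmentAssignment] = {}
    for (condition, participant), grp in data.groupby(
        ["condition", "participant"], sort=True
    ):
        grp = grp.sort_values("trial")
        seq = sequence_from_ids(
            grp["stimulus_id"].to_numpy(dtype=int),
            str(condition),
            structure.n_stimuli,
        )
        scheme = "sequential" if condition == "control" else "power_law"
        seg = grp["segment"].to_numpy(dtype=int)
        sequences[(condition, participant)] = seq
        assignments[(condition, participant)] = SegmentAssignment(
            scheme, seg, int(seg.max())
        )
    return Cohort(data, sequences, assignments, structure, None)
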