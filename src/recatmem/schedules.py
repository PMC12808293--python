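"""Presentation schedules and environmental-recency diagnostics.

Two presentation regimes:

* **control** (uniform): every block of N trials is an independent random
  permutation of all N stimuli, so each stimulus is equally likely at every
  point and mean recency is flat over the session.
* **experimental** (power-law): new stimuli are introduced at fixed intervals
  and thereafter reappear with probability proportional to ``delay**-gamma``,
  so each stimulus is initially frequent and then increasingly rare — an
  approximation of real-world "need" statistics, where recently seen items
  are the ones most likely to recur.

Trials are binned into *segments* for analysis: contiguous equal blocks for
the control condition (sequential segments), and presentation-index bins for
the experimental condition (power-law segments: the k-th appearances of all
stimuli land in the same segment even though they are scattered in time).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .stimuli import CategoryStructure

CONDITIONS = ("control", "experimental")
SCHEMES = ("sequential", "power_law")


@dataclass(frozen=True)
class TrialSequence:
    """An ordered presentation sequence with recency annotations.

    ``presentation_index[t]`` is the 1-based count of appearances of the
    trial-t stimulus up to and including trial t. ``delay[t]`` is the number
    of trials since that stimulus last appeared (NaN on first appearance).
    Trials are numbered 1..T externally; arrays are 0-based.
    """

    condition: str
    stimulus_ids: np.ndarray
    presentation_index: np.ndarray
    delay: np.ndarray
    n_stimuli: int
    seed: int | None = None

    @property
    def n_trials(self) -> int:
        return len(self.stimulus_ids)

    @property
    def trials(self) -> np.ndarray:
        """1-based trial numbers."""
        return np.arange(1, self.n_trials + 1)


def _annotate(ids: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    pidx = np.zeros(len(ids), dtype=int)
    delay = np.full(len(ids), np.nan)
    last: dict[int, int] = {}
    count: dict[int, int] = {}
    for t, s in enumerate(ids):
        s = int(s)
        count[s] = count.get(s, 0) + 1
        pidx[t] = count[s]
        if s in last:
            delay[t] = t - last[s]
        last[s] = t
    return pidx, delay


def sequence_from_ids(
    ids, condition: str, n_stimuli: int, seed: int | None = None
) -> TrialSequence:
    """Build an annotated TrialSequence from a raw stimulus-id list."""
    ids = np.asarray(ids, dtype=int)
    pidx, delay = _annotate(ids)
    return TrialSequence(condition, ids, pidx, delay, n_stimuli, seed)


def make_uniform_sequence(
    structure: CategoryStructure, n_blocks: int, seed
) -> TrialSequence:
    """Uniform (control) schedule: ``n_blocks`` seeded permutations of all stimuli.

    With the 14-stimulus structure and 44 blocks this gives the canonical
    616-trial session.
    """
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    rng = np.random.default_rng(seed)
    ids = structure.ids
    blocks = [rng.permutation(ids) for _ in range(n_blocks)]
    return sequence_from_ids(
        np.concatenate(blocks),
        "control",
        structure.n_stimuli,
        seed if isinstance(seed, (int, np.integer)) else None,
    )


def make_powerlaw_sequence(
    structure: CategoryStructure,
    total_trials: int = 616,
    intro_interval: int = 35,
    decay_gamma: float = 2.0,
    seed=None,
    quota_exponent: float = 0.4,
) -> TrialSequence:
    """Power-law (experimental) schedule.

    Stimuli are introduced in randomized order, one every ``intro_interval``
    trials starting at trial 1 (so the s-th introduced stimulus first appears
    at trial (s-1)*intro_interval + 1). Each stimulus s is allotted a total
    appearance quota proportional to ``span_s ** quota_exponent`` (span_s =
    trials remaining after its introduction; quotas sum to T), and its
    successive reappearances are scheduled with desired gaps growing as a
    power of its presentation count,

        gap_s(k) = a_s * k ** decay_gamma,

    with a_s chosen so the stimulus's appearances nominally fill its span.
    Trials are allocated by deadline scheduling: every non-introduction trial
    shows the introduced, quota-remaining stimulus whose (jittered) deadline
    ``last_appearance + gap_s(k_s)`` is earliest. The result is the intended
    recency environment: each stimulus is initially frequent and becomes
    systematically rarer, the mean delay between repetitions rises across
    power-law segments well past the uniform schedule's constant delay, and
    per-segment mean presentation counts stay close to the uniform
    schedule's.
    """
    n = structure.n_stimuli
    if intro_interval * n > total_trials:
        raise ValueError("intro_interval * n_stimuli must be <= total_trials")
    if decay_gamma <= 0:
        raise ValueError("decay_gamma must be > 0")
    rng = np.random.default_rng(seed)
    order = [int(x) for x in rng.permutation(structure.ids)]
    spans = np.array(
        [total_trials - (r * intro_interval + 1) for r in range(n)], dtype=float
    )
    raw = spans**quota_exponent
    quota = np.maximum(2, np.round(total_trials * raw / raw.sum()).astype(int))
    while quota.sum() != total_trials:  # rounding slack -> earliest stimuli
        if quota.sum() < total_trials:
            quota[int(np.argmax(spans))] += 1
        else:
            quota[int(np.argmax(quota))] -= 1
    rate: dict[int, float] = {}
    quota_of: dict[int, int] = {}
    for r, s in enumerate(order):
        ks = np.arange(1, quota[r], dtype=float)
        rate[s] = spans[r] / (ks**decay_gamma).sum() if len(ks) else 0.0
        quota_of[s] = int(quota[r])

    ids = np.empty(total_trials, dtype=int)
    last: dict[int, int] = {}
    shown: dict[int, int] = {s: 0 for s in order}
    introduced: list[int] = []
    for t in range(1, total_trials + 1):
        r = (t - 1) // intro_interval
        if (t - 1) % intro_interval == 0 and r < n:
            s = order[r]
            introduced.append(s)
        else:
            active = [s for s in introduced if shown[s] < quota_of[s]]
            if not active:  # all quotas met early (tiny configs); recycle
                active = introduced
            deadlines = np.array(
                [last[s] + rate[s] * shown[s] ** decay_gamma for s in active]
            ) + rng.uniform(0.0, 1.0, len(active))
            s = active[int(np.argmin(deadlines))]
        shown[s] += 1
        last[s] = t
        ids[t - 1] = s
    return sequence_from_ids(
        ids,
        "experimental",
        n,
        seed if isinstance(seed, (np.integer, int)) else None,
    )


@dataclass(frozen=True)
class SegmentAssignment:
    """Per-trial segment labels (1-based, 1..n_segments)."""

    scheme: str
    segment_of_trial: np.ndarray
    n_segments: int

    def trials_in(self, segment: int) -> np.ndarray:
        """0-based trial indices belonging to ``segment``."""
        return np.flatnonzero(self.segment_of_trial == segment)


def assign_segments(
    seq: TrialSequence, scheme: str, n_segments: int = 11
) -> SegmentAssignment:
    """Bin trials into analysis segments.

    sequential
        Contiguous blocks of T // S trials; the final segment absorbs any
        remainder.
    power_law
        Cut-points on the presentation index, greedily balanced so segment
        trial counts are as close to T / S as possible while the segment is
        non-decreasing in presentation index. The first segment thus holds
        the initial few appearances of every stimulus, wherever they fall in
        time.
    """
    t_total = seq.n_trials
    if scheme not in SCHEMES:
        raise ValueError(f"unknown scheme {scheme!r}")
    if n_segments > t_total or n_segments < 1:
        raise ValueError("n_segments must be in 1..T")
    if scheme == "sequential":
        base = t_total // n_segments
        seg = np.minimum(np.arange(t_total) // base + 1, n_segments)
        return SegmentAssignment(scheme, seg.astype(int), n_segments)

    pidx = seq.presentation_index
    ks, counts = np.unique(pidx, return_counts=True)
    seg_of_k: dict[int, int] = {}
    seg, acc = 1, 0
    total_left = t_total
    target = total_left / n_segments
    for i, (k, h) in enumerate(zip(ks, counts)):
        n_left = len(ks) - i  # bins still unassigned, including this one
        if seg < n_segments and acc > 0:
            must_close = n_left == n_segments - seg
            overshoot = abs(acc + h - target) >= abs(acc - target)
            if must_close or overshoot:
                total_left -= acc
                seg += 1
                target = total_left / (n_segments - seg + 1)
                acc = 0
        seg_of_k[int(k)] = seg
        acc += int(h)
    segment_of_trial = np.array([seg_of_k[int(k)] for k in pidx], dtype=int)
    return SegmentAssignment(scheme, segment_of_trial, n_segments)


@dataclass(frozen=True)
class RecencyProfile:
    """Environmental-recency diagnostics for a sequence.

    ``need_odds`` tabulates, per recency lag r, the empirical probability
    p_stim that the stimulus shown r trials ago is shown again now, expressed
    as odds p/(1-p). ``by_segment`` gives per-segment mean delay between
    repetitions (first appearances excluded) and mean presentation count.
    """

    need_odds: pd.DataFrame
    by_segment: pd.DataFrame | None = None


def recency_profile(
    seq: TrialSequence,
    assignment: SegmentAssignment | None = None,
    max_lag: int | None = None,
) -> RecencyProfile:
    """Compute need-odds by recency and per-segment delay/repetition stats."""
    ids = seq.stimulus_ids
    t_total = seq.n_trials
    if max_lag is None:
        max_lag = min(50, t_total - 1)
    rows = []
    for r in range(1, max_lag + 1):
        p = float(np.mean(ids[r:] == ids[:-r]))
        odds = p / (1 - p) if p < 1 else np.inf
        rows.append((r, p, odds))
    need = pd.DataFrame(rows, columns=["recency", "p_stim", "need_odds"])

    by_segment = None
    if assignment is not None:
        recs = []
        for s in range(1, assignment.n_segments + 1):
            idx = assignment.trials_in(s)
            if len(idx) == 0:
                raise ValueError(f"segment {s} is empty")
            d = seq.delay[idx]
            recs.append(
                {
                    "segment": s,
                    "n_trials": len(idx),
                    "mean_delay": float(np.nanmean(d)) if np.any(~np.isnan(d)) else np.nan,
                    "mean_presentation_count": float(
                        np.mean(seq.presentation_index[idx])
                    ),
                }
            )
        by_segment = pd.DataFrame(recs)
    return RecencyProfile(need, by_segment)


# ---------------------------------------------------------------------------
# I/O


def sequence_to_frame(
    seq: TrialSequence,
    participant=None,
    sequential: SegmentAssignment | None = None,
    power_law: SegmentAssignment | None = None,
) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "participant": participant,
            "condition": seq.condition,
            "trial": seq.trials,
            "stimulus_id": seq.stimulus_ids,
            "presentation_index": seq.presentation_index,
            "delay": seq.delay,
        }
    )
    if sequential is not None:
        df["segment_sequential"] = sequential.segment_of_trial
    if power_law is not None:
        df["segment_powerlaw"] = power_law.segment_of_trial
    return df


def sequence_from_frame(df: pd.DataFrame, n_stimuli: int | None = None) -> TrialSequence:
    df = df.sort_values("trial")
    ids = df["stimulus_id"].to_numpy(dtype=int)
    if n_stimuli is None:
        n_stimuli = len(np.unique(ids))
    return sequence_from_ids(ids, str(df["condition"].iloc[0]), n_stimuli)
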