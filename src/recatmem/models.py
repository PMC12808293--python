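"""Categorization models: prototype, exemplar, exemplar-forgetting, mixture.

All four models share the generalized-context-model machinery: a weighted
city-block distance between binary feature vectors,

    d(x, y) = sum_m w_m |x_m - y_m|,     w_m >= 0, sum_m w_m = 1,

an exponential similarity gradient s = exp(-c d) with sensitivity c >= 0, and
a ratio choice rule P(A) = S_A / (S_A + S_B).

* The **prototype** model compares the probe to the two fixed category
  prototypes (S_A is the similarity to the A prototype).
* The **exemplar** model compares the probe to every stored token — one token
  per past trial, labelled with the feedback category — and sums similarities
  within each category.
* The **exemplar-forgetting** model weights each token's similarity by a
  power-law memory strength M = j**-beta, where j is the delay in trials
  since the token was stored and beta >= 0 the decay rate.  beta = 0 recovers
  the base exemplar model.
* The **mixture** model blends prototype and exemplar choice probabilities,
  P(A) = alpha * P_prototype + (1 - alpha) * P_exemplar, with one shared
  attention simplex and separate sensitivities per component.

Free-parameter counts (M = 6 features): 6 for prototype/exemplar (five free
weights plus c), 7 for forgetting (+ beta), 8 for the mixture with a scalar
alpha (5 weights + c_proto + c_exem + alpha).

``predict_sequence`` runs a model across a trial sequence, growing the token
store one trial at a time; ``SequenceContext`` is the vectorized engine behind
it and behind model fitting.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .schedules import TrialSequence
from .stimuli import CategoryStructure

FAMILIES = ("prototype", "exemplar", "exemplar_forgetting", "mixture")

_SIMPLEX_TOL = 1e-6


def validate_weights(w, n_features: int | None = None, tol: float = _SIMPLEX_TOL):
    """Check an attention-weight vector lies on the simplex; return as array."""
    w = np.asarray(w, dtype=float)
    if n_features is not None and w.shape != (n_features,):
        raise ValueError(f"expected {n_features} attention weights")
    if np.any(w < -tol) or np.any(w > 1 + tol):
        raise ValueError("attention weights must lie in [0, 1]")
    if abs(w.sum() - 1.0) > tol:
        raise ValueError("attention weights must sum to 1")
    return w


@dataclass
class ModelParams:
    """Parameters of one model family.

    ``alpha`` may be a scalar or a per-segment vector (mixture model in the
    power-law condition, where only the mixture weight varies by segment).
    """

    family: str
    w: np.ndarray
    c: float | None = None
    beta: float | None = None
    c_proto: float | None = None
    c_exem: float | None = None
    alpha: float | np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        self.w = validate_weights(self.w)
        if self.family == "mixture":
            if self.c_proto is None or self.c_exem is None or self.alpha is None:
                raise ValueError("mixture needs c_proto, c_exem and alpha")
            a = np.atleast_1d(np.asarray(self.alpha, dtype=float))
            if np.any(a < 0) or np.any(a > 1):
                raise ValueError("alpha must lie in [0, 1]")
        else:
            if self.c is None or self.c < 0:
                raise ValueError("c must be a non-negative number")
            if self.family == "exemplar_forgetting":
                if self.beta is None or self.beta < 0:
                    raise ValueError("beta must be a non-negative number")

    @property
    def n_free(self) -> int:
        """Number of free parameters (weights contribute M - 1)."""
        m = len(self.w) - 1
        if self.family in ("prototype", "exemplar"):
            return m + 1
        if self.family == "exemplar_forgetting":
            return m + 2
        return m + 2 + np.atleast_1d(np.asarray(self.alpha)).size


@dataclass
class ExemplarStore:
    """Tokens of previously seen trials: features, feedback category, trial index."""

    features: np.ndarray  # (n_tokens, M)
    categories: np.ndarray  # (n_tokens,) of "A"/"B"
    stored_at: np.ndarray  # (n_tokens,) 1-based trial numbers, increasing

    def __post_init__(self) -> None:
        self.features = np.atleast_2d(np.asarray(self.features, dtype=float))
        self.categories = np.atleast_1d(np.asarray(self.categories))
        self.stored_at = np.atleast_1d(np.asarray(self.stored_at, dtype=int))
        if len(self.categories) and np.any(np.diff(self.stored_at) < 0):
            raise ValueError("stored_at must be non-decreasing")

    @classmethod
    def empty(cls, n_features: int) -> "ExemplarStore":
        return cls(
            np.empty((0, n_features)), np.empty(0, dtype="<U1"), np.empty(0, dtype=int)
        )

    @property
    def n_tokens(self) -> int:
        return len(self.stored_at)


def _distance(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    return np.abs(x - y) @ w


def prototype_predict(features, w, c: float, prototypes) -> np.ndarray | float:
    """P(A) under the prototype model for one probe or a batch of probes."""
    f = np.atleast_2d(np.asarray(features, dtype=float))
    prototypes = np.asarray(prototypes, dtype=float)
    w = validate_weights(w, f.shape[1])
    d_a = _distance(f, prototypes[0], w)
    d_b = _distance(f, prototypes[1], w)
    s_a = np.exp(-c * d_a)
    s_b = np.exp(-c * d_b)
    p = s_a / (s_a + s_b)
    return float(p[0]) if np.ndim(features) == 1 else p


def memory_strength(delay, beta: float) -> np.ndarray | float:
    """Power-law trace strength ``delay**-beta`` (delay in trials, >= 1)."""
    d = np.asarray(delay, dtype=float)
    if np.any(d < 1):
        raise ValueError("delay must be >= 1 trial")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    m = d**-beta
    return float(m) if np.isscalar(delay) else m


def _summed_similarity(features, w, c, store: ExemplarStore, strengths=None):
    f = np.asarray(features, dtype=float)
    if store.n_tokens == 0:
        return 0.0, 0.0
    w = validate_weights(w, store.features.shape[1])
    d = np.abs(store.features - f) @ w
    s = np.exp(-c * d)
    if strengths is not None:
        s = s * strengths
    is_a = store.categories == "A"
    return float(s[is_a].sum()), float(s[~is_a].sum())


def exemplar_predict(features, w, c: float, store: ExemplarStore) -> float:
    """P(A) under the base exemplar model; an empty store gives 0.5."""
    s_a, s_b = _summed_similarity(features, w, c, store)
    total = s_a + s_b
    return 0.5 if total == 0 else s_a / total


def forgetting_predict(
    features, w, c: float, beta: float, store: ExemplarStore, current_trial: int
) -> float:
    """P(A) under the exemplar model with power-law forgetting.

    Each token's similarity is weighted by ``(current_trial - stored_at)**-beta``
    before the category sums. All tokens must predate ``current_trial``.
    """
    if store.n_tokens and np.any(store.stored_at >= current_trial):
        raise ValueError("store contains tokens at or after current_trial")
    strengths = (
        memory_strength(current_trial - store.stored_at, beta)
        if store.n_tokens
        else None
    )
    s_a, s_b = _summed_similarity(features, w, c, store, strengths)
    total = s_a + s_b
    return 0.5 if total == 0 else s_a / total


def mixture_predict(
    features, w, c_proto: float, c_exem: float, alpha: float, store, prototypes
) -> float:
    """alpha-weighted blend of prototype and base-exemplar P(A)."""
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    p_proto = prototype_predict(features, w, c_proto, prototypes)
    p_exem = exemplar_predict(features, w, c_exem, store)
    return alpha * p_proto + (1 - alpha) * p_exem


# ---------------------------------------------------------------------------
# Sequence-level prediction


class SequenceContext:
    """Vectorized per-sequence prediction engine.

    Precomputes, for one (sequence, structure) pair, everything that does not
    depend on model parameters: stimulus-row indices, pairwise feature
    differences, cumulative token counts per stimulus, and log-delays for the
    forgetting weights. Because the token store at trial t is exactly the
    feedback-labelled history of trials 1..t-1, category sums reduce to
    ``sum_k W[t, k] * exp(-c * d[stim_t, k])`` where W[t, k] is the (memory
    weighted) number of earlier tokens of stimulus k.
    """

    def __init__(self, seq: TrialSequence, structure: CategoryStructure):
        self.seq = seq
        self.structure = structure
        ids = structure.ids
        row_of = {int(s): i for i, s in enumerate(ids)}
        try:
            self.stim = np.array([row_of[int(s)] for s in seq.stimulus_ids])
        except KeyError as e:  # pragma: no cover - guard
            raise ValueError(f"sequence stimulus {e} not in structure") from None
        self.F = structure.feature_matrix
        self.is_a = structure.categories == "A"
        self.pairdiff = np.abs(self.F[:, None, :] - self.F[None, :, :])
        self.protodiff = np.abs(self.F[:, None, :] - structure.prototype_matrix[None])
        t_total = seq.n_trials
        onehot = np.zeros((t_total, len(ids)))
        onehot[np.arange(t_total), self.stim] = 1.0
        self.onehot = onehot
        counts = np.cumsum(onehot, axis=0)
        self.counts = np.vstack([np.zeros(len(ids)), counts[:-1]])
        idx = np.arange(t_total)
        dmat = idx[:, None] - idx[None, :]
        self._valid = dmat > 0
        with np.errstate(divide="ignore"):
            self._logd = np.where(self._valid, np.log(np.maximum(dmat, 1)), 0.0)
        self._w_cache: dict = {}

    @property
    def n_trials(self) -> int:
        return self.seq.n_trials

    def _rows(self, rows):
        return np.arange(self.n_trials) if rows is None else np.asarray(rows)

    def weighted_counts(self, beta: float, rows=None) -> np.ndarray:
        """(len(rows), N) matrix of memory-weighted earlier-token counts."""
        r = self._rows(rows)
        if beta == 0:
            return self.counts[r]
        key = (float(beta), r.tobytes())
        hit = self._w_cache.get(key)
        if hit is not None:
            return hit
        m = np.exp(-beta * self._logd[r]) * self._valid[r]
        w = m @ self.onehot
        if len(self._w_cache) > 16:
            self._w_cache.clear()
        self._w_cache[key] = w
        return w

    def prototype_trace(self, w, c, rows=None) -> np.ndarray:
        """Per-trial P(A); ``c`` may be scalar or per-trial (matching rows)."""
        r = self._rows(rows)
        w = validate_weights(w, self.structure.n_features)
        d = self.protodiff @ w  # (N, 2)
        c = np.asarray(c, dtype=float)
        d_a, d_b = d[self.stim[r], 0], d[self.stim[r], 1]
        # P(A) = 1 / (1 + exp(-c (d_B - d_A)))
        return 1.0 / (1.0 + np.exp(-c * (d_b - d_a)))

    def exemplar_trace(self, w, c, beta: float = 0.0, rows=None) -> np.ndarray:
        """Per-trial P(A) for the (forgetting-)exemplar model."""
        r = self._rows(rows)
        w = validate_weights(w, self.structure.n_features)
        d = self.pairdiff @ w  # (N, N)
        c = np.asarray(c, dtype=float)
        c_col = c[..., None] if c.ndim else c
        e = np.exp(-c_col * d[self.stim[r]])  # (len(r), N)
        wc = self.weighted_counts(beta, r)
        num = e * wc
        s_a = num[:, self.is_a].sum(axis=1)
        s_b = num[:, ~self.is_a].sum(axis=1)
        total = s_a + s_b
        return np.where(total > 0, s_a / np.where(total > 0, total, 1.0), 0.5)

    def mixture_trace(self, w, c_proto, c_exem, alpha, rows=None) -> np.ndarray:
        """Blend of prototype and base-exemplar traces; alpha scalar or per-trial."""
        alpha = np.asarray(alpha, dtype=float)
        p_p = self.prototype_trace(w, c_proto, rows)
        p_e = self.exemplar_trace(w, c_exem, 0.0, rows)
        return alpha * p_p + (1 - alpha) * p_e

    def trace(
        self, params: ModelParams, rows=None, c_per_trial=None, alpha_per_trial=None
    ) -> np.ndarray:
        """Dispatch on family; per-trial schedules override scalar c / alpha."""
        fam = params.family
        if fam == "mixture":
            alpha = params.alpha if alpha_per_trial is None else alpha_per_trial
            if np.ndim(alpha) and alpha_per_trial is None:
                raise ValueError(
                    "vector alpha needs alpha_per_trial mapped via segments"
                )
            return self.mixture_trace(
                params.w, params.c_proto, params.c_exem, alpha, rows
            )
        c = params.c if c_per_trial is None else c_per_trial
        if fam == "prototype":
            return self.prototype_trace(params.w, c, rows)
        beta = params.beta if fam == "exemplar_forgetting" else 0.0
        return self.exemplar_trace(params.w, c, beta, rows)


def store_at_trial(
    seq: TrialSequence, structure: CategoryStructure, trial: int
) -> ExemplarStore:
    """The token store available when predicting 1-based ``trial``.

    One token per earlier trial, labelled with the true (feedback) category;
    the current trial's stimulus is excluded.
    """
    row_of = {int(s.id): i for i, s in enumerate(structure.stimuli)}
    rows = [row_of[int(s)] for s in seq.stimulus_ids[: trial - 1]]
    return ExemplarStore(
        structure.feature_matrix[rows] if rows else np.empty((0, structure.n_features)),
        structure.categories[rows],
        np.arange(1, trial),
    )


def predict_sequence(
    params: ModelParams,
    seq: TrialSequence,
    structure: CategoryStructure,
    c_per_trial=None,
    alpha_per_trial=None,
    ctx: SequenceContext | None = None,
) -> np.ndarray:
    """Per-trial P(A) across a whole sequence (the model's prediction trace)."""
    if ctx is None:
        ctx = SequenceContext(seq, structure)
    return ctx.trace(params, c_per_trial=c_per_trial, alpha_per_trial=alpha_per_trial)
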