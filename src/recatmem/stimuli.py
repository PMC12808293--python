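"""Rule-plus-exception category structures over binary feature vectors.

Two categories, A and B, are anchored by complementary prototypes (all-0 and
all-1 feature vectors). Most members of a category are *typicals*: one-off
variants of their own prototype. Each category additionally holds zero or
more *exceptions*: items assigned to the category while lying at Hamming
distance 1 from the *opposite* prototype. Exceptions are the diagnostic items
that separate exemplar from prototype accounts of categorization, because a
prototype comparison necessarily mis-sorts them while stored exemplars can
rescue them.

Stimuli can be rendered as six-letter nonsense words (alternating
consonant/vowel positions, one of two letters per position), e.g. the A
prototype 000000 -> "gafuzi" and the B prototype 111111 -> "livamo" with the
default letter table. Words are cosmetic; all models operate on the feature
vectors.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml

CATEGORIES = ("A", "B")
ROLES = ("prototype", "typical", "exception")

#: Default letter table: row m gives (letter for feature value 0, letter for
#: feature value 1) at position m. Consonant/vowel positions alternate.
DEFAULT_LETTERS: tuple[tuple[str, str], ...] = (
    ("g", "l"),
    ("a", "i"),
    ("f", "v"),
    ("u", "a"),
    ("z", "m"),
    ("i", "o"),
)

_VOWELS = set("aeiou")


@dataclass(frozen=True)
class Stimulus:
    """A single category-learning item.

    Attributes
    ----------
    id : int
        Stable integer identifier, unique within a structure.
    features : tuple of int
        Binary feature vector of length M.
    category : {"A", "B"}
        True (feedback) category.
    role : {"prototype", "typical", "exception"}
        Position in the rule-plus-exception design.
    word : str or None
        Optional nonsense-word rendering.
    """

    id: int
    features: tuple[int, ...]
    category: str
    role: str
    word: str | None = None

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if any(v not in (0, 1) for v in self.features):
            raise ValueError("features must be binary")


@dataclass(frozen=True)
class CategoryStructure:
    """An ordered collection of stimuli forming a rule-plus-exception design."""

    stimuli: tuple[Stimulus, ...]
    n_features: int
    n_exceptions_per_category: int

    def __post_init__(self) -> None:
        vecs = {s.features for s in self.stimuli}
        if len(vecs) != len(self.stimuli):
            raise ValueError("duplicate feature vectors in structure")
        if any(len(s.features) != self.n_features for s in self.stimuli):
            raise ValueError("feature length mismatch")

    @property
    def n_stimuli(self) -> int:
        return len(self.stimuli)

    @property
    def ids(self) -> np.ndarray:
        return np.array([s.id for s in self.stimuli], dtype=int)

    @property
    def feature_matrix(self) -> np.ndarray:
        """(n_stimuli, n_features) binary matrix in stimulus order."""
        return np.array([s.features for s in self.stimuli], dtype=float)

    @property
    def categories(self) -> np.ndarray:
        return np.array([s.category for s in self.stimuli])

    @property
    def roles(self) -> np.ndarray:
        return np.array([s.role for s in self.stimuli])

    @property
    def is_exception(self) -> np.ndarray:
        return self.roles == "exception"

    @property
    def prototypes(self) -> tuple[Stimulus, Stimulus]:
        """The (A, B) prototype records."""
        protos = {s.category: s for s in self.stimuli if s.role == "prototype"}
        return protos["A"], protos["B"]

    @property
    def prototype_matrix(self) -> np.ndarray:
        """(2, M) array: row 0 the A prototype, row 1 the B prototype."""
        a, b = self.prototypes
        return np.array([a.features, b.features], dtype=float)

    def by_id(self, stimulus_id: int) -> Stimulus:
        for s in self.stimuli:
            if s.id == stimulus_id:
                return s
        raise KeyError(stimulus_id)


def _exception_dims(n_features: int, n_exceptions: int) -> tuple[list[int], list[int]]:
    """Dimensions (0-based) flipped by the exceptions of each category.

    The two categories use *distinct* dimensions, interleaved from the top:
    B-category exceptions flip M-1, M-3, ... of the A prototype; A-category
    exceptions flip M-2, M-4, ... of the B prototype. Distinctness keeps every
    feature imperfectly predictive of category, which is what makes exception
    items diagnostic.
    """
    desc = list(range(n_features - 1, -1, -1))
    dims_b = desc[0::2][:n_exceptions]
    dims_a = desc[1::2][:n_exceptions]
    return dims_a, dims_b


def make_rule_plus_exception(
    n_features: int = 6, n_exceptions_per_category: int = 1
) -> CategoryStructure:
    """Build the rule-plus-exception structure.

    Parameters
    ----------
    n_features : int
        Number of binary feature dimensions M (default 6).
    n_exceptions_per_category : int
        Exceptions per category K. Must satisfy 2*K <= M so that the two
        categories' exceptions can occupy distinct dimensions and all feature
        vectors stay unique.

    Returns
    -------
    CategoryStructure
        2 prototypes, M - max(K, 1) typicals per category, and K exceptions
        per category. The default (6, 1) yields the canonical 14-item set:
        2 prototypes + 10 typicals + 2 exceptions.
    """
    m, k = int(n_features), int(n_exceptions_per_category)
    if m < 2:
        raise ValueError("n_features must be >= 2")
    if k < 0:
        raise ValueError("n_exceptions_per_category must be >= 0")
    if 2 * k > m:
        raise ValueError(
            "n_exceptions_per_category too large: the two categories' "
            "exceptions need distinct dimensions (2*K <= M)"
        )
    if k >= 1 and m < 3:
        # with M = 2 an exception (distance M-1 = 1 from its own prototype)
        # is indistinguishable from a typical
        raise ValueError("exceptions require n_features >= 3")

    proto = {"A": np.zeros(m, dtype=int), "B": np.ones(m, dtype=int)}
    exc_dims = dict(zip("AB", _exception_dims(m, k)))

    stimuli: list[Stimulus] = []
    next_id = 0

    def add(features: np.ndarray, category: str, role: str) -> None:
        nonlocal next_id
        stimuli.append(
            Stimulus(next_id, tuple(int(v) for v in features), category, role)
        )
        next_id += 1

    for cat in CATEGORIES:
        add(proto[cat], cat, "prototype")

    # Typicals flip single dimensions of the own prototype, avoiding the
    # dimensions reserved for the *opposite* category's exceptions (those
    # distance-1 vectors are taken).  With K = 0 the last dimension is left
    # unflipped so the count is M - 1.
    n_typ = m - max(k, 1)
    for cat, opp in (("A", "B"), ("B", "A")):
        candidates = [d for d in range(m) if d not in exc_dims[opp]]
        for d in candidates[:n_typ]:
            v = proto[cat].copy()
            v[d] = 1 - v[d]
            add(v, cat, "typical")

    # Exceptions: own-category items one flip away from the opposite prototype.
    for cat, opp in (("A", "B"), ("B", "A")):
        for d in exc_dims[cat]:
            v = proto[opp].copy()
            v[d] = 1 - v[d]
            add(v, cat, "exception")

    return CategoryStructure(tuple(stimuli), m, k)


def _validate_letter_table(letters, n_features: int) -> None:
    if len(letters) != n_features:
        raise ValueError(f"letter table must have {n_features} rows")
    for row in letters:
        if len(row) != 2:
            raise ValueError("each letter-table row needs exactly 2 letters")
    for m, (a, b) in enumerate(letters):
        if a == b:
            raise ValueError(f"letters at position {m} are not distinct")
        want_vowel = m % 2 == 1
        for ch in (a, b):
            if (ch.lower() in _VOWELS) != want_vowel:
                raise ValueError(
                    "letter table does not alternate consonant/vowel positions"
                )


def render_words(
    structure: CategoryStructure,
    letters=DEFAULT_LETTERS,
    validate: bool = True,
) -> CategoryStructure:
    """Attach nonsense-word renderings to every stimulus.

    The m-th letter of a word is ``letters[m][features[m]]``. With the default
    table the prototypes render to 'gafuzi' and 'livamo'. Set ``validate=False``
    to allow degenerate tables (duplicate letters, broken alternation).
    """
    if validate:
        _validate_letter_table(letters, structure.n_features)
    elif len(letters) != structure.n_features:
        raise ValueError("letter table length mismatch")
    rendered = tuple(
        replace(s, word="".join(letters[m][v] for m, v in enumerate(s.features)))
        for s in structure.stimuli
    )
    return CategoryStructure(
        rendered, structure.n_features, structure.n_exceptions_per_category
    )


def hamming_matrix(structure: CategoryStructure) -> np.ndarray:
    """Pairwise Hamming distances between all stimuli (symmetric, zero diag)."""
    f = structure.feature_matrix
    return np.abs(f[:, None, :] - f[None, :, :]).sum(axis=2)


# ---------------------------------------------------------------------------
# I/O


def structure_to_frame(structure: CategoryStructure) -> pd.DataFrame:
    cols = {
        "id": [s.id for s in structure.stimuli],
        **{
            f"f{m + 1}": [s.features[m] for s in structure.stimuli]
            for m in range(structure.n_features)
        },
        "category": [s.category for s in structure.stimuli],
        "role": [s.role for s in structure.stimuli],
        "word": [s.word for s in structure.stimuli],
    }
    return pd.DataFrame(cols)


def structure_from_frame(df: pd.DataFrame) -> CategoryStructure:
    fcols = sorted(
        (c for c in df.columns if c.startswith("f") and c[1:].isdigit()),
        key=lambda c: int(c[1:]),
    )
    stimuli = tuple(
        Stimulus(
            int(row["id"]),
            tuple(int(row[c]) for c in fcols),
            str(row["category"]),
            str(row["role"]),
            None if pd.isna(row.get("word")) else str(row["word"]),
        )
        for _, row in df.iterrows()
    )
    n_exc = sum(s.role == "exception" and s.category == "A" for s in stimuli)
    return CategoryStructure(stimuli, len(fcols), n_exc)


def write_structure_csv(structure: CategoryStructure, path) -> None:
    structure_to_frame(structure).to_csv(path, index=False)


def read_structure_csv(path) -> CategoryStructure:
    return structure_from_frame(pd.read_csv(path))


def structure_from_config(config: dict) -> CategoryStructure:
    """Build a structure from a YAML-style mapping.

    Recognised keys: ``n_features``, ``n_exceptions_per_category``,
    ``letters`` (optional M x 2 table; triggers word rendering).
    """
    structure = make_rule_plus_exception(
        config.get("n_features", 6), config.get("n_exceptions_per_category", 1)
    )
    if "letters" in config:
        structure = render_words(structure, [tuple(r) for r in config["letters"]])
    return structure


def read_structure_yaml(path) -> CategoryStructure:
    with open(path) as fh:
        return structure_from_config(yaml.safe_load(fh))
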