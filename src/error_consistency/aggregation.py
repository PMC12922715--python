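"""Superclass probability aggregation for fine-grained classifiers.

Image classifiers trained on fine-grained label sets (e.g. the 1,000
ImageNet categories) are scored on the 8 basic-level superclasses
(airplane, boat, car, bike, elephant, bear, dog, bird) by *averaging* the
probabilities of each superclass's constituent fine classes.  Averaging —
rather than summing — is the correct way to handle a prior shift from the
fine training distribution to a balanced superclass test set, so the
scores are deliberately not renormalised before the argmax (renormalised
scores are available separately for reporting).

For embedding models scored by similarity, :func:`softmax_scores` turns a
vector of similarities into fine-class probabilities first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy.special import softmax as _softmax

__all__ = [
    "SUPERCLASSES",
    "FineProbabilityVector",
    "SuperClassMap",
    "SuperClassScores",
    "aggregate_probabilities",
    "decide_class",
    "softmax_scores",
    "read_superclass_map",
]

SUPERCLASSES = (
    "airplane", "bear", "bike", "bird", "boat", "car", "dog", "elephant",
)

_NORM_TOL = 1e-6


@dataclass(frozen=True)
class FineProbabilityVector:
    """A length-K probability vector over fine-grained class ids."""

    class_ids: tuple
    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        ids = tuple(self.class_ids)
        if probs.ndim != 1 or probs.size != len(ids):
            raise ValueError("class_ids and probs must be aligned 1-D")
        if (probs < 0).any():
            raise ValueError("probabilities must be nonnegative")
        if abs(probs.sum() - 1.0) > _NORM_TOL:
            raise ValueError(f"probabilities sum to {probs.sum()!r}, not 1")
        object.__setattr__(self, "class_ids", ids)
        object.__setattr__(self, "probs", probs)


@dataclass(frozen=True)
class SuperClassMap:
    """Partial map from fine class id to one of the 8 superclasses."""

    mapping: Mapping[object, str]

    def __post_init__(self) -> None:
        mapping = dict(self.mapping)
        bad = {s for s in mapping.values() if s not in SUPERCLASSES}
        if bad:
            raise ValueError(f"unknown superclasses in map: {sorted(bad)}")
        object.__setattr__(self, "mapping", mapping)

    def constituents(self, superclass: str) -> list:
        return [k for k, v in self.mapping.items() if v == superclass]


@dataclass(frozen=True)
class SuperClassScores:
    """Aggregated (mean-constituent) scores for the 8 superclasses."""

    scores: Mapping[str, float]

    @property
    def normalized(self) -> dict[str, float]:
        total = sum(self.scores.values())
        if total <= 0:
            return {k: float("nan") for k in self.scores}
        return {k: v / total for k, v in self.scores.items()}


def aggregate_probabilities(
    v: FineProbabilityVector, m: SuperClassMap
) -> SuperClassScores:
    """Mean constituent probability per superclass; unmapped classes ignored.

    Raises
    ------
    ValueError
        If some superclass has no constituent present in ``v``.
    """
    index = {cid: i for i, cid in enumerate(v.class_ids)}
    scores: dict[str, float] = {}
    for sc in SUPERCLASSES:
        members = [index[c] for c in m.constituents(sc) if c in index]
        if not members:
            raise ValueError(f"superclass {sc!r} has no constituents in the vector")
        scores[sc] = float(v.probs[members].mean())
    return SuperClassScores(scores)


def decide_class(
    scores: SuperClassScores,
    tie_rule: str = "fixed",
    seed: int | None = None,
) -> str:
    """Argmax decision over the 8 superclass scores.

    Ties are broken by the canonical (alphabetical) label order under the
    default ``fixed`` rule, or uniformly at random (reproducible under
    ``seed``) under ``random``.
    """
    vals = np.array([scores.scores[sc] for sc in SUPERCLASSES])
    winners = np.flatnonzero(vals == vals.max())
    if tie_rule == "fixed" or winners.size == 1:
        return SUPERCLASSES[winners[0]]
    if tie_rule == "random":
        rng = np.random.default_rng(seed)
        return SUPERCLASSES[rng.choice(winners)]
    raise ValueError(f"unknown tie rule {tie_rule!r}")


def softmax_scores(
    similarities: Sequence[float],
    class_ids: Sequence | None = None,
    temperature: float = 1.0,
) -> FineProbabilityVector:
    """Softmax over similarity scores (max-subtracted for stability)."""
    sims = np.asarray(similarities, dtype=float)
    if not np.isfinite(sims).all():
        raise ValueError("similarities must be finite")
    if temperature <= 0:
        raise ValueError("temperature must be > 0")
    if class_ids is None:
        class_ids = tuple(range(sims.size))
    return FineProbabilityVector(tuple(class_ids), _softmax(sims / temperature))


def read_superclass_map(path) -> SuperClassMap:
    """Read a two-column delimited text map (fine_class_id, superclass)."""
    import pandas as pd

    df = pd.read_csv(path, sep=None, engine="python", comment="#")
    if df.shape[1] != 2:
        raise ValueError("superclass map must have exactly two columns")
    fine, sup = df.columns
    return SuperClassMap(dict(zip(df[fine], df[sup])))
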