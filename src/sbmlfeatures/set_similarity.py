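"""Semantic similarity between feature sets.

Two ontology concepts are compared with a path-length/depth measure in the
style of Li et al.:

    S(c1, c2) = exp(-alpha * l) * tanh(beta * h)

where ``l`` is the shortest is_a path length between the concepts through
their least common subsumer and ``h`` is the depth of that subsumer.  The
exponential discounts distant concepts, the tanh saturates with depth: a
deep shared subsumer means the concepts agree on a lot of specific
classification, a root-level subsumer (h = 0) means they share nothing and
the similarity is 0.  Defaults alpha = 0.2, beta = 0.6.  Identical concepts
score exactly 1 by convention (the raw formula saturates below 1).

Two *sets* of features are compared by scoring every cross pair, aligning
features one-to-one with the Hungarian method (maximum total weight), and
normalizing the matched weight by the larger set size, which penalizes
unmatched features and makes self-similarity exactly 1.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .errors import InputError
from .feature_extraction import FeatureSet
from .ontology import Taxonomy

__all__ = [
    "SimilarityParams",
    "SimilarityReport",
    "concept_similarity",
    "similarity_matrix",
    "hungarian_assignment",
    "set_similarity",
]


@dataclass(frozen=True)
class SimilarityParams:
    """Path-length decay ``alpha`` and depth-saturation ``beta``."""

    alpha: float = 0.2
    beta: float = 0.6

    def __post_init__(self):
        if self.alpha < 0 or self.beta < 0:
            raise InputError("alpha and beta must be non-negative")


@dataclass
class SimilarityReport:
    """Pairwise matrix, optimal one-to-one alignment, and total similarity."""

    matrix: np.ndarray
    assignment: list[tuple[int, int]]
    total: float
    a_ids: list[str]
    b_ids: list[str]

    def to_dict(self) -> dict:
        return {
            "a_ids": self.a_ids,
            "b_ids": self.b_ids,
            "matrix": np.asarray(self.matrix).tolist(),
            "assignment": [list(p) for p in self.assignment],
            "total": self.total,
        }

    def dump(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)


def concept_similarity(
    t: Taxonomy, c1: str, c2: str, prm: SimilarityParams | None = None
) -> float:
    """Path/depth similarity of two concepts; 1.0 for identical ids."""
    prm = prm or SimilarityParams()
    if c1 not in t or c2 not in t:
        missing = c1 if c1 not in t else c2
        raise KeyError(f"unknown concept {missing!r}")
    if c1 == c2:
        return 1.0
    lcs = t.least_common_subsumer(c1, c2)
    l = t.path_length(c1, c2)
    h = t.depth(lcs)
    return math.exp(-prm.alpha * l) * math.tanh(prm.beta * h)


def similarity_matrix(
    t: Taxonomy,
    a: FeatureSet,
    b: FeatureSet,
    prm: SimilarityParams | None = None,
) -> np.ndarray:
    """|A| x |B| matrix of pairwise concept similarities."""
    if a.ontology != b.ontology:
        raise InputError(
            f"cannot compare feature sets from different ontologies "
            f"({a.ontology!r} vs {b.ontology!r})"
        )
    prm = prm or SimilarityParams()
    m = np.zeros((len(a), len(b)))
    for i, fi in enumerate(a.features):
        for j, fj in enumerate(b.features):
            m[i, j] = concept_similarity(t, fi.id, fj.id, prm)
    return m


def hungarian_assignment(m: np.ndarray) -> list[tuple[int, int]]:
    """Maximum-total-weight one-to-one matching of size min(rows, cols)."""
    m = np.asarray(m, dtype=float)
    if m.size == 0:
        return []
    if not np.all(np.isfinite(m)) or np.any(m < 0):
        raise InputError("similarity matrix must be finite and non-negative")
    rows, cols = linear_sum_assignment(m, maximize=True)
    return sorted(zip(rows.tolist(), cols.tolist()))


def set_similarity(
    t: Taxonomy,
    a: FeatureSet,
    b: FeatureSet,
    prm: SimilarityParams | None = None,
) -> SimilarityReport:
    """Total similarity of two feature sets in [0, 1].

    ``total = (sum of matched pair similarities) / max(|A|, |B|)``;
    identical non-empty sets score exactly 1, sets whose features live in
    disjoint root branches score 0.
    """
    prm = prm or SimilarityParams()
    m = similarity_matrix(t, a, b, prm)
    if len(a) == 0 or len(b) == 0:
        warnings.warn("comparing an empty feature set; total similarity is 0",
                      stacklevel=2)
        return SimilarityReport(m, [], 0.0, a.ids, b.ids)
    assignment = hungarian_assignment(m)
    matched = float(sum(m[i, j] for i, j in assignment))
    total = matched / max(len(a), len(b))
    return SimilarityReport(m, assignment, total, a.ids, b.ids)
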