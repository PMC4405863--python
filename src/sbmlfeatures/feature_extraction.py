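"""Condense a taxonomy (optionally weighted by corpus annotations) into at
most ``max_features`` characteristic concepts.

Four methods are provided:

* **Method 1** — static top-down clustering.  Starting from the root, the
  frontier concept with the largest probability ``p(c)`` is repeatedly
  replaced by its children while the frontier fits the feature budget.  The
  result depends only on the ontology, not on any model set.
* **Method 2** — top-down clustering driven by the corpus: the ranking
  quantity is the entity probability ``ep(c) = EF(c)/EF(root)`` and only
  concepts with aggregated entity frequency ``EF > 0`` may enter the
  frontier.  A directly annotated concept that is split stays in the result
  as a non-splittable member, so every annotated concept remains covered by
  a feature that subsumes it.
* **Method 3** — bottom-up clustering over the same quantities.  Clusters
  start at the directly annotated concepts and are merged into their
  parents in ascending ``ep`` order until the budget is met.  The merge
  order is the exact inverse of Method 2's split order, so on trees the two
  methods provably return identical feature sets whenever no ``ep`` tie
  forces an arbitrary choice; ties are detected and reported.
* **Method 4** — overgeneralization-aware scoring.  Each directly annotated
  concept is represented by the self-inclusive ancestor maximizing
  ``Score_T(c) = IC(c) * EF(c)``; the distinct representatives are the
  features.  High IC pulls representatives down, high EF pulls them up, so
  the method balances specificity against support and typically returns
  fewer, deeper features than Method 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .annotation_harvest import CorpusIndex
from .errors import InputError
from .ontology import Taxonomy

__all__ = [
    "ExtractionConfig",
    "Feature",
    "FeatureSet",
    "method1_static",
    "method2_topdown",
    "method3_bottomup",
    "method4_scored",
    "score_T",
    "extract",
]


@dataclass(frozen=True)
class ExtractionConfig:
    """Method number, feature budget, and document-frequency floor.

    ``max_features`` defaults to 15 (5 is the usual alternate budget);
    ``min_df`` of 0/1 disables vocabulary reduction.  Ties are always broken
    lexicographically by concept id — the rule is fixed so that every method
    is deterministic.
    """

    method: int = 4
    max_features: int = 15
    min_df: int = 1
    tie_break: str = "lex"

    def __post_init__(self):
        if self.method not in (1, 2, 3, 4):
            raise InputError(f"unknown method {self.method}; expected 1-4")
        if self.max_features < 1:
            raise InputError("max_features must be >= 1")
        if self.min_df < 0:
            raise InputError("min_df must be >= 0")


@dataclass(frozen=True)
class Feature:
    """One characteristic concept with its bookkeeping quantities."""

    id: str
    depth: int
    ef: int
    ep: float
    ic: float
    score: float


@dataclass
class FeatureSet:
    """The bounded list of concepts characterizing (corpus, ontology, method)."""

    ontology: str
    method: int
    features: list[Feature]
    corpus_id: str = ""
    max_features: int | None = None
    ties: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.features)

    @property
    def ids(self) -> list[str]:
        return [f.id for f in self.features]

    @property
    def average_depth(self) -> float:
        if not self.features:
            raise InputError("average depth of an empty feature set is undefined")
        return sum(f.depth for f in self.features) / len(self.features)

    @property
    def tied(self) -> bool:
        return bool(self.ties)

    def to_dict(self) -> dict:
        return {
            "ontology": self.ontology,
            "method": self.method,
            "corpus_id": self.corpus_id,
            "max_features": self.max_features,
            "average_depth": self.average_depth if self.features else None,
            "ties": self.ties,
            "features": [vars(f) for f in self.features],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSet":
        return cls(
            ontology=d["ontology"],
            method=d["method"],
            corpus_id=d.get("corpus_id", ""),
            max_features=d.get("max_features"),
            ties=list(d.get("ties", [])),
            features=[Feature(**f) for f in d["features"]],
        )


def short_id(cid: str) -> str:
    """Table-style shortened id: drop the prefix and leading zeros, keep at
    least three digits (SBO:0000064 -> 064)."""
    tail = cid.split(":", 1)[-1]
    if tail.isdigit():
        return tail.lstrip("0").rjust(3, "0")
    return tail


def score_T(t: Taxonomy, idx: CorpusIndex, cid: str) -> float:
    """Representativeness score ``IC(c) * EF(c)``: information content times
    aggregated entity frequency.  Zero at the root (IC 0) and for concepts
    without annotation support (EF 0)."""
    return t.ic(cid) * idx.EF(cid)


def _build_feature(t: Taxonomy, idx: CorpusIndex | None, cid: str) -> Feature:
    if idx is None:
        return Feature(cid, t.depth(cid), 0, 0.0, t.ic(cid), 0.0)
    return Feature(
        cid, t.depth(cid), idx.EF(cid), idx.entity_probability(cid),
        t.ic(cid), score_T(t, idx, cid),
    )


def _finalize(
    t: Taxonomy,
    idx: CorpusIndex | None,
    ids,
    method: int,
    cfg: ExtractionConfig,
    ties: list[str],
    corpus_id: str = "",
) -> FeatureSet:
    ids = set(ids)
    if t.synthetic_root:
        ids.discard(t.root)
    return FeatureSet(
        ontology=t.ontology,
        method=method,
        features=[_build_feature(t, idx, c) for c in sorted(ids)],
        corpus_id=corpus_id,
        max_features=cfg.max_features,
        ties=ties,
    )


def _topdown(t, rank, pos_children, retain, max_features):
    """Shared frontier-splitting engine for methods 1 and 2.

    Splits happen in strictly descending ``(rank, id)`` order — rank first,
    smaller id first among equal ranks — and the loop stops at the first
    split that would push the frontier past the budget.  Method 3 merges in
    the exact reverse order, so the two corpus-driven methods coincide; the
    one constellation where the shared order breaks down (a child with the
    same rank as its parent but a smaller id, which enters the frontier
    after the parent's turn has passed) is recorded as a tie.
    """
    active = {t.root}
    retired: set[str] = set()
    ties: list[str] = []
    while True:
        splittable = [c for c in active if pos_children(c)]
        if not splittable:
            break
        chosen = min(splittable, key=lambda c: (-rank(c), c))
        incoming = pos_children(chosen) - active - retired
        new_size = (
            len(active) + len(retired) - 1 + len(incoming) + (1 if retain(chosen) else 0)
        )
        if new_size > max_features:
            break
        for ch in incoming:
            if rank(ch) == rank(chosen) and ch < chosen:
                ties.append(f"order:{chosen}<>{ch}")
        active.discard(chosen)
        active |= incoming
        if retain(chosen):
            retired.add(chosen)
    return active | retired, ties


def method1_static(t: Taxonomy, cfg: ExtractionConfig | None = None) -> FeatureSet:
    """Static top-down clustering by concept probability ``p(c)``."""
    cfg = cfg or ExtractionConfig(method=1)
    ids, ties = _topdown(
        t,
        rank=t.p,
        pos_children=lambda c: t.children(c),
        retain=lambda c: False,
        max_features=cfg.max_features,
    )
    return _finalize(t, None, ids, 1, cfg, ties)


def method2_topdown(
    t: Taxonomy, idx: CorpusIndex, cfg: ExtractionConfig | None = None
) -> FeatureSet:
    """Corpus-driven top-down clustering by entity probability ``ep(c)``."""
    cfg = cfg or ExtractionConfig(method=2)
    if idx.EF(t.root) == 0:
        warnings.warn("corpus index is empty; returning an empty feature set",
                      stacklevel=2)
        return _finalize(t, idx, [], 2, cfg, [], corpus_id=_corpus_id(idx))
    ids, ties = _topdown(
        t,
        rank=idx.entity_probability,
        pos_children=lambda c: {ch for ch in t.children(c) if idx.EF(ch) > 0},
        retain=lambda c: idx.direct_count.get(c, 0) > 0,
        max_features=cfg.max_features,
    )
    return _finalize(t, idx, ids, 2, cfg, ties, corpus_id=_corpus_id(idx))


def method3_bottomup(
    t: Taxonomy, idx: CorpusIndex, cfg: ExtractionConfig | None = None
) -> FeatureSet:
    """Bottom-up clustering: merge annotated concepts into their parents in
    ascending ``ep`` order until at most ``max_features`` clusters remain.

    A parent is *mergeable* when every one of its EF>0 children is a current
    representative and, if the parent itself carries direct annotations, the
    parent is one too.  Merging replaces those children by the parent.
    Merges are ordered by (ep ascending, id descending) — the exact reverse
    of Method 2's split order — so on trees the two methods return the same
    feature set, except when an equal-ep parent/child pair with inverted
    ids makes the shared order ambiguous (reported as a tie).
    """
    cfg = cfg or ExtractionConfig(method=3)
    if idx.EF(t.root) == 0:
        warnings.warn("corpus index is empty; returning an empty feature set",
                      stacklevel=2)
        return _finalize(t, idx, [], 3, cfg, [], corpus_id=_corpus_id(idx))
    reps = set(idx.annotated_concepts())
    ties: list[str] = []

    def pos_children(c):
        return {ch for ch in t.children(c) if idx.EF(ch) > 0}

    while len(reps) > cfg.max_features:
        parents = set()
        for r in reps:
            parents |= t.parents(r)
        mergeable = [
            p
            for p in parents
            if pos_children(p) <= reps
            and (idx.direct_count.get(p, 0) == 0 or p in reps)
        ]
        if not mergeable:
            warnings.warn(
                "no mergeable parent; returning more clusters than requested",
                stacklevel=2,
            )
            break
        chosen = max(mergeable, key=lambda c: (-idx.entity_probability(c), c))
        ep_c = idx.entity_probability(chosen)
        for ch in pos_children(chosen):
            if idx.entity_probability(ch) == ep_c and ch < chosen:
                ties.append(f"order:{chosen}<>{ch}")
        reps -= pos_children(chosen)
        reps.add(chosen)
    return _finalize(t, idx, reps, 3, cfg, ties, corpus_id=_corpus_id(idx))


def _climb(t, idx, cid, ties: list[str], force_first_step: bool = False):
    """Merge ``cid`` upward while the representative's Score_T strictly
    improves; returns the reached local score maximum.

    Among parents sharing the best score the deepest, then lexicographically
    smallest, is taken (a genuine tie is recorded).  ``force_first_step``
    moves to the best parent unconditionally before climbing — used when
    the feature budget forces representatives to generalize further.
    """
    current = cid
    first = force_first_step
    while True:
        parents = t.parents(current)
        if not parents:
            return current
        ranked = sorted(
            parents, key=lambda a: (-score_T(t, idx, a), -t.depth(a), a)
        )
        best = ranked[0]
        if len(ranked) > 1 and (
            score_T(t, idx, ranked[1]) == score_T(t, idx, best)
            and t.depth(ranked[1]) == t.depth(best)
        ):
            ties.append(f"parent:{current}")
        if not first and score_T(t, idx, best) <= score_T(t, idx, current):
            return current
        current = best
        first = False


def method4_scored(
    t: Taxonomy, idx: CorpusIndex, cfg: ExtractionConfig | None = None
) -> FeatureSet:
    """Score-based clustering: each directly annotated concept is merged
    with the ancestor reaching the highest possible ``Score_T = IC * EF``
    (upward hill-climb, stopping once no parent strictly improves the
    score); the distinct representatives are the features.

    High IC keeps representatives specific, high aggregated EF rewards
    ancestors with broad annotation support; a well-supported concept
    represents itself.  If the representatives still exceed the budget,
    each is forced one step up and re-climbed, repeating until the budget
    is met (score-ranked truncation is the last resort).
    """
    cfg = cfg or ExtractionConfig(method=4)
    annotated = idx.annotated_concepts()
    if not annotated:
        return _finalize(t, idx, [], 4, cfg, [], corpus_id=_corpus_id(idx))
    ties: list[str] = []
    reps = {_climb(t, idx, c, ties) for c in annotated}
    while len(reps) > cfg.max_features:
        # generalize the weakest representative one step (then re-climb);
        # an ancestor with zero score (the root, or an unannotated branch)
        # carries no information and never absorbs a representative
        movable = [
            r
            for r in reps
            if t.parents(r)
            and max(score_T(t, idx, p) for p in t.parents(r)) > 0.0
        ]
        if not movable:
            reps = set(
                sorted(reps, key=lambda c: (-score_T(t, idx, c), c))[: cfg.max_features]
            )
            warnings.warn("feature budget enforced by score truncation",
                          stacklevel=2)
            break
        weakest = min(movable, key=lambda c: (score_T(t, idx, c), c))
        reps.discard(weakest)
        target = _climb(t, idx, weakest, ties, force_first_step=True)
        # group fusion: if the climb lands inside an existing representative's
        # subtree, the weak group joins that feature instead of adding a new one
        if not (t.ancestors(target) - {target}) & reps:
            reps.add(target)
    return _finalize(t, idx, reps, 4, cfg, ties, corpus_id=_corpus_id(idx))


def _corpus_id(idx: CorpusIndex) -> str:
    return f"{len(idx.models)}models"


def extract(
    t: Taxonomy, idx: CorpusIndex | None, cfg: ExtractionConfig
) -> FeatureSet:
    """Dispatch to the configured method (applying the ``min_df`` filter for
    the corpus-driven methods)."""
    if cfg.method == 1:
        return method1_static(t, cfg)
    if idx is None:
        raise InputError(f"method {cfg.method} requires a corpus index")
    if cfg.min_df > 1:
        from .annotation_harvest import df_filter

        idx = df_filter(idx, cfg.min_df)
    fn = {2: method2_topdown, 3: method3_bottomup, 4: method4_scored}[cfg.method]
    return fn(t, idx, cfg)


def to_tsv(fs: FeatureSet, path) -> None:
    """Write a feature table with shortened ids (e.g. SBO:0000064 -> 064)."""
    with open(path, "w") as fh:
        fh.write("short_id\tconcept_id\tdepth\tEF\tep\tic\tscore\n")
        for f in fs.features:
            fh.write(
                f"{short_id(f.id)}\t{f.id}\t{f.depth}\t{f.ef}\t"
                f"{f.ep:.6g}\t{f.ic:.6g}\t{f.score:.6g}\n"
            )
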