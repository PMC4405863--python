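"""Descriptive statistics of annotation corpora and feature sets: depth
distributions, top-level branch distributions, average feature depth, and
feature overlaps between sets (Venn cells)."""

from __future__ import annotations

import json
from dataclasses import dataclass

from .annotation_harvest import CorpusIndex
from .errors import InputError
from .feature_extraction import FeatureSet
from .ontology import Taxonomy

__all__ = [
    "DepthDistribution",
    "BranchDistribution",
    "depth_distribution",
    "branch_distribution",
    "average_feature_depth",
    "feature_overlap",
]


@dataclass
class DepthDistribution:
    """Histogram of annotated-concept depths; one entry per resolved record."""

    counts: dict[int, int]
    average: float

    @property
    def n_records(self) -> int:
        return sum(self.counts.values())

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("depth\tcount\n")
            for d in sorted(self.counts):
                fh.write(f"{d}\t{self.counts[d]}\n")


@dataclass
class BranchDistribution:
    """Per top-level branch: share of taxonomy concepts and share of
    annotation records.  The two shares are independent quantities — a small
    branch may attract most of the annotations.  The root belongs to no
    branch; records directly on the root are reported separately.  On DAGs
    a concept may fall under several branches, so shares can exceed 1 and
    are flagged as overlapping."""

    concept_share: dict[str, float]
    annotation_share: dict[str, float]
    root_annotation_share: float = 0.0
    overlapping: bool = False

    def to_dict(self) -> dict:
        return {
            "concept_share": self.concept_share,
            "annotation_share": self.annotation_share,
            "root_annotation_share": self.root_annotation_share,
            "overlapping": self.overlapping,
        }


def depth_distribution(t: Taxonomy, idx: CorpusIndex) -> DepthDistribution:
    """Depth histogram over resolved annotation records; each record
    contributes the depth of its concept once."""
    counts: dict[int, int] = {}
    total_depth = 0
    for rec in idx.records:
        d = t.depth(rec.concept_id)
        counts[d] = counts.get(d, 0) + 1
        total_depth += d
    n = sum(counts.values())
    return DepthDistribution(counts=counts, average=(total_depth / n) if n else 0.0)


def branch_distribution(t: Taxonomy, idx: CorpusIndex) -> BranchDistribution:
    """Concept and annotation shares of the root's top-level branches."""
    branches = sorted(t.children(t.root))
    if not branches:
        raise InputError("taxonomy root has no children; no branches to report")

    membership: dict[str, frozenset] = {
        b: t.descendants(b) | {b} for b in branches
    }
    # a concept under two branches (DAG) makes the shares overlap
    seen: set[str] = set()
    overlapping = False
    for b in branches:
        if membership[b] & seen:
            overlapping = True
        seen |= membership[b]

    total_concepts = sum(len(membership[b]) for b in branches)
    concept_share = {
        b: len(membership[b]) / total_concepts for b in branches
    }

    root_ef = idx.EF(t.root)
    if root_ef:
        annotation_share = {b: idx.EF(b) / root_ef for b in branches}
        root_share = idx.direct_count.get(t.root, 0) / root_ef
    else:
        annotation_share = {b: 0.0 for b in branches}
        root_share = 0.0
    return BranchDistribution(
        concept_share=concept_share,
        annotation_share=annotation_share,
        root_annotation_share=root_share,
        overlapping=overlapping,
    )


def average_feature_depth(fs: FeatureSet) -> float:
    """Mean depth of the features (the per-table "avg depth" statistic)."""
    return fs.average_depth


def feature_overlap(sets: list[FeatureSet]) -> dict[frozenset, int]:
    """Venn cells over >= 2 feature sets from the same ontology: for every
    non-empty subset of set indices, the number of concepts belonging to
    exactly those sets.  Cell counts sum to the size of the union."""
    if len(sets) < 2:
        raise InputError("feature_overlap needs at least two feature sets")
    ontologies = {fs.ontology for fs in sets}
    if len(ontologies) > 1:
        raise InputError(f"mixed ontologies in overlap: {sorted(ontologies)}")
    members = [set(fs.ids) for fs in sets]
    union = set().union(*members)
    cells: dict[frozenset, int] = {}
    for cid in union:
        pattern = frozenset(i for i, m in enumerate(members) if cid in m)
        cells[pattern] = cells.get(pattern, 0) + 1
    return cells


def overlap_to_json(cells: dict[frozenset, int], path) -> None:
    payload = {
        "+".join(str(i) for i in sorted(k)): v for k, v in sorted(
            cells.items(), key=lambda kv: sorted(kv[0])
        )
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1)
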