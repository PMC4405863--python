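"""Taxonomy model of an is_a ontology and its information-theoretic statics.

A bio-ontology (GO, ChEBI, SBO, or any is_a taxonomy) is represented as a
rooted DAG of :class:`Concept` nodes.  For every concept ``c`` the taxonomy
provides

* ``freq(c)`` — the number of concepts subsumed by ``c``, self-inclusive,
  with multi-path descendants counted once;
* ``p(c) = freq(c) / N`` — the probability that a uniformly chosen concept
  is classified under ``c`` (``N`` is the total concept count);
* ``IC(c) = -log2 p(c)`` — the information content in bits.  The root
  subsumes everything, so ``p(root) = 1`` and ``IC(root) = 0``; rare, deep
  concepts carry more information;
* ``depth(c)`` — the shortest is_a path length from the root (a DAG admits
  several depths; the shortest one is deterministic and is the convention
  used throughout the package, in particular for the ``h`` term of the
  path/depth similarity measure);
* least common subsumer and shortest is_a path length between concepts.

Only is_a edges are used so that GO, ChEBI and SBO are handled uniformly;
part_of and other relations are ignored.  Multi-rooted ontologies (such as
GO's three namespaces) receive a synthetic root at depth 0, which makes the
LCS of concepts from different namespaces the synthetic root and their
similarity zero.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Iterable, Mapping

import networkx as nx
import obonet

from .errors import InputError, TaxonomyError

__all__ = [
    "Concept",
    "ConceptStatics",
    "Taxonomy",
    "load_obo",
    "concept_statics",
    "least_common_subsumer",
    "path_length",
]


@dataclass
class Concept:
    """One ontology term: an identifier, a label, and its is_a neighbourhood."""

    id: str
    name: str = ""
    parents: set[str] = field(default_factory=set)
    children: set[str] = field(default_factory=set)
    namespace: str | None = None


@dataclass(frozen=True)
class ConceptStatics:
    """Static per-concept quantities: subsumed-concept count, probability,
    information content (bits) and depth (shortest path from root)."""

    freq: int
    p: float
    ic: float
    depth: int


class Taxonomy:
    """A rooted is_a DAG with cached structural statistics.

    Parameters
    ----------
    concepts:
        Mapping id -> :class:`Concept`.  Parent/child links must be mutually
        consistent; construction validates acyclicity and reachability.
    root:
        Identifier of the single root concept.
    ontology:
        Prefix tag such as ``"GO"``; used to refuse cross-ontology
        comparisons downstream.
    synthetic_root:
        True when the root was inserted to join a multi-rooted ontology.
    """

    def __init__(
        self,
        concepts: dict[str, Concept],
        root: str,
        ontology: str = "",
        synthetic_root: bool = False,
    ):
        if root not in concepts:
            raise TaxonomyError(f"root {root!r} not among concepts")
        self.concepts = concepts
        self.root = root
        self.ontology = ontology
        self.synthetic_root = synthetic_root
        self._graph = nx.DiGraph()  # edges parent -> child
        self._graph.add_nodes_from(concepts)
        for c in concepts.values():
            for p in c.parents:
                if p not in concepts:
                    raise TaxonomyError(f"{c.id} names unknown parent {p}")
                self._graph.add_edge(p, c.id)
        self._validate()
        self._depth: dict[str, int] = dict(
            nx.shortest_path_length(self._graph, source=root)
        )
        unreachable = set(concepts) - set(self._depth)
        if unreachable:
            raise TaxonomyError(
                f"concepts unreachable from root: {sorted(unreachable)[:5]}"
            )
        self._desc: dict[str, frozenset[str]] | None = None

    # -- construction helpers -------------------------------------------------

    @classmethod
    def from_parents(
        cls,
        parent_map: Mapping[str, Iterable[str]],
        ontology: str = "",
        names: Mapping[str, str] | None = None,
    ) -> "Taxonomy":
        """Build a taxonomy from an id -> parents mapping (root has none)."""
        names = names or {}
        concepts = {
            cid: Concept(cid, names.get(cid, ""), parents=set(ps))
            for cid, ps in parent_map.items()
        }
        for c in concepts.values():
            for p in c.parents:
                if p in concepts:
                    concepts[p].children.add(c.id)
        roots = sorted(cid for cid, c in concepts.items() if not c.parents)
        if len(roots) != 1:
            raise TaxonomyError(f"expected exactly one root, found {roots}")
        return cls(concepts, roots[0], ontology=ontology)

    def _validate(self) -> None:
        for cid, c in self.concepts.items():
            for p in c.parents:
                if cid not in self.concepts[p].children:
                    raise TaxonomyError(f"inconsistent link {cid} -> {p}")
        if not nx.is_directed_acyclic_graph(self._graph):
            cycle = nx.find_cycle(self._graph)
            raise TaxonomyError(f"is_a cycle detected involving {cycle[0][0]!r}")

    # -- basic queries --------------------------------------------------------

    def __contains__(self, cid: str) -> bool:
        return cid in self.concepts

    def __len__(self) -> int:
        return len(self.concepts)

    @property
    def N(self) -> int:
        """Total concept count (includes a synthetic root if one was added)."""
        return len(self.concepts)

    def _require(self, cid: str) -> None:
        if cid not in self.concepts:
            raise KeyError(f"unknown concept {cid!r} in ontology {self.ontology!r}")

    def parents(self, cid: str) -> set[str]:
        self._require(cid)
        return set(self.concepts[cid].parents)

    def children(self, cid: str) -> set[str]:
        self._require(cid)
        return set(self.concepts[cid].children)

    def depth(self, cid: str) -> int:
        self._require(cid)
        return self._depth[cid]

    # -- statics (Resnik-style) ----------------------------------------------

    def _descendant_sets(self) -> dict[str, frozenset[str]]:
        if self._desc is None:
            desc: dict[str, frozenset[str]] = {}
            for node in reversed(list(nx.topological_sort(self._graph))):
                acc: set[str] = set()
                for ch in self.concepts[node].children:
                    acc.add(ch)
                    acc |= desc[ch]
                desc[node] = frozenset(acc)
            self._desc = desc
        return self._desc

    def descendants(self, cid: str) -> frozenset[str]:
        """Strict descendants of ``cid`` as a set (multi-path counted once)."""
        self._require(cid)
        return self._descendant_sets()[cid]

    def freq(self, cid: str) -> int:
        return len(self.descendants(cid)) + 1

    def p(self, cid: str) -> float:
        return self.freq(cid) / self.N

    def ic(self, cid: str) -> float:
        p = self.p(cid)
        return 0.0 if p == 1.0 else -math.log2(p)

    def statics(self, cid: str) -> ConceptStatics:
        return ConceptStatics(
            freq=self.freq(cid), p=self.p(cid), ic=self.ic(cid), depth=self.depth(cid)
        )

    # -- ancestors, LCS, path length ------------------------------------------

    @lru_cache(maxsize=None)
    def _up_distances(self, cid: str) -> dict[str, int]:
        """Shortest upward is_a distance from ``cid`` to each ancestor
        (self-inclusive, distance 0 to itself)."""
        self._require(cid)
        dist = {cid: 0}
        frontier = [cid]
        while frontier:
            nxt = []
            for node in frontier:
                for p in self.concepts[node].parents:
                    if p not in dist:
                        dist[p] = dist[node] + 1
                        nxt.append(p)
            frontier = nxt
        return dist

    def ancestors(self, cid: str) -> frozenset[str]:
        """Self-inclusive ancestor set."""
        return frozenset(self._up_distances(cid))

    def least_common_subsumer(self, c1: str, c2: str) -> str:
        """Deepest common ancestor; depth ties broken by smallest id."""
        common = self.ancestors(c1) & self.ancestors(c2)
        best_depth = max(self._depth[a] for a in common)
        return min(a for a in common if self._depth[a] == best_depth)

    def path_length(self, c1: str, c2: str) -> int:
        """Shortest is_a path length through the least common subsumer."""
        lcs = self.least_common_subsumer(c1, c2)
        return self._up_distances(c1)[lcs] + self._up_distances(c2)[lcs]

    # -- serialization ---------------------------------------------------------

    def statics_table(self) -> dict[str, dict]:
        return {
            cid: {
                "freq": self.freq(cid),
                "p": self.p(cid),
                "ic": self.ic(cid),
                "depth": self.depth(cid),
            }
            for cid in sorted(self.concepts)
        }

    def dump_statics(self, path) -> None:
        """Write the per-concept statics (id, freq, p, ic, depth) as JSON."""
        payload = {
            "ontology": self.ontology,
            "root": self.root,
            "N": self.N,
            "concepts": self.statics_table(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)


def load_obo(path, prefix: str) -> Taxonomy:
    """Load an OBO flat file into a :class:`Taxonomy`.

    Only ``is_a`` edges are kept; obsolete terms and all other relationship
    types are dropped.  If the file has more than one is_a root, a synthetic
    root ``<prefix>:ROOT`` is inserted with the natural roots as children.
    """
    try:
        graph = obonet.read_obo(path, ignore_obsolete=True)
    except FileNotFoundError as exc:
        raise InputError(f"cannot read OBO file {path!r}: {exc}") from exc
    except Exception as exc:  # obonet/networkx parse failures
        raise InputError(f"cannot parse OBO file {path!r}: {exc}") from exc
    concepts: dict[str, Concept] = {}
    for node, data in graph.nodes(data=True):
        concepts[node] = Concept(
            id=node, name=data.get("name", ""), namespace=data.get("namespace")
        )
    if not concepts:
        raise InputError(f"OBO file {path!r} contains no non-obsolete terms")
    # obonet edges run child -> parent, keyed by relationship type
    for child, parent, rel in graph.edges(keys=True):
        if rel != "is_a" or parent not in concepts:
            continue
        concepts[child].parents.add(parent)
        concepts[parent].children.add(child)
    roots = sorted(cid for cid, c in concepts.items() if not c.parents)
    if not roots:
        g = nx.DiGraph(
            (p, cid) for cid, c in concepts.items() for p in c.parents
        )
        cycle = nx.find_cycle(g)
        raise TaxonomyError(f"is_a cycle detected involving {cycle[0][0]!r}")
    synthetic = False
    if len(roots) > 1:
        root = f"{prefix}:ROOT"
        concepts[root] = Concept(id=root, name=f"synthetic {prefix} root")
        for r in roots:
            concepts[r].parents.add(root)
            concepts[root].children.add(r)
        synthetic = True
    else:
        root = roots[0]
    return Taxonomy(concepts, root, ontology=prefix, synthetic_root=synthetic)


# Thin functional facade over the Taxonomy methods.

def concept_statics(t: Taxonomy, cid: str) -> ConceptStatics:
    """freq, p = freq/N, IC = -log2(p) and depth for one concept."""
    return t.statics(cid)


def least_common_subsumer(t: Taxonomy, c1: str, c2: str) -> str:
    return t.least_common_subsumer(c1, c2)


def path_length(t: Taxonomy, c1: str, c2: str) -> int:
    return t.path_length(c1, c2)
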