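"""Seeded synthetic taxonomies and annotated toy SBML corpora.

Every stage of the pipeline is testable without downloading real ontologies
or BioModels entries.  The generator emulates the shape of real inputs:

* a rooted is_a taxonomy with configurable size and branching, optionally
  thickened into a DAG with extra is_a edges;
* a corpus of minimal SBML Level 3 documents whose species carry RDF
  ``bqbiol:is`` annotations (identifiers.org dialect by default, MIRIAM
  URNs on request) and, for SBO-prefixed taxonomies, ``sboTerm``
  attributes on reactions;
* annotation concepts are sampled with a depth bias (weight ``(depth+1)^2``)
  so the depth profile is unimodal and skewed towards specific concepts, as
  observed in curated model repositories;
* "thematic" corpora concentrate their annotations inside one focal
  subtree (fully, by default; ``focus_fraction`` admits leakage), standing
  in for topic-focused model sets, while "broad" corpora sample the whole
  taxonomy.

Everything is deterministic per seed: the same spec produces byte-identical
OBO and SBML files.
"""

from __future__ import annotations

import json
import random
from dataclasses import dataclass, asdict
from pathlib import Path

from .annotation_harvest import AnnotationRecord
from .errors import InputError
from .ontology import Taxonomy

__all__ = [
    "FixtureSpec",
    "generate_taxonomy",
    "generate_corpus",
    "sample_annotations",
    "write_obo",
    "default_focus",
]


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic study condition."""

    seed: int = 0
    n_concepts: int = 1800
    branching: tuple[int, int] = (2, 2)
    n_models: int = 20
    annotations_per_model: tuple[int, int] = (3, 10)
    focus: str | None = None  # concept id, or None/"broad" for a broad corpus
    focus_fraction: float = 0.9
    dag_extra_edges: int = 0
    prefix: str = "SYN"
    dialect: str = "identifiers"  # or "miriam"
    use_sboterm: bool = False

    def __post_init__(self):
        if self.n_concepts < 2:
            raise InputError("n_concepts must be >= 2")
        lo, hi = self.branching
        if lo < 1 or hi < lo:
            raise InputError(f"infeasible branching range {self.branching}")
        if self.dialect not in ("identifiers", "miriam"):
            raise InputError(f"unknown URI dialect {self.dialect!r}")
        if not 0.0 <= self.focus_fraction <= 1.0:
            raise InputError("focus_fraction must lie in [0, 1]")
        if self.use_sboterm and self.prefix != "SBO":
            raise InputError("sboTerm attributes require an SBO-prefixed taxonomy")


def _cid(prefix: str, i: int) -> str:
    return f"{prefix}:{i:07d}"


def generate_taxonomy(spec: FixtureSpec, obo_path=None) -> Taxonomy:
    """Random rooted taxonomy, breadth-first with ``branching`` children per
    node; ``dag_extra_edges`` additional is_a edges (cycle-free) turn the
    tree into a DAG.  With branching (2, 2) and ``n_concepts`` = 2^k - 1 the
    result is a perfect binary tree.  Optionally written as a reloadable
    OBO file."""
    rng = random.Random(spec.seed)
    lo, hi = spec.branching
    parents: dict[str, set[str]] = {_cid(spec.prefix, 1): set()}
    queue = [1]
    next_id = 2
    while next_id <= spec.n_concepts:
        if not queue:
            raise InputError("branching range exhausted before n_concepts reached")
        node = queue.pop(0)
        k = min(rng.randint(lo, hi), spec.n_concepts - next_id + 1)
        for _ in range(k):
            parents[_cid(spec.prefix, next_id)] = {_cid(spec.prefix, node)}
            queue.append(next_id)
            next_id += 1

    if spec.dag_extra_edges:
        # strict descendants per node, maintained incrementally for cycle checks
        t0 = Taxonomy.from_parents(parents, ontology=spec.prefix)
        ids = sorted(parents)
        added = 0
        attempts = 0
        while added < spec.dag_extra_edges and attempts < 200 * spec.dag_extra_edges:
            attempts += 1
            child = rng.choice(ids[1:])
            parent = rng.choice(ids)
            if (
                parent == child
                or parent in parents[child]
                or parent in t0.descendants(child)
                or parent in t0.ancestors(child)
            ):
                continue
            parents[child] = set(parents[child]) | {parent}
            t0 = Taxonomy.from_parents(parents, ontology=spec.prefix)
            added += 1

    names = {cid: f"synthetic concept {cid.split(':')[1].lstrip('0') or '0'}"
             for cid in parents}
    t = Taxonomy.from_parents(parents, ontology=spec.prefix, names=names)
    if obo_path is not None:
        write_obo(t, obo_path)
    return t


def write_obo(t: Taxonomy, path) -> None:
    """Serialize a taxonomy as an OBO 1.2 flat file (is_a edges only)."""
    lines = ["format-version: 1.2", f"ontology: {t.ontology.lower()}", ""]
    for cid in sorted(t.concepts):
        c = t.concepts[cid]
        lines.append("[Term]")
        lines.append(f"id: {cid}")
        lines.append(f"name: {c.name or cid}")
        for p in sorted(c.parents):
            lines.append(f"is_a: {p} ! {t.concepts[p].name or p}")
        lines.append("")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text("\n".join(lines))


def default_focus(t: Taxonomy, depth: int = 1, rank: int = 0) -> str:
    """Deterministic focal concept: the ``rank``-th largest subtree head at
    the given depth (ties by id).  Useful for building thematic corpora and
    disjoint-branch pairs."""
    level = sorted(
        (c for c in t.concepts if t.depth(c) == depth),
        key=lambda c: (-t.freq(c), c),
    )
    if rank >= len(level):
        raise InputError(f"no concept of rank {rank} at depth {depth}")
    return level[rank]


def sample_annotations(spec: FixtureSpec, t: Taxonomy) -> list[list[str]]:
    """The concept ids each model will annotate, deterministic per seed.

    Concept popularity combines a depth bias (weight ``(depth+1)^2``,
    favouring specific concepts) with a per-corpus Zipf factor (a seeded
    random popularity ranking, ``1/rank``), so that a handful of concepts
    recur across many models the way curated repositories reuse popular
    terms.  Thematic specs draw each annotation from the focal subtree
    with probability ``focus_fraction``.
    """
    if spec.n_models < 1:
        raise InputError("n_models must be >= 1")
    focus = None if spec.focus in (None, "broad") else spec.focus
    if focus is not None and focus not in t:
        raise InputError(f"focus concept {focus!r} not in taxonomy")
    rng = random.Random(spec.seed * 2654435761 % (2**31) + 17)
    pool = sorted(c for c in t.concepts if c != t.root)
    ranks = list(range(1, len(pool) + 1))
    rng.shuffle(ranks)
    weight = {
        c: (t.depth(c) + 1) ** 2 / r for c, r in zip(pool, ranks)
    }
    weights = [weight[c] for c in pool]
    if focus is not None:
        focal = sorted((t.descendants(focus) | {focus}) - {t.root})
        focal_weights = [weight[c] for c in focal]
    lo, hi = spec.annotations_per_model
    out: list[list[str]] = []
    for _ in range(spec.n_models):
        n = rng.randint(lo, hi)
        chosen: list[str] = []
        for _ in range(n):
            if focus is not None and rng.random() < spec.focus_fraction:
                chosen.append(rng.choices(focal, weights=focal_weights, k=1)[0])
            else:
                chosen.append(rng.choices(pool, weights=weights, k=1)[0])
        out.append(chosen)
    return out


_SBML_HEADER = (
    '<?xml version="1.0" encoding="UTF-8"?>\n'
    '<sbml xmlns="http://www.sbml.org/sbml/level3/version1/core" '
    'level="3" version="1">\n'
)


def _uri_for(cid: str, dialect: str) -> str:
    prefix = cid.split(":", 1)[0]
    if dialect == "identifiers":
        return f"http://identifiers.org/{prefix.lower()}/{cid}"
    return f"urn:miriam:{prefix.lower()}:{cid.replace(':', '%3A')}"


def _species_xml(mid: str, i: int, cid: str, dialect: str) -> str:
    meta = f"{mid}.s{i}"
    uri = _uri_for(cid, dialect)
    return (
        f'      <species id="s{i}" metaid="{meta}" compartment="c" '
        'hasOnlySubstanceUnits="false" boundaryCondition="false" constant="false">\n'
        "        <annotation>\n"
        '          <rdf:RDF xmlns:rdf="http://www.w3.org/1999/02/22-rdf-syntax-ns#" '
        'xmlns:bqbiol="http://biomodels.net/biology-qualifiers/">\n'
        f'            <rdf:Description rdf:about="#{meta}">\n'
        "              <bqbiol:is>\n"
        "                <rdf:Bag>\n"
        f'                  <rdf:li rdf:resource="{uri}"/>\n'
        "                </rdf:Bag>\n"
        "              </bqbiol:is>\n"
        f"            </rdf:Description>\n"
        "          </rdf:RDF>\n"
        "        </annotation>\n"
        "      </species>\n"
    )


def _reaction_xml(mid: str, i: int, cid: str) -> str:
    meta = f"{mid}.r{i}"
    return (
        f'      <reaction id="r{i}" metaid="{meta}" reversible="false" '
        f'fast="false" sboTerm="{cid}"/>\n'
    )


def generate_corpus(
    spec: FixtureSpec, t: Taxonomy, out_dir
) -> tuple[list[Path], list[AnnotationRecord]]:
    """Write one minimal SBML file per model and return the paths together
    with the exact annotation records embedded (the generator's tally, for
    round-trip verification).  For ``use_sboterm`` specs every third
    annotation is emitted as a reaction ``sboTerm`` attribute instead of an
    RDF resource."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    per_model = sample_annotations(spec, t)
    paths: list[Path] = []
    records: list[AnnotationRecord] = []
    for k, concepts in enumerate(per_model):
        mid = f"M{spec.seed:04d}x{k:03d}"
        species_parts: list[str] = []
        reaction_parts: list[str] = []
        for i, cid in enumerate(concepts):
            if spec.use_sboterm and i % 3 == 2:
                reaction_parts.append(_reaction_xml(mid, i, cid))
                records.append(
                    AnnotationRecord(mid, f"{mid}.r{i}", "sboTerm",
                                     cid.split(":")[0], cid)
                )
            else:
                species_parts.append(_species_xml(mid, i, cid, spec.dialect))
                records.append(
                    AnnotationRecord(mid, f"{mid}.s{i}", "bqbiol:is",
                                     cid.split(":")[0], cid)
                )
        body = [
            _SBML_HEADER,
            f'  <model id="{mid}" metaid="{mid}">\n',
            "    <listOfCompartments>\n"
            '      <compartment id="c" constant="true"/>\n'
            "    </listOfCompartments>\n",
        ]
        if species_parts:
            body.append("    <listOfSpecies>\n")
            body.extend(species_parts)
            body.append("    </listOfSpecies>\n")
        if reaction_parts:
            body.append("    <listOfReactions>\n")
            body.extend(reaction_parts)
            body.append("    </listOfReactions>\n")
        body.append("  </model>\n</sbml>\n")
        path = out_dir / f"{mid}.xml"
        path.write_text("".join(body))
        paths.append(path)
    with open(out_dir / "fixture_spec.json", "w") as fh:
        json.dump(asdict(spec), fh, indent=1, sort_keys=True)
    return paths, records
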