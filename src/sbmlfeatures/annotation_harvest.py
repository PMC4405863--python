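"""Harvest MIRIAM-style ontology annotations from SBML files and index them.

SBML models attach semantics to their elements in two ways: RDF annotation
blocks whose ``bqbiol:*`` / ``bqmodel:*`` qualifier elements carry resource
URIs (MIRIAM URNs or identifiers.org URLs), and the ``sboTerm`` attribute
linking an element to the Systems Biology Ontology.  This module extracts
both into flat :class:`AnnotationRecord` rows and aggregates them over a
model corpus against a loaded taxonomy:

* direct entity frequency — how many annotation records point at a concept;
* aggregated entity frequency ``EF(c)`` — the direct counts of ``c`` and all
  of its descendants (as a set, so multi-parent descendants are not double
  counted within one ancestor);
* entity probability ``ep(c) = EF(c) / EF(root)``;
* document frequency — in how many models a concept (or a descendant of it)
  is referenced; used for vocabulary reduction of rarely used concepts.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from urllib.parse import unquote, urlparse

from lxml import etree

from .errors import FormatError, InputError
from .ontology import Taxonomy

__all__ = [
    "AnnotationRecord",
    "CorpusIndex",
    "normalize_identifier",
    "parse_sbml_annotations",
    "build_corpus_index",
    "index_records",
    "df_filter",
]

RDF_NS = "http://www.w3.org/1999/02/22-rdf-syntax-ns#"
BQBIOL_NS = "http://biomodels.net/biology-qualifiers/"
BQMODEL_NS = "http://biomodels.net/model-qualifiers/"

#: MIRIAM / identifiers.org namespace tokens for the three target ontologies.
NAMESPACE_MAP = {
    "obo.go": "GO",
    "go": "GO",
    "obo.chebi": "CHEBI",
    "chebi": "CHEBI",
    "biomodels.sbo": "SBO",
    "sbo": "SBO",
}

_CURIE_RE = re.compile(r"^([A-Za-z][A-Za-z0-9.\-]*)[:_](\d+)$")


@dataclass(frozen=True)
class AnnotationRecord:
    """One resolved (or unresolvable) ontology reference from a model element."""

    model_id: str
    element_id: str
    qualifier: str  # e.g. "bqbiol:is" or "sboTerm"
    ontology: str  # CURIE prefix (GO | CHEBI | SBO | ...) or "other"
    concept_id: str


def normalize_identifier(uri: str) -> tuple[str | None, str]:
    """Map a resource URI to an ``(ontology prefix, concept id)`` pair.

    Recognized dialects: ``urn:miriam:<ns>:<id>``,
    ``http(s)://identifiers.org/<ns>/<id>`` and
    ``http(s)://identifiers.org/<PREFIX>:<id>``, plus bare CURIEs (used by
    ``sboTerm`` attributes).  ``%3A`` is percent-decoded to ``:``.  Ids of
    CURIE shape ``PREFIX:digits`` are tagged with their prefix; anything
    else from an unmapped namespace is tagged ``"other"``.  Total function:
    an unparseable URI is returned as ``(None, uri)`` for the unresolved
    bucket.
    """
    s = uri.strip()
    ns: str | None = None
    ident: str | None = None
    low = s.lower()
    if low.startswith("urn:miriam:"):
        rest = s[len("urn:miriam:"):]
        parts = rest.split(":", 1)
        ns = parts[0].lower()
        ident = unquote(parts[1]) if len(parts) > 1 else ""
    elif low.startswith(("http://", "https://")):
        parsed = urlparse(s)
        if parsed.netloc.lower() not in {"identifiers.org", "www.identifiers.org"}:
            return (None, uri)
        segs = [p for p in parsed.path.split("/") if p]
        if not segs:
            return (None, uri)
        if ":" in unquote(segs[0]):
            ident = unquote("/".join(segs))
        else:
            ns = segs[0].lower()
            ident = unquote("/".join(segs[1:]))
    elif _CURIE_RE.match(unquote(s)):
        ident = unquote(s)
    else:
        return (None, uri)
    if not ident and ns is None:
        return (None, uri)

    mapped = NAMESPACE_MAP.get(ns) if ns else None
    if mapped:
        m = re.fullmatch(rf"(?:{mapped}[:_])?(\d+)", ident or "", flags=re.IGNORECASE)
        if m:
            return (mapped, f"{mapped}:{m.group(1)}")
    m = _CURIE_RE.match(ident or "")
    if m:
        prefix = m.group(1).upper()
        prefix = NAMESPACE_MAP.get(prefix.lower(), prefix)
        return (prefix, f"{prefix}:{m.group(2)}")
    if not ident:
        return (None, uri)
    return ("other", ident)


def _localname(el) -> str:
    return etree.QName(el).localname if isinstance(el.tag, str) else ""


def parse_sbml_annotations(path) -> list[AnnotationRecord]:
    """Extract all annotation records from one SBML (Level 2+) file.

    One record is produced per ``(element, qualifier, resource URI)`` triple
    found in RDF annotation blocks — duplicates are preserved, each
    occurrence counts — plus one ``sboTerm`` record per element carrying the
    attribute.
    """
    try:
        tree = etree.parse(str(path))
    except OSError as exc:
        raise InputError(f"cannot read SBML file {path!r}: {exc}") from exc
    except etree.XMLSyntaxError as exc:
        raise InputError(f"malformed XML in {path!r}: {exc}") from exc
    root = tree.getroot()
    if _localname(root) != "sbml":
        raise FormatError(f"{path!r} is XML but not an SBML document")
    model = next((el for el in root if _localname(el) == "model"), None)
    model_id = (
        model.get("id") or model.get("metaid") or Path(str(path)).stem
        if model is not None
        else Path(str(path)).stem
    )
    records: list[AnnotationRecord] = []
    for el in tree.iter():
        if not isinstance(el.tag, str):
            continue
        elem_id = el.get("metaid") or el.get("id") or _localname(el)
        sbo = el.get("sboTerm")
        if sbo:
            ont, cid = normalize_identifier(sbo)
            records.append(
                AnnotationRecord(model_id, elem_id, "sboTerm", ont or "other", cid)
            )
        annotation = next(
            (ch for ch in el if isinstance(ch.tag, str) and _localname(ch) == "annotation"),
            None,
        )
        if annotation is None:
            continue
        for qual in annotation.iter():
            if not isinstance(qual.tag, str):
                continue
            qname = etree.QName(qual)
            if qname.namespace == BQBIOL_NS:
                qualifier = f"bqbiol:{qname.localname}"
            elif qname.namespace == BQMODEL_NS:
                qualifier = f"bqmodel:{qname.localname}"
            else:
                continue
            for li in qual.iter(f"{{{RDF_NS}}}li"):
                uri = li.get(f"{{{RDF_NS}}}resource")
                if uri is None:
                    continue
                ont, cid = normalize_identifier(uri)
                records.append(
                    AnnotationRecord(model_id, elem_id, qualifier, ont or "other", cid)
                )
    return records


@dataclass
class CorpusIndex:
    """Aggregated annotation counts of one model corpus against one taxonomy."""

    ontology: str
    taxonomy: Taxonomy
    models: list[str]
    records: list[AnnotationRecord]  # resolved against the taxonomy
    unresolved: list[AnnotationRecord]
    direct_count: dict[str, int]
    ef: dict[str, int]
    ep: dict[str, float]
    doc_freq: dict[str, int]
    per_model: dict[str, dict[str, int]] = field(default_factory=dict)

    def EF(self, cid: str) -> int:
        return self.ef.get(cid, 0)

    def entity_probability(self, cid: str) -> float:
        return self.ep.get(cid, 0.0)

    @property
    def total_resolved(self) -> int:
        return len(self.records)

    def annotated_concepts(self) -> list[str]:
        """Concepts with at least one direct annotation, sorted by id."""
        return sorted(c for c, n in self.direct_count.items() if n > 0)


def index_records(
    records: list[AnnotationRecord],
    models: list[str],
    taxonomy: Taxonomy,
    qualifiers: set[str] | None = None,
    include_model_level: bool = True,
) -> CorpusIndex:
    """Build a :class:`CorpusIndex` from already-parsed annotation records.

    A record is resolved when its concept id exists in ``taxonomy``;
    everything else lands in ``unresolved``.  ``qualifiers`` optionally
    restricts harvesting to a whitelist (e.g. ``{"bqbiol:is"}``);
    ``include_model_level=False`` drops records attached to the model
    element itself (publication references etc.).
    """
    if not models:
        raise InputError("empty model list")
    kept: list[AnnotationRecord] = []
    unresolved: list[AnnotationRecord] = []
    for rec in records:
        if qualifiers is not None and rec.qualifier not in qualifiers:
            continue
        if not include_model_level and rec.element_id == rec.model_id:
            continue
        if rec.concept_id in taxonomy:
            kept.append(rec)
        else:
            unresolved.append(rec)

    direct: dict[str, int] = {}
    per_model: dict[str, dict[str, int]] = {m: {} for m in models}
    for rec in kept:
        direct[rec.concept_id] = direct.get(rec.concept_id, 0) + 1
        bucket = per_model.setdefault(rec.model_id, {})
        bucket[rec.concept_id] = bucket.get(rec.concept_id, 0) + 1

    ef: dict[str, int] = {}
    for cid, n in direct.items():
        ef[cid] = ef.get(cid, 0) + n
        for anc in taxonomy.ancestors(cid) - {cid}:
            ef[anc] = ef.get(anc, 0) + n

    root_ef = ef.get(taxonomy.root, 0)
    ep = {cid: (v / root_ef if root_ef else 0.0) for cid, v in ef.items()}

    doc_freq: dict[str, int] = {}
    for m, bucket in per_model.items():
        touched: set[str] = set()
        for cid in bucket:
            touched |= taxonomy.ancestors(cid)
        for cid in touched:
            doc_freq[cid] = doc_freq.get(cid, 0) + 1

    return CorpusIndex(
        ontology=taxonomy.ontology,
        taxonomy=taxonomy,
        models=sorted(models),
        records=kept,
        unresolved=unresolved,
        direct_count=direct,
        ef=ef,
        ep=ep,
        doc_freq=doc_freq,
        per_model=per_model,
    )


def build_corpus_index(
    model_paths,
    taxonomy: Taxonomy,
    qualifiers: set[str] | None = None,
    include_model_level: bool = True,
) -> CorpusIndex:
    """Parse a list of SBML files and aggregate their annotations."""
    paths = list(model_paths)
    if not paths:
        raise InputError("empty model list")
    records: list[AnnotationRecord] = []
    models: list[str] = []
    for p in paths:
        recs = parse_sbml_annotations(p)
        models.append(recs[0].model_id if recs else Path(str(p)).stem)
        records.extend(recs)
    return index_records(
        records, models, taxonomy,
        qualifiers=qualifiers, include_model_level=include_model_level,
    )


def df_filter(idx: CorpusIndex, min_df: int = 1) -> CorpusIndex:
    """Vocabulary reduction: drop concepts referenced in fewer than
    ``min_df`` models (by aggregated document frequency) and rebuild the
    index.  ``min_df`` of 0 or 1 is the identity."""
    if min_df < 0:
        raise InputError("min_df must be >= 0")
    if min_df <= 1:
        return idx
    taxonomy = idx.taxonomy
    kept = [r for r in idx.records if idx.doc_freq.get(r.concept_id, 0) >= min_df]
    filtered = index_records(kept, idx.models, taxonomy)
    if filtered.EF(taxonomy.root) == 0 and idx.records:
        warnings.warn(
            f"df_filter(min_df={min_df}) removed every annotation", stacklevel=2
        )
    filtered.unresolved = list(idx.unresolved)
    return filtered


def unresolved_to_tsv(idx: CorpusIndex, path) -> None:
    """Dump unresolved records for inspection (model, element, qualifier, id)."""
    with open(path, "w") as fh:
        fh.write("model_id\telement_id\tqualifier\tontology\tconcept_id\n")
        for r in idx.unresolved:
            fh.write(
                f"{r.model_id}\t{r.element_id}\t{r.qualifier}\t{r.ontology}\t{r.concept_id}\n"
            )
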