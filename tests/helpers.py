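"""Shared test utilities: in-memory corpus construction and tiny taxonomies."""

from sbmlfeatures import (
    AnnotationRecord,
    CorpusIndex,
    FixtureSpec,
    Taxonomy,
    index_records,
    sample_annotations,
)


def corpus_index(t: Taxonomy, spec: FixtureSpec) -> CorpusIndex:
    """Build a CorpusIndex from sampled annotations without touching disk."""
    per_model = sample_annotations(spec, t)
    models = [f"M{k:03d}" for k in range(spec.n_models)]
    records = [
        AnnotationRecord(models[k], f"{models[k]}.s{i}", "bqbiol:is",
                         cid.split(":")[0], cid)
        for k, concepts in enumerate(per_model)
        for i, cid in enumerate(concepts)
    ]
    return index_records(records, models, t)


def records_for(t: Taxonomy, counts: dict[str, int],
                model_id: str = "M0") -> list[AnnotationRecord]:
    """Explicit direct-count records on one model."""
    out = []
    for cid, n in counts.items():
        for i in range(n):
            out.append(
                AnnotationRecord(model_id, f"{model_id}.{cid}.{i}", "bqbiol:is",
                                 cid.split(":")[0], cid)
            )
    return out


def index_from_counts(t: Taxonomy, counts: dict[str, int]) -> "CorpusIndex":
    return index_records(records_for(t, counts), ["M0"], t)


def chain_taxonomy(*ids: str, ontology: str = "T") -> Taxonomy:
    """r -> a -> b -> ... linear taxonomy."""
    parents = {ids[0]: []}
    for prev, cur in zip(ids, ids[1:]):
        parents[cur] = [prev]
    return Taxonomy.from_parents(parents, ontology=ontology)


def small_tree() -> Taxonomy:
    """r -> p -> {a, b}; N = 4."""
    return Taxonomy.from_parents(
        {"T:r": [], "T:p": ["T:r"], "T:a": ["T:p"], "T:b": ["T:p"]},
        ontology="T",
    )


def perfect_binary(depth: int, ontology: str = "T") -> Taxonomy:
    """Perfect binary tree with 2^(depth+1)-1 concepts, BFS-numbered ids."""
    n = 2 ** (depth + 1) - 1
    parents = {f"{ontology}:{i:04d}": ([f"{ontology}:{i // 2:04d}"] if i > 1 else [])
               for i in range(1, n + 1)}
    return Taxonomy.from_parents(parents, ontology=ontology)
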