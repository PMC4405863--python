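# sbmlfeatures

Characteristic ontology features for sets of SBML models.

Curated model repositories such as BioModels annotate model elements with
concepts from bio-ontologies — Gene Ontology (GO), ChEBI, and the Systems
Biology Ontology (SBO) — through MIRIAM-style RDF annotations and `sboTerm`
attributes. `sbmlfeatures` answers the question *"what is this set of
models about?"* by condensing those annotations into a small set of
**characteristic features**: ontology concepts that summarize a model
corpus without over-generalizing. Feature sets of two corpora can then be
compared with a semantic similarity score, so that, e.g., a collection of
cell-cycle models is computationally distinguishable from an arbitrary
model collection.

It is aimed at people who curate, search, or cluster collections of
systems-biology models, and at anyone who wants annotation statistics
(depth distributions, branch usage, concept reuse) for an SBML corpus.

## The quantities at the core

For an is_a taxonomy with `N` concepts, each concept `c` has

- frequency `freq(c)` — the number of concepts it subsumes (self-inclusive),
- probability `p(c) = freq(c) / N`,
- information content `IC(c) = -log2 p(c)` — 0 bits at the root, maximal at
  rare leaves,
- depth — shortest is_a path from the root.

For a model corpus, each concept additionally has an **entity frequency**
(number of annotation records pointing at it), an **aggregated entity
frequency** `EF(c)` (its own plus all descendants' records), and an
**entity probability** `ep(c) = EF(c) / EF(root)`.

Four extraction methods condense the taxonomy to at most `k` features
(defaults `k = 15`, alternate 5):

1. **Method 1** (static top-down): split the most probable frontier concept
   into its children while the frontier fits the budget. Depends only on
   the ontology.
2. **Method 2** (corpus top-down): the same frontier algorithm ranked by
   `ep(c)`, restricted to concepts with `EF > 0`.
3. **Method 3** (corpus bottom-up): start from the annotated concepts and
   merge clusters into parents in ascending-`ep` order; constructed as the
   exact inverse of Method 2, with residual order ambiguities (ties)
   detected and reported.
4. **Method 4** (score-based): merge each annotated concept with the
   ancestor reaching the highest score `Score_T(c) = IC(c) · EF(c)`, which
   trades generality (EF grows upward) against specificity (IC shrinks
   upward) and so counters over-generalization.

Two feature sets `A`, `B` from the same ontology are compared pairwise with
the path/depth similarity

```
S(c1, c2) = exp(-α·l) · tanh(β·h)        α = 0.2, β = 0.6
```

(`l` = shortest is_a path between the concepts, `h` = depth of their least
common subsumer; identical concepts score 1), aligned one-to-one with the
Hungarian method, and aggregated as
`total = (sum of matched similarities) / max(|A|, |B|)`.

## Worked example

Everything below runs without downloads: the package generates a seeded
synthetic taxonomy (OBO) and annotated toy SBML corpora.

```python
from pathlib import Path
from sbmlfeatures import (FixtureSpec, generate_taxonomy, generate_corpus,
                          build_corpus_index, ExtractionConfig, method2_topdown,
                          method4_scored, set_similarity, depth_distribution)
from sbmlfeatures.synthetic_fixtures import default_focus

out = Path("demo")
t = generate_taxonomy(FixtureSpec(seed=42), obo_path=out / "SYN.obo")
focus = default_focus(t, depth=1)          # head of the largest root branch

broad, _ = generate_corpus(FixtureSpec(seed=101), t, out / "broad")
themed, _ = generate_corpus(FixtureSpec(seed=202, focus=focus), t, out / "themed")
ib, it = build_corpus_index(broad, t), build_corpus_index(themed, t)

cfg2 = ExtractionConfig(method=2, max_features=15)
cfg4 = ExtractionConfig(method=4, max_features=15)
f4b, f4t = method4_scored(t, ib, cfg4), method4_scored(t, it, cfg4)
print(set_similarity(t, f4b, f4t).total)
```

Output of the full script:

```
taxonomy: 1800 concepts, root SYN:0000001 focal branch SYN:0000002
broad corpus: 126 annotations, mean depth 9.30
themed corpus: 130 annotations, mean depth 9.44
method 2: broad 15 features (avg depth 4.27), themed 15 features (avg depth 5.13)
method 4: broad 15 features (avg depth 6.40), themed 15 features (avg depth 7.13)
set similarity broad-vs-themed (method 4): 0.3868
set similarity themed-vs-themed (self):    1.0000
```

Reading this: extraction generalizes — features sit well above the
annotations (depth ~4–7 vs ~9.3) — but the score-based Method 4 stays
about two levels more specific than Method 2; a thematically focused
corpus gets deeper features than a broad one; identical feature sets score
exactly 1.0, while a themed corpus only partially matches a broad one.

The same workflow is available from the shell:

```
sbmlfeatures simulate --seed 42 --out demo
sbmlfeatures extract --ontology SYN=demo/SYN.obo --models demo/models \
                     --method 4 --max-features 15 --out demo/features
sbmlfeatures compare demo/features/A.features.json demo/features/B.features.json \
                     --ontology SYN=demo/SYN.obo
sbmlfeatures stats   --ontology SYN=demo/SYN.obo --models demo/models
```

Real ontologies work the same way: point `--ontology GO=go.obo` at an OBO
release and `--models` at a directory of annotated SBML files.

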