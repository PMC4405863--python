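# Methods

## Model

The package treats a bio-ontology as a rooted is_a DAG ("taxonomy") and a
model corpus as a multiset of annotation records, each linking one SBML
element to one ontology concept. Two families of quantities are computed.

**Static (ontology-only).** With `N` the total concept count,
`freq(c) = |{c} ∪ descendants(c)|` (descendants as a *set*, so a concept
reachable along several is_a paths counts once), `p(c) = freq(c)/N` and
`IC(c) = -log2 p(c)`. `freq` is self-inclusive because that is the only
reading under which the root — which subsumes everything — has
`p = 1` and `IC = 0` exactly. `depth(c)` is the shortest is_a path from
the root; a DAG admits several path lengths and the shortest is the
deterministic, cheap convention, which also fixes the meaning of the
depth term in the similarity measure below. Only is_a edges are used, so
GO, ChEBI and SBO are handled uniformly; part_of and other relations are
dropped at load time, as are obsolete terms. A multi-rooted ontology gets
a synthetic root at depth 0; concepts from different natural roots then
have the synthetic root as their only common subsumer and similarity 0.

**Corpus-weighted.** Direct entity frequency counts annotation records
per concept (multiset semantics: a concept annotated twice on one element
counts twice). Aggregated entity frequency `EF(c)` sums direct counts
over `{c} ∪ descendants(c)`; on DAGs the set semantics prevents
double-counting within one ancestor, at the price that sibling EF values
may sum to more than `EF(root)` — conservation (`EF(root)` = number of
resolved records) is therefore only asserted on trees. Entity probability
is `ep(c) = EF(c)/EF(root)`. Document frequency is aggregated the same
way (a model touching a concept touches all its ancestors) because its
role is vocabulary reduction: `df_filter` zeroes concepts referenced in
fewer than `min_df` models and rebuilds the index (doc_freq included, to
keep the index self-consistent). All `bqbiol:*`/`bqmodel:*` qualifiers
and `sboTerm` attributes are harvested by default; a qualifier whitelist
and a switch for model-level records are available.

## Extraction methods

All four methods return at most `max_features` concepts (default 15,
alternate 5) and break every tie deterministically.

**Methods 1/2 (top-down).** A frontier starts at the root. Repeatedly the
frontier concept with the highest rank — `p(c)` for Method 1, `ep(c)` for
Method 2, ties to the smaller id — is replaced by its children (Method 2:
only children with `EF > 0`), provided the enlarged frontier still fits
the budget; the loop stops at the first over-budget split. Because a
child's rank never exceeds its parent's, splits happen in strictly
descending `(rank, id)` order. A directly annotated concept that is split
stays in the result as a non-splittable member: dropping it would leave
its own records unrepresented and would break the correspondence with the
bottom-up method. Under this rule the un-budgeted split limit of Method 2
is exactly the set of directly annotated concepts.

**Method 3 (bottom-up).** Clusters start at the directly annotated
concepts. A parent is *mergeable* when all of its `EF > 0` children are
current representatives (and, if it carries direct records, it is one
itself); the mergeable parent with the smallest `(ep, id-descending)` key
absorbs its children, until the budget is met. This is by construction
the exact inverse of Method 2's split sequence, so on trees the two
methods return identical feature sets — the directional freedom only
matters when an equal-`ep` parent/child pair has ids ordered against the
taxonomy, and exactly that constellation is recorded in
`FeatureSet.ties`. The package treats a run without recorded ties as
provably direction-independent; tied runs are still deterministic but the
two directions may differ.

**Method 4 (score-based).** `Score_T(c) = IC(c) · EF(c)` rewards concepts
that are both specific and well supported. Each annotated concept is
merged upward while a parent strictly improves the score (hill-climb to a
local score maximum; among equal-scoring parents the deeper, then
lexicographically smaller one is taken). The distinct representatives are
the features; a strongly recurring concept represents itself, weakly
supported concepts are absorbed by the nearest well-supported ancestor.
The climb intentionally stops at a *local* maximum: continuing to the
global maximum of the whole ancestor chain lets high-level branch heads
— whose large `EF` outweighs their low `IC` at realistic taxonomy sizes
— absorb everything, which is precisely the over-generalization the score
is meant to prevent. If the representatives exceed the budget, the
weakest-scoring one is generalized a single step (and re-climbed), fusing
with an existing feature whenever it lands inside that feature's subtree;
a zero-score ancestor (the root, or a branch without annotations) never
absorbs a representative, since a representative with zero information
content or zero support characterizes nothing. Score-ranked truncation is
a last resort and is reported via a warning. Features may be nested (one
an ancestor of another).

## Set similarity

Concept pairs are scored with `S = exp(-α·l) · tanh(β·h)` with `l` the
shortest is_a path through the least common subsumer, `h` the LCS depth,
and defaults `α = 0.2`, `β = 0.6`. Identical concepts score exactly 1 by
convention — the raw formula saturates at `tanh(β·depth) < 1` even for a
concept compared with itself, and self-comparison of identical feature
sets should read 1. The LCS is the deepest common ancestor, depth ties
broken by smallest id, and the same LCS choice is used for `l` and `h`.

Feature sets are aligned with `scipy.optimize.linear_sum_assignment`
(maximum total weight, size `min(|A|, |B|)`) and aggregated as
`total = matched sum / max(|A|, |B|)`. Dividing by the larger set size
penalizes unmatched features, keeps the value in `[0, 1]`, makes the
score symmetric, and gives self-similarity exactly 1. The aggregation is
isolated in `set_similarity` so an alternative normalization is a
one-line change. Features enter unweighted; EF-weighting is deliberately
not applied (feature lists are bare concept sets). Cross-ontology
comparisons are refused rather than scored 0.

## Synthetic study conditions

The fixture generator exists so every pipeline stage is testable without
ontology releases or repository downloads. Defaults
(`FixtureSpec`): 1800 concepts, binary branching, 20 models per corpus,
3–10 annotations per model, identifiers.org URIs.

* **Taxonomy shape.** Breadth-first construction with 2 children per node
  gives a balanced binary taxonomy of depth 10. The shape is fixed across
  seeds, mirroring how one fixed ontology release underlies many corpora;
  seeds vary the corpora. Two properties of real bio-ontologies matter
  and are reproduced: a large IC spread between leaves (~10.8 bits) and
  branch heads (~1 bit), comparable to GO's ratio — on toy taxonomies of
  a hundred concepts the spread is so small that `EF` always dominates
  `Score_T` and the score-based method degenerates; and unit-increment
  frontier growth, under which the top-down methods fill their budget
  exactly, the reference behavior against which "the score-based method
  finds fewer features" is measured. `branching`, `n_concepts` and
  `dag_extra_edges` (extra cycle-free is_a edges for DAG fixtures) are
  all configurable.
* **Annotation sampling.** Concept popularity is the product of a depth
  bias `(depth+1)^2` — curated annotations favour specific concepts —
  and a per-corpus Zipf factor `1/rank` over a seeded random popularity
  ranking, emulating the heavy reuse of popular terms across curated
  models (single GO terms are referenced by tens to hundreds of models).
  This yields unimodal, deep-skewed depth profiles and recurring
  concepts, both of which the extraction methods rely on.
* **Thematic corpora** draw each annotation from a focal subtree with
  probability `focus_fraction` (default 0.9, i.e. ≥90% focal with ~10%
  leakage into the rest of the ontology, as thematically collected model
  sets still carry general-purpose annotations). Tests that assert
  *total* containment of features in the focal subtree use
  `focus_fraction = 1.0`, since any leaked annotation legitimately pulls
  a feature outside.

What the generator does **not** emulate: biologically meaningful model
structure (kinetics, stoichiometry), realistic qualifier mixtures,
multi-namespace ontologies with cross-links, annotation errors, or the
very unbalanced branch sizes of real GO/ChEBI. Passing tests demonstrate
the algorithmic properties (conservation, method agreement, specificity
ordering, distinctness, round-trip exactness) under controlled, realistic
scale — not numeric agreement with any particular ontology release or
repository snapshot.

## Numerical and degenerate-input conventions

* Ties anywhere (rank selection, score maxima, LCS depth) resolve by the
  documented deterministic keys; no randomness exists outside fixture
  generation.
* An empty corpus index (no resolved records, or everything removed by
  `df_filter`) yields an empty feature set with a warning; comparing an
  empty feature set yields total similarity 0 with a warning; the average
  depth of an empty feature set is an error, not NaN.
* Unknown concept ids raise `KeyError` (lookup errors); malformed files
  raise `InputError`/`FormatError`; structural ontology violations
  (cycles, unreachable concepts, inconsistent links) raise
  `TaxonomyError` naming a witness.
* Annotation identifiers are normalized from MIRIAM URNs, identifiers.org
  paths (both namespace and CURIE form) and bare CURIEs; `%3A` is
  percent-decoded. Ids of the form `PREFIX:digits` keep their CURIE
  prefix as ontology tag; anything else from an unmapped namespace is
  tagged `other`. Records whose concept is absent from the loaded
  taxonomy go to an `unresolved` list and never enter the counts.

## Known limitations

* The exact top-down/bottom-up correspondence is proven for trees; on
  DAGs both methods are deterministic and well-defined but may differ.
* Only is_a structure is used; part_of hierarchies (relevant for GO
  cellular component) are ignored by design.
* The total-similarity normalization `max(|A|, |B|)` is one consistent
  choice among several; it is isolated behind a single function.
* OWL ontologies are out of scope; convert to OBO first.
* Feature-value vectors per model (for ranked retrieval) are not
  computed; the package characterizes corpora, not individual models.
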