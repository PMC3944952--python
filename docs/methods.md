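# Methods

## The model

`atlasbridge` represents neuroanatomy as a set of named classes connected by
three structural relations:

- `is_a` — taxonomic subsumption. Used chiefly for lateralization (*Right
  superior frontal gyrus* `is_a` *Superior frontal gyrus*) and for linking
  sided specializations to non-lateralized vocabulary entries (NeuroLex
  does not attribute side).
- `part_of` — generic transitive parthood.
- `regional_part_of` — spatially delimited regional parthood, modeled as a
  transitive sub-relation of `part_of`: every `regional_part_of` edge
  participates in the `part_of` closure, and `has_regional_part` is simply
  the inverse query direction, not a stored relation. Constitutional
  (material-composition) parthood is not modeled; the atlas-harmonization
  use cases exercise regional parts only.

Each class carries a preferred name (unique case-insensitively), synonyms, a
laterality attribute (`left` / `right` / `unpaired`) and an entity category:
`material_structure` or `anatomical_space`. The category distinction does
real work: sulci and ventricles are spaces, and connectivity assertions are
restricted to material structures.

Both relation graphs are kept acyclic, irreflexive and antisymmetric at
insertion time. The ontology never states this about anatomy per se; it is a
machine-processing requirement — closure queries, path search and validation
all assume DAGs. `validate()` additionally reports, without raising:
cycles (via `networkx.find_cycle` on each closure graph), dangling assertion
endpoints, duplicate preferred names, connectivity touching an anatomical
space, and *non-exclusive term* reuse — a regional part sharing its whole's
preferred name, the classic annotation hazard with tract segments.

### Closure queries

`ancestors`/`descendants` perform breadth-first traversal over the relevant
edge set (`part_of` traversal includes `regional_part_of` edges). Output
order is deterministic: by BFS depth, ties broken by preferred name. The
test suite checks closure output against an independent brute-force
per-node DFS oracle on seeded random DAGs up to 1000 nodes.

## Label grammars and normalization

Talairach Daemon labels are period-separated five-level strings (hemisphere,
lobe, gyrus, tissue type, cell type). The parser requires exactly five
components; partial labels must pad trailing levels with `*` (the daemon
emits incomplete labels in practice, the worked examples are always
five-level). Parsing round-trips exactly.

Normalization lowercases, splits on the scheme's delimiter (DK `-`, AAL
`_`, otherwise whitespace), expands abbreviations through a per-scheme
table, and extracts a delimited side token (`left/lh/l`, `right/rh/r`) into
the laterality attribute. Expansion is single-pass, so tables cannot loop.
The shipped tables carry the documented abbreviations (`ctx`, `lh`, `rh`,
`wm`, ...) plus the common positional shorthands (`sup`, `inf`, `mid`,
`med`, `lat`, `ant`, `post`); they are deliberately small and extensible
via YAML config, since no complete dictionary exists for these schemes.
Unknown short tokens (≤ 3 characters, not a side/stop word) pass through
verbatim with a warning record rather than failing: curators should see the
label, not an exception. Stopwords (*of*, *the*, *area*) are retained at
normalization — it stays lossless — and dropped only inside the lexical
matcher.

## Term mapping

Candidate generation compares a normalized label against every class under
four methods with fixed precedence `exact > synonym > abbreviation >
lexical`:

- exact / synonym: the raw label text equals the preferred name / a
  recorded synonym (case-insensitive, whitespace-collapsed);
- abbreviation: the token *multiset* after expansion (side word included)
  equals the class name's or a synonym's tokens — multiset equality makes
  the comparison order-insensitive, which AAL's postfix word order
  requires;
- lexical: one stopword-free token set contains the other, scored by
  Jaccard overlap with a 0.5 reporting threshold. The method is named in
  the field; the metric and threshold are this package's choices.

Exact/synonym/abbreviation candidates score 1.0. Ties between equal-method,
equal-score candidates are never auto-accepted (only unambiguous exact
matches may be, behind a flag): binding creation is a curation act.
Bindings are unique per (scheme, label), may attach an external identifier
(e.g. a NeuroLex id), and are not inherited down `is_a` — each class's
bindings are its own.

On synthesized labels with known ground truth (casing, abbreviation and
synonym perturbations of generated class names), top-1 recovery is exact by
construction of the matcher; the acceptance script measures it at run time
rather than asserting it.

## Modeling patterns

- **Intersection classes.** Gyral parcellations (surface landmarks) and
  Brodmann areas (cytoarchitecture) partition the cortex along independent
  criteria, so neither hierarchy contains the other. The overlap of a
  gyral gray-matter region and a Brodmann area becomes its own class,
  `regional_part_of` both parents and `is_a` an auto-created *Segment of
  Brodmann area N*. Generated names follow the established phrasing
  ("Brodmann area 6 of right superior frontal gyrus") so that external
  label tables and documentation can be matched string-wise. The
  constructor is idempotent.
- **Lateralization** creates *Left/Right X* `is_a` *X*. Structural context
  is recovered through taxonomy queries, never copied onto the children —
  copying would have to be maintained under every later edit.
- **Sulcal segments.** A sulcus is an anatomical space; the cortex buried
  in it is material and belongs to its gyrus. *Sulcal segment of X gyrus*
  is `regional_part_of` the gyrus and `is_a` *Segment of gyrus of brain*.
  The sulcus–segment adjacency is a dedicated association record rather
  than parthood, since a space is not a part of a material gyrus; a sulcus
  flanked by two gyri therefore links to exactly two segments.
- **Tract partition** declares named segments as regional parts of the
  whole tract and rejects any segment name equal to the whole-tract term —
  the "non-exclusive term" annotation hazard.

## Connectivity and pathway inference

The relation vocabulary distinguishes granularity: `innervates` and the
symmetric `synapses_with` at neuron level; `projects_to` / `projects_from`
at tract level (aliases `terminate_in` / `originate_in` canonicalized on
input); `sends_output_to` / `receives_input_from` at region level, declared
subproperties of the tract-level pair; and the ternary `has_pathway(A, B,
via=T)`. Symmetric kinds are stored once in canonical order and answered in
both directions.

The derivation rule is the literal reading of the ternary definition: for
every tract `T` with `projects_from(T, A…)` and `projects_to(T, B…)`, every
origin–termination pair `(A, B)` yields inferred `sends_output_to(A, B)`
and `has_pathway(A, B, via=T)`; the send/receive duality is then closed in
both directions over asserted and derived pairs. For multi-origin,
multi-termination tracts this Cartesian product over-generates relative to
true axonal topography — that is why derived edges carry an `inferred` flag
curators can act on, and why derivation recomputes the inferred set from
asserted facts each run (idempotent, never overwriting an assertion).
Neuron-level kinds are stored but excluded from region-level derivation.
Whether a segment's projections should propagate to its whole tract through
the partonomy is left unimplemented: anatomically a tract projects wherever
its segments do, but the converse fails, and a one-directional propagation
rule needs curatorial review first.

## Correlation queries

`correlate_label` resolves the source label through its binding, then
searches: identity (source class itself bound in the target scheme), the
`part_of` closure upward, then downward; taxonomic `is_a` hops join the
search only when the part search finds nothing or the target vocabulary is
non-lateralized (NeuroLex), which is exactly where delateralization is
needed. Shortest path per target label, BFS with lexical tie-breaks, so
output is deterministic. Downward correlation returns *all* bound
descendants, flagged `down`: one coarse label legitimately corresponds to
many finer ones, and choosing one would misrepresent the concordance
problem. A full Talairach label always resolves at its cell-level entity;
correlating a gyrus-level component of a partial label at gyrus granularity
is a possible extension, not current behavior.

Granularity levels (`cytoarchitectural_area`, `cortical_gray_matter`,
`gyrus`, `lobe`, `hemisphere`, `other`) are assigned from naming patterns;
on the reference fixture they coarsen monotonically along upward part
paths, which the suite checks.

`overlap_query(A, B)` reports shared part-closure descendants and whether
each side has parts outside the other — the reasoning behind "part of the
inferior temporal gyrus is in Brodmann area 20 and part is not".
`annotate_table` applies binding lookup, granularity and ancestor expansion
to tabular (scheme, label) data, flagging unmapped rows rather than
dropping them.

## Fixtures

`build_reference_fixture()` deterministically reconstructs the worked
mini-ontology (85 classes): the frontal partonomy with the Brodmann
6/8/9/10/11 × superior-frontal intersections and the five gyral overlaps of
area 6, the lateralized superior-frontal chain with its four scheme
bindings, the temporal chain for the Brodmann-20 annotation example, the
superior-longitudinal-fasciculus partition with SLF I's projections, the
corticospinal partition, sulcal segments for the middle frontal sulcus, and
a small basal-ganglia neighborhood. Content not fixed by the documented
examples — corticospinal segment names, putamen-adjacent connectivity —
is synthetic: plausible placeholders flagged as such in class definitions,
present so that the query surface has data to exercise, and not to be read
as anatomical ground truth.

`random_ontology(spec)` generates layered DAGs (edges only point to earlier
layers, so acyclicity holds by construction) with Poisson out-degrees, plus
generator-side ground truth: brute-force closures and perturbed labels with
their true classes. Identical seeds give identical ontologies. Default
sizes (50 classes, 5 layers, ~1.5 part edges per class) keep property tests
fast while exercising multi-path reachability; the acceptance run spreads
100 seeds over 20–1000 classes.

What the generators do *not* emulate: real atlas releases' full label sets
(DK's 34 × 2 regions, AAL's 90), inter-rater boundary disagreement, spatial
coordinates, or quantitative overlap. Passing tests show the reasoning and
mapping machinery is correct on faithful miniatures, not that any two real
atlases concord spatially.

## Serialization

A bundle is a directory: `ontology.ttl` (classes, structural edges, sulcus
adjacency, reified `has_pathway` statements with deterministic node IRIs),
`bindings.tsv`, `connectivity.tsv` (with an asserted/inferred provenance
column). The Turtle is written by a canonical serializer — fixed prefixes,
sorted triples, no timestamps — so equal ontologies give byte-identical
files; rdflib parses on load. Bindings and connectivity load from the TSVs
(the hand-editable curation surface); the reified pathway triples exist for
RDF consumers. Load enforces referential integrity (a triple or row naming
an undeclared class is an error) and rejects unknown relation IRIs with the
accepted vocabulary listed.

## Known limitations

- One label binds to at most one class; labels that genuinely span two
  structures cannot be represented as a union binding.
- `is_a` participation in correlation is heuristic (non-lateralized targets
  or part-search failure); a description-logic reasoner would derive more.
- The lexical matcher is token-set containment; no stemming, no embeddings,
  by design — candidates are for curators, and false positives are cheaper
  than opaque scores.
- Sulcus associations record only the gyri whose segments were explicitly
  created; other bounding structures are not inferred.
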