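# atlasbridge

Harmonize human brain-atlas labels through a structural anatomy ontology.

Neuroimaging datasets are annotated with region labels from different
parcellation schemes — the Talairach Daemon's five-level coordinate labels,
the Desikan-Killiany (FreeSurfer) gyral surface parcellation, the AAL
volumetric regions, and the NeuroLex vocabulary. These schemes delimit
regions by different criteria (surface morphology vs. cytoarchitecture vs.
volume tracing) and at different granularities, so their label sets do not
stand in one-to-one correspondence and data labeled in one scheme cannot be
compared with data labeled in another on label strings alone. This is the
*brain atlas concordance problem*.

`atlasbridge` takes the qualitative, ontology-based route: every atlas label
is bound to a class in a structural anatomy ontology, and correspondences
between schemes are read off the ontology's `part_of` / `regional_part_of`
partonomy and `is_a` taxonomy. For the canonical worked example, the
Talairach label

```
Right Cerebrum.Frontal Lobe.Superior Frontal Gyrus.Gray Matter.Brodmann area 6
```

binds to the class *Brodmann area 6 of right superior frontal gyrus*, which
is `regional_part_of` *Gray matter of right superior frontal gyrus* (the
class bound to DK's `ctx-rh-superiorfrontal`), in turn `regional_part_of`
*Right superior frontal gyrus* (bound to AAL's `Frontal_superior_right`),
which `is_a` the non-lateralized *Superior frontal gyrus* (NeuroLex). The
query engine returns those chains as explicit, hop-by-hop auditable paths.

The package provides:

- an in-memory ontology store with acyclicity-checked `is_a` / `part_of` /
  `regional_part_of` assertions and deterministic transitive-closure queries
  (`regional_part_of` counts toward the `part_of` closure);
- label grammars for the four schemes, including the five-level Talairach
  parser and abbreviation expansion (`ctx` → cortex, `lh` → left, ...);
- semi-automatic term mapping (exact / synonym / abbreviation / lexical
  matching with Jaccard scoring) plus a curation workflow that produces
  unique terminology bindings;
- the modeling patterns that make harmonization possible: Brodmann-by-gyrus
  intersection classes, lateralization, sulcal segments of gyri (a sulcus is
  an anatomical space; the buried cortex is a material segment), and
  white-matter tract partitions with exclusive segment names;
- Table-style connectivity relations (`projects_to/from` at tract level,
  `sends_output_to` / `receives_input_from` at region level, ternary
  `has_pathway`) with rule-based pathway inference;
- deterministic Turtle + TSV serialization and a `atlasbridge` CLI.

## Worked example

```sh
$ atlasbridge build-fixture ref
wrote bundle with 85 classes to ref

$ atlasbridge correlate --bundle ref --from talairach --to aal \
    "Right Cerebrum.Frontal Lobe.Superior Frontal Gyrus.Gray Matter.Brodmann area 6"
aal	Frontal_superior_right	up	[regional_part_of] Gray matter of right superior frontal gyrus -> [regional_part_of] Right superior frontal gyrus

$ atlasbridge validate ref
0 violations

$ printf 'Lateral occipital cortex\n' > labels.txt
$ atlasbridge map --scheme neurolex --bundle ref labels.txt
scheme	label	class_id	method	score	status
neurolex	Lateral occipital cortex	na:cortex-of-lateral-occipital-gyrus	lexical	0.750	candidate
```

Reading the output: the Talairach cell-level label correlates *upward* to
the AAL gyrus label in two partonomy hops, via the DK-bound gray-matter
class — i.e. the Talairach region is a finer-grained part of the region the
AAL label names. The `map` row says the NeuroLex phrase "Lateral occipital
cortex" is a *lexical* match (token-overlap score 0.75) to the ontology
class *Cortex of lateral occipital gyrus*, a candidate a curator would then
accept into a binding.

The same operations are available as a library:

```python
from atlasbridge import build_reference_fixture, correlate_label, SchemeId

onto = build_reference_fixture()
for r in correlate_label(onto, "Frontal_superior_right",
                         SchemeId.AAL, SchemeId.NEUROLEX):
    print(r.target_label, r.direction.value,
          [(onto.name_of(c), k.value) for c, k in r.path])
```

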