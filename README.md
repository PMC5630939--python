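# belflow

Semi-automated extraction of causal biological knowledge from free text,
modelled on the curation workflows used to build disease networks such as
the atherosclerotic plaque destabilization network in the ApoE⁻/⁻ mouse.

`belflow` turns article passages into **BEL** (Biological Expression
Language) statements — triples `subject relation object` over typed
biological entities, e.g.

```
p(HGNC:CYP4A11) -> bp(GOBP:angiogenesis)
p(HGNC:CYP4A11) -> (sec(a(CHEBI:20-HETE)) -> bp(GOBP:'blood vessel development'))
```

and compiles curated BEL documents into a **knowledge assembly model
(KAM)**: a directed multigraph whose nodes are canonical BEL terms and
whose edges carry a relation, a causal/non-causal flag and the supporting
evidence sentences.

Who it is for: curators and systems-biology groups who want a scriptable,
fully testable stand-in for the classic semi-automated curation stack
(dictionary NER → event extraction → BEL conversion → curation →
compilation → Cytoscape export), and anyone who needs a compact, validated
BEL parser/writer with BEL Script and XBEL support.

## What is inside

| module | role |
| --- | --- |
| `belflow.bel_core` | BEL data model, grammar (15 functions, 9 relations, one nesting level), parser/serializer, syntax validator, BEL Script + XBEL readers/writers |
| `belflow.extraction` | text clean-up, section selection (abstract/methods/results), sentence segmentation, dictionary longest-match NER, trigger-pattern regulation-event extraction, recall evaluation |
| `belflow.bel_convert` | event → statement conversion, document assembly with evidence/context annotations, JSON sidecar (entity offsets, alternative namespaces), programmatic curation edits with re-validation |
| `belflow.kam` | compiler BEL documents → KAM, structural (non-causal) edge inference, merge, node/edge censuses, XGMML export/import |
| `belflow.analysis` | degrees, hubs (degree > mean), scale-free check, network comparison, evidence overlap, curation-efficiency metrics |
| `belflow.fixtures` | deterministic generators: gold-annotated corpora, synthetic BEL corpora, preferential-attachment / uniform random graphs |
| `belflow.cli` | `belflow` command: `clean`, `extract`, `convert`, `curate`, `compile`, `export`, `analyze`, `fixtures`, `run` |

The NER and event extractors are rule-based functional stand-ins for the
heavyweight tools used in production curation pipelines (ProMiner-class
dictionary taggers, SVM event extractors such as TEES) with the same
output contracts, so real tools can be plugged in behind the same
interface.

## Worked example

```python
from belflow.extraction import ner, extract_events
from belflow.bel_convert import event_to_statement
from belflow.fixtures import bundled_dictionaries

sentence = "CYP4A11 transfection significantly increased microvessel density"
mentions = ner(sentence, bundled_dictionaries())
(event,) = extract_events(sentence, mentions)
print(event_to_statement(event))
```

prints

```
p(HGNC:CYP4A11) -> bp(GOBP:angiogenesis)
```

— the gene mention is normalized to its HGNC symbol, "microvessel density"
is normalized to the GO biological process *angiogenesis*, and the
positive-regulation trigger becomes the BEL `increases` relation.

Compiling that statement together with its nested manual annotation:

```python
from belflow.kam import compile_documents, edge_census
# doc holds the two statements shown at the top of this page
kam = compile_documents([doc])
print(kam.node_count, kam.edge_count, edge_census(kam))
```

```
5 4 {'total': 4, 'causal': 3, 'non_causal': 1, 'by_relation':
     {'hasComponent': 1, 'increases': 3}}
```

The nested statement contributes the inner edge `sec(a(CHEBI:20-HETE)) ->
bp(...)`, the outer edge `p(HGNC:CYP4A11) -> bp(...)`, and a non-causal
`hasComponent` edge linking the secretion wrapper to the chemical it
secretes — which is how a network built from purely causal statements
acquires non-causal "different forms of the same entity" edges.

End-to-end on the bundled synthetic corpus:

```
belflow run --out out --seed 5
```

writes cleaned passages, an XBEL document + curation sidecar, the compiled
KAM (JSON + XGMML for Cytoscape) and a topology report, plus a manifest of
SHA-256 hashes; reruns with the same seed are byte-identical.

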