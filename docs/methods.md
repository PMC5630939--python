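# Methods

## The knowledge-extraction model

`belflow` implements a six-stage semi-automated curation workflow:

1. **Text preparation.** PDF-derived text is normalized (line-break
   de-hyphenation, smart-quote/ligature folding, control-character
   removal); only the factual sections — abstract, methods, results — are
   retained, because introductions and discussions mostly restate results
   or speculate. `clean_text` is idempotent, and all downstream character
   offsets are 0-based half-open spans over the cleaned text.
2. **Entity recognition.** Dictionary-based longest-match NER over
   token-boundary-anchored spans. Each dictionary is namespace-scoped
   (HGNC gene symbols, ChEBI chemicals, GO biological processes, …) and
   maps surface forms to a preferred identifier. Overlap resolution:
   longer span wins, then the configured dictionary priority. Case policy:
   surface forms of ≤ 4 characters match exactly (gene symbols are
   case-significant), longer forms case-insensitively; this is a
   dictionary-level configuration, not hard-coded.
3. **Event extraction.** A trigger lexicon (lemmas such as
   *increase/induce/promote/upregulate/enhance* → positive regulation,
   *decrease/inhibit/reduce/suppress/downregulate* → negative regulation,
   inflected forms derived automatically) anchors regulation events inside
   one sentence: cause = nearest mention before the trigger, theme =
   nearest mention after it. A trigger without a following mention yields
   nothing; a missing cause yields a statement *fragment*. Negated
   triggers ("did not increase") produce no event by default; an opt-in
   flag maps them to `causesNoChange`.
4. **BEL conversion.** Positive/negative regulation become the indirect
   relations `->` / `-|` (a text-mined trigger cannot establish
   directness; the direct forms `=>` / `=|` are reachable only through
   curation edits). Entity classes map to term functions: gene/protein →
   `p()`, chemical → `a()`, process → `bp()`, complex → `complex()`,
   family → `p()` with the family namespace. Statements are grouped into
   one evidence block per sentence, ordered by (article, sentence span,
   subject serialization) so builds are deterministic, and a JSON
   *sidecar* carries what BEL cannot: entity text locations and
   alternative namespace candidates for each mention.
5. **Curation.** Edits (accept / reject / modify / assemble-fragments /
   set-annotation) are applied to a copy — the original document is never
   mutated — and every surviving statement is re-validated; an edit that
   would produce an invalid statement is refused together with the
   validator's violation list. Assembling one `subject-relation` fragment
   with one `relation-object` fragment whose relations agree consumes both
   and yields a complete statement.
6. **Compilation and export.** Validated documents compile into a single
   knowledge assembly model; XGMML export makes the network loadable in
   Cytoscape.

## The BEL subset

The grammar covers 15 functions: six abundance-class functions taking one
namespace value (`a`, `p`, `r`, `g`, `bp`, `path`), two grouping functions
(`complex`, `composite`: one value or ≥ 2 member terms), and seven
single-argument wrappers (`act`, `pep`, `kin`, `cat`, `tscript`, `deg`,
`sec`). Wrappers require a *molecular* abundance inside (`a/p/r/g`):
`kin(bp(...))` is a class violation, while `bp`/`path` are
namespace-value-arity abundances everywhere else. Term nesting is capped
at depth 2 and statement-object nesting at one level, which is exactly
what curated cardiovascular networks exercise. Nine relations are
supported; `increases`, `decreases`, `directlyIncreases`,
`directlyDecreases` and `causesNoChange` are causal, `association`,
`hasComponent`, `transcribedTo`, `translatedTo` are not. Long and short
function spellings are accepted on input; the short form is canonical on
output. Namespace keywords are case-insensitive (upper-case canonical),
values case-sensitive, quoted iff they contain characters outside
`[A-Za-z0-9_-]` (so `CHEBI:20-HETE` is canonically unquoted even where
source texts quote it); typographic quotes from PDF extraction are folded
to ASCII before parsing.

Both document formats are line/element dialects documented in the module
docstrings: BEL Script (`SET`/`DEFINE` directives + statement lines) and
XBEL (an XML schema with header, namespace and annotation declarations,
and evidence-scoped statement groups supporting one nesting level). The
UIMA-specific XMI companion of the original pipeline is replaced by a JSON
sidecar with the same declared content.

## KAM compilation semantics

* One node per distinct canonical term across all documents, including
  inner terms of wrappers and complex members.
* Duplicate statements merge into one edge keyed by
  (source, target, relation), accumulating evidence `(pmid, sentence)`
  pairs; evidence counts are conserved.
* A nested statement `A -> (B -> C)` produces the inner edge `B -> C`
  *and* the outer edge `A -> C`: both annotation styles of a mediated
  effect then connect the upstream protein to the downstream process.
  This policy is isolated in one function for easy change.
* Structural non-causal edges are inferred (each rule independently
  switchable): `complex → member` and `wrapper → inner term`
  (`hasComponent`), `g(X) → r(X)` (`transcribedTo`) and `r(X) → p(X)`
  (`translatedTo`) whenever both plain forms of the same
  `namespace:value` occur in the graph. The nine-relation inventory has
  no dedicated wrapper-link relation, so `hasComponent` covers both
  membership and wrapping. These rules are why causal-only source
  statements still yield non-causal edges connecting different forms of
  one entity.
* `causesNoChange` edges count as causal but carry the flag needed to
  exclude them from topology if desired. Self-edges are retained and
  counted once. Merging is idempotent and compilation order-independent.

## Topology conventions

Degrees are computed on the undirected simple-graph projection (parallel
edges collapsed) by default, matching Cytoscape Network Analyzer; a
`count` policy and directed in/out degrees are available. **Hubs** are the
nodes with degree strictly above the mean degree — ties at the mean are
excluded. The scale-free check follows the Network Analyzer approach: a
least-squares line on log₁₀(frequency) vs log₁₀(degree) over degrees ≥ 1,
verdict "scale-free" when the slope lies in [−4, −1] and r² ≥ 0.7 (both
configurable), "indeterminate" below 10 distinct degree values. Unbinned
LSQ slopes are known to flatten relative to the true exponent (a
preferential-attachment graph with asymptotic exponent −3 fits around −2
at n = 2000), so a discrete maximum-likelihood exponent (Clauset-style
closed form) is reported alongside for reference; the verdict uses the
LSQ fit.

Evidence overlap between two document sets normalizes sentences
(lower-case, punctuation stripped, whitespace collapsed) and reports the
Jaccard index as the headline plus both per-set fractions, since "x% of
sentences overlapped" phrasings leave the denominator open. Curation
metrics divide per-arm minutes by statements and by statements +
annotations, rounded half-up to one decimal — the published efficiency
table reproduces under this rule for three of its four ratios, while its
fourth (1.2 min per statement+annotation, assisted arm) is inconsistent
with its own inputs (395/346 = 1.14 → 1.1); the recomputed 1.1 is reported
and the discrepancy documented rather than matched.

## Synthetic data: what it emulates and what it does not

The corpus generator emulates a small curation exercise: 7 articles by
default (the size of the published two-arm comparison), ~20 sentences per
article split over abstract and results plus excluded introduction
passages, short templated factual sentences ("Notably, ⟨gene⟩
significantly increased ⟨process⟩ in ApoE-/- mice.") with entities drawn
from bundled HGNC/GOBP/CHEBI excerpt dictionaries (~120/70/60 entries of
real vascular-biology vocabulary), a 10% fragment rate (cause-less
sentences), 5% negated sentences and 25% distractors. Sentences are built
so the rule-based extractors resolve them exactly; gold mentions, events
and statements are emitted alongside, which makes 100% end-to-end recall
on the clean setting a *construction invariant* (itself tested), not an
empirical claim. A withheld-synonym rate renders that fraction of planted
mentions with a surface form absent from every dictionary, so measured
recall degrades by the planted rate ± sampling error.

What passing these tests shows: the plumbing — offsets, normalization,
longest-match resolution, conversion, compilation — is exact. What it does
not show: performance on real prose. Real articles have coordination,
anaphora, nested clauses, OCR noise beyond hyphenation/smart quotes, and
entity synonymy far beyond the bundled excerpts; published F-scores of
the production tools this package stands in for are therefore not
reproduction targets. Likewise the published recall-by-dictionary table
and the 7-article network node counts depend on a proprietary gold corpus
and dictionary versions and are out of scope.

The BEL-corpus generator emits 5 documents × 40 statements by default with
a 10% duplicate rate (duplicates get fresh evidence, making compile-time
merging observable). The graph generator wraps networkx
preferential-attachment (n = 500, m = 2 default; n = 2000 where a stable
degree distribution matters) and G(n, p) (p = 0.01) graphs in KAM form as
positive/negative controls for the scale-free check. All generators are
driven by a single integer seed; identical configs give byte-identical
outputs.

## Numerical and design choices

* Rounding of curation ratios: decimal half-up at one decimal, applied to
  the exact float ratio's shortest repr.
* Hub thresholding uses a strict inequality; a regular graph has no hubs.
* The recall evaluator matches on (sentence, span, namespace, id) —
  partial-span or wrong-namespace finds count as misses and as spurious
  precision hits; it errors when a requested namespace has no gold
  mentions (undefined recall).
* Dictionary synonym collisions (one surface form, two ids in one
  namespace) are load-time errors, not match-time surprises; alternative
  readings *across* namespaces are preserved in the sidecar instead of
  being resolved silently.
* Documents containing fragments validate (fragments are legitimate
  curation intermediates) but refuse to compile; the pipeline's
  uncurated `run` drops fragments at compile time.
* The parser is a hand-rolled tokenizer + recursive descent (~200 lines):
  the subset grammar is small, and syntax errors need exact character
  offsets for the curation interface contract.

## Problem sizes in the default test run

Round-trip properties use 500 generated statements; compile/merge oracles
use 200-statement corpora; topology properties use n = 500–2000 graphs,
with 10–20 seeded replicates for the uniform-random negative control;
recall properties use 10–20 article corpora (≈ 300–600 gold mentions).
These sizes give stable verdicts for every property while keeping the full
suite fast.

## Known limitations

* The trigger-pattern extractor handles one event per trigger and no
  cross-sentence or coordinated structures; it is a contract-compatible
  stand-in, not a competitive event extractor.
* The XBEL dialect is this package's documented schema, not the historical
  OpenBEL XBEL XSD; likewise BEL Script covers the directive subset the
  workflow needs.
* Protein modifications, variants, translocation and the RDF serialization
  of BEL are out of scope.
* Scale-free verdicts are heuristic by design (regression on a log-log
  histogram); the MLE exponent is informative but no goodness-of-fit test
  is attached.
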