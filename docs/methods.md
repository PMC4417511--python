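# Methods

`tcgafed` implements a data-distribution scheme and a federated SPARQL
query engine tailored to TCGA-style level-3 cancer-genomics data published
as Linked Data. This note records the model, the parameters that matter,
the design choices made where the design was genuinely open, and what the
synthetic fixtures do and do not demonstrate.

## Data model

Level-3 results are per-patient processed measurements: DNA methylation
beta values, exon-expression RPKM, copy-number segment means, gene
expression estimates, miRNA and protein expression values, plus clinical
records. Every patient is identified by a barcode `TCGA-<TSS>-<PatientNo>`;
the tissue-source-site (TSS) code maps to a tumour type through a hash
table built from File_Sample_Map TSVs. RDFization mints, per surviving
table row, a result resource `<ns><barcode>-<code><ordinal>` whose single
code character names the result kind (`d` methylation, `e` exon expression,
`c` copy number, `g` gene expression, `m` miRNA, `p` protein expression).
Each resource carries an `rdf:type`, one typed literal per selected field
(integers for coordinates, decimals for measurement values) and a
`tcga:result` linkage triple from its patient.

The refiner drops a row entirely when any selected field holds a
missing-value token (`NA`, `Null`, `Unknown`, `Not Reported`, empty;
case-insensitive). Field selection is configuration: the shipped defaults
(methylation: chromosome/position/beta_value; copy number:
chromosome/start/stop/seq_mean; exon: chromosome/start/stop/RPKM; gene
expression: chromosome/scaled_estimate; miRNA:
chromosome/start/stop/miRNA_value; protein:
chromosome/protein_expression_value; clinical:
drug/follow_up/radiation) are reconstructed from the queries the engine
must answer, since upstream field lists are deployment-specific. Annotation
tables (e.g. probe-name → chromosome/position) are supported as lookup
rules; a lookup miss drops the row with a warning.

## Distribution

Each tumour's data is split into three colour categories: **green** holds
only methylation results, **pink** only exon expression, **blue**
everything else (observed size ratio roughly 1:3:4 blue:pink:green, which
motivates layouts such as 2/6/9 endpoints for a 33-tumour deployment and
2/3/5 for the 10-tumour benchmark). Within a colour, endpoints receive
balanced contiguous tumour ranges; when the count does not divide evenly,
the earlier endpoints take the extra tumour (33 tumours over 9 green
endpoints → six endpoints with four tumours, three with three). Every
tumour is stored exactly once per colour.

Routing: a result triple goes to the unique endpoint matching its node's
colour (from the code character) and tumour (TSS lookup). The
`tcga:result` linkage triple travels with its result node, so each record
is reachable from its patient at its own endpoint. Patient and clinical
triples are replicated to the matching-tumour endpoint of **every**
colour — each patient can be found at exactly one endpoint per colour. The
alternative (clinical data blue-only) was considered and rejected: the
replication reading also makes patient-barcode patterns answerable at
whichever colour the rest of a query selects, which the selection algorithm
relies on.

The index consists of an N3 specification file — per endpoint: URL, colour,
tumour list, file order; plus the predicate/class sets below — and the
TSS→tumour table. The specification vocabulary (`fed:hasColour`,
`fed:storesTumour`, `fed:setD`, ...) is this package's own minimal design;
any file carrying the same information validates.

## Source selection

The selector works per basic graph pattern and per triple pattern, using
only the index (no endpoint round-trips except where noted).

Predicate/class sets (defaults; editable in the specification file):

| set | content | role |
|-----|---------|------|
| D | seq_mean, scaled_estimate, protein_expression_value, miRNA_value, clinical, drug, follow_up, radiation | predicates unique to blue |
| C | CopyNumberResult, GeneExpressionResult, MirnaResult, ProteinExpressionResult, ClinicalRecord | classes unique to blue |
| M | beta_value, position | predicates unique to green |
| B | DnaMethylationResult | classes unique to green |
| F | RPKM | predicates unique to pink |
| E | ExonExpressionResult | classes unique to pink |
| A | chromosome, start, stop | shared predicates |
| G | result, bcr_patient_barcode | shared predicates |

Cases, in order:

1. **Bound subject.** A result URI yields colour and tumour directly → one
   endpoint. A bare patient/clinical URI yields one endpoint per colour.
   A foreign IRI falls back to ASK probing (or all endpoints when no
   transport is available).
2. **Bound predicate.** Three colour conditions are evaluated
   independently and the selected categories unioned. For a colour with
   unique predicate set U and class set K:
   *membership* — p ∈ U ∪ A ∪ G, or p = `rdf:type` with the object class
   in K (an `rdf:type` pattern with an unbound object satisfies membership
   for every colour, since it cannot discriminate); and
   *join clause* — the pattern star/path-joins a pattern whose predicate or
   type class is in U ∪ K, **or** joins nothing unique to any other colour.
   If no condition holds the blue category is selected: predicates not
   listed in the index (clinical detail, etc.) live in blue.
3. **Only the object bound.** SPARQL ASK probes to all endpoints,
   data-exact by construction. When the predicate is bound too, the
   condition logic wins and no probe is sent.
4. **Nothing bound.** All endpoints.

A known tumour — supplied, or inferred when a pattern with predicate
`tcga:bcr_patient_barcode` and a bound object star-joins a `tcga:result`
pattern (the TSS of the barcode is then looked up) — narrows every
condition- or subject-derived selection to the one endpoint per colour
holding that tumour. ASK-derived selections are already exact and are not
filtered.

**Join context.** "Star join" = same subject; "path join" = object of one
pattern is the subject of another (via a shared variable or identical bound
term). For the join clause, a pattern sees its star group plus the patterns
path-joined *out of* that group. This one-group-plus-outgoing-paths scope is
deliberate: it is what lets a patient-barcode pattern inherit blue from a
copy-number record star two hops away (barcode —star— result —path—
seq_mean), while stopping short of full connected-component reach, which
would leak colour evidence *across* the patient hub in cross-colour queries
(a methylation star would see RPKM through the shared patient variable and
lose its green classification, breaking recall).

Soundness: pruning a colour for a pattern is safe exactly when no data of
that colour can contribute to the *joined* result. Unique-set joins prove
which colour the star's records must have; patient replication guarantees
barcode/linkage patterns are answerable at whichever colours survive.

The reported metric is the triple-pattern-wise source count
tpws(q) = Σᵢ |mᵢ| over the query's patterns, mᵢ being the endpoints
selected for pattern tᵢ.

**ASK baseline.** The index-free comparison selector probes every
(pattern, endpoint) pair with ASK, caching by (variable-normalized pattern
signature, endpoint URL): a cold cache costs n_patterns × n_endpoints
requests; a warm cache costs none.

On a colour-pure distribution the baseline is per-pattern data-exact, so an
index-only selector can only match it — not beat it — on queries whose
patterns carry no unique predicates. The two generic benchmark queries are
therefore built from universally stored predicates (barcode, result,
chromosome; and result plus one value predicate per colour), the regime in
which both selectors provably coincide; on a description that pins
blue/pink-only predicates such as start/stop, an index-only selector
over-selects relative to exact probing, and no join logic can repair that
without per-predicate coverage information.

## Execution

Supported query subset: `SELECT [DISTINCT]` over one conjunctive BGP with
`FILTER`s and `LIMIT`. FILTER expressions are opaque text: pushed into a
remote sub-query when one step binds all their variables, otherwise
evaluated at integration time by rdflib over a `VALUES` block.

Planning: patterns whose selection is the same single endpoint merge into
one exclusive-group sub-query; remaining steps are ordered by ascending
source count, then pattern index. Joins are block nested-loop bound joins:
distinct shared-variable bindings are shipped in `VALUES` blocks of 20
(configurable) and merged locally under compatible-mapping semantics.

Because patient/clinical triples are replicated once per colour, naive
union of remote rows would triple-count them. Integration therefore dedupes
solutions on their full variable bindings — SPARQL BGP evaluation is a set
at that granularity — and duplicate *rows* re-appear only through final
projection, which is exactly the behaviour of centralized evaluation. The
recall oracle is rdflib evaluating the original query text over the union
of all endpoint data.

Transports: in-process rdflib stores (tests, fixtures) and a SPARQL 1.1
protocol client over HTTP GET with JSON results; a minimal threaded HTTP
server exposes any in-process store for protocol-level testing. Reported
timings, where any, would measure time to first result; nothing in the
test suite asserts wall-clock behaviour.

## Synthetic fixtures

The generator is seed-deterministic end to end (barcodes, tables, dumps,
spec files, query instantiations, reports). Defaults mirror the two study
setups:

- **benchmark**: 10 tumour types (one distinct TSS each), 25 patients
  assigned cyclically, 3 records per result kind per patient, 10% missing
  rows, 2/3/5 blue/pink/green endpoints;
- **deployment**: 33 tumour types, one patient each, 2 records per kind,
  2/6/9 endpoints.

Values are uniform in documented ranges: beta_value ∈ [0,1], seq_mean ∈
[−2,2], RPKM ∈ [0,500], scaled_estimate ∈ [0,1], miRNA_value ∈ [0,100],
protein value ∈ [−3,3]; coordinates are 1-based with start < stop. A
configurable fraction of rows carries a missing-value token in one selected
field; the ground-truth index records exactly the surviving rows, giving
the refiner and the recall oracle an independent reference.

What the fixtures do **not** emulate: genomic realism (no linkage between
kinds, no per-gene structure, no chromosome-length weighting), many-to-one
TSS→tumour codes (supported by the table, not generated by default),
clinical richness (three properties of the ~300 real ones), result-set
scale, endpoint latency or failure. Passing tests demonstrate the routing,
selection and integration logic — not performance at billions of triples.

The ten benchmark queries follow the published descriptions (patient
barcodes substituted with fixture patients and recorded in the query
metadata; bound constants such as a seq_mean value or a record URI are
drawn from the generator's ground truth). Query 1's genomic range is kept
as printed (554268–5994290) without a chromosome constraint; the two
generic queries (5 and 10) use only universally stored predicates for the
reasons above. The taxonomy labels (2 single-colour star, 2 cross-colour
star, 2 single-colour hybrid, 4 cross-colour hybrid) are carried as
metadata.

## Numerical and degenerate-input choices

- Ordinals restart from 1 after refinement and follow source-row order.
- Decimal literals keep their printed lexical form (4–6 decimal places);
  bound decimal objects in queries are written as quoted typed literals.
- Endpoint order is specification-file order; all serialized selections,
  reports and N3 files are sorted for byte determinism.
- An empty refined table still emits the patient node. An empty selection
  for any pattern short-circuits execution to zero rows without contacting
  endpoints. A TSS missing from the table is a routing error when
  partitioning, and degrades to "no tumour narrowing" (with a warning)
  during selection.
- `(?s ?p ?o)` selects all endpoints — the safe over-approximation; the
  same applies to bound-subject fallback when no ASK transport is wired.

## Known limitations

- One BGP per query; no OPTIONAL/UNION/property paths/aggregates.
- Join ordering is the ascending-source-count heuristic, not a cost model;
  only result equivalence is guaranteed, not plan optimality.
- The colour conditions assume the unique/shared predicate sets are
  correct for the deployed data; a predicate missing from the index is
  implicitly blue, which is sound only while unlisted predicates are
  indeed stored blue (or replicated, as patient/clinical data is).
- The ASK baseline models the probing and caching behaviour of index-free
  federators, not any specific engine's exclusive-group or cost logic.
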