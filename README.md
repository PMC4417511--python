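# tcgafed

Colour-partitioned RDF distribution and join-aware federated SPARQL
querying for TCGA-style level-3 cancer-genomics data.

## The problem

The Cancer Genome Atlas publishes processed ("level-3") molecular results —
DNA methylation beta values, exon-expression RPKM, copy-number segment
means, gene/miRNA/protein expression, clinical records — as per-patient
tab-delimited files. Published as Linked Data, the corpus is far too large
for one triple store, so it is spread over many SPARQL endpoints; a
federated engine must then decide, for every triple pattern of a query,
*which* endpoints can contribute answers. Generic federators probe every
endpoint with SPARQL ASK requests and still over-select, because a pattern
like `?r tcga:chromosome ?c` matches everywhere even when the rest of the
query restricts `?r` to copy-number records.

`tcgafed` is for data engineers and biomedical-informatics developers who
need this pipeline end to end and offline-testable: an RDFizer for level-3
TSVs, a colour-category partitioner, a join-aware source selector with an
ASK-probing baseline, a federated executor, and a deterministic synthetic
data generator.

## The method

**Distribution.** Each tumour's data is split into three colour
categories — green (methylation only), pink (exon expression only), blue
(everything else) — and each category's endpoints hold balanced contiguous
tumour ranges, so every tumour is stored exactly once per colour. Patient
and clinical triples are replicated to one endpoint per colour. An N3
specification file (endpoint URL, colour, tumour list, predicate/class
sets) plus a TSS→tumour hash table (from File_Sample_Map TSVs; the TSS is
the middle field of a `TCGA-<TSS>-<PatientNo>` barcode) form the
federation's entire index.

**Source selection.** For a pattern t with predicate p, three colour
conditions are checked independently against the index's sets (D/C unique
to blue, M/B to green, F/E to pink, A/G shared); for a colour with unique
sets U, K the condition is

&nbsp;&nbsp;[ p ∈ U ∪ A ∪ G ∨ (p = rdf:type ∧ o ∈ K) ] ∧
[ joins(t, U ∪ K) ∨ ¬ joins(t, unique sets of the other colours) ]

where joins(t, X) scans t's star group (same subject) and the patterns
path-joined out of it. Selected colours are unioned; no colour means blue
(unlisted predicates live there). Bound result-URI subjects resolve
directly to one endpoint; a bound patient barcode star-joined with
`tcga:result` lets the TSS lookup narrow every selection to one endpoint
per surviving colour. Only patterns binding *just* their object fall back
to ASK probing. The quality metric is the triple-pattern-wise source count
tpws(q) = Σᵢ |mᵢ|.

**Execution.** Patterns selecting the same single endpoint ship as one
exclusive-group sub-query; the rest join by ascending source count with
block bound joins (`VALUES`-injected bindings). Integration dedupes on
full variable bindings so per-colour replication never inflates results:
federated answers are multiset-identical to centralized evaluation over
the union of all endpoint data (100% recall).

## Worked example

`python examples/03_source_selection.py` generates the 17-endpoint
deployment fixture (33 tumours; 2 blue / 6 pink / 9 green endpoints) and
runs selection for a patient-specific copy-number query:

```
patient TCGA-18-4748 (TSS 18 -> LUSC)

pattern 0: 1 source(s) -> ['memory://blue2']
pattern 1: 1 source(s) -> ['memory://blue2']
pattern 2: 1 source(s) -> ['memory://blue2']
pattern 3: 1 source(s) -> ['memory://blue2']
pattern 4: 1 source(s) -> ['memory://blue2']
pattern 5: 1 source(s) -> ['memory://blue2']

triple-pattern-wise source count: 6 out of 102 pattern-endpoint pairs
```

The barcode's TSS resolves the tumour (LUSC), `tcga:seq_mean` is unique to
blue, and the star/path joins propagate that colour to all six patterns —
one endpoint each, so the whole query ships as a single remote sub-query.
The ASK baseline on the same query (`examples/04_ask_baseline.py`) issues
102 cold-cache probes and selects 3 + 17 + 17 + 8 + 8 + 2 = 55
pattern-wise sources. On the ten-query benchmark
(`examples/05_federated_query.py`, 25 patients over 10 tumours on 10
endpoints) every query returns exactly the centralized result multiset;
join-aware selection never exceeds the baseline and matches it only on the
two generic queries:

```
query tpws  rows  recall  description
Q1       6     0  100%   Chromosome, start, stop and copy-number segment mean of
Q2      12    69  100%   Chromosome, start, stop and exon-expression RPKM of all
Q3      15    69  100%   Chromosome, position and methylation beta value of all
...
Q10     40   498  100%   Generic cross-colour retrieval: gene expression, exon e
```

A thin CLI wraps the same library: `tcgafed fixture | rdfize | partition |
select | query` (see `tcgafed --help`).

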