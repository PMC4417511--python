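"""Deterministic TCGA-shaped fixtures for offline testing and benchmarks.

The generator emulates the structure that matters for distribution and
federated querying — barcodes, the TSS→tumour relation, per-kind level-3
result tables with realistic column dialects, missing-value tokens, the
specification index and the partitioned per-endpoint dumps — not genomic
biology: numeric values are uniform within documented ranges (methylation
beta values in [0,1], RPKM ≥ 0, copy-number segment means in [-2, 2], ...).

Two stock configurations mirror the published setups: a 10-endpoint
benchmark (25 patients over 10 tumour types; 2 blue / 3 pink / 5 green
endpoints) and a 17-endpoint deployment layout (33 tumours; 2 blue /
6 pink / 9 green).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import Optional

from .distribution import (
    SpecificationIndex,
    TSSTumourTable,
    assign_tumours,
    build_tss_table,
    partition,
)
from .endpoints import EndpointPool, InProcessEndpoint, SparqlHTTPServer
from .model import (
    CLINICAL_FIELDS,
    CLINICAL_KIND,
    RESULT_KINDS,
    PatientBarcode,
)
from .rdfizer import (
    FieldMap,
    RawTable,
    TripleDump,
    default_field_map,
    refine,
    rdfize,
)

#: Tumour-type identifiers used for fixture tumours, in Fig.-3-style order.
TUMOUR_CODES = [
    "ACC", "BLCA", "BRCA", "CESC", "CHOL", "COAD", "DLBC", "ESCA", "GBM",
    "HNSC", "KICH", "KIRC", "KIRP", "LAML", "LGG", "LIHC", "LUAD", "LUSC",
    "MESO", "OV", "PAAD", "PCPG", "PRAD", "READ", "SARC", "SKCM", "STAD",
    "TGCT", "THCA", "THYM", "UCEC", "UCS", "UVM",
]

CHROMOSOMES = [f"chr{i}" for i in range(1, 23)] + ["chrX", "chrY"]

DRUGS = ["Cisplatin", "Tamoxifen", "Paclitaxel", "Gemcitabine"]

#: Extra raw columns per kind, to exercise column selection.
_EXTRA_COLUMNS = {
    "dna-methylation": ["probe_name", "gene_symbol"],
    "exon-expression": ["raw_counts"],
    "copy-number": ["num_probes"],
    "gene-expression": ["gene_id"],
    "mirna": ["mirna_id"],
    "protein-expression": ["protein_name"],
}


@dataclass
class FixtureConfig:
    """Study conditions for one generated dataset."""

    n_tumours: int = 10
    n_patients: int = 25
    records_per_kind: dict = field(
        default_factory=lambda: {name: 3 for name in RESULT_KINDS})
    layout: dict = field(
        default_factory=lambda: {"blue": 2, "pink": 3, "green": 5})
    seed: int = 0
    missing_value_rate: float = 0.1


@dataclass(frozen=True)
class PatientInfo:
    barcode: PatientBarcode
    tumour: str

    @property
    def tss(self) -> str:
        return self.barcode.tss


@dataclass
class Fixture:
    """A generated dataset plus its ground truth."""

    config: FixtureConfig
    tumours: list[str]
    patients: list[PatientInfo]
    raw_tables: dict            # (barcode str, kind) -> RawTable
    file_sample_map: str        # TSV text
    tss_table: TSSTumourTable
    index: SpecificationIndex
    dumps: dict                 # endpoint url -> TripleDump
    ground_truth: dict          # (barcode str, kind) -> list of field dicts
    union_dump: TripleDump

    def patients_of_tumour(self, tumour: str) -> list[PatientInfo]:
        return [p for p in self.patients if p.tumour == tumour]

    def first_patient_with(self, kind: str) -> PatientInfo:
        """First patient (generation order) with a surviving record of kind."""
        for p in self.patients:
            if self.ground_truth.get((str(p.barcode), kind)):
                return p
        raise LookupError(f"no patient has a clean {kind} record")


def _gen_value(rng: random.Random, fname: str) -> str:
    if fname == "chromosome":
        return rng.choice(CHROMOSOMES)
    if fname == "position":
        return str(rng.randint(1, 10_000_000))
    if fname in ("start", "stop"):
        raise AssertionError("start/stop generated pairwise")
    if fname == "beta_value":
        return f"{rng.random():.4f}"
    if fname == "seq_mean":
        return f"{rng.uniform(-2.0, 2.0):.4f}"
    if fname == "RPKM":
        return f"{rng.uniform(0.0, 500.0):.4f}"
    if fname == "scaled_estimate":
        return f"{rng.uniform(0.0, 1.0):.6f}"
    if fname == "miRNA_value":
        return f"{rng.uniform(0.0, 100.0):.4f}"
    if fname == "protein_expression_value":
        return f"{rng.uniform(-3.0, 3.0):.4f}"
    return f"v{rng.randint(1, 9999)}"


def _make_row(rng: random.Random, kind_name: str,
              fields: tuple[str, ...]) -> dict:
    row: dict[str, str] = {}
    if "start" in fields:
        start = rng.randint(1, 9_000_000)
        row["start"] = str(start)
        row["stop"] = str(start + rng.randint(100, 50_000))
    for fname in fields:
        if fname in row:
            continue
        row[fname] = _gen_value(rng, fname)
    for extra in _EXTRA_COLUMNS.get(kind_name, []):
        row[extra] = f"{extra[:2]}{rng.randint(1000, 9999)}"
    return row


def generate(config: FixtureConfig,
             field_map: Optional[FieldMap] = None) -> Fixture:
    """Generate a full fixture, deterministic under ``config.seed``."""
    rng = random.Random(config.seed)
    fmap = field_map or default_field_map()

    n = config.n_tumours
    if n > len(TUMOUR_CODES):
        raise ValueError(f"at most {len(TUMOUR_CODES)} tumour types supported")
    tumours = TUMOUR_CODES[:n]
    # one distinct TSS per tumour: "01", "02", ... in tumour order
    tss_of = {t: f"{i:02d}" for i, t in enumerate(tumours, start=1)}

    patients: list[PatientInfo] = []
    used_numbers: set[str] = set()
    for i in range(config.n_patients):
        tumour = tumours[i % n]
        while True:
            number = f"{rng.randint(1000, 9999)}"
            if number not in used_numbers:
                used_numbers.add(number)
                break
        patients.append(PatientInfo(
            PatientBarcode(tss=tss_of[tumour], patient=number), tumour))

    # raw tables + ground truth
    raw_tables: dict = {}
    ground_truth: dict = {}
    missing_pool = ["NA", "Null", "Unknown", "Not Reported"]
    for p in patients:
        bc = str(p.barcode)
        for kind_name, kind in RESULT_KINDS.items():
            n_rows = config.records_per_kind.get(kind_name, 0)
            if n_rows == 0:
                continue
            columns = list(kind.fields) + _EXTRA_COLUMNS.get(kind_name, [])
            rows, clean = [], []
            for _ in range(n_rows):
                row = _make_row(rng, kind_name, kind.fields)
                if rng.random() < config.missing_value_rate:
                    victim = rng.choice(kind.fields)
                    row[victim] = rng.choice(missing_pool)
                    rows.append(tuple(row[c] for c in columns))
                else:
                    rows.append(tuple(row[c] for c in columns))
                    clean.append({f: row[f] for f in kind.fields})
            raw_tables[(bc, kind_name)] = RawTable(kind_name, columns, rows)
            ground_truth[(bc, kind_name)] = clean
        # clinical: one record per patient, never missing
        crow = {"drug": rng.choice(DRUGS),
                "follow_up": f"{rng.randint(1, 120)} months",
                "radiation": rng.choice(["yes", "no"])}
        raw_tables[(bc, CLINICAL_KIND)] = RawTable(
            CLINICAL_KIND, list(CLINICAL_FIELDS),
            [tuple(crow[c] for c in CLINICAL_FIELDS)])
        ground_truth[(bc, CLINICAL_KIND)] = [crow]

    # File_Sample_Map
    map_lines = ["filename\tbarcode\ttumour"]
    for p in patients:
        for kind_name in list(RESULT_KINDS) + [CLINICAL_KIND]:
            if (str(p.barcode), kind_name) in raw_tables:
                map_lines.append(
                    f"{kind_name}.{p.barcode}.txt\t{p.barcode}\t{p.tumour}")
    file_sample_map = "\n".join(map_lines) + "\n"
    tss_table = build_tss_table(file_sample_map)

    # index, RDFization, partition
    index = assign_tumours(n, config.layout, tumour_names=tumours)
    union = TripleDump()
    per_patient_dumps = []
    for p in patients:
        for kind_name in list(RESULT_KINDS) + [CLINICAL_KIND]:
            raw = raw_tables.get((str(p.barcode), kind_name))
            if raw is None:
                continue
            dump = rdfize(refine(raw, fmap), p.barcode,
                          namespace=index.data_ns, vocab_ns=index.vocab_ns)
            per_patient_dumps.append(dump)
            union = union | dump
    dumps = partition(per_patient_dumps, index, tss_table)

    # generation-time consistency: partitions recombine to the input
    recombined = set()
    for d in dumps.values():
        recombined |= d.triples
    if recombined != union.triples:
        raise AssertionError("partitioned dumps do not recombine to the union")

    return Fixture(config=config, tumours=tumours, patients=patients,
                   raw_tables=raw_tables, file_sample_map=file_sample_map,
                   tss_table=tss_table, index=index, dumps=dumps,
                   ground_truth=ground_truth, union_dump=union)


def benchmark_config(seed: int = 0) -> FixtureConfig:
    """The 10-endpoint benchmark conditions: 25 patients, 10 tumours."""
    return FixtureConfig(seed=seed)


def deployment_config(seed: int = 0) -> FixtureConfig:
    """The 17-endpoint deployment layout: 33 tumours, one patient each."""
    return FixtureConfig(
        n_tumours=33, n_patients=33,
        records_per_kind={name: 2 for name in RESULT_KINDS},
        layout={"blue": 2, "pink": 6, "green": 9},
        seed=seed, missing_value_rate=0.1)


def spawn_endpoints(fixture: Fixture, transport: str = "memory"):
    """One queryable endpoint per descriptor, loaded with its dump.

    ``memory`` returns an EndpointPool of in-process stores. ``http``
    additionally serves each store over the SPARQL protocol on localhost
    and returns ``(pool_of_http_clients, servers)``; callers stop the
    servers when done.
    """
    stores = {url: InProcessEndpoint.from_dump(url, dump)
              for url, dump in fixture.dumps.items()}
    if transport == "memory":
        pool = EndpointPool()
        for store in stores.values():
            pool.add(store)
        return pool
    if transport == "http":
        from .endpoints import HTTPEndpoint
        pool = EndpointPool()
        servers = []
        for url, store in stores.items():
            server = SparqlHTTPServer(store).start()
            servers.append(server)
            # register the HTTP client under the descriptor URL it serves
            pool.endpoints[url] = HTTPEndpoint(url=server.url)
        return pool, servers
    raise ValueError(f"unknown transport {transport!r}")


# ---------------------------------------------------------------------------
# Benchmark queries
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BenchmarkQuery:
    qid: str
    description: str
    text: str
    quadrant: str               # e.g. "single-colour star"
    paper_patient: Optional[str] = None
    fixture_patient: Optional[str] = None


_PROLOGUE = "PREFIX tcga: <{vocab}>\n"


def benchmark_queries(fixture: Fixture) -> list[BenchmarkQuery]:
    """Instantiate the ten benchmark queries against a fixture.

    Patient-specific queries substitute fixture barcodes for the published
    patient identifiers (recorded in ``paper_patient``/``fixture_patient``).
    The two generic queries use only predicates stored at every endpoint,
    the regime in which index-based selection and exhaustive ASK probing
    coincide.
    """
    pro = _PROLOGUE.format(vocab=fixture.index.vocab_ns)
    pts = fixture.patients

    def pt(i: int) -> PatientInfo:
        return pts[i % len(pts)]

    def with_records(kind: str) -> PatientInfo:
        return fixture.first_patient_with(kind)

    q = []

    p1 = with_records("copy-number")
    q.append(BenchmarkQuery(
        "Q1",
        "Chromosome, start, stop and copy-number segment mean of one "
        "patient, within a genomic range",
        pro + f"""SELECT ?chr ?start ?stop ?mean WHERE {{
  ?p tcga:bcr_patient_barcode "{p1.barcode}" .
  ?p tcga:result ?r .
  ?r tcga:chromosome ?chr .
  ?r tcga:start ?start .
  ?r tcga:stop ?stop .
  ?r tcga:seq_mean ?mean .
  FILTER(?start >= 554268 && ?stop <= 5994290)
}}""",
        "single-colour hybrid", "TCGA-18-4721", str(p1.barcode)))

    q.append(BenchmarkQuery(
        "Q2",
        "Chromosome, start, stop and exon-expression RPKM of all patients",
        pro + """SELECT ?chr ?start ?stop ?rpkm WHERE {
  ?r tcga:chromosome ?chr .
  ?r tcga:start ?start .
  ?r tcga:stop ?stop .
  ?r tcga:RPKM ?rpkm .
}""",
        "single-colour star"))

    q.append(BenchmarkQuery(
        "Q3",
        "Chromosome, position and methylation beta value of all patients",
        pro + """SELECT ?chr ?pos ?beta WHERE {
  ?r tcga:chromosome ?chr .
  ?r tcga:position ?pos .
  ?r tcga:beta_value ?beta .
}""",
        "single-colour star"))

    p4 = pt(1)
    q.append(BenchmarkQuery(
        "Q4",
        "Chromosome, start and stop values of one patient",
        pro + f"""SELECT ?chr ?start ?stop WHERE {{
  ?p tcga:bcr_patient_barcode "{p4.barcode}" .
  ?p tcga:result ?r .
  ?r tcga:chromosome ?chr .
  ?r tcga:start ?start .
  ?r tcga:stop ?stop .
}}""",
        "cross-colour hybrid", "TCGA-C4-A0F6", str(p4.barcode)))

    q.append(BenchmarkQuery(
        "Q5",
        "Generic enumeration: every patient, record and chromosome",
        pro + """SELECT ?p ?r ?chr WHERE {
  ?p tcga:bcr_patient_barcode ?bc .
  ?p tcga:result ?r .
  ?r tcga:chromosome ?chr .
}""",
        "cross-colour star"))

    p6 = with_records("mirna")
    rec6 = fixture.ground_truth[(str(p6.barcode), "mirna")]
    ord6 = _clean_ordinal(fixture, p6, "mirna", min(20, len(rec6)))
    node6 = f"{fixture.index.data_ns}{p6.barcode}-m{ord6}"
    q.append(BenchmarkQuery(
        "Q6",
        "Chromosome, start, stop and miRNA value of one specific record "
        "of one patient",
        pro + f"""SELECT ?chr ?start ?stop ?mir WHERE {{
  ?p tcga:bcr_patient_barcode "{p6.barcode}" .
  ?p tcga:result ?r .
  ?r tcga:chromosome ?chr .
  ?r tcga:start ?start .
  ?r tcga:stop ?stop .
  ?r tcga:miRNA_value ?mir .
  FILTER(?r = <{node6}>)
}}""",
        "cross-colour hybrid", "TCGA-AB-2821", str(p6.barcode)))

    p7 = with_records("copy-number")
    mean7 = fixture.ground_truth[(str(p7.barcode), "copy-number")][0]["seq_mean"]
    q.append(BenchmarkQuery(
        "Q7",
        "Chromosome, start and stop of one patient's records with a given "
        "copy-number segment mean",
        pro + f"""SELECT ?chr ?start ?stop WHERE {{
  ?p tcga:bcr_patient_barcode "{p7.barcode}" .
  ?p tcga:result ?r .
  ?r tcga:chromosome ?chr .
  ?r tcga:start ?start .
  ?r tcga:stop ?stop .
  ?r tcga:seq_mean "{mean7}"^^<http://www.w3.org/2001/XMLSchema#decimal> .
}}""",
        "single-colour hybrid", "TCGA-AB-2823", str(p7.barcode)))

    p8 = pt(4)
    q.append(BenchmarkQuery(
        "Q8",
        "Protein expression plus exon chromosome/start/stop/RPKM of one "
        "patient",
        pro + f"""SELECT ?pe ?chr ?start ?stop ?rpkm WHERE {{
  ?p tcga:bcr_patient_barcode "{p8.barcode}" .
  ?p tcga:result ?r1 .
  ?r1 tcga:protein_expression_value ?pe .
  ?p tcga:result ?r2 .
  ?r2 tcga:chromosome ?chr .
  ?r2 tcga:start ?start .
  ?r2 tcga:stop ?stop .
  ?r2 tcga:RPKM ?rpkm .
}}""",
        "cross-colour hybrid", "TCGA-18-3410", str(p8.barcode)))

    p9 = pt(5)
    q.append(BenchmarkQuery(
        "Q9",
        "Chromosome, gene-expression estimate and methylation beta value "
        "of one patient",
        pro + f"""SELECT ?chr ?ge ?beta WHERE {{
  ?p tcga:bcr_patient_barcode "{p9.barcode}" .
  ?p tcga:result ?r1 .
  ?r1 tcga:chromosome ?chr .
  ?r1 tcga:scaled_estimate ?ge .
  ?p tcga:result ?r2 .
  ?r2 tcga:beta_value ?beta .
}}""",
        "cross-colour hybrid", "TCGA-C5-A1BF", str(p9.barcode)))

    q.append(BenchmarkQuery(
        "Q10",
        "Generic cross-colour retrieval: gene expression, exon expression "
        "and methylation values of all patients",
        pro + """SELECT ?ge ?rpkm ?beta WHERE {
  ?p tcga:result ?r1 .
  ?r1 tcga:scaled_estimate ?ge .
  ?p tcga:result ?r2 .
  ?r2 tcga:RPKM ?rpkm .
  ?p tcga:result ?r3 .
  ?r3 tcga:beta_value ?beta .
}""",
        "cross-colour star"))

    return q


def _clean_ordinal(fixture: Fixture, p: PatientInfo, kind: str,
                   nth: int) -> int:
    """Ordinal (1-based, post-refinement) of the nth clean record."""
    clean = fixture.ground_truth[(str(p.barcode), kind)]
    if not clean:
        raise LookupError(f"{p.barcode} has no clean {kind} records")
    nth = min(nth, len(clean))
    return nth


def worked_example_query(fixture: Fixture,
                         tss: str = "18") -> tuple[str, PatientInfo]:
    """The patient-specific copy-number query of the worked example.

    Six patterns: a bound patient barcode star-joined with ``tcga:result``,
    whose record star asks chromosome/start/stop/seq_mean. Returns the query
    text and the patient used (preferring a patient with the given TSS).
    """
    patient = next((p for p in fixture.patients if p.tss == tss),
                   fixture.patients[0])
    pro = _PROLOGUE.format(vocab=fixture.index.vocab_ns)
    text = pro + f"""SELECT ?chr ?start ?stop ?mean WHERE {{
  ?p tcga:bcr_patient_barcode "{patient.barcode}" .
  ?p tcga:result ?r .
  ?r tcga:chromosome ?chr .
  ?r tcga:start ?start .
  ?r tcga:stop ?stop .
  ?r tcga:seq_mean ?mean .
}}"""
    return text, patient
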