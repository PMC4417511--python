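"""Core domain vocabulary shared across the package.

The data model mirrors how TCGA level-3 results are published as Linked
Data: every patient is identified by a barcode ``TCGA-<TSS>-<PatientNo>``
(TSS = tissue source site, mappable to a tumour type), and every per-record
result resource is minted under a common namespace as
``<namespace><barcode>-<code><ordinal>`` where the single-character code
names the result kind ('d' = DNA methylation, 'e' = exon expression, ...).

Result kinds are routed to one of three colour categories used for endpoint
load balancing: green holds DNA methylation, pink holds exon expression and
blue holds everything else.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field
from typing import Optional

from rdflib import Literal, URIRef, Variable
from rdflib.namespace import RDF, XSD

#: Default namespace under which patient and result resources are minted.
DATA_NS = "http://tcga.deri.ie/"
#: Default namespace of the tcga vocabulary (predicates and classes).
VOCAB_NS = "http://tcga.deri.ie/schema/"


class ModelError(ValueError):
    """Malformed barcode, URI or term."""


# ---------------------------------------------------------------------------
# RDF terms and query algebra
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Term:
    """A SPARQL term: IRI, literal or variable.

    ``kind`` is one of ``"iri"``, ``"literal"``, ``"variable"``. Literals may
    carry an optional datatype IRI.
    """

    kind: str
    value: str
    datatype: Optional[str] = None

    def __post_init__(self) -> None:
        if self.kind not in ("iri", "literal", "variable"):
            raise ModelError(f"unknown term kind: {self.kind!r}")
        if self.kind == "variable" and not self.value:
            raise ModelError("variable names must be non-empty")
        if self.kind == "iri" and "://" not in self.value:
            raise ModelError(f"IRIs must be absolute: {self.value!r}")

    # -- constructors -------------------------------------------------
    @staticmethod
    def iri(value: str) -> "Term":
        return Term("iri", value)

    @staticmethod
    def literal(value: str, datatype: Optional[str] = None) -> "Term":
        return Term("literal", value, datatype)

    @staticmethod
    def variable(name: str) -> "Term":
        return Term("variable", name.lstrip("?"))

    # -- predicates ---------------------------------------------------
    @property
    def is_bound(self) -> bool:
        return self.kind != "variable"

    # -- conversions --------------------------------------------------
    def to_rdflib(self):
        if self.kind == "iri":
            return URIRef(self.value)
        if self.kind == "variable":
            return Variable(self.value)
        if self.datatype:
            return Literal(self.value, datatype=URIRef(self.datatype))
        return Literal(self.value)

    @staticmethod
    def from_rdflib(node) -> "Term":
        if isinstance(node, URIRef):
            return Term.iri(str(node))
        if isinstance(node, Variable):
            return Term.variable(str(node))
        if isinstance(node, Literal):
            dt = str(node.datatype) if node.datatype else None
            return Term("literal", str(node), dt)
        raise ModelError(f"cannot convert {node!r} to a Term")

    def sparql(self) -> str:
        """Serialize as a SPARQL token."""
        if self.kind == "variable":
            return f"?{self.value}"
        return self.to_rdflib().n3()


@dataclass(frozen=True)
class TriplePattern:
    """One subject/predicate/object template inside a basic graph pattern."""

    subject: Term
    predicate: Term
    object: Term
    index: int = 0

    def __post_init__(self) -> None:
        if self.subject.kind == "literal":
            raise ModelError("triple pattern subjects cannot be literals")
        if self.predicate.kind == "literal":
            raise ModelError("triple pattern predicates cannot be literals")

    def variables(self) -> set[str]:
        return {t.value for t in (self.subject, self.predicate, self.object)
                if t.kind == "variable"}

    def sparql(self) -> str:
        return (f"{self.subject.sparql()} {self.predicate.sparql()} "
                f"{self.object.sparql()} .")


@dataclass(frozen=True)
class FilterExpr:
    """An opaque FILTER expression, passed through verbatim."""

    text: str

    def variables(self) -> set[str]:
        return set(re.findall(r"[?$](\w+)", self.text))

    def sparql(self) -> str:
        return f"FILTER({self.text})"


@dataclass
class BasicGraphPattern:
    """An ordered conjunction of triple patterns plus attached FILTERs."""

    patterns: list[TriplePattern] = field(default_factory=list)
    filters: list[FilterExpr] = field(default_factory=list)

    def __post_init__(self) -> None:
        indices = [tp.index for tp in self.patterns]
        if indices != list(range(len(self.patterns))):
            raise ModelError("pattern indices must be 0..n-1 in order")

    def variables(self) -> set[str]:
        out: set[str] = set()
        for tp in self.patterns:
            out |= tp.variables()
        return out

    def __len__(self) -> int:
        return len(self.patterns)


def bgp_from_triples(triples, filters=()) -> BasicGraphPattern:
    """Build a BGP from (s, p, o) Term triples, assigning indices in order."""
    patterns = [TriplePattern(s, p, o, index=i)
                for i, (s, p, o) in enumerate(triples)]
    return BasicGraphPattern(patterns, [
        f if isinstance(f, FilterExpr) else FilterExpr(f) for f in filters])


# ---------------------------------------------------------------------------
# Patient barcodes and result URIs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PatientBarcode:
    """``TCGA-<TSS>-<PatientNo>``; TSS codes are opaque strings."""

    tss: str
    patient: str
    project: str = "TCGA"

    def __post_init__(self) -> None:
        if not self.tss or not self.patient:
            raise ModelError("TSS and patient number must be non-empty")

    def __str__(self) -> str:
        return f"{self.project}-{self.tss}-{self.patient}"


def parse_patient_barcode(s: str) -> PatientBarcode:
    """Parse a strict three-field patient barcode.

    >>> parse_patient_barcode("TCGA-18-3406")
    PatientBarcode(tss='18', patient='3406', project='TCGA')
    """
    parts = s.split("-")
    if len(parts) != 3:
        raise ModelError(f"not a patient barcode (need 3 fields): {s!r}")
    project, tss, patient = parts
    if project != "TCGA":
        raise ModelError(f"unexpected project prefix in barcode: {s!r}")
    if not tss or not patient:
        raise ModelError(f"empty field in barcode: {s!r}")
    return PatientBarcode(tss=tss, patient=patient)


def extract_tss(barcode: str) -> str:
    """Lenient TSS extraction, tolerating sample-level suffixes.

    File-to-sample maps carry barcodes like ``TCGA-18-3406-01A``; only the
    project prefix and a non-empty TSS field are required here.
    """
    parts = barcode.strip().split("-")
    if len(parts) < 3 or parts[0] != "TCGA" or not parts[1]:
        raise ModelError(f"cannot extract TSS from {barcode!r}")
    return parts[1]


class Colour(enum.Enum):
    """Endpoint colour category."""

    BLUE = "blue"
    PINK = "pink"
    GREEN = "green"

    def __str__(self) -> str:  # spec files and reports use the bare word
        return self.value


def colour_of_result_type(code: str) -> Colour:
    """Map a result-type code character to its colour category.

    'e' (exon expression) is pink, 'd' (DNA methylation) is green and every
    other code is blue. Total on single characters.
    """
    if len(code) != 1:
        raise ModelError(f"result-type codes are single characters: {code!r}")
    if code == "e":
        return Colour.PINK
    if code == "d":
        return Colour.GREEN
    return Colour.BLUE


@dataclass(frozen=True)
class ResultRef:
    """A parsed result URI: patient barcode + result-type code + ordinal."""

    barcode: PatientBarcode
    code: str
    ordinal: int

    @property
    def colour(self) -> Colour:
        return colour_of_result_type(self.code)


_RESULT_TYPE_RE = re.compile(r"^([a-z])([1-9]\d*)$")


def parse_result_uri(uri: str, namespace: str = DATA_NS) -> ResultRef:
    """Parse ``<namespace>TCGA-<TSS>-<No>-<code><ordinal>``.

    >>> parse_result_uri("http://tcga.deri.ie/TCGA-A2-A0CX-d1").code
    'd'
    """
    if not uri.startswith(namespace):
        raise ModelError(f"URI outside namespace {namespace!r}: {uri!r}")
    local = uri[len(namespace):]
    parts = local.split("-")
    if len(parts) != 4:
        raise ModelError(f"not a result URI: {uri!r}")
    barcode = parse_patient_barcode("-".join(parts[:3]))
    m = _RESULT_TYPE_RE.match(parts[3])
    if not m:
        raise ModelError(f"malformed result-type segment in {uri!r}")
    return ResultRef(barcode=barcode, code=m.group(1), ordinal=int(m.group(2)))


def patient_uri(barcode: PatientBarcode, namespace: str = DATA_NS) -> URIRef:
    return URIRef(namespace + str(barcode))


def clinical_uri(barcode: PatientBarcode, namespace: str = DATA_NS) -> URIRef:
    return URIRef(f"{namespace}{barcode}-clinical")


# ---------------------------------------------------------------------------
# Result-kind registry and vocabulary
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ResultKind:
    """A level-3 result kind: its code character, RDF class and fields."""

    name: str
    code: str
    class_name: str
    fields: tuple[str, ...]

    @property
    def colour(self) -> Colour:
        return colour_of_result_type(self.code)


#: Default analysis-relevant fields per result kind. The upstream field
#: lists are site configuration in real deployments; these defaults carry
#: exactly the fields the benchmark queries touch.
RESULT_KINDS: dict[str, ResultKind] = {k.name: k for k in [
    ResultKind("dna-methylation", "d", "DnaMethylationResult",
               ("chromosome", "position", "beta_value")),
    ResultKind("exon-expression", "e", "ExonExpressionResult",
               ("chromosome", "start", "stop", "RPKM")),
    ResultKind("copy-number", "c", "CopyNumberResult",
               ("chromosome", "start", "stop", "seq_mean")),
    ResultKind("gene-expression", "g", "GeneExpressionResult",
               ("chromosome", "scaled_estimate")),
    ResultKind("mirna", "m", "MirnaResult",
               ("chromosome", "start", "stop", "miRNA_value")),
    ResultKind("protein-expression", "p", "ProteinExpressionResult",
               ("chromosome", "protein_expression_value")),
]}

KIND_BY_CODE: dict[str, ResultKind] = {k.code: k for k in RESULT_KINDS.values()}

#: Clinical records are layer-2 data: a patient-linked node with
#: string-literal properties, not a result kind.
CLINICAL_KIND = "clinical"
CLINICAL_FIELDS = ("drug", "follow_up", "radiation")

INTEGER_FIELDS = frozenset({"position", "start", "stop"})
DECIMAL_FIELDS = frozenset({"beta_value", "seq_mean", "RPKM",
                            "scaled_estimate", "miRNA_value",
                            "protein_expression_value"})


def vocab(name: str, vocab_ns: str = VOCAB_NS) -> URIRef:
    return URIRef(vocab_ns + name)


def field_literal(fname: str, value: str) -> Literal:
    """Type a field value the way the RDFizer and queries both expect."""
    if fname in INTEGER_FIELDS:
        return Literal(value, datatype=XSD.integer)
    if fname in DECIMAL_FIELDS:
        return Literal(value, datatype=XSD.decimal)
    return Literal(value)


RDF_TYPE = RDF.type
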