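"""Refine level-3 result tables and convert them to N3 triples.

The conversion runs in two stages. The *refiner* selects the
analysis-relevant columns out of a raw tab-delimited result file — either
directly or through an annotation-table lookup (e.g. chromosome/position by
probe name) — and drops every row in which a selected field carries a
missing-value token. The *RDFizer* then mints one result resource per
surviving row under the data namespace and attaches one typed literal per
selected field, plus the linkage triples that tie the resource to its
patient.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional

from rdflib import Graph, Literal, URIRef

from .model import (
    CLINICAL_FIELDS,
    CLINICAL_KIND,
    DATA_NS,
    RESULT_KINDS,
    VOCAB_NS,
    ModelError,
    PatientBarcode,
    RDF_TYPE,
    clinical_uri,
    field_literal,
    patient_uri,
    vocab,
)

log = logging.getLogger(__name__)

#: Case-insensitive tokens treated as missing values during refinement.
MISSING_TOKENS = frozenset({"na", "null", "unknown", "not reported", ""})


class ConfigurationError(KeyError):
    """A result kind without a field mapping."""


def is_missing(value: str) -> bool:
    return value.strip().lower() in MISSING_TOKENS


# ---------------------------------------------------------------------------
# Tables and field maps
# ---------------------------------------------------------------------------

@dataclass
class RawTable:
    """A parsed level-3 TSV: header names plus string rows."""

    result_kind: str
    columns: list[str]
    rows: list[tuple[str, ...]]

    def __post_init__(self) -> None:
        for row in self.rows:
            if len(row) != len(self.columns):
                raise ValueError(
                    f"row width {len(row)} != header width {len(self.columns)}")

    @classmethod
    def from_tsv(cls, text: str, result_kind: str) -> "RawTable":
        lines = [ln for ln in text.splitlines() if ln != ""]
        if not lines:
            raise ValueError("empty table")
        header = lines[0].split("\t")
        rows = [tuple(ln.split("\t")) for ln in lines[1:]]
        return cls(result_kind, header, rows)

    def to_tsv(self) -> str:
        out = ["\t".join(self.columns)]
        out += ["\t".join(r) for r in self.rows]
        return "\n".join(out) + "\n"


@dataclass(frozen=True)
class FieldRule:
    """How one output field is obtained.

    Either ``column`` names a raw column directly, or ``lookup_key_column``
    + ``annotation_column`` resolve the value from an annotation table keyed
    by the raw key column (methylation annotation files map probe names to
    chromosome and position).
    """

    output: str
    column: Optional[str] = None
    lookup_key_column: Optional[str] = None
    annotation_column: Optional[str] = None

    def __post_init__(self) -> None:
        direct = self.column is not None
        lookup = (self.lookup_key_column is not None
                  and self.annotation_column is not None)
        if direct == lookup:
            raise ValueError(
                f"field {self.output!r} must use exactly one of "
                "column / annotation lookup")


@dataclass
class FieldMap:
    """Per-result-kind field selection rules."""

    rules: dict[str, list[FieldRule]] = field(default_factory=dict)

    def fields_for(self, result_kind: str) -> list[str]:
        return [r.output for r in self.rules_for(result_kind)]

    def rules_for(self, result_kind: str) -> list[FieldRule]:
        try:
            return self.rules[result_kind]
        except KeyError:
            raise ConfigurationError(
                f"no field mapping for result kind {result_kind!r}") from None


def default_field_map() -> FieldMap:
    """Direct-column mapping for every registered result kind + clinical."""
    rules = {name: [FieldRule(f, column=f) for f in kind.fields]
             for name, kind in RESULT_KINDS.items()}
    rules[CLINICAL_KIND] = [FieldRule(f, column=f) for f in CLINICAL_FIELDS]
    return FieldMap(rules)


@dataclass
class AnnotationTable:
    """An annotation TSV keyed by its first column (e.g. probe name)."""

    key_column: str
    columns: list[str]
    by_key: dict[str, dict[str, str]]

    @classmethod
    def from_tsv(cls, text: str) -> "AnnotationTable":
        lines = [ln for ln in text.splitlines() if ln != ""]
        header = lines[0].split("\t")
        by_key: dict[str, dict[str, str]] = {}
        for ln in lines[1:]:
            cells = ln.split("\t")
            by_key[cells[0]] = dict(zip(header, cells))
        return cls(key_column=header[0], columns=header, by_key=by_key)


@dataclass
class RefinedTable:
    """Selected fields only; no cell holds a missing-value token."""

    result_kind: str
    columns: list[str]
    rows: list[tuple[str, ...]]


# ---------------------------------------------------------------------------
# Refinement
# ---------------------------------------------------------------------------

def refine(raw: RawTable, fmap: FieldMap,
           annotations: Optional[dict[str, AnnotationTable]] = None,
           ) -> RefinedTable:
    """Select the mapped fields and drop rows with missing values.

    A row is dropped entirely if any selected field is a missing-value
    token, or if an annotation lookup misses (logged). Row order is
    preserved.
    """
    rules = fmap.rules_for(raw.result_kind)
    col_index = {c: i for i, c in enumerate(raw.columns)}
    annotations = annotations or {}

    out_rows: list[tuple[str, ...]] = []
    for row in raw.rows:
        values: list[str] = []
        ok = True
        for rule in rules:
            if rule.column is not None:
                try:
                    value = row[col_index[rule.column]]
                except KeyError:
                    raise ConfigurationError(
                        f"column {rule.column!r} absent from "
                        f"{raw.result_kind!r} table") from None
            else:
                key = row[col_index[rule.lookup_key_column]]
                table = annotations.get(raw.result_kind)
                entry = table.by_key.get(key) if table else None
                if entry is None:
                    log.warning("annotation lookup miss for key %r in %s; "
                                "row dropped", key, raw.result_kind)
                    ok = False
                    break
                value = entry[rule.annotation_column]
            if is_missing(value):
                ok = False
                break
            values.append(value)
        if ok:
            out_rows.append(tuple(values))
    return RefinedTable(raw.result_kind, [r.output for r in rules], out_rows)


# ---------------------------------------------------------------------------
# RDFization
# ---------------------------------------------------------------------------

def mint_result_uri(barcode: PatientBarcode, code: str, ordinal: int,
                    namespace: str = DATA_NS) -> URIRef:
    """``<namespace><barcode>-<code><ordinal>``; injective over its inputs."""
    if len(code) != 1 or not code.isalpha():
        raise ModelError(f"result-type codes are single letters: {code!r}")
    if ordinal < 1:
        raise ValueError(f"ordinals start at 1, got {ordinal}")
    return URIRef(f"{namespace}{barcode}-{code}{ordinal}")


@dataclass
class TripleDump:
    """A set of RDF triples with deterministic N3 serialization."""

    triples: set = field(default_factory=set)

    def add(self, s, p, o) -> None:
        self.triples.add((s, p, o))

    def __len__(self) -> int:
        return len(self.triples)

    def __or__(self, other: "TripleDump") -> "TripleDump":
        return TripleDump(self.triples | other.triples)

    def to_graph(self) -> Graph:
        g = Graph()
        for t in self.triples:
            g.add(t)
        return g

    def to_n3(self, data_ns: str = DATA_NS, vocab_ns: str = VOCAB_NS) -> str:
        """Serialize deterministically: sorted triples, tcga: prefix bound."""
        lines = [f"@prefix tcga: <{vocab_ns}> ."]

        def token(node) -> str:
            if isinstance(node, URIRef):
                s = str(node)
                if s == str(RDF_TYPE):
                    return "a"
                if s.startswith(vocab_ns):
                    return "tcga:" + s[len(vocab_ns):]
                return f"<{s}>"
            return node.n3()

        for s, p, o in sorted(self.triples,
                              key=lambda t: (str(t[0]), str(t[1]), t[2].n3())):
            lines.append(f"{token(s)} {token(p)} {token(o)} .")
        return "\n".join(lines) + "\n"

    @classmethod
    def from_n3(cls, text: str) -> "TripleDump":
        g = Graph()
        g.parse(data=text, format="n3")
        return cls(set(g))


def rdfize(refined: RefinedTable, barcode: PatientBarcode,
           namespace: str = DATA_NS, vocab_ns: str = VOCAB_NS) -> TripleDump:
    """Convert a refined table into triples under the three-layer schema.

    Emits the patient node (type + barcode literal), then per row ``i`` a
    result node ``mint_result_uri(barcode, code, i)`` carrying one typed
    literal per selected field plus the ``tcga:result`` linkage triple.
    Clinical tables instead populate the patient-linked clinical node.
    """
    dump = TripleDump()
    p_uri = patient_uri(barcode, namespace)
    dump.add(p_uri, RDF_TYPE, vocab("Patient", vocab_ns))
    dump.add(p_uri, vocab("bcr_patient_barcode", vocab_ns),
             Literal(str(barcode)))

    if refined.result_kind == CLINICAL_KIND:
        c_uri = clinical_uri(barcode, namespace)
        for row in refined.rows:
            dump.add(p_uri, vocab("clinical", vocab_ns), c_uri)
            dump.add(c_uri, RDF_TYPE, vocab("ClinicalRecord", vocab_ns))
            for fname, value in zip(refined.columns, row):
                dump.add(c_uri, vocab(fname, vocab_ns), Literal(value))
        return dump

    kind = RESULT_KINDS.get(refined.result_kind)
    if kind is None:
        raise ConfigurationError(
            f"unknown result kind {refined.result_kind!r}")
    for i, row in enumerate(refined.rows, start=1):
        node = mint_result_uri(barcode, kind.code, i, namespace)
        dump.add(p_uri, vocab("result", vocab_ns), node)
        dump.add(node, RDF_TYPE, vocab(kind.class_name, vocab_ns))
        for fname, value in zip(refined.columns, row):
            dump.add(node, vocab(fname, vocab_ns), field_literal(fname, value))
    return dump


def write_n3(dump: TripleDump, sink) -> None:
    """Write a dump to a path or file-like object."""
    text = dump.to_n3()
    if hasattr(sink, "write"):
        sink.write(text)
    else:
        with open(sink, "w") as fh:
            fh.write(text)


def read_n3(source) -> TripleDump:
    """Read N3 from a path, file-like object or text."""
    if hasattr(source, "read"):
        return TripleDump.from_n3(source.read())
    text = str(source)
    if "\n" not in text and text.endswith((".n3", ".ttl", ".nt")):
        with open(text) as fh:
            return TripleDump.from_n3(fh.read())
    return TripleDump.from_n3(text)


def rdfize_raw(raw: RawTable, barcode: PatientBarcode,
               fmap: Optional[FieldMap] = None,
               annotations=None, namespace: str = DATA_NS,
               vocab_ns: str = VOCAB_NS) -> TripleDump:
    """Convenience: refine then rdfize in one call."""
    fmap = fmap or default_field_map()
    return rdfize(refine(raw, fmap, annotations), barcode, namespace, vocab_ns)
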