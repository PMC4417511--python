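"""Colour-category data distribution across SPARQL endpoints.

Each tumour's data is split into three colour categories — green (DNA
methylation), pink (exon expression), blue (everything else) — and each
colour's endpoints receive contiguous tumour ranges so that every tumour is
stored at exactly one endpoint per colour. Patient and clinical triples are
replicated to the matching-tumour endpoint of every colour; result triples
live only at the endpoint matching their colour and tumour.

The index that drives federated source selection consists of an N3
specification file (endpoint URL, colour, tumour list per endpoint, plus
the predicate/class sets) and a TSS-to-tumour hash table built from
File_Sample_Map-style TSVs.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field
from typing import Iterable, Optional

from rdflib import Graph, Literal, URIRef

from .model import (
    DATA_NS,
    VOCAB_NS,
    Colour,
    ModelError,
    RDF_TYPE,
    extract_tss,
    parse_result_uri,
    vocab,
)
from .rdfizer import TripleDump

#: Vocabulary of the specification file itself.
SPEC_NS = "http://tcgafed.example.org/spec#"


class ValidationError(ValueError):
    """A specification index violating its invariants."""


class RoutingError(ValueError):
    """A triple that cannot be assigned to any endpoint."""


# ---------------------------------------------------------------------------
# Index data model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EndpointDescriptor:
    url: str
    colour: Colour
    tumours: frozenset[str]
    order: int

    def __post_init__(self) -> None:
        if not self.tumours:
            raise ValidationError(f"endpoint {self.url} stores no tumours")


@dataclass(frozen=True)
class PredicateSets:
    """Predicate/class sets driving the colour conditions.

    D/C: predicates/classes unique to blue; M/B: unique to green
    (methylation); F/E: unique to pink (exon expression); A/G: shared
    across categories.
    """

    D: frozenset
    C: frozenset
    B: frozenset
    M: frozenset
    F: frozenset
    E: frozenset
    A: frozenset
    G: frozenset

    def __post_init__(self) -> None:
        uniques = [("D", self.D), ("M", self.M), ("F", self.F),
                   ("C", self.C), ("B", self.B), ("E", self.E)]
        for i, (n1, s1) in enumerate(uniques):
            for n2, s2 in uniques[i + 1:]:
                if s1 & s2:
                    raise ValidationError(f"sets {n1} and {n2} overlap")
        shared = self.A | self.G
        for name, s in uniques:
            if shared & s:
                raise ValidationError(f"shared sets overlap unique set {name}")

    def predicates_for(self, colour: Colour) -> frozenset:
        return {Colour.BLUE: self.D, Colour.PINK: self.F,
                Colour.GREEN: self.M}[colour]

    def classes_for(self, colour: Colour) -> frozenset:
        return {Colour.BLUE: self.C, Colour.PINK: self.E,
                Colour.GREEN: self.B}[colour]

    @staticmethod
    def default(vocab_ns: str = VOCAB_NS) -> "PredicateSets":
        v = lambda n: vocab(n, vocab_ns)
        return PredicateSets(
            D=frozenset({v("seq_mean"), v("scaled_estimate"),
                         v("protein_expression_value"), v("miRNA_value"),
                         v("clinical"), v("drug"), v("follow_up"),
                         v("radiation")}),
            C=frozenset({v("CopyNumberResult"), v("GeneExpressionResult"),
                         v("MirnaResult"), v("ProteinExpressionResult"),
                         v("ClinicalRecord")}),
            M=frozenset({v("beta_value"), v("position")}),
            B=frozenset({v("DnaMethylationResult")}),
            F=frozenset({v("RPKM")}),
            E=frozenset({v("ExonExpressionResult")}),
            A=frozenset({v("chromosome"), v("start"), v("stop")}),
            G=frozenset({v("result"), v("bcr_patient_barcode")}),
        )


@dataclass
class SpecificationIndex:
    """Endpoint descriptors + predicate sets: the federation's index."""

    endpoints: list[EndpointDescriptor]
    sets: PredicateSets
    data_ns: str = DATA_NS
    vocab_ns: str = VOCAB_NS

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        urls = [e.url for e in self.endpoints]
        if len(set(urls)) != len(urls):
            raise ValidationError("endpoint URLs must be unique")
        for colour in Colour:
            seen: dict[str, str] = {}
            for ep in self.by_colour(colour):
                for t in ep.tumours:
                    if t in seen:
                        raise ValidationError(
                            f"tumour {t} stored at two {colour} endpoints: "
                            f"{seen[t]} and {ep.url}")
                    seen[t] = ep.url

    def by_colour(self, colour: Colour) -> list[EndpointDescriptor]:
        return [e for e in self.endpoints if e.colour is colour]

    def endpoint_for(self, colour: Colour,
                     tumour: str) -> Optional[EndpointDescriptor]:
        for ep in self.by_colour(colour):
            if tumour in ep.tumours:
                return ep
        return None

    def tumours(self) -> set[str]:
        out: set[str] = set()
        for ep in self.endpoints:
            out |= ep.tumours
        return out

    def __len__(self) -> int:
        return len(self.endpoints)


@dataclass
class TSSTumourTable:
    """Hash table from tissue-source-site code to tumour identifier."""

    mapping: dict[str, str] = field(default_factory=dict)

    def lookup(self, tss: str) -> Optional[str]:
        return self.mapping.get(tss)

    def add(self, tss: str, tumour: str) -> None:
        existing = self.mapping.get(tss)
        if existing is not None and existing != tumour:
            raise ValidationError(
                f"TSS {tss!r} mapped to both {existing!r} and {tumour!r}")
        self.mapping[tss] = tumour

    def __len__(self) -> int:
        return len(self.mapping)


# ---------------------------------------------------------------------------
# Tumour assignment
# ---------------------------------------------------------------------------

def _contiguous_split(items: list[str], k: int) -> list[list[str]]:
    """Balanced contiguous ranges; the first n%k endpoints take the extra
    item (the first six green endpoints hold four tumours, the last three
    hold three, in the 33-tumour/9-endpoint layout)."""
    n = len(items)
    base, extra = divmod(n, k)
    out, pos = [], 0
    for i in range(k):
        size = base + (1 if i < extra else 0)
        out.append(items[pos:pos + size])
        pos += size
    return out


def assign_tumours(n_tumours: int, layout: dict, tumour_names=None,
                   url_template: str = "memory://{colour}{i}",
                   sets: Optional[PredicateSets] = None,
                   data_ns: str = DATA_NS,
                   vocab_ns: str = VOCAB_NS) -> SpecificationIndex:
    """Build a specification index skeleton from per-colour endpoint counts.

    ``layout`` maps colour (Colour or its name) to an endpoint count. Every
    colour receives all tumours, split into balanced contiguous ranges.
    """
    layout = {c if isinstance(c, Colour) else Colour(c): k
              for c, k in layout.items()}
    for colour, k in layout.items():
        if k < 1:
            raise ValidationError(f"{colour} needs at least one endpoint")
        if n_tumours < k:
            raise ValidationError(
                f"{n_tumours} tumours cannot cover {k} {colour} endpoints")
    if tumour_names is None:
        tumour_names = [f"T{i:02d}" for i in range(1, n_tumours + 1)]
    if len(tumour_names) != n_tumours:
        raise ValidationError("tumour_names length must equal n_tumours")

    endpoints: list[EndpointDescriptor] = []
    order = 0
    for colour in (Colour.BLUE, Colour.PINK, Colour.GREEN):
        k = layout.get(colour, 0)
        if k == 0:
            raise ValidationError(f"layout missing colour {colour}")
        for i, chunk in enumerate(_contiguous_split(list(tumour_names), k),
                                  start=1):
            endpoints.append(EndpointDescriptor(
                url=url_template.format(colour=colour.value, i=i),
                colour=colour, tumours=frozenset(chunk), order=order))
            order += 1
    return SpecificationIndex(endpoints, sets or PredicateSets.default(vocab_ns),
                              data_ns=data_ns, vocab_ns=vocab_ns)


# ---------------------------------------------------------------------------
# Partitioning
# ---------------------------------------------------------------------------

def _route_patient_subject(uri: str, data_ns: str):
    """Barcode of a patient or clinical node URI, else None."""
    if not uri.startswith(data_ns):
        return None
    local = uri[len(data_ns):]
    if local.endswith("-clinical"):
        local = local[:-len("-clinical")]
    parts = local.split("-")
    if len(parts) == 3 and parts[0] == "TCGA" and all(parts):
        return local
    return None


def partition(dumps, index: SpecificationIndex,
              tss_table: TSSTumourTable) -> dict[str, TripleDump]:
    """Route every triple of the input dump(s) to its endpoint(s).

    Result triples (and the patient→result linkage of each result node) go
    to the unique endpoint matching the node's colour and tumour. Patient
    and clinical triples are replicated to the matching-tumour endpoint of
    every colour, so that each patient can be found at exactly one endpoint
    per colour.
    """
    if isinstance(dumps, TripleDump):
        dumps = [dumps]
    out: dict[str, TripleDump] = {e.url: TripleDump() for e in index.endpoints}
    result_pred = vocab("result", index.vocab_ns)

    def tumour_of(barcode_str: str) -> str:
        tss = extract_tss(barcode_str)
        tumour = tss_table.lookup(tss)
        if tumour is None:
            raise RoutingError(
                f"TSS of barcode {barcode_str!r} not in the TSS table")
        return tumour

    def route_result(uri: str) -> EndpointDescriptor:
        ref = parse_result_uri(uri, index.data_ns)
        tumour = tumour_of(str(ref.barcode))
        ep = index.endpoint_for(ref.colour, tumour)
        if ep is None:
            raise RoutingError(
                f"no {ref.colour} endpoint stores tumour {tumour!r}")
        return ep

    for dump in dumps:
        for s, p, o in dump.triples:
            s_str, o_str = str(s), str(o)
            try:
                parse_result_uri(s_str, index.data_ns)
                is_result_subject = True
            except ModelError:
                is_result_subject = False

            if is_result_subject:
                out[route_result(s_str).url].add(s, p, o)
            elif p == result_pred and isinstance(o, URIRef):
                # linkage triple: lives with its result node
                out[route_result(o_str).url].add(s, p, o)
            else:
                barcode = _route_patient_subject(s_str, index.data_ns)
                if barcode is None:
                    raise RoutingError(f"unroutable subject {s_str!r}")
                tumour = tumour_of(barcode)
                for colour in Colour:
                    ep = index.endpoint_for(colour, tumour)
                    if ep is None:
                        raise RoutingError(
                            f"no {colour} endpoint stores tumour {tumour!r}")
                    out[ep.url].add(s, p, o)
    return out


# ---------------------------------------------------------------------------
# Specification file I/O
# ---------------------------------------------------------------------------

_SET_NAMES = ("D", "C", "B", "M", "F", "E", "A", "G")


def write_spec_file(index: SpecificationIndex, sink=None) -> str:
    """Serialize the index as deterministic N3; optionally write to sink."""
    fed = lambda n: URIRef(SPEC_NS + n)
    dump = TripleDump()
    cfg = fed("config")
    dump.add(cfg, fed("dataNamespace"), Literal(index.data_ns))
    dump.add(cfg, fed("vocabNamespace"), Literal(index.vocab_ns))
    for ep in index.endpoints:
        node = URIRef(ep.url)
        dump.add(node, RDF_TYPE, fed("Endpoint"))
        dump.add(node, fed("hasColour"), Literal(ep.colour.value))
        dump.add(node, fed("order"), Literal(ep.order))
        for t in ep.tumours:
            dump.add(node, fed("storesTumour"), Literal(t))
    sets_node = fed("sets")
    for name in _SET_NAMES:
        for member in getattr(index.sets, name):
            dump.add(sets_node, fed("set" + name), member)

    lines = [f"@prefix fed: <{SPEC_NS}> ."]
    for s, p, o in sorted(dump.triples,
                          key=lambda t: (str(t[0]), str(t[1]), t[2].n3())):
        def tok(n):
            if isinstance(n, URIRef):
                s_ = str(n)
                if s_ == str(RDF_TYPE):
                    return "a"
                if s_.startswith(SPEC_NS):
                    return "fed:" + s_[len(SPEC_NS):]
                return f"<{s_}>"
            return n.n3()
        lines.append(f"{tok(s)} {tok(p)} {tok(o)} .")
    text = "\n".join(lines) + "\n"
    if sink is not None:
        if hasattr(sink, "write"):
            sink.write(text)
        else:
            with open(sink, "w") as fh:
                fh.write(text)
    return text


def load_spec_file(source) -> SpecificationIndex:
    """Parse and validate a specification file (path, file object or text)."""
    if hasattr(source, "read"):
        text = source.read()
    else:
        text = str(source)
        if "\n" not in text and text.endswith((".n3", ".ttl")):
            with open(text) as fh:
                text = fh.read()
    g = Graph()
    g.parse(data=text, format="n3")
    fed = lambda n: URIRef(SPEC_NS + n)

    data_ns = str(next(g.objects(fed("config"), fed("dataNamespace")),
                       Literal(DATA_NS)))
    vocab_ns = str(next(g.objects(fed("config"), fed("vocabNamespace")),
                        Literal(VOCAB_NS)))

    endpoints = []
    for node in g.subjects(RDF_TYPE, fed("Endpoint")):
        url = str(node)
        colour = next(g.objects(node, fed("hasColour")), None)
        order = next(g.objects(node, fed("order")), None)
        tumours = frozenset(str(t) for t in g.objects(node, fed("storesTumour")))
        if colour is None or order is None:
            raise ValidationError(f"endpoint {url} missing colour or order")
        if not tumours:
            raise ValidationError(f"endpoint {url} lists no tumours")
        try:
            col = Colour(str(colour))
        except ValueError:
            raise ValidationError(
                f"endpoint {url} has unknown colour {colour!s}") from None
        endpoints.append(EndpointDescriptor(url, col, tumours, int(order)))
    endpoints.sort(key=lambda e: e.order)

    kwargs = {}
    for name in _SET_NAMES:
        kwargs[name] = frozenset(g.objects(fed("sets"), fed("set" + name)))
    sets = PredicateSets(**kwargs)
    return SpecificationIndex(endpoints, sets, data_ns=data_ns,
                              vocab_ns=vocab_ns)


# ---------------------------------------------------------------------------
# TSS-to-tumour table
# ---------------------------------------------------------------------------

def build_tss_table(file_sample_map) -> TSSTumourTable:
    """Build the TSS→tumour table from a File_Sample_Map-style TSV.

    Accepts a path, file-like object or TSV text with a header naming a
    barcode column and a tumour column (a filename column may precede
    them). The TSS is extracted from each barcode; a TSS mapped to two
    different tumours is a conflict error.
    """
    if hasattr(file_sample_map, "read"):
        text = file_sample_map.read()
    else:
        text = str(file_sample_map)
        if "\n" not in text and text.endswith((".tsv", ".txt")):
            with open(text) as fh:
                text = fh.read()
    table = TSSTumourTable()
    reader = csv.DictReader(io.StringIO(text), delimiter="\t")
    if reader.fieldnames is None:
        return table
    barcode_col = next((c for c in reader.fieldnames
                        if "barcode" in c.lower()), None)
    tumour_col = next((c for c in reader.fieldnames
                       if "tumour" in c.lower() or "tumor" in c.lower()), None)
    if barcode_col is None or tumour_col is None:
        raise ValidationError(
            f"File_Sample_Map needs barcode and tumour columns, "
            f"got {reader.fieldnames}")
    for row in reader:
        table.add(extract_tss(row[barcode_col]), row[tumour_col])
    return table
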