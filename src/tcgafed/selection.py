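"""Join-aware triple-pattern-wise source selection, plus the ASK baseline.

For each triple pattern of a basic graph pattern the selector tries to
derive the colour category and tumour of the data that can contribute to
the *joined* query answer, using only the specification index and the
TSS-to-tumour table — no endpoint is contacted unless a pattern binds only
its object.

Colour derivation is driven by three conditions, one per category. For
blue: the pattern's predicate must be a member of D ∪ A ∪ G (or be
``rdf:type`` with an object class in C), and the pattern must either
star/path-join with a pattern whose predicate (or type class) is unique to
blue, or not join with anything unique to another colour. Pink and green
substitute their own unique sets. Conditions are evaluated independently
and the selected colour categories are unioned; if none holds, the blue
category is queried (unlisted predicates default there). A known tumour
then narrows each colour to its single matching endpoint.

Join context: a pattern sees its star group (patterns sharing its subject)
and the patterns path-joined from that group (whose subject is the object
of a group member). This is what lets a patient-barcode pattern inherit the
colour of the record star it feeds.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Callable, Optional

from rdflib import URIRef

from .distribution import (
    EndpointDescriptor,
    PredicateSets,
    SpecificationIndex,
    TSSTumourTable,
)
from .model import (
    BasicGraphPattern,
    Colour,
    ModelError,
    RDF_TYPE,
    Term,
    TriplePattern,
    colour_of_result_type,
    parse_patient_barcode,
    parse_result_uri,
    vocab,
)

log = logging.getLogger(__name__)

#: ``ask(url, query_text) -> bool`` — transport hook for ASK probing.
AskFn = Callable[[str, str], bool]


class SelectionError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Join graph
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class JoinGraph:
    """Star pairs (unordered, shared subject) and path pairs (ordered,
    object of the first is subject of the second)."""

    star_pairs: frozenset[frozenset[int]]
    path_pairs: frozenset[tuple[int, int]]

    def star_partners(self, i: int) -> set[int]:
        return {j for pair in self.star_pairs if i in pair
                for j in pair if j != i}

    def reach(self, i: int, bgp: BasicGraphPattern) -> set[int]:
        """Patterns joined with pattern i for colour-condition purposes:
        its star group plus everything path-joined out of that group."""
        group = {i} | self.star_partners(i)
        out = set(group)
        for g in group:
            out |= {j for (a, j) in self.path_pairs if a == g}
        out.discard(i)
        return out


def _joinable(a: Term, b: Term) -> bool:
    """Two positions join via a shared variable or identical bound term."""
    if a.kind == "variable" or b.kind == "variable":
        return a == b
    return a == b


def build_join_graph(bgp: BasicGraphPattern) -> JoinGraph:
    stars = set()
    paths = set()
    for tp1, tp2 in itertools.combinations(bgp.patterns, 2):
        if _joinable(tp1.subject, tp2.subject):
            stars.add(frozenset({tp1.index, tp2.index}))
    for tp1 in bgp.patterns:
        for tp2 in bgp.patterns:
            if tp1.index == tp2.index:
                continue
            if tp1.object.kind != "literal" and \
                    _joinable(tp1.object, tp2.subject):
                paths.add((tp1.index, tp2.index))
    return JoinGraph(frozenset(stars), frozenset(paths))


# ---------------------------------------------------------------------------
# Selection results
# ---------------------------------------------------------------------------

@dataclass
class SourceSelection:
    """Per-pattern endpoint sets m_i plus the triple-pattern-wise count."""

    selections: dict[int, tuple[EndpointDescriptor, ...]]
    total_sources: int

    @property
    def tpws(self) -> int:
        return sum(len(v) for v in self.selections.values())

    def sources(self, i: int) -> tuple[EndpointDescriptor, ...]:
        return self.selections[i]

    def to_report(self) -> dict:
        return {
            "tpws": self.tpws,
            "total_sources": self.total_sources,
            "per_pattern": {str(i): sorted(e.url for e in eps)
                            for i, eps in self.selections.items()},
        }


def tpws_count(sel: SourceSelection) -> int:
    """Triple-pattern-wise source count: sum over patterns of |m_i|."""
    return sel.tpws


@dataclass
class SelectionContext:
    index: SpecificationIndex
    tss_table: TSSTumourTable
    tumour_no: Optional[str] = None


# ---------------------------------------------------------------------------
# Tumour inference
# ---------------------------------------------------------------------------

def infer_tumour_number(bgp: BasicGraphPattern, join_graph: JoinGraph,
                        tss_table: TSSTumourTable,
                        vocab_ns: Optional[str] = None) -> Optional[str]:
    """Tumour from a bound patient barcode star-joined with ``tcga:result``.

    Returns the TSS-table lookup of the barcode's TSS when a pattern with
    predicate ``tcga:bcr_patient_barcode`` and a bound object star-joins a
    pattern with predicate ``tcga:result``; otherwise None.
    """
    barcode_pred = str(vocab("bcr_patient_barcode", vocab_ns)) if vocab_ns \
        else None
    result_pred = str(vocab("result", vocab_ns)) if vocab_ns else None

    def pred_is(tp: TriplePattern, local: str, full: Optional[str]) -> bool:
        if not tp.predicate.is_bound:
            return False
        value = tp.predicate.value
        if full is not None:
            return value == full
        return value.endswith("/" + local) or value.endswith("#" + local)

    for tp in bgp.patterns:
        if not pred_is(tp, "bcr_patient_barcode", barcode_pred):
            continue
        if not tp.object.is_bound:
            continue
        partners = join_graph.star_partners(tp.index)
        if not any(pred_is(bgp.patterns[j], "result", result_pred)
                   for j in partners):
            continue
        try:
            barcode = parse_patient_barcode(tp.object.value)
        except ModelError:
            continue
        tumour = tss_table.lookup(barcode.tss)
        if tumour is None:
            log.warning("TSS %r absent from the TSS table; tumour unknown",
                        barcode.tss)
            return None
        return tumour
    return None


# ---------------------------------------------------------------------------
# Colour conditions
# ---------------------------------------------------------------------------

def _in_set(tp: TriplePattern, members: frozenset) -> bool:
    """Pattern's predicate in a predicate set, or rdf:type into a class
    set (class sets are checked through the object)."""
    if not tp.predicate.is_bound:
        return False
    pred = URIRef(tp.predicate.value)
    if pred == RDF_TYPE:
        return tp.object.is_bound and URIRef(tp.object.value) in members
    return pred in members


def _joins_with(tp: TriplePattern, reach: set[int], bgp: BasicGraphPattern,
                members: frozenset) -> bool:
    return any(_in_set(bgp.patterns[j], members) for j in reach)


def evaluate_colour_condition(tp: TriplePattern, join_graph: JoinGraph,
                              bgp: BasicGraphPattern, sets: PredicateSets,
                              colour: Colour) -> bool:
    """Does the colour's condition hold for this pattern?

    membership: p ∈ unique(colour) ∪ A ∪ G, or p = rdf:type with the object
    class in the colour's class set (an rdf:type pattern with an unbound
    object cannot discriminate and satisfies membership for every colour);
    join clause: the pattern star/path-joins something unique to the
    colour, or joins nothing unique to any other colour.
    """
    pred = URIRef(tp.predicate.value) if tp.predicate.is_bound else None
    own_preds = sets.predicates_for(colour)
    own_classes = sets.classes_for(colour)
    own = own_preds | own_classes

    if pred == RDF_TYPE and not tp.object.is_bound:
        member = True
    else:
        member = (tp.predicate.is_bound and pred in (own_preds | sets.A | sets.G)) \
            or _in_set(tp, own_classes)
    if not member:
        return False

    other: frozenset = frozenset()
    for c in Colour:
        if c is not colour:
            other |= sets.predicates_for(c) | sets.classes_for(c)

    reach = join_graph.reach(tp.index, bgp)
    return (_joins_with(tp, reach, bgp, own)
            or not _joins_with(tp, reach, bgp, other))


# ---------------------------------------------------------------------------
# The selection algorithm
# ---------------------------------------------------------------------------

def _tumour_filter(endpoints: list[EndpointDescriptor],
                   tumour: Optional[str]) -> list[EndpointDescriptor]:
    if tumour is None:
        return endpoints
    return [e for e in endpoints if tumour in e.tumours]


def select_for_bound_subject(tp: TriplePattern, ctx: SelectionContext,
                             ask: Optional[AskFn] = None,
                             ) -> list[EndpointDescriptor]:
    """Selection when the subject is a bound IRI.

    A result URI yields both colour (from the result-type code) and tumour
    (TSS lookup): a single endpoint. A bare patient or clinical URI yields
    one endpoint per colour (patient data is replicated per colour). A
    foreign IRI falls back to ASK probing over all endpoints.
    """
    index = ctx.index
    uri = tp.subject.value
    try:
        ref = parse_result_uri(uri, index.data_ns)
        tumour = ctx.tss_table.lookup(ref.barcode.tss)
        if tumour is not None:
            ep = index.endpoint_for(ref.colour, tumour)
            if ep is not None:
                return [ep]
        log.warning("tumour unknown for %r; probing instead", uri)
    except ModelError:
        barcode = None
        local = uri[len(index.data_ns):] if uri.startswith(index.data_ns) \
            else None
        if local is not None:
            if local.endswith("-clinical"):
                local = local[:-len("-clinical")]
            try:
                barcode = parse_patient_barcode(local)
            except ModelError:
                barcode = None
        if barcode is not None:
            tumour = ctx.tss_table.lookup(barcode.tss)
            if tumour is not None:
                eps = [index.endpoint_for(c, tumour) for c in Colour]
                return [e for e in eps if e is not None]
        log.warning("subject %r not resolvable from the index; probing", uri)
    return _ask_probe(tp, index.endpoints, ask)


def _ask_probe(tp: TriplePattern, endpoints: list[EndpointDescriptor],
               ask: Optional[AskFn]) -> list[EndpointDescriptor]:
    if ask is None:
        return list(endpoints)  # no transport: safe over-approximation
    query = f"ASK {{ {tp.sparql()} }}"
    return [e for e in endpoints if ask(e.url, query)]


def select_sources(bgp: BasicGraphPattern, ctx: SelectionContext,
                   ask: Optional[AskFn] = None) -> SourceSelection:
    """Join-aware source selection for every pattern of a BGP.

    Per pattern: a bound subject resolves directly through the URI scheme; a
    bound predicate goes through the three colour conditions (union of the
    colours whose condition holds, blue if none); a pattern binding only its
    object is ASK-probed; a fully unbound pattern selects every endpoint.
    Condition- and subject-derived selections are then narrowed to the
    known tumour, when one was given or inferred.
    """
    index = ctx.index
    if not index.endpoints:
        raise SelectionError("specification index lists no endpoints")
    jg = build_join_graph(bgp)
    tumour = ctx.tumour_no
    if tumour is None:
        tumour = infer_tumour_number(bgp, jg, ctx.tss_table,
                                     vocab_ns=index.vocab_ns)

    selections: dict[int, tuple[EndpointDescriptor, ...]] = {}
    for tp in bgp.patterns:
        if tp.subject.kind == "iri":
            chosen = select_for_bound_subject(tp, ctx, ask)
            chosen = _tumour_filter(chosen, tumour) or chosen
        elif tp.predicate.is_bound:
            colours = [c for c in Colour
                       if evaluate_colour_condition(tp, jg, bgp, index.sets, c)]
            if not colours:
                colours = [Colour.BLUE]  # unlisted predicates live in blue
            chosen = [e for c in colours for e in index.by_colour(c)]
            chosen = _tumour_filter(chosen, tumour)
        elif tp.object.is_bound:
            chosen = _ask_probe(tp, index.endpoints, ask)
        else:
            chosen = _tumour_filter(list(index.endpoints), tumour)
        chosen = sorted(chosen, key=lambda e: e.order)
        selections[tp.index] = tuple(chosen)
    return SourceSelection(selections, total_sources=len(index.endpoints))


# ---------------------------------------------------------------------------
# ASK-probing baseline
# ---------------------------------------------------------------------------

def _pattern_signature(tp: TriplePattern) -> str:
    """Cache key: the pattern with variables normalized positionally."""
    names: dict[str, str] = {}

    def tok(t: Term) -> str:
        if t.kind != "variable":
            return t.sparql()
        if t.value not in names:
            names[t.value] = f"?v{len(names)}"
        return names[t.value]

    return " ".join(tok(t) for t in (tp.subject, tp.predicate, tp.object))


@dataclass
class AskCache:
    """(pattern signature, endpoint URL) → ASK result."""

    entries: dict[tuple[str, str], bool] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.entries)


def ask_baseline(bgp: BasicGraphPattern, index: SpecificationIndex,
                 ask: AskFn, cache: Optional[AskCache] = None,
                 ) -> tuple[SourceSelection, int]:
    """Probe every (pattern, endpoint) pair with SPARQL ASK.

    Returns the per-pattern selections and the number of ASK requests
    actually issued (cache hits are not re-sent). With a cold cache this is
    ``n_patterns × n_endpoints``.
    """
    cache = cache if cache is not None else AskCache()
    ask_count = 0
    selections: dict[int, tuple[EndpointDescriptor, ...]] = {}
    for tp in bgp.patterns:
        sig = _pattern_signature(tp)
        chosen = []
        for ep in index.endpoints:
            key = (sig, ep.url)
            if key not in cache.entries:
                query = f"ASK {{ {tp.sparql()} }}"
                try:
                    cache.entries[key] = ask(ep.url, query)
                except Exception as exc:
                    raise SelectionError(
                        f"endpoint {ep.url} unreachable during ASK probing"
                    ) from exc
                ask_count += 1
            if cache.entries[key]:
                chosen.append(ep)
        selections[tp.index] = tuple(sorted(chosen, key=lambda e: e.order))
    return (SourceSelection(selections, total_sources=len(index.endpoints)),
            ask_count)
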