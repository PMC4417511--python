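"""Federated query pipeline: parse → select sources → plan → execute.

The supported SPARQL subset is SELECT over one conjunctive basic graph
pattern with FILTERs and an optional LIMIT — enough for genomic-region and
patient-centric retrieval over the colour-partitioned data. FILTER
expressions are opaque: they are forwarded verbatim to remote endpoints
when a single sub-query binds all their variables, and otherwise evaluated
at integration time (rdflib evaluates the expression over a VALUES block).

Planning follows the usual federation playbook: patterns whose selection is
the same single endpoint are merged into one exclusive-group sub-query;
remaining patterns are ordered by ascending source count and joined with a
block nested-loop bound join (bindings shipped in a VALUES clause).

Because patient and clinical triples are replicated once per colour,
integration dedupes on full variable bindings — SPARQL BGP solutions are a
set at that granularity — and duplicate rows re-appear only through
projection, exactly as in centralized evaluation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Optional

from rdflib import Graph, Literal, URIRef
from rdflib.namespace import XSD

from .distribution import SpecificationIndex, TSSTumourTable
from .endpoints import EndpointPool
from .model import (
    BasicGraphPattern,
    FilterExpr,
    Term,
    TriplePattern,
)
from .selection import (
    AskCache,
    SelectionContext,
    SourceSelection,
    ask_baseline,
    select_sources,
)


class QueryParseError(ValueError):
    pass


class ExecutionError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

@dataclass
class ParsedQuery:
    prefixes: dict[str, str]
    select_vars: list[str]        # empty means SELECT *
    distinct: bool
    bgp: BasicGraphPattern
    limit: Optional[int] = None

    @property
    def bgps(self) -> list[BasicGraphPattern]:
        return [self.bgp]

    def prologue(self) -> str:
        return "".join(f"PREFIX {p}: <{iri}>\n"
                       for p, iri in self.prefixes.items())


_UNSUPPORTED = ("OPTIONAL", "UNION", "GRAPH", "SERVICE", "MINUS", "GROUP BY",
                "ORDER BY", "CONSTRUCT", "DESCRIBE", "ASK {", "EXISTS", "BIND",
                "VALUES", "HAVING")

_PREFIX_RE = re.compile(r"PREFIX\s+(\w*):\s*<([^>]*)>", re.IGNORECASE)
_SELECT_RE = re.compile(
    r"SELECT\s+(DISTINCT\s+)?(.*?)\s*WHERE\s*\{", re.IGNORECASE | re.DOTALL)
_LIMIT_RE = re.compile(r"\}\s*LIMIT\s+(\d+)\s*$", re.IGNORECASE)

_TERM_RE = re.compile(r"""
    (?P<iri><[^>]*>)
  | (?P<var>[?$]\w+)
  | (?P<literal>"(?:[^"\\]|\\.)*"(?:\^\^(?:<[^>]*>|\w+:\w+))?)
  | (?P<num>[+-]?\d+(?:\.\d+)?)
  | (?P<a>\ba\b)
  | (?P<pname>\w*:[\w.\-]*)
""", re.VERBOSE)


def _strip_comments(text: str) -> str:
    out_lines = []
    for line in text.splitlines():
        in_str = in_iri = False
        for i, ch in enumerate(line):
            if ch == '"' and not in_iri:
                in_str = not in_str
            elif ch == "<" and not in_str:
                in_iri = True
            elif ch == ">" and not in_str:
                in_iri = False
            elif ch == "#" and not in_str and not in_iri:
                line = line[:i]
                break
        out_lines.append(line)
    return "\n".join(out_lines)


def _parse_term(token: str, prefixes: dict[str, str]) -> Term:
    m = _TERM_RE.fullmatch(token)
    if not m:
        raise QueryParseError(f"unrecognized term {token!r}")
    if m.group("iri"):
        return Term.iri(token[1:-1])
    if m.group("var"):
        return Term.variable(token[1:])
    if m.group("a"):
        return Term.iri("http://www.w3.org/1999/02/22-rdf-syntax-ns#type")
    if m.group("num"):
        dt = XSD.decimal if "." in token else XSD.integer
        return Term.literal(token, str(dt))
    if m.group("literal"):
        body = token
        dt = None
        if "^^" in token:
            body, dt_tok = token.rsplit("^^", 1)
            if dt_tok.startswith("<"):
                dt = dt_tok[1:-1]
            else:
                pfx, local = dt_tok.split(":", 1)
                if pfx not in prefixes:
                    raise QueryParseError(f"unknown prefix {pfx!r}")
                dt = prefixes[pfx] + local
        return Term.literal(body[1:-1].replace('\\"', '"'), dt)
    # prefixed name
    pfx, local = token.split(":", 1)
    if pfx not in prefixes:
        raise QueryParseError(f"unknown prefix {pfx!r}")
    return Term.iri(prefixes[pfx] + local)


def _split_body(body: str):
    """Split a group-graph-pattern body into triple statements and FILTERs."""
    statements: list[tuple[str, str]] = []  # (kind, text)
    i, n = 0, len(body)
    while i < n:
        ch = body[i]
        if ch.isspace():
            i += 1
            continue
        if body[i:i + 6].upper() == "FILTER":
            j = body.index("(", i)
            depth, k = 0, j
            while k < n:
                if body[k] == "(":
                    depth += 1
                elif body[k] == ")":
                    depth -= 1
                    if depth == 0:
                        break
                k += 1
            if depth != 0:
                raise QueryParseError("unbalanced parentheses in FILTER")
            statements.append(("filter", body[j + 1:k]))
            i = k + 1
            # optional trailing dot
            while i < n and (body[i].isspace() or body[i] == "."):
                i += 1
        else:
            # a triple statement up to the next top-level '.'
            j = i
            in_str = in_iri = False
            while j < n:
                c = body[j]
                if c == '"' and not in_iri:
                    in_str = not in_str
                elif c == "<" and not in_str:
                    in_iri = True
                elif c == ">" and not in_str:
                    in_iri = False
                elif c == "." and not in_str and not in_iri:
                    # dots inside numbers: digit on both sides
                    prev_ = body[j - 1] if j > 0 else " "
                    next_ = body[j + 1] if j + 1 < n else " "
                    if not (prev_.isdigit() and next_.isdigit()):
                        break
                j += 1
            statements.append(("triple", body[i:j].strip()))
            i = j + 1
    return statements


def parse_query(text: str) -> ParsedQuery:
    """Parse a SELECT query of the supported subset into one BGP."""
    stripped = _strip_comments(text)
    upper = stripped.upper()
    for feature in _UNSUPPORTED:
        if feature in upper:
            raise QueryParseError(f"unsupported feature: {feature.strip()}")
    if "/" in re.sub(r"<[^>]*>|\"[^\"]*\"|#.*", "", stripped) and \
            re.search(r"[\w>]\s*/\s*\w+:", stripped):
        raise QueryParseError("unsupported feature: property path")

    prefixes = {m.group(1): m.group(2)
                for m in _PREFIX_RE.finditer(stripped)}
    body_region = _PREFIX_RE.sub("", stripped)
    m = _SELECT_RE.search(body_region)
    if not m:
        raise QueryParseError("only SELECT queries are supported")
    distinct = bool(m.group(1))
    proj = m.group(2).strip()
    if proj == "*":
        select_vars: list[str] = []
    else:
        select_vars = [v.lstrip("?$") for v in proj.split()]
        if not all(re.fullmatch(r"[?$]\w+", v) for v in proj.split()):
            raise QueryParseError(f"unsupported projection {proj!r}")

    rest = body_region[m.end():]
    limit = None
    lm = _LIMIT_RE.search(rest)
    if lm:
        limit = int(lm.group(1))
        rest = rest[:lm.start()] + "}"
    # find the matching closing brace of the WHERE block
    depth = 1
    for i, ch in enumerate(rest):
        if ch == "{":
            depth += 1
        elif ch == "}":
            depth -= 1
            if depth == 0:
                body = rest[:i]
                tail = rest[i + 1:].strip()
                break
    else:
        raise QueryParseError("unterminated WHERE block")
    if tail:
        raise QueryParseError(f"unsupported trailing clause {tail!r}")

    patterns: list[TriplePattern] = []
    filters: list[FilterExpr] = []
    for kind, stmt in _split_body(body):
        if kind == "filter":
            filters.append(FilterExpr(stmt.strip()))
            continue
        if not stmt:
            continue
        tokens = [t for t in _TERM_RE.finditer(stmt)]
        covered = "".join(stmt[m0.start():m0.end()] for m0 in tokens)
        leftover = re.sub(r"\s+", "", stmt)
        for m0 in tokens:
            leftover = leftover.replace(
                re.sub(r"\s+", "", stmt[m0.start():m0.end()]), "", 1)
        if len(tokens) != 3 or leftover:
            raise QueryParseError(f"cannot parse triple statement {stmt!r}")
        s, p, o = (_parse_term(t.group(0), prefixes) for t in tokens)
        patterns.append(TriplePattern(s, p, o, index=len(patterns)))
    if not patterns:
        raise QueryParseError("query has no triple patterns")
    return ParsedQuery(prefixes, select_vars, distinct,
                       BasicGraphPattern(patterns, filters), limit)


# ---------------------------------------------------------------------------
# Planning
# ---------------------------------------------------------------------------

@dataclass
class SubQuery:
    """Patterns shipped together to a set of candidate endpoints.

    An exclusive group (all patterns selected exactly the same single
    endpoint) has one endpoint; otherwise a single pattern with its
    per-pattern selection.
    """

    patterns: list[TriplePattern]
    endpoint_urls: list[str]
    pushed_filters: list[FilterExpr] = field(default_factory=list)

    def variables(self) -> set[str]:
        out: set[str] = set()
        for tp in self.patterns:
            out |= tp.variables()
        return out


@dataclass
class ExecutionPlan:
    steps: list[SubQuery]
    local_filters: list[FilterExpr]
    select_vars: list[str]
    distinct: bool
    limit: Optional[int]
    prologue: str = ""

    def covers(self) -> set[int]:
        return {tp.index for step in self.steps for tp in step.patterns}


def plan(parsed: ParsedQuery, selection: SourceSelection) -> ExecutionPlan:
    """Exclusive-group merging + ascending-|m_i| join ordering."""
    bgp = parsed.bgp
    groups: dict[str, list[TriplePattern]] = {}
    singles: list[TriplePattern] = []
    for tp in bgp.patterns:
        eps = selection.sources(tp.index)
        if len(eps) == 1:
            groups.setdefault(eps[0].url, []).append(tp)
        else:
            singles.append(tp)

    steps: list[SubQuery] = []
    for url, tps in groups.items():
        steps.append(SubQuery(patterns=sorted(tps, key=lambda t: t.index),
                              endpoint_urls=[url]))
    for tp in singles:
        steps.append(SubQuery(
            patterns=[tp],
            endpoint_urls=[e.url for e in selection.sources(tp.index)]))

    steps.sort(key=lambda s: (len(s.endpoint_urls), s.patterns[0].index))

    # push each FILTER into the first step that binds all its variables
    local_filters: list[FilterExpr] = []
    for f in parsed.bgp.filters:
        fvars = f.variables()
        for step in steps:
            if fvars <= step.variables():
                step.pushed_filters.append(f)
                break
        else:
            local_filters.append(f)

    return ExecutionPlan(steps=steps, local_filters=local_filters,
                         select_vars=parsed.select_vars,
                         distinct=parsed.distinct, limit=parsed.limit,
                         prologue=parsed.prologue())


# ---------------------------------------------------------------------------
# Execution
# ---------------------------------------------------------------------------

#: bindings shipped per bound-join round
DEFAULT_BLOCK_SIZE = 20

_EMPTY = Graph()


def _values_clause(variables: list[str], tuples: list[tuple]) -> str:
    heads = " ".join(f"?{v}" for v in variables)
    rows = []
    for tup in tuples:
        rows.append("(" + " ".join(t.n3() for t in tup) + ")")
    return f"VALUES ({heads}) {{ {' '.join(rows)} }}"


def _subquery_text(step: SubQuery, prologue: str,
                   values: Optional[str]) -> str:
    parts = [values] if values else []
    parts += [tp.sparql() for tp in step.patterns]
    parts += [f.sparql() for f in step.pushed_filters]
    return f"{prologue}SELECT * WHERE {{ {' '.join(parts)} }}"


def _compatible(sol: dict, row: dict) -> bool:
    return all(sol.get(v, row[v]) == row[v] for v in row)


def _merge(sol: dict, row: dict) -> dict:
    out = dict(sol)
    out.update(row)
    return out


def _dedupe(solutions: list[dict]) -> list[dict]:
    seen = set()
    out = []
    for sol in solutions:
        key = frozenset(sol.items())
        if key not in seen:
            seen.add(key)
            out.append(sol)
    return out


def _eval_filter_local(f: FilterExpr, solutions: list[dict],
                       prologue: str) -> list[dict]:
    """Evaluate an opaque FILTER over solution mappings via rdflib."""
    fvars = sorted(f.variables())
    distinct_tuples = sorted({tuple(sol[v] for v in fvars)
                              for sol in solutions
                              if all(v in sol for v in fvars)},
                             key=lambda t: [x.n3() for x in t])
    if not distinct_tuples:
        return []
    query = (f"{prologue}SELECT * WHERE {{ "
             f"{_values_clause(fvars, distinct_tuples)} {f.sparql()} }}")
    passing = set()
    for row in _EMPTY.query(query):
        passing.add(tuple(row[i] for i in range(len(fvars))))
    return [sol for sol in solutions
            if all(v in sol for v in fvars)
            and tuple(sol[v] for v in fvars) in passing]


def execute(plan_: ExecutionPlan, pool: EndpointPool,
            block_size: int = DEFAULT_BLOCK_SIZE) -> list[dict]:
    """Run the plan; returns projected solution mappings (bag semantics)."""
    solutions: list[dict] = [{}]
    bound_vars: set[str] = set()

    for step in plan_.steps:
        if not step.endpoint_urls:
            solutions = []
            break
        step_vars = step.variables()
        shared = sorted(step_vars & bound_vars)
        new_solutions: list[dict] = []

        if not shared or solutions == [{}]:
            query = _subquery_text(step, plan_.prologue, None)
            rows: list[dict] = []
            for url in step.endpoint_urls:
                try:
                    rows.extend(pool.select(url, query))
                except Exception as exc:
                    raise ExecutionError(
                        f"sub-query failed at {url}: {exc}") from exc
            for sol in solutions:
                for row in rows:
                    if _compatible(sol, row):
                        new_solutions.append(_merge(sol, row))
        else:
            usable = [s for s in solutions if all(v in s for v in shared)]
            tuples = sorted({tuple(s[v] for v in shared) for s in usable},
                            key=lambda t: [x.n3() for x in t])
            rows = []
            for start in range(0, len(tuples), block_size):
                block = tuples[start:start + block_size]
                query = _subquery_text(step, plan_.prologue,
                                       _values_clause(shared, block))
                for url in step.endpoint_urls:
                    try:
                        rows.extend(pool.select(url, query))
                    except Exception as exc:
                        raise ExecutionError(
                            f"sub-query failed at {url}: {exc}") from exc
            for sol in solutions:
                for row in rows:
                    if _compatible(sol, row):
                        new_solutions.append(_merge(sol, row))

        solutions = _dedupe(new_solutions)
        bound_vars |= step_vars
        if not solutions:
            break

    for f in plan_.local_filters:
        solutions = _eval_filter_local(f, solutions, plan_.prologue)

    # projection re-introduces duplicate rows, as in centralized evaluation
    proj = plan_.select_vars or sorted(bound_vars)
    rows_out = [{v: sol[v] for v in proj if v in sol} for sol in solutions]
    if plan_.distinct:
        rows_out = _dedupe(rows_out)
    if plan_.limit is not None:
        rows_out = rows_out[:plan_.limit]
    return rows_out


# ---------------------------------------------------------------------------
# End-to-end runner and the centralized oracle
# ---------------------------------------------------------------------------

@dataclass
class FederationConfig:
    index: SpecificationIndex
    tss_table: TSSTumourTable
    pool: EndpointPool
    engine: str = "joinaware"       # or "ask"
    block_size: int = DEFAULT_BLOCK_SIZE
    ask_cache: Optional[AskCache] = None


@dataclass
class QueryReport:
    engine: str
    tpws: int
    ask_count: int
    per_pattern_sources: dict[str, list[str]]

    def to_dict(self) -> dict:
        return {"engine": self.engine, "tpws": self.tpws,
                "ask_count": self.ask_count,
                "per_pattern_sources": self.per_pattern_sources}


@dataclass
class QueryResult:
    rows: list[dict]
    report: QueryReport
    selection: SourceSelection


def run_query(text: str, config: FederationConfig) -> QueryResult:
    """parse → select (join-aware or ASK baseline) → plan → execute."""
    parsed = parse_query(text)
    ask_count = 0
    if config.engine == "joinaware":
        ctx = SelectionContext(config.index, config.tss_table)
        selection = select_sources(parsed.bgp, ctx, ask=config.pool.ask)
    elif config.engine == "ask":
        selection, ask_count = ask_baseline(
            parsed.bgp, config.index, config.pool.ask,
            cache=config.ask_cache)
    else:
        raise ValueError(f"unknown engine {config.engine!r}")
    plan_ = plan(parsed, selection)
    rows = execute(plan_, config.pool, block_size=config.block_size)
    report = QueryReport(
        engine=config.engine, tpws=selection.tpws, ask_count=ask_count,
        per_pattern_sources={str(i): sorted(e.url for e in eps)
                             for i, eps in selection.selections.items()})
    return QueryResult(rows=rows, report=report, selection=selection)


def centralized_eval(text: str, graph: Graph) -> list[dict]:
    """Evaluate the original query over one union store (the recall oracle)."""
    res = graph.query(text)
    rows = []
    for binding in res:
        row = {}
        for var, val in zip(res.vars, binding):
            if val is not None:
                row[str(var)] = val
        rows.append(row)
    return rows


def rows_multiset(rows: list[dict]) -> list[tuple]:
    """Canonical multiset form of solution rows, for comparisons."""
    out = []
    for row in rows:
        out.append(tuple(sorted((v, t.n3()) for v, t in row.items())))
    return sorted(out)
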