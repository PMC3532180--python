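"""The query surface: taxonomy-level lookups and application-level searches.

Taxonomy-level queries (listing, id/name search, annotation retrieval,
hierarchy navigation) read the ontology as a vocabulary.  Application-level
queries treat it as a knowledge base about simulation algorithms: which
characteristics an algorithm possesses, which algorithms share a profile, and
which is the nearest substitute when a requested method is unavailable.

Conventions applied uniformly:

* Negation ("lacks", query ``NOT``) is closed-world over the *inferred*
  characteristic sets — appropriate for matching tool capabilities, where an
  unstated characteristic is an absent one.
* Deprecated algorithms stay resolvable by id and name (legacy simulation
  descriptions must not break) but are excluded from every candidate or
  result set of the application-level queries: a substitute must be a live
  term.
* "Same characteristics" means set equality of the (optionally type-filtered)
  inferred profiles; subset matching is what
  :func:`algorithms_by_characteristics` is for.
* Similarity rankings sort by ascending hierarchy distance, ties broken by
  ascending numeric id, and never contain the query algorithm itself.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, NamedTuple, Union

from . import inference
from .errors import QuerySyntaxError, UnknownTermError, WrongBranchError
from .identifiers import IdentifierFormatError, TermId, normalize_identifier
from .model import OntologyGraph, OntologyTerm, Synonym

# ---------------------------------------------------------------------------
# taxonomy level
# ---------------------------------------------------------------------------


def list_terms(graph: OntologyGraph, branch: str) -> list[OntologyTerm]:
    """All terms of one branch (deprecated ones included, flagged), by id."""
    if branch not in ("algorithm", "characteristic", "parameter", "other"):
        raise ValueError(f"unknown branch {branch!r}")
    return sorted(
        (t for t in graph.terms.values() if t.branch == branch), key=lambda t: t.id
    )


def term_kind(graph: OntologyGraph, term_id: TermId) -> str:
    """Branch of a term: algorithm, characteristic, parameter or other."""
    return graph.term(term_id).branch


def is_algorithm(graph: OntologyGraph, term_id: TermId) -> bool:
    return term_kind(graph, term_id) == "algorithm"


def is_characteristic(graph: OntologyGraph, term_id: TermId) -> bool:
    return term_kind(graph, term_id) == "characteristic"


def is_parameter(graph: OntologyGraph, term_id: TermId) -> bool:
    return term_kind(graph, term_id) == "parameter"


def search_by_id(graph: OntologyGraph, text: str | TermId) -> OntologyTerm:
    """Resolve any identifier form (short id, IRI, MIRIAM URN, identifiers.org
    URL) to its term."""
    return graph.term(normalize_identifier(text))


def search_by_name(graph: OntologyGraph, text: str, substring: bool = False) -> set[OntologyTerm]:
    """Terms whose label or any synonym matches ``text`` case-insensitively;
    with ``substring=True`` a containment match instead of exact equality."""
    needle = text.casefold()

    def matches(candidate: str) -> bool:
        hay = candidate.casefold()
        return needle in hay if substring else needle == hay

    return {
        term
        for term in graph.terms.values()
        if matches(term.label) or any(matches(s.text) for s in term.synonyms)
    }


class Annotations(NamedTuple):
    label: str
    synonyms: frozenset[Synonym]
    definition: str | None
    links: frozenset[str]
    deprecated: bool


def annotations(graph: OntologyGraph, term_id: TermId) -> Annotations:
    """The stored annotation bundle of one term."""
    term = graph.term(term_id)
    return Annotations(term.label, term.synonyms, term.definition, term.links, term.deprecated)


def synonyms(graph: OntologyGraph, term_id: TermId, scope: str | None = None) -> frozenset[str]:
    """Synonym strings of a term, optionally one scope only."""
    return graph.term(term_id).synonym_texts(scope)


# ---------------------------------------------------------------------------
# application level: characteristics
# ---------------------------------------------------------------------------


def _as_ids(value: TermId | Iterable[TermId]) -> tuple[TermId, ...]:
    if isinstance(value, TermId):
        return (value,)
    return tuple(value)


def _require_characteristics(graph: OntologyGraph, ids: Iterable[TermId]) -> tuple[TermId, ...]:
    ids = tuple(ids)
    for c in ids:
        inference.require_branch(graph, c, "characteristic")
    return ids


def _live_algorithms(graph: OntologyGraph) -> list[TermId]:
    return [t.id for t in graph.terms.values() if t.branch == "algorithm" and not t.deprecated]


def characteristics_of(
    graph: OntologyGraph,
    algorithm: TermId,
    type_filter: Iterable[TermId] | None = None,
) -> frozenset[TermId]:
    """Inferred characteristics of an algorithm, optionally restricted to the
    descendants of the given characteristic types (e.g. pass the *type of
    system behaviour* class to get just the behaviour value)."""
    inferred = inference.inferred_characteristics(graph, algorithm)
    if type_filter is None:
        return inferred
    allowed: set[TermId] = set()
    for type_id in _require_characteristics(graph, type_filter):
        allowed |= inference.descendants(graph, type_id)
    return inferred & allowed


def has_characteristic(
    graph: OntologyGraph,
    algorithm: TermId,
    characteristics: TermId | Iterable[TermId],
) -> bool:
    """True iff the algorithm possesses every listed characteristic
    (vacuously true for an empty list)."""
    wanted = _require_characteristics(graph, _as_ids(characteristics))
    inferred = inference.inferred_characteristics(graph, algorithm)
    return all(c in inferred for c in wanted)


def algorithms_by_characteristics(
    graph: OntologyGraph,
    characteristics: TermId | Iterable[TermId],
    mode: str = "possess",
) -> frozenset[TermId]:
    """Non-deprecated algorithms that possess every listed characteristic —
    or, with ``mode="lack"``, those missing at least one (closed-world).

    Possessing a more specific characteristic counts as possessing the listed
    one, via the upward closure of inferred characteristic sets.
    """
    if mode not in ("possess", "lack"):
        raise ValueError(f"mode must be 'possess' or 'lack', got {mode!r}")
    wanted = _require_characteristics(graph, _as_ids(characteristics))
    result = set()
    for algorithm in _live_algorithms(graph):
        inferred = graph.index.inferred_characteristics[algorithm]
        possesses_all = all(c in inferred for c in wanted)
        if (mode == "possess") == possesses_all:
            result.add(algorithm)
    return frozenset(result)


def algorithms_with_same_characteristics(
    graph: OntologyGraph,
    algorithm: TermId,
    type_filter: Iterable[TermId] | None = None,
) -> frozenset[TermId]:
    """Non-deprecated algorithms (other than the query one) whose filtered
    characteristic profile equals the query algorithm's, set-wise."""
    reference = characteristics_of(graph, algorithm, type_filter)
    return frozenset(
        other
        for other in _live_algorithms(graph)
        if other != algorithm and characteristics_of(graph, other, type_filter) == reference
    )


@dataclass(frozen=True)
class SimilarityResult:
    """One ranked substitute candidate; ``distance`` is the subclass-path
    length to the query algorithm (``None`` when not connected)."""

    algorithm: TermId
    distance: int | None

    @property
    def sort_key(self) -> tuple:
        return (self.distance is None, self.distance or 0, int(self.algorithm))


def n_most_similar(
    graph: OntologyGraph,
    algorithm: TermId,
    n: int,
    type_filter: Iterable[TermId] | None = None,
) -> list[SimilarityResult]:
    """The ``n`` algorithms most similar to the given one: candidates share
    its (filtered) characteristic profile, ranked by hierarchy distance with
    ties broken by ascending id.  Fewer than ``n`` are returned when fewer
    candidates exist; the query algorithm itself never appears."""
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    candidates = algorithms_with_same_characteristics(graph, algorithm, type_filter)
    ranked = sorted(
        (SimilarityResult(c, inference.hierarchy_distance(graph, algorithm, c))
         for c in candidates),
        key=lambda r: r.sort_key,
    )
    return ranked[:n]


# ---------------------------------------------------------------------------
# application level: boolean characteristic/parameter queries
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Atom:
    kind: str  # "characteristic" | "parameter"
    term: TermId

    def evaluate(self, graph: OntologyGraph, algorithm: TermId) -> bool:
        if self.kind == "characteristic":
            return self.term in graph.index.inferred_characteristics[algorithm]
        return self.term in graph.index.inferred_parameters[algorithm]


@dataclass(frozen=True)
class Not:
    operand: "QueryExpr"

    def evaluate(self, graph, algorithm) -> bool:
        return not self.operand.evaluate(graph, algorithm)


@dataclass(frozen=True)
class And:
    operands: tuple["QueryExpr", ...]

    def evaluate(self, graph, algorithm) -> bool:
        return all(op.evaluate(graph, algorithm) for op in self.operands)


@dataclass(frozen=True)
class Or:
    operands: tuple["QueryExpr", ...]

    def evaluate(self, graph, algorithm) -> bool:
        return any(op.evaluate(graph, algorithm) for op in self.operands)


QueryExpr = Union[Atom, Not, And, Or]

_TOKEN = re.compile(r'\(|\)|"[^"]*"|[^()\s"]+')
_ATOM_FUNCS = {
    "has_characteristic": "characteristic",
    "characteristic": "characteristic",
    "has_parameter": "parameter",
    "parameter": "parameter",
}


def _resolve_reference(graph: OntologyGraph, token: str, kind: str) -> TermId:
    if token.startswith('"') and token.endswith('"'):
        label = token[1:-1]
        hits = {t for t in search_by_name(graph, label) if t.branch == kind}
        if not hits:
            raise QuerySyntaxError(f"no {kind} named {label!r} in the ontology")
        if len(hits) > 1:
            raise QuerySyntaxError(f"ambiguous {kind} name {label!r}")
        return next(iter(hits)).id
    try:
        term_id = normalize_identifier(token)
    except IdentifierFormatError as exc:
        raise QuerySyntaxError(str(exc)) from exc
    if term_id not in graph.terms:
        raise QuerySyntaxError(f"query atom names unknown term {term_id}")
    if graph.terms[term_id].branch != kind:
        raise QuerySyntaxError(
            f"query atom {term_id} is not in the {kind} branch"
        )
    return term_id


def parse_query(graph: OntologyGraph, text: str) -> QueryExpr:
    """Parse an infix boolean query such as::

        has_characteristic(kisao:9100002) AND NOT has_parameter("tau-leaping epsilon")

    Keywords ``AND``/``OR``/``NOT`` are case-insensitive; atoms name a term by
    any identifier form or by a double-quoted label; parentheses group.
    """
    tokens = _TOKEN.findall(text)
    pos = 0

    def peek() -> str | None:
        return tokens[pos] if pos < len(tokens) else None

    def take() -> str:
        nonlocal pos
        if pos >= len(tokens):
            raise QuerySyntaxError(f"unexpected end of query: {text!r}")
        tok = tokens[pos]
        pos += 1
        return tok

    def expect(tok: str) -> None:
        got = take()
        if got != tok:
            raise QuerySyntaxError(f"expected {tok!r}, found {got!r} in {text!r}")

    def parse_or() -> QueryExpr:
        parts = [parse_and()]
        while peek() is not None and peek().upper() == "OR":
            take()
            parts.append(parse_and())
        return parts[0] if len(parts) == 1 else Or(tuple(parts))

    def parse_and() -> QueryExpr:
        parts = [parse_factor()]
        while peek() is not None and peek().upper() == "AND":
            take()
            parts.append(parse_factor())
        return parts[0] if len(parts) == 1 else And(tuple(parts))

    def parse_factor() -> QueryExpr:
        tok = take()
        if tok.upper() == "NOT":
            return Not(parse_factor())
        if tok == "(":
            inner = parse_or()
            expect(")")
            return inner
        kind = _ATOM_FUNCS.get(tok.casefold())
        if kind is None:
            raise QuerySyntaxError(f"expected an atom or NOT/(, found {tok!r} in {text!r}")
        expect("(")
        ref = take()
        expect(")")
        return Atom(kind, _resolve_reference(graph, ref, kind))

    if not tokens:
        raise QuerySyntaxError("empty query")
    expr = parse_or()
    if pos != len(tokens):
        raise QuerySyntaxError(f"trailing tokens after query: {tokens[pos:]}")
    return expr


def algorithms_by_query(graph: OntologyGraph, query: str | QueryExpr) -> frozenset[TermId]:
    """Evaluate a boolean characteristic/parameter expression against every
    non-deprecated algorithm; NOT is the closed-world complement within that
    set."""
    expr = parse_query(graph, query) if isinstance(query, str) else query
    return frozenset(a for a in _live_algorithms(graph) if expr.evaluate(graph, a))


# ---------------------------------------------------------------------------
# application level: parameters and hybrids
# ---------------------------------------------------------------------------


def parameters_of(graph: OntologyGraph, algorithm: TermId) -> frozenset[TermId]:
    """Parameters used by an algorithm (asserted or inherited)."""
    return inference.inferred_parameters(graph, algorithm)


def parameter_type(graph: OntologyGraph, parameter: TermId) -> str | None:
    """The declared datatype of a parameter (e.g. ``double``), or ``None``
    when the ontology declares no type."""
    inference.require_branch(graph, parameter, "parameter")
    declared = sorted(
        ax.object for ax in graph.links
        if ax.subject == parameter and ax.relation == "has_type"
    )
    return declared[0] if declared else None


def parameters_by_characteristics(
    graph: OntologyGraph,
    characteristics: TermId | Iterable[TermId],
    ancestor: TermId | None = None,
) -> frozenset[TermId]:
    """Union of the parameters of every non-deprecated algorithm possessing
    all the listed characteristics (and, when given, descending from —
    or equal to — ``ancestor``)."""
    matching = algorithms_by_characteristics(graph, characteristics, "possess")
    if ancestor is not None:
        inference.require_branch(graph, ancestor, "algorithm")
        matching = frozenset(a for a in matching if inference.is_a(graph, a, ancestor))
    out: set[TermId] = set()
    for algorithm in matching:
        out |= graph.index.inferred_parameters[algorithm]
    return frozenset(out)


def has_parameter(
    graph: OntologyGraph,
    subject: TermId | Iterable[TermId],
    parameters: TermId | Iterable[TermId],
) -> bool:
    """With an algorithm subject: does it use all the listed parameters?
    With a collection of characteristics as subject: are the listed
    parameters among those used by the algorithms possessing them all?"""
    wanted = set(_as_ids(parameters))
    for p in wanted:
        inference.require_branch(graph, p, "parameter")
    if isinstance(subject, TermId):
        return wanted <= inference.inferred_parameters(graph, subject)
    return wanted <= parameters_by_characteristics(graph, subject)


def is_hybrid(graph: OntologyGraph, algorithm: TermId) -> bool:
    """Whether the algorithm is composed of other algorithms."""
    return bool(inference.inferred_hybrid_parts(graph, algorithm))


def hybrid_of(graph: OntologyGraph, algorithm: TermId) -> frozenset[TermId]:
    """The algorithms this one is a hybrid of (asserted or inherited)."""
    return inference.inferred_hybrid_parts(graph, algorithm)
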