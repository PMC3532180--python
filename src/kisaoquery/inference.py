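"""Structural reasoning over the subclass DAG.

KiSAO-shaped files only need a small, decidable fragment of OWL semantics,
which this module computes directly instead of delegating to a tableau
reasoner:

* transitive ancestor/descendant closures of ``subClassOf``;
* inheritance of existential restrictions down the hierarchy — an algorithm
  possesses every characteristic/parameter/hybrid-part asserted on any of its
  ancestors;
* upward entailment of characteristics — possessing *stochastic system
  behaviour* entails possessing its superclass *type of system behaviour*
  (parameters are deliberately not generalised upward: a specific parameter
  does not imply its generalisations are used);
* the hierarchy distance used to rank substitute algorithms: the shortest
  undirected subclass-path length between two algorithm classes, restricted
  to the algorithm branch.  The hierarchy is a DAG, not a tree; with several
  parents the minimum path counts.

All closures are computed once per graph and cached on
``OntologyGraph.index``.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .errors import UnknownTermError, WrongBranchError
from .identifiers import TermId
from .model import OntologyGraph


@dataclass
class ClosureIndex:
    """Precomputed transitive closures and inferred link sets."""

    ancestor_sets: dict[TermId, frozenset[TermId]]
    descendant_sets: dict[TermId, frozenset[TermId]]
    inferred_characteristics: dict[TermId, frozenset[TermId]]
    inferred_parameters: dict[TermId, frozenset[TermId]]
    inferred_hybrid_parts: dict[TermId, frozenset[TermId]]
    parents: dict[TermId, frozenset[TermId]]
    children: dict[TermId, frozenset[TermId]]
    algorithm_undirected: nx.Graph


def build_index(graph: OntologyGraph) -> ClosureIndex:
    up = nx.DiGraph()  # child -> parent
    up.add_nodes_from(graph.terms)
    up.add_edges_from(graph.subclass_edges)

    ancestor_sets = {t: frozenset(nx.descendants(up, t)) for t in up.nodes}
    descendant_sets = {t: frozenset(nx.ancestors(up, t)) for t in up.nodes}
    parents = {t: frozenset(up.successors(t)) for t in up.nodes}
    children = {t: frozenset(up.predecessors(t)) for t in up.nodes}

    asserted: dict[str, dict[TermId, set[TermId]]] = {
        "has_characteristic": {},
        "has_parameter": {},
        "is_hybrid_of": {},
    }
    for axiom in graph.links:
        if axiom.relation in asserted:
            asserted[axiom.relation].setdefault(axiom.subject, set()).add(axiom.object)

    def inherited(relation: str, algorithm: TermId) -> set[TermId]:
        table = asserted[relation]
        out: set[TermId] = set()
        for subject in {algorithm} | ancestor_sets[algorithm]:
            out |= table.get(subject, set())
        return out

    algorithms = [t for t, term in graph.terms.items() if term.branch == "algorithm"]

    inferred_characteristics: dict[TermId, frozenset[TermId]] = {}
    inferred_parameters: dict[TermId, frozenset[TermId]] = {}
    inferred_hybrid_parts: dict[TermId, frozenset[TermId]] = {}
    for algorithm in algorithms:
        chars = inherited("has_characteristic", algorithm)
        closed = set(chars)
        for c in chars:  # possessing a characteristic entails its generalisations
            closed |= {
                a for a in ancestor_sets.get(c, frozenset())
                if graph.terms[a].branch == "characteristic"
            }
        inferred_characteristics[algorithm] = frozenset(closed)
        inferred_parameters[algorithm] = frozenset(inherited("has_parameter", algorithm))
        inferred_hybrid_parts[algorithm] = frozenset(inherited("is_hybrid_of", algorithm))

    undirected = nx.Graph()
    undirected.add_nodes_from(algorithms)
    undirected.add_edges_from(
        (c, p) for c, p in graph.subclass_edges
        if graph.terms[c].branch == "algorithm" and graph.terms[p].branch == "algorithm"
    )

    return ClosureIndex(
        ancestor_sets=ancestor_sets,
        descendant_sets=descendant_sets,
        inferred_characteristics=inferred_characteristics,
        inferred_parameters=inferred_parameters,
        inferred_hybrid_parts=inferred_hybrid_parts,
        parents=parents,
        children=children,
        algorithm_undirected=undirected,
    )


def _require(graph: OntologyGraph, term_id: TermId) -> None:
    if term_id not in graph.terms:
        raise UnknownTermError(f"no such term in the ontology: {term_id}")


def require_branch(graph: OntologyGraph, term_id: TermId, branch: str) -> None:
    _require(graph, term_id)
    actual = graph.terms[term_id].branch
    if actual != branch:
        raise WrongBranchError(
            f"{term_id} is in the {actual!r} branch; a {branch} term is required"
        )


def ancestors(graph: OntologyGraph, term_id: TermId, direct: bool = False) -> frozenset[TermId]:
    """Superclasses of ``term_id``: immediate parents if ``direct``, else the
    transitive closure (excluding the term itself)."""
    _require(graph, term_id)
    idx = graph.index
    return idx.parents[term_id] if direct else idx.ancestor_sets[term_id]


def descendants(graph: OntologyGraph, term_id: TermId, direct: bool = False) -> frozenset[TermId]:
    """Subclasses of ``term_id``; mirror of :func:`ancestors`."""
    _require(graph, term_id)
    idx = graph.index
    return idx.children[term_id] if direct else idx.descendant_sets[term_id]


def is_a(graph: OntologyGraph, descendant: TermId, ancestor: TermId) -> bool:
    """Reflexive subclass test: true iff ``descendant`` equals ``ancestor`` or
    lies below it in the subclass DAG."""
    _require(graph, descendant)
    _require(graph, ancestor)
    return descendant == ancestor or ancestor in graph.index.ancestor_sets[descendant]


def inferred_characteristics(graph: OntologyGraph, algorithm: TermId) -> frozenset[TermId]:
    """All characteristics an algorithm possesses: asserted on it or any
    ancestor, closed upward within the characteristic branch."""
    require_branch(graph, algorithm, "algorithm")
    return graph.index.inferred_characteristics[algorithm]


def inferred_parameters(graph: OntologyGraph, algorithm: TermId) -> frozenset[TermId]:
    """All parameters an algorithm uses (asserted on it or any ancestor)."""
    require_branch(graph, algorithm, "algorithm")
    return graph.index.inferred_parameters[algorithm]


def inferred_hybrid_parts(graph: OntologyGraph, algorithm: TermId) -> frozenset[TermId]:
    """Algorithms this one is a hybrid of (asserted or inherited)."""
    require_branch(graph, algorithm, "algorithm")
    return graph.index.inferred_hybrid_parts[algorithm]


def hierarchy_distance(graph: OntologyGraph, a: TermId, b: TermId) -> int | None:
    """Shortest undirected subclass-path length between two algorithms within
    the algorithm branch; ``None`` if they are not connected."""
    require_branch(graph, a, "algorithm")
    require_branch(graph, b, "algorithm")
    try:
        return nx.shortest_path_length(graph.index.algorithm_undirected, a, b)
    except nx.NetworkXNoPath:
        return None
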