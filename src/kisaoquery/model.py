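"""In-memory ontology model.

An :class:`OntologyGraph` is the parsed, indexed form of a KiSAO-shaped OWL
file: a term table, the subclass DAG, and the link axioms connecting
algorithms to characteristics, parameters and hybrid parts.  It is the single
data structure every query in this package runs against.

Branch membership (algorithm / characteristic / parameter) is purely
structural: a term belongs to the branch whose configured root class it
reaches by following ``subClassOf`` edges upward (roots belong to their own
branch).  A term reaching no root is branch ``other``; a term reaching two
roots makes the file invalid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property
from typing import Iterable, Union

import networkx as nx

from .config import BRANCHES, RELATIONS, SYNONYM_SCOPES, OntologyConfig
from .errors import OntologyFormatError, UnknownTermError
from .identifiers import TermId


@dataclass(frozen=True, order=True)
class Synonym:
    """An alternative name with its OBO scope (exact/related/broad/narrow)."""

    text: str
    scope: str = "exact"

    def __post_init__(self) -> None:
        if self.scope not in SYNONYM_SCOPES:
            raise ValueError(
                f"synonym scope must be one of {SYNONYM_SCOPES}, got {self.scope!r}"
            )


@dataclass(frozen=True)
class OntologyTerm:
    """One ontology class with its annotations and branch assignment."""

    id: TermId
    label: str = ""
    synonyms: frozenset[Synonym] = frozenset()
    definition: str | None = None
    links: frozenset[str] = frozenset()
    deprecated: bool = False
    branch: str = "other"

    def __post_init__(self) -> None:
        if self.branch not in BRANCHES:
            raise ValueError(f"branch must be one of {BRANCHES}, got {self.branch!r}")

    def synonym_texts(self, scope: str | None = None) -> frozenset[str]:
        """Synonym strings, optionally restricted to one scope."""
        if scope is not None and scope not in SYNONYM_SCOPES:
            raise ValueError(f"scope must be one of {SYNONYM_SCOPES}, got {scope!r}")
        return frozenset(s.text for s in self.synonyms if scope is None or s.scope == scope)


@dataclass(frozen=True, order=True)
class LinkAxiom:
    """An asserted relationship.

    ``has_characteristic``, ``has_parameter`` and ``is_hybrid_of`` point at
    another term; ``has_type`` points at a datatype name such as ``double``.
    """

    subject: TermId
    relation: str
    object: Union[TermId, str]

    def __post_init__(self) -> None:
        if self.relation not in RELATIONS:
            raise ValueError(f"relation must be one of {RELATIONS}, got {self.relation!r}")
        if self.relation == "has_type":
            if not isinstance(self.object, str):
                raise ValueError("has_type axioms must carry a datatype name")
        elif not isinstance(self.object, TermId):
            raise ValueError(f"{self.relation} axioms must point at a TermId")


def assign_branches(
    term_ids: Iterable[TermId],
    subclass_edges: Iterable[tuple[TermId, TermId]],
    roots: tuple[TermId, TermId, TermId],
) -> dict[TermId, str]:
    """Partition terms into branches by reachability to the three roots.

    Raises :class:`OntologyFormatError` if any term reaches two roots.
    """
    down = nx.DiGraph()  # parent -> child
    down.add_nodes_from(term_ids)
    down.add_edges_from((parent, child) for child, parent in subclass_edges)
    branches: dict[TermId, str] = {t: "other" for t in down.nodes}
    for root, name in zip(roots, ("algorithm", "characteristic", "parameter")):
        if root not in down:
            continue
        members = {root} | nx.descendants(down, root)
        for term in members:
            if branches[term] != "other":
                raise OntologyFormatError(
                    f"term {term} is below both the {branches[term]} and {name} branch roots"
                )
            branches[term] = name
    return branches


@dataclass
class OntologyGraph:
    """Parsed, indexed ontology: terms, subclass DAG, link axioms."""

    terms: dict[TermId, OntologyTerm]
    subclass_edges: frozenset[tuple[TermId, TermId]]  # (child, parent)
    links: frozenset[LinkAxiom]
    config: OntologyConfig = field(default_factory=OntologyConfig)

    @property
    def branch_roots(self) -> tuple[TermId, TermId, TermId]:
        return self.config.branch_roots

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for child, parent in self.subclass_edges:
            for end in (child, parent):
                if end not in self.terms:
                    raise OntologyFormatError(f"subclass edge references unknown term {end}")
        dag = nx.DiGraph()
        dag.add_nodes_from(self.terms)
        dag.add_edges_from(self.subclass_edges)
        if not nx.is_directed_acyclic_graph(dag):
            cycle = nx.find_cycle(dag)
            raise OntologyFormatError(f"subclass axioms contain a cycle: {cycle}")
        for axiom in self.links:
            if axiom.subject not in self.terms:
                raise OntologyFormatError(f"link axiom references unknown subject {axiom.subject}")
            if isinstance(axiom.object, TermId) and axiom.object not in self.terms:
                raise OntologyFormatError(f"link axiom references unknown object {axiom.object}")
            subject_branch = self.terms[axiom.subject].branch
            required = "parameter" if axiom.relation == "has_type" else "algorithm"
            if subject_branch != required:
                raise OntologyFormatError(
                    f"{axiom.relation} axiom on {axiom.subject} requires a {required}-branch "
                    f"subject, found {subject_branch}"
                )

    # -- lookup helpers -----------------------------------------------------

    def term(self, term_id: TermId) -> OntologyTerm:
        try:
            return self.terms[term_id]
        except KeyError:
            raise UnknownTermError(f"no such term in the ontology: {term_id}") from None

    def branch_of(self, term_id: TermId) -> str:
        return self.term(term_id).branch

    def parents(self, term_id: TermId) -> frozenset[TermId]:
        self.term(term_id)
        return frozenset(p for c, p in self.subclass_edges if c == term_id)

    def children(self, term_id: TermId) -> frozenset[TermId]:
        self.term(term_id)
        return frozenset(c for c, p in self.subclass_edges if p == term_id)

    def links_by_subject(self, term_id: TermId, relation: str) -> frozenset[LinkAxiom]:
        return frozenset(
            ax for ax in self.links if ax.subject == term_id and ax.relation == relation
        )

    @cached_property
    def index(self):
        """The eagerly computed closure index (see :mod:`kisaoquery.inference`)."""
        from .inference import build_index

        return build_index(self)
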