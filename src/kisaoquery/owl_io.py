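"""Load a KiSAO-shaped OWL file into an :class:`~kisaoquery.model.OntologyGraph`.

The loader understands the OWL constructs KiSAO actually uses:

* ``A rdfs:subClassOf B`` with ``B`` a named class → a subclass edge;
* ``A rdfs:subClassOf [ owl:Restriction ; owl:onProperty R ;
  owl:someValuesFrom B ]`` with ``R`` one of the configured relation
  properties → a link axiom (``has_type`` restrictions may target an XSD
  datatype via ``owl:someValuesFrom`` or carry ``owl:hasValue``);
* OBO-in-OWL annotations (label, typed synonyms, definition, xrefs/seeAlso,
  ``owl:deprecated``).

Anything else (restrictions on unlisted properties, unions, non-KiSAO class
IRIs) is skipped with a warning naming the subject, never fatally: ontology
releases grow constructs faster than tooling.
"""

from __future__ import annotations

import logging
from pathlib import Path
from urllib.parse import urlparse

import rdflib
from rdflib import BNode, Literal, URIRef
from rdflib.namespace import OWL, RDF, RDFS

from .config import OntologyConfig, load_config
from .errors import IdentifierFormatError, OntologyFormatError, OntologyIOError
from .identifiers import TermId, normalize_identifier
from .model import LinkAxiom, OntologyGraph, OntologyTerm, Synonym, assign_branches

logger = logging.getLogger(__name__)

_XSD_NS = "http://www.w3.org/2001/XMLSchema#"


def _is_url(source: str) -> bool:
    return urlparse(source).scheme in ("http", "https")


def _parse_rdf(source: str | Path) -> rdflib.Graph:
    graph = rdflib.Graph()
    location = str(source)
    if not _is_url(location):
        path = Path(location)
        if not path.is_file():
            raise OntologyIOError(f"ontology source not readable: {location}")
    last_error: Exception | None = None
    for fmt in ("xml", "turtle"):
        try:
            graph.parse(location, format=fmt)
            return graph
        except OSError as exc:
            raise OntologyIOError(f"cannot read ontology source {location}: {exc}") from exc
        except Exception as exc:  # rdflib raises assorted parse errors
            last_error = exc
    raise OntologyFormatError(
        f"source {location} is neither RDF/XML nor Turtle OWL: {last_error}"
    )


def _datatype_name(node) -> str | None:
    if isinstance(node, URIRef):
        iri = str(node)
        if iri.startswith(_XSD_NS):
            return iri[len(_XSD_NS):]
        return iri.rsplit("#", 1)[-1].rsplit("/", 1)[-1]
    if isinstance(node, Literal):
        if node.datatype is not None:
            return _datatype_name(node.datatype)
        return type(node.toPython()).__name__
    return None


def load_ontology(
    source: str | Path,
    config: OntologyConfig | str | Path | None = None,
) -> OntologyGraph:
    """Parse and index an OWL file (local path or http(s) URL).

    ``config`` may be an :class:`OntologyConfig`, the path of an INI config
    file, or ``None`` for KiSAO defaults.  Loading from a URL is supported but
    never implicit: the caller must pass the URL explicitly.
    """
    if config is None:
        config = OntologyConfig()
    elif not isinstance(config, OntologyConfig):
        config = load_config(config)

    rdf = _parse_rdf(source)

    relation_by_iri = {URIRef(iri): name for name, iri in config.relation_iris.items()}
    synonym_by_iri = {URIRef(iri): scope for scope, iri in config.synonym_iris.items()}
    label_iri = URIRef(config.label_iri)
    definition_iri = URIRef(config.definition_iri)
    link_iris = tuple(URIRef(iri) for iri in config.link_iris)
    deprecated_iri = URIRef(config.deprecated_iri)

    # Named classes carrying a KiSAO-style IRI become terms; others are skipped.
    term_nodes: dict[TermId, URIRef] = {}
    for cls in rdf.subjects(RDF.type, OWL.Class):
        if isinstance(cls, BNode):
            continue
        try:
            term_nodes[normalize_identifier(str(cls))] = cls
        except IdentifierFormatError:
            logger.warning("skipping class with non-KiSAO IRI: %s", cls)

    subclass_edges: set[tuple[TermId, TermId]] = set()
    link_axioms: set[LinkAxiom] = set()

    for term_id, node in sorted(term_nodes.items()):
        for parent in rdf.objects(node, RDFS.subClassOf):
            if isinstance(parent, URIRef):
                try:
                    parent_id = normalize_identifier(str(parent))
                except IdentifierFormatError:
                    logger.warning(
                        "skipping subclass axiom of %s: non-KiSAO superclass %s", node, parent
                    )
                    continue
                subclass_edges.add((term_id, parent_id))
            elif isinstance(parent, BNode) and (parent, RDF.type, OWL.Restriction) in rdf:
                axiom = _restriction_axiom(rdf, node, term_id, parent, relation_by_iri)
                if axiom is not None:
                    link_axioms.add(axiom)
            else:
                logger.warning("skipping unsupported superclass construct on %s", node)

    # Referenced-but-undeclared terms get a placeholder so the graph closes.
    referenced = {p for _, p in subclass_edges} | {
        ax.object for ax in link_axioms if isinstance(ax.object, TermId)
    }
    for term_id in referenced - set(term_nodes):
        logger.warning("term %s is referenced but not declared as owl:Class", term_id)
        term_nodes[term_id] = URIRef(term_id.iri)

    branches = assign_branches(term_nodes, subclass_edges, config.branch_roots)

    terms: dict[TermId, OntologyTerm] = {}
    for term_id, node in term_nodes.items():
        label = next((str(v) for v in rdf.objects(node, label_iri)), "")
        definition = next((str(v) for v in rdf.objects(node, definition_iri)), None)
        synonyms = frozenset(
            Synonym(str(v), scope)
            for iri, scope in synonym_by_iri.items()
            for v in rdf.objects(node, iri)
        )
        links = frozenset(str(v) for iri in link_iris for v in rdf.objects(node, iri))
        deprecated = any(
            isinstance(v, Literal) and bool(v.toPython())
            for v in rdf.objects(node, deprecated_iri)
        )
        terms[term_id] = OntologyTerm(
            id=term_id,
            label=label or (term_id.short if not deprecated else ""),
            synonyms=synonyms,
            definition=definition,
            links=links,
            deprecated=deprecated,
            branch=branches[term_id],
        )

    graph = OntologyGraph(
        terms=terms,
        subclass_edges=frozenset(subclass_edges),
        links=frozenset(link_axioms),
        config=config,
    )
    graph.index  # closures are cheap at KiSAO's size; build eagerly
    return graph


def _restriction_axiom(rdf, node, term_id, restriction, relation_by_iri) -> LinkAxiom | None:
    prop = next(rdf.objects(restriction, OWL.onProperty), None)
    relation = relation_by_iri.get(prop)
    if relation is None:
        logger.warning("skipping restriction on unlisted property %s (subject %s)", prop, node)
        return None
    if relation == "has_type":
        filler = next(rdf.objects(restriction, OWL.someValuesFrom), None)
        if filler is None:
            filler = next(rdf.objects(restriction, OWL.hasValue), None)
        datatype = _datatype_name(filler)
        if datatype is None:
            logger.warning("skipping has_type restriction without datatype (subject %s)", node)
            return None
        return LinkAxiom(term_id, "has_type", datatype)
    filler = next(rdf.objects(restriction, OWL.someValuesFrom), None)
    if not isinstance(filler, URIRef):
        logger.warning("skipping %s restriction without named filler (subject %s)", relation, node)
        return None
    try:
        object_id = normalize_identifier(str(filler))
    except IdentifierFormatError:
        logger.warning("skipping %s restriction to non-KiSAO class %s (subject %s)",
                       relation, filler, node)
        return None
    return LinkAxiom(term_id, relation, object_id)
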