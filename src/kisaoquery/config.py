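"""Loader configuration: branch roots, relation and annotation property IRIs.

KiSAO-shaped ontologies carry their structure in a handful of property IRIs:
three branch-root classes, four link relations (``has characteristic``,
``has parameter``, ``is hybrid of`` between classes, ``has type`` to a
datatype) and OBO-in-OWL annotation properties for labels, synonyms,
definitions, cross-references and deprecation.  All of them are configurable;
the defaults match KiSAO releases.

A configuration can also be read from a small INI file::

    [branch_roots]
    algorithm = kisao:0000000
    characteristic = kisao:0000097
    parameter = kisao:0000201

    [relations]
    has_characteristic = http://www.biomodels.net/kisao/KISAO#hasCharacteristic
    has_parameter = http://www.biomodels.net/kisao/KISAO#hasParameter
    is_hybrid_of = http://www.biomodels.net/kisao/KISAO#isHybridOf
    has_type = http://www.biomodels.net/kisao/KISAO#hasType

    [annotations]
    label = http://www.w3.org/2000/01/rdf-schema#label
    definition = http://purl.obolibrary.org/obo/IAO_0000115
    synonym_exact = http://www.geneontology.org/formats/oboInOwl#hasExactSynonym
    synonym_related = http://www.geneontology.org/formats/oboInOwl#hasRelatedSynonym
    synonym_broad = http://www.geneontology.org/formats/oboInOwl#hasBroadSynonym
    synonym_narrow = http://www.geneontology.org/formats/oboInOwl#hasNarrowSynonym
    links = http://www.geneontology.org/formats/oboInOwl#hasDbXref, http://www.w3.org/2000/01/rdf-schema#seeAlso
    deprecated = http://www.w3.org/2002/07/owl#deprecated

Unknown sections or keys are rejected so that typos do not silently fall back
to defaults.
"""

from __future__ import annotations

import configparser
from dataclasses import dataclass, field, replace
from pathlib import Path

from .errors import OntologyFormatError
from .identifiers import TermId, normalize_identifier

KISAO_NAMESPACE = "http://www.biomodels.net/kisao/KISAO#"
OBO_IN_OWL = "http://www.geneontology.org/formats/oboInOwl#"

#: synonym scopes, in documentation order
SYNONYM_SCOPES = ("exact", "related", "broad", "narrow")

#: link-axiom relation names
RELATIONS = ("has_characteristic", "has_parameter", "is_hybrid_of", "has_type")

#: branch kinds a term can be assigned
BRANCHES = ("algorithm", "characteristic", "parameter", "other")


def _default_synonym_iris() -> dict[str, str]:
    return {
        "exact": OBO_IN_OWL + "hasExactSynonym",
        "related": OBO_IN_OWL + "hasRelatedSynonym",
        "broad": OBO_IN_OWL + "hasBroadSynonym",
        "narrow": OBO_IN_OWL + "hasNarrowSynonym",
    }


def _default_relation_iris() -> dict[str, str]:
    return {
        "has_characteristic": KISAO_NAMESPACE + "hasCharacteristic",
        "has_parameter": KISAO_NAMESPACE + "hasParameter",
        "is_hybrid_of": KISAO_NAMESPACE + "isHybridOf",
        "has_type": KISAO_NAMESPACE + "hasType",
    }


@dataclass(frozen=True)
class OntologyConfig:
    """Everything the loader needs to know about a KiSAO-shaped file."""

    algorithm_root: TermId = TermId("0000000")
    characteristic_root: TermId = TermId("0000097")
    parameter_root: TermId = TermId("0000201")
    relation_iris: dict[str, str] = field(default_factory=_default_relation_iris)
    label_iri: str = "http://www.w3.org/2000/01/rdf-schema#label"
    definition_iri: str = "http://purl.obolibrary.org/obo/IAO_0000115"
    synonym_iris: dict[str, str] = field(default_factory=_default_synonym_iris)
    link_iris: tuple[str, ...] = (
        OBO_IN_OWL + "hasDbXref",
        "http://www.w3.org/2000/01/rdf-schema#seeAlso",
    )
    deprecated_iri: str = "http://www.w3.org/2002/07/owl#deprecated"

    @property
    def branch_roots(self) -> tuple[TermId, TermId, TermId]:
        return (self.algorithm_root, self.characteristic_root, self.parameter_root)

    def root_of(self, branch: str) -> TermId:
        return {
            "algorithm": self.algorithm_root,
            "characteristic": self.characteristic_root,
            "parameter": self.parameter_root,
        }[branch]


def load_config(path: str | Path) -> OntologyConfig:
    """Read an :class:`OntologyConfig` from an INI file (keys as documented
    above; every key optional, defaults filled in)."""
    parser = configparser.ConfigParser()
    read = parser.read(str(path))
    if not read:
        raise OntologyFormatError(f"config file not readable: {path}")
    cfg = OntologyConfig()
    known = {"branch_roots", "relations", "annotations"}
    extra = set(parser.sections()) - known
    if extra:
        raise OntologyFormatError(f"unknown config sections: {sorted(extra)}")

    if parser.has_section("branch_roots"):
        roots = {}
        for key in ("algorithm", "characteristic", "parameter"):
            if parser.has_option("branch_roots", key):
                roots[f"{key}_root"] = normalize_identifier(parser.get("branch_roots", key))
        bad = set(parser.options("branch_roots")) - {"algorithm", "characteristic", "parameter"}
        if bad:
            raise OntologyFormatError(f"unknown branch_roots keys: {sorted(bad)}")
        cfg = replace(cfg, **roots)

    if parser.has_section("relations"):
        rels = dict(cfg.relation_iris)
        for key in parser.options("relations"):
            if key not in RELATIONS:
                raise OntologyFormatError(f"unknown relation key: {key}")
            rels[key] = parser.get("relations", key).strip()
        cfg = replace(cfg, relation_iris=rels)

    if parser.has_section("annotations"):
        syn = dict(cfg.synonym_iris)
        updates: dict[str, object] = {}
        for key in parser.options("annotations"):
            value = parser.get("annotations", key).strip()
            if key == "label":
                updates["label_iri"] = value
            elif key == "definition":
                updates["definition_iri"] = value
            elif key == "deprecated":
                updates["deprecated_iri"] = value
            elif key == "links":
                updates["link_iris"] = tuple(v.strip() for v in value.split(",") if v.strip())
            elif key.startswith("synonym_") and key[len("synonym_"):] in SYNONYM_SCOPES:
                syn[key[len("synonym_"):]] = value
            else:
                raise OntologyFormatError(f"unknown annotation key: {key}")
        updates["synonym_iris"] = syn
        cfg = replace(cfg, **updates)

    return cfg
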