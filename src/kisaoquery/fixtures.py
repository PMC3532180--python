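"""KiSAO-shaped test ontologies with ground-truth manifests.

Two generators are provided:

* :func:`paper_manifest` — a small, fully deterministic ontology holding the
  tau-leaping family (Poisson, binomial, multinomial and implicit variants
  under the tau-leaping method, all stochastic and discrete), the LSODE
  solver (deterministic, continuous), the characteristic types they
  instantiate, and the ``tau-leaping epsilon`` parameter of type ``double``.
  Ids with an established KiSAO value (tau-leaping method 0000039, LSODE
  0000071, the branch roots) use it; everything else draws from a reserved
  synthetic 9xxxxxx range so no real id is shadowed.
* :func:`random_manifest` — seeded random ontologies (DAG-shaped branches,
  random typed links, annotations, a configurable deprecated fraction) for
  property-based testing against brute-force oracles.

Each generator returns a :class:`FixtureManifest`: the exact term, edge and
link tables the serialized OWL file encodes, so a test can compare what the
loader produced with what the generator meant.  :func:`write_owl` serializes
a manifest to RDF/XML with fully sorted output, so identical inputs yield
byte-identical files.
"""

from __future__ import annotations

import random
import string
from dataclasses import dataclass, field
from pathlib import Path
from typing import Union
from xml.sax.saxutils import escape, quoteattr

from .config import SYNONYM_SCOPES, OntologyConfig
from .identifiers import TermId

XSD_NS = "http://www.w3.org/2001/XMLSchema#"
DATATYPES = ("double", "integer", "boolean")

LinkRow = tuple[TermId, str, Union[TermId, str]]


@dataclass(frozen=True)
class TermRecord:
    """Ground truth for one class: annotations as the file will carry them."""

    label: str
    definition: str | None = None
    deprecated: bool = False
    synonyms: tuple[tuple[str, str], ...] = ()  # (text, scope)
    links: tuple[str, ...] = ()


@dataclass
class FixtureManifest:
    """The generator's own record of every axiom in the emitted OWL file."""

    terms: dict[TermId, TermRecord]
    edges: frozenset[tuple[TermId, TermId]]  # (child, parent)
    links: frozenset[LinkRow]
    config: OntologyConfig = field(default_factory=OntologyConfig)
    seed: int | None = None

    @property
    def label_to_id(self) -> dict[str, TermId]:
        return {rec.label: tid for tid, rec in self.terms.items()}

    def edge_set(self) -> set[tuple[str, str]]:
        return {(c.short, p.short) for c, p in self.edges}

    def link_set(self) -> set[tuple[str, str, str]]:
        return {
            (s.short, rel, o.short if isinstance(o, TermId) else o)
            for s, rel, o in self.links
        }


# ---------------------------------------------------------------------------
# paper fixture
# ---------------------------------------------------------------------------

TAU_LEAPING = TermId("0000039")
LSODE = TermId("0000071")
POISSON_TAU_LEAPING = TermId("9000001")
BINOMIAL_TAU_LEAPING = TermId("9000002")
MULTINOMIAL_TAU_LEAPING = TermId("9000003")
IMPLICIT_TAU_LEAPING = TermId("9000004")
TYPE_OF_SYSTEM_BEHAVIOUR = TermId("9100001")
STOCHASTIC_BEHAVIOUR = TermId("9100002")
DETERMINISTIC_BEHAVIOUR = TermId("9100003")
TYPE_OF_VARIABLE = TermId("9100004")
DISCRETE_VARIABLE = TermId("9100005")
CONTINUOUS_VARIABLE = TermId("9100006")
TAU_LEAPING_EPSILON = TermId("9200001")


def paper_manifest(config: OntologyConfig | None = None) -> FixtureManifest:
    """The deterministic tau-leaping/LSODE fixture described above."""
    cfg = config or OntologyConfig()
    alg_root, char_root, par_root = cfg.branch_roots

    terms: dict[TermId, TermRecord] = {
        alg_root: TermRecord("simulation algorithm"),
        char_root: TermRecord("simulation algorithm characteristic"),
        par_root: TermRecord("simulation algorithm parameter"),
        TAU_LEAPING: TermRecord(
            "tau-leaping method",
            definition=(
                "Approximate acceleration of the stochastic simulation algorithm that "
                "fires several reactions per leap over a preselected time step tau."
            ),
            synonyms=(("tauL", "exact"),),
            links=("doi:10.1063/1.1378322",),
        ),
        POISSON_TAU_LEAPING: TermRecord(
            "Poisson tau-leaping method",
            definition="Tau-leaping variant drawing reaction firings from Poisson distributions.",
        ),
        BINOMIAL_TAU_LEAPING: TermRecord("binomial tau-leaping method"),
        MULTINOMIAL_TAU_LEAPING: TermRecord("multinomial tau-leaping method"),
        IMPLICIT_TAU_LEAPING: TermRecord("implicit tau-leaping method"),
        LSODE: TermRecord(
            "LSODE",
            definition="Livermore Solver for Ordinary Differential Equations.",
            synonyms=(("Livermore Solver for Ordinary Differential Equations", "exact"),),
        ),
        TYPE_OF_SYSTEM_BEHAVIOUR: TermRecord("type of system behaviour"),
        STOCHASTIC_BEHAVIOUR: TermRecord("stochastic system behaviour"),
        DETERMINISTIC_BEHAVIOUR: TermRecord("deterministic system behaviour"),
        TYPE_OF_VARIABLE: TermRecord("type of variable"),
        DISCRETE_VARIABLE: TermRecord("discrete variable"),
        CONTINUOUS_VARIABLE: TermRecord("continuous variable"),
        TAU_LEAPING_EPSILON: TermRecord(
            "tau-leaping epsilon",
            definition="Error-control parameter bounding the relative change in propensities per leap.",
        ),
    }

    edges = frozenset(
        {
            (TAU_LEAPING, alg_root),
            (LSODE, alg_root),
            (POISSON_TAU_LEAPING, TAU_LEAPING),
            (BINOMIAL_TAU_LEAPING, TAU_LEAPING),
            (MULTINOMIAL_TAU_LEAPING, TAU_LEAPING),
            (IMPLICIT_TAU_LEAPING, TAU_LEAPING),
            (TYPE_OF_SYSTEM_BEHAVIOUR, char_root),
            (STOCHASTIC_BEHAVIOUR, TYPE_OF_SYSTEM_BEHAVIOUR),
            (DETERMINISTIC_BEHAVIOUR, TYPE_OF_SYSTEM_BEHAVIOUR),
            (TYPE_OF_VARIABLE, char_root),
            (DISCRETE_VARIABLE, TYPE_OF_VARIABLE),
            (CONTINUOUS_VARIABLE, TYPE_OF_VARIABLE),
            (TAU_LEAPING_EPSILON, par_root),
        }
    )

    # The four variants inherit their profile from the tau-leaping method.
    links = frozenset(
        {
            (TAU_LEAPING, "has_characteristic", STOCHASTIC_BEHAVIOUR),
            (TAU_LEAPING, "has_characteristic", DISCRETE_VARIABLE),
            (TAU_LEAPING, "has_parameter", TAU_LEAPING_EPSILON),
            (LSODE, "has_characteristic", DETERMINISTIC_BEHAVIOUR),
            (LSODE, "has_characteristic", CONTINUOUS_VARIABLE),
            (TAU_LEAPING_EPSILON, "has_type", "double"),
        }
    )

    return FixtureManifest(terms=terms, edges=edges, links=links, config=cfg)


# ---------------------------------------------------------------------------
# random fixtures
# ---------------------------------------------------------------------------

_WORDS = (
    "leap", "step", "euler", "gibson", "rosenbrock", "midpoint", "adams",
    "heun", "verlet", "magnus", "krylov", "pade", "chord", "nordsieck",
    "radau", "gear", "bdf", "ssa", "milstein", "runge",
)

_BRANCH_BASES = {"algorithm": 9000000, "characteristic": 9100000, "parameter": 9200000}


def _word(rng: random.Random) -> str:
    w = rng.choice(_WORDS)
    if rng.random() < 0.3:
        w += "-" + "".join(rng.choice(string.ascii_lowercase) for _ in range(3))
    return w


def random_manifest(
    n_algorithms: int,
    n_characteristics: int,
    n_parameters: int,
    max_parents: int = 2,
    link_density: float = 0.15,
    deprecated_fraction: float = 0.1,
    seed: int = 0,
    config: OntologyConfig | None = None,
) -> FixtureManifest:
    """A seeded random KiSAO-shaped ontology.

    Each branch is a rooted DAG (every class reaches its root; up to
    ``max_parents`` superclasses).  Each algorithm links to each
    characteristic with probability ``link_density`` (parameters at 70% of
    that); some algorithms are hybrids; most parameters are typed.  The same
    seed always produces the same manifest, and hence the same OWL bytes.
    """
    for name, value in (
        ("n_algorithms", n_algorithms),
        ("n_characteristics", n_characteristics),
        ("n_parameters", n_parameters),
    ):
        if value < 0:
            raise ValueError(f"{name} must be >= 0, got {value}")
    if max_parents < 1:
        raise ValueError(f"max_parents must be >= 1, got {max_parents}")
    if not 0.0 <= link_density <= 1.0:
        raise ValueError(f"link_density must be in [0, 1], got {link_density}")
    if not 0.0 <= deprecated_fraction <= 1.0:
        raise ValueError(f"deprecated_fraction must be in [0, 1], got {deprecated_fraction}")

    cfg = config or OntologyConfig()
    rng = random.Random(seed)

    terms: dict[TermId, TermRecord] = {
        cfg.algorithm_root: TermRecord("simulation algorithm"),
        cfg.characteristic_root: TermRecord("simulation algorithm characteristic"),
        cfg.parameter_root: TermRecord("simulation algorithm parameter"),
    }
    edges: set[tuple[TermId, TermId]] = set()
    links: set[LinkRow] = set()

    branch_nodes: dict[str, list[TermId]] = {}
    for branch, count in (
        ("algorithm", n_algorithms),
        ("characteristic", n_characteristics),
        ("parameter", n_parameters),
    ):
        root = cfg.root_of(branch)
        nodes: list[TermId] = []
        for i in range(1, count + 1):
            tid = TermId(str(_BRANCH_BASES[branch] + i))
            pool = [root] + nodes
            k = rng.randint(1, min(max_parents, len(pool)))
            for parent in rng.sample(pool, k):
                edges.add((tid, parent))
            synonym_list = []
            while rng.random() < 0.4 and len(synonym_list) < 3:
                synonym_list.append((_word(rng), rng.choice(SYNONYM_SCOPES)))
            terms[tid] = TermRecord(
                label=f"synthetic {branch} {_word(rng)} {i}",
                definition=(f"Synthetic {branch} class number {i}."
                            if rng.random() < 0.5 else None),
                deprecated=rng.random() < deprecated_fraction,
                synonyms=tuple(sorted(synonym_list)),
                links=((f"doi:10.{rng.randint(1000, 9999)}/{_word(rng)}",)
                       if rng.random() < 0.4 else ()),
            )
            nodes.append(tid)
        branch_nodes[branch] = nodes

    for alg in branch_nodes["algorithm"]:
        for char in branch_nodes["characteristic"]:
            if rng.random() < link_density:
                links.add((alg, "has_characteristic", char))
        for par in branch_nodes["parameter"]:
            if rng.random() < link_density * 0.7:
                links.add((alg, "has_parameter", par))
        others = [a for a in branch_nodes["algorithm"] if a != alg]
        if others and rng.random() < 0.15:
            for part in rng.sample(others, rng.randint(1, min(2, len(others)))):
                links.add((alg, "is_hybrid_of", part))

    for par in branch_nodes["parameter"]:
        if rng.random() < 0.8:
            links.add((par, "has_type", rng.choice(DATATYPES)))

    return FixtureManifest(
        terms=terms, edges=frozenset(edges), links=frozenset(links),
        config=cfg, seed=seed,
    )


# ---------------------------------------------------------------------------
# deterministic OWL RDF/XML writer
# ---------------------------------------------------------------------------

_CORE_PREFIXES = {
    "http://www.w3.org/1999/02/22-rdf-syntax-ns#": "rdf",
    "http://www.w3.org/2000/01/rdf-schema#": "rdfs",
    "http://www.w3.org/2002/07/owl#": "owl",
    XSD_NS: "xsd",
}


def _split_iri(iri: str) -> tuple[str, str]:
    cut = max(iri.rfind("#"), iri.rfind("/")) + 1
    return iri[:cut], iri[cut:]


def serialize_owl(manifest: FixtureManifest) -> bytes:
    """Render a manifest as RDF/XML.  Output is fully sorted, so equal
    manifests serialize to identical bytes."""
    cfg = manifest.config

    property_iris = (
        [cfg.label_iri, cfg.definition_iri, cfg.deprecated_iri]
        + [cfg.synonym_iris[s] for s in SYNONYM_SCOPES]
        + [cfg.link_iris[0]]
        + [cfg.relation_iris[r] for r in sorted(cfg.relation_iris)]
    )
    prefixes = dict(_CORE_PREFIXES)
    counter = 1
    for iri in property_iris:
        ns, _ = _split_iri(iri)
        if ns not in prefixes:
            prefixes[ns] = f"ns{counter}"
            counter += 1

    def qname(iri: str) -> str:
        ns, local = _split_iri(iri)
        return f"{prefixes[ns]}:{local}"

    out: list[str] = ['<?xml version="1.0" encoding="UTF-8"?>']
    xmlns = " ".join(
        f'xmlns:{p}={quoteattr(ns)}'
        for ns, p in sorted(prefixes.items(), key=lambda kv: kv[1])
    )
    out.append(f"<rdf:RDF {xmlns}>")
    out.append('  <owl:Ontology rdf:about="http://example.org/kisaoquery/fixture"/>')
    for rel in sorted(cfg.relation_iris):
        kind = "DatatypeProperty" if rel == "has_type" else "ObjectProperty"
        out.append(f"  <owl:{kind} rdf:about={quoteattr(cfg.relation_iris[rel])}/>")
    for iri in [cfg.label_iri, cfg.definition_iri, cfg.link_iris[0]] + [
        cfg.synonym_iris[s] for s in SYNONYM_SCOPES
    ]:
        out.append(f"  <owl:AnnotationProperty rdf:about={quoteattr(iri)}/>")

    edges_by_child: dict[TermId, list[TermId]] = {}
    for child, parent in manifest.edges:
        edges_by_child.setdefault(child, []).append(parent)
    links_by_subject: dict[TermId, list[LinkRow]] = {}
    for row in manifest.links:
        links_by_subject.setdefault(row[0], []).append(row)

    for tid in sorted(manifest.terms):
        rec = manifest.terms[tid]
        out.append(f"  <owl:Class rdf:about={quoteattr(tid.iri)}>")
        if rec.label:
            out.append(f"    <{qname(cfg.label_iri)}>{escape(rec.label)}</{qname(cfg.label_iri)}>")
        if rec.definition:
            el = qname(cfg.definition_iri)
            out.append(f"    <{el}>{escape(rec.definition)}</{el}>")
        for text, scope in sorted(rec.synonyms):
            el = qname(cfg.synonym_iris[scope])
            out.append(f"    <{el}>{escape(text)}</{el}>")
        for link in sorted(rec.links):
            el = qname(cfg.link_iris[0])
            out.append(f"    <{el}>{escape(link)}</{el}>")
        if rec.deprecated:
            el = qname(cfg.deprecated_iri)
            out.append(
                f'    <{el} rdf:datatype="{XSD_NS}boolean">true</{el}>'
            )
        for parent in sorted(edges_by_child.get(tid, [])):
            out.append(f"    <rdfs:subClassOf rdf:resource={quoteattr(parent.iri)}/>")
        for _, relation, obj in sorted(
            links_by_subject.get(tid, []),
            key=lambda row: (row[1], str(row[2])),
        ):
            target = XSD_NS + obj if relation == "has_type" else obj.iri
            out.append("    <rdfs:subClassOf>")
            out.append("      <owl:Restriction>")
            out.append(
                f"        <owl:onProperty rdf:resource={quoteattr(cfg.relation_iris[relation])}/>"
            )
            out.append(f"        <owl:someValuesFrom rdf:resource={quoteattr(target)}/>")
            out.append("      </owl:Restriction>")
            out.append("    </rdfs:subClassOf>")
        out.append("  </owl:Class>")
    out.append("</rdf:RDF>")
    return ("\n".join(out) + "\n").encode("utf-8")


def write_owl(manifest: FixtureManifest, path: str | Path) -> Path:
    path = Path(path)
    path.write_bytes(serialize_owl(manifest))
    return path


# ---------------------------------------------------------------------------
# manifest TSV round-trip
# ---------------------------------------------------------------------------

_MANIFEST_FILES = ("terms.tsv", "synonyms.tsv", "edges.tsv", "links.tsv", "meta.tsv")


def _check_field(value: str) -> str:
    if "\t" in value or "\n" in value or "|" in value:
        raise ValueError(f"manifest field may not contain tab/newline/pipe: {value!r}")
    return value


def write_manifest(manifest: FixtureManifest, directory: str | Path) -> Path:
    """Dump the ground-truth tables as TSV files under ``directory``."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    with open(directory / "terms.tsv", "w", encoding="utf-8") as fh:
        fh.write("id\tlabel\tdefinition\tdeprecated\tlinks\n")
        for tid in sorted(manifest.terms):
            rec = manifest.terms[tid]
            fh.write(
                "\t".join(
                    (
                        tid.short,
                        _check_field(rec.label),
                        _check_field(rec.definition or ""),
                        "1" if rec.deprecated else "0",
                        "|".join(_check_field(x) for x in sorted(rec.links)),
                    )
                )
                + "\n"
            )
    with open(directory / "synonyms.tsv", "w", encoding="utf-8") as fh:
        fh.write("id\ttext\tscope\n")
        for tid in sorted(manifest.terms):
            for text, scope in sorted(manifest.terms[tid].synonyms):
                fh.write(f"{tid.short}\t{_check_field(text)}\t{scope}\n")
    with open(directory / "edges.tsv", "w", encoding="utf-8") as fh:
        fh.write("child\tparent\n")
        for child, parent in sorted(manifest.edges):
            fh.write(f"{child.short}\t{parent.short}\n")
    with open(directory / "links.tsv", "w", encoding="utf-8") as fh:
        fh.write("subject\trelation\tobject\n")
        for subject, relation, obj in sorted(
            manifest.links, key=lambda r: (r[0], r[1], str(r[2]))
        ):
            rendered = obj.short if isinstance(obj, TermId) else obj
            fh.write(f"{subject.short}\t{relation}\t{rendered}\n")
    with open(directory / "meta.tsv", "w", encoding="utf-8") as fh:
        fh.write("key\tvalue\n")
        fh.write(f"seed\t{'' if manifest.seed is None else manifest.seed}\n")
        fh.write(f"algorithm_root\t{manifest.config.algorithm_root.short}\n")
        fh.write(f"characteristic_root\t{manifest.config.characteristic_root.short}\n")
        fh.write(f"parameter_root\t{manifest.config.parameter_root.short}\n")
    return directory


def read_manifest(directory: str | Path, config: OntologyConfig | None = None) -> FixtureManifest:
    """Rebuild a :class:`FixtureManifest` from :func:`write_manifest` output."""
    from .identifiers import normalize_identifier

    directory = Path(directory)

    def rows(name: str) -> list[list[str]]:
        lines = (directory / name).read_text(encoding="utf-8").splitlines()
        return [line.split("\t") for line in lines[1:]]

    synonyms: dict[TermId, list[tuple[str, str]]] = {}
    for tid_s, text, scope in rows("synonyms.tsv"):
        synonyms.setdefault(normalize_identifier(tid_s), []).append((text, scope))

    terms: dict[TermId, TermRecord] = {}
    for tid_s, label, definition, deprecated, links in rows("terms.tsv"):
        tid = normalize_identifier(tid_s)
        terms[tid] = TermRecord(
            label=label,
            definition=definition or None,
            deprecated=deprecated == "1",
            synonyms=tuple(sorted(synonyms.get(tid, []))),
            links=tuple(x for x in links.split("|") if x),
        )

    edges = frozenset(
        (normalize_identifier(c), normalize_identifier(p)) for c, p in rows("edges.tsv")
    )
    links_set: set[LinkRow] = set()
    for subj, relation, obj in rows("links.tsv"):
        parsed: TermId | str = obj if relation == "has_type" else normalize_identifier(obj)
        links_set.add((normalize_identifier(subj), relation, parsed))

    meta = dict(rows("meta.tsv"))
    seed = int(meta["seed"]) if meta.get("seed") else None
    return FixtureManifest(
        terms=terms, edges=edges, links=frozenset(links_set),
        config=config or OntologyConfig(), seed=seed,
    )


def generate_paper_fixture(
    owl_path: str | Path, manifest_dir: str | Path | None = None
) -> FixtureManifest:
    """Write the deterministic tau-leaping/LSODE fixture and return its manifest."""
    manifest = paper_manifest()
    write_owl(manifest, owl_path)
    if manifest_dir is not None:
        write_manifest(manifest, manifest_dir)
    return manifest


def generate_random_ontology(
    owl_path: str | Path,
    n_algorithms: int,
    n_characteristics: int,
    n_parameters: int,
    max_parents: int = 2,
    link_density: float = 0.15,
    deprecated_fraction: float = 0.1,
    seed: int = 0,
    manifest_dir: str | Path | None = None,
) -> FixtureManifest:
    """Write a seeded random ontology and return its manifest."""
    manifest = random_manifest(
        n_algorithms, n_characteristics, n_parameters,
        max_parents=max_parents, link_density=link_density,
        deprecated_fraction=deprecated_fraction, seed=seed,
    )
    write_owl(manifest, owl_path)
    if manifest_dir is not None:
        write_manifest(manifest, manifest_dir)
    return manifest
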