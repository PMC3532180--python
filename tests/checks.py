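"""The central cross-check: every query operation against its brute-force
manifest oracle, on one (manifest, loaded graph) pair.

Small fixtures are checked exhaustively; large ones on deterministic random
samples so the fleet stays fast.
"""

from __future__ import annotations

import random

from kisaoquery import inference, queries
from kisaoquery.fixtures import FixtureManifest
from kisaoquery.identifiers import TermId
from kisaoquery.model import OntologyGraph

from oracles import ManifestOracle, random_expression


def _loaded_link_rows(graph: OntologyGraph) -> set[tuple[str, str, str]]:
    return {
        (ax.subject.short, ax.relation,
         ax.object.short if isinstance(ax.object, TermId) else ax.object)
        for ax in graph.links
    }


def check_structure(manifest: FixtureManifest, graph: OntologyGraph) -> None:
    """Loader output must equal the generator's axiom tables exactly."""
    assert set(graph.terms) == set(manifest.terms)
    assert {(c.short, p.short) for c, p in graph.subclass_edges} == manifest.edge_set()
    assert _loaded_link_rows(graph) == manifest.link_set()
    oracle = ManifestOracle(manifest)
    for tid, rec in manifest.terms.items():
        term = graph.terms[tid]
        assert term.label == rec.label
        assert term.definition == rec.definition
        assert term.deprecated == rec.deprecated
        assert {(s.text, s.scope) for s in term.synonyms} == set(rec.synonyms)
        assert set(term.links) == set(rec.links)
        assert term.branch == oracle.branch_of(tid)


def check_queries_against_oracle(
    manifest: FixtureManifest, graph: OntologyGraph, seed: int
) -> None:
    oracle = ManifestOracle(manifest)
    rng = random.Random(seed)
    terms = sorted(graph.terms)

    for branch in ("algorithm", "characteristic", "parameter"):
        listed = queries.list_terms(graph, branch)
        assert {t.id for t in listed} == set(oracle.branch_members(branch))
        assert [t.id for t in listed] == sorted(t.id for t in listed)

    sample_terms = terms if len(terms) <= 80 else sorted(rng.sample(terms, 60))
    for tid in sample_terms:
        assert inference.ancestors(graph, tid) == oracle.reach_up(tid)
        assert inference.descendants(graph, tid) == oracle.reach_down(tid)
        assert inference.ancestors(graph, tid, direct=True) == oracle.direct_parents(tid)
        assert inference.descendants(graph, tid, direct=True) == oracle.direct_children(tid)
        assert queries.term_kind(graph, tid) == oracle.branch_of(tid)
    for _ in range(min(100, len(terms) ** 2)):
        a, b = rng.choice(terms), rng.choice(terms)
        assert inference.is_a(graph, a, b) == oracle.is_a(a, b)

    algorithms = sorted(oracle.branch_members("algorithm"))
    chars = sorted(oracle.branch_members("characteristic"))
    params = sorted(oracle.branch_members("parameter"))

    alg_sample = algorithms if len(algorithms) <= 60 else sorted(rng.sample(algorithms, 40))
    for a in alg_sample:
        assert inference.inferred_characteristics(graph, a) == oracle.characteristics(a)
        assert inference.inferred_parameters(graph, a) == set(oracle.parameters(a))
        assert queries.parameters_of(graph, a) == set(oracle.parameters(a))
        assert queries.hybrid_of(graph, a) == set(oracle.hybrid_parts(a))
        assert queries.is_hybrid(graph, a) == bool(oracle.hybrid_parts(a))
    for p in params:
        assert queries.parameter_type(graph, p) == oracle.parameter_type(p)

    if len(algorithms) >= 2:
        for _ in range(min(150, len(algorithms) ** 2)):
            a, b = rng.choice(algorithms), rng.choice(algorithms)
            assert inference.hierarchy_distance(graph, a, b) == oracle.distance(a, b)

    for _ in range(10):
        selection = rng.sample(chars, rng.randint(0, min(3, len(chars))))
        assert queries.algorithms_by_characteristics(graph, selection, "possess") \
            == oracle.possess(selection)
        assert queries.algorithms_by_characteristics(graph, selection, "lack") \
            == oracle.lack(selection)
        assert queries.parameters_by_characteristics(graph, selection) \
            == oracle.parameters_by_characteristics(selection)
        if algorithms:
            anc = rng.choice(algorithms)
            assert queries.parameters_by_characteristics(graph, selection, anc) \
                == oracle.parameters_by_characteristics(selection, anc)
        if params:
            wanted = rng.sample(params, rng.randint(1, min(2, len(params))))
            assert queries.has_parameter(graph, selection, wanted) \
                == (set(wanted) <= oracle.parameters_by_characteristics(selection))

    for a in alg_sample[:12]:
        for type_filter in (None, rng.sample(chars, min(2, len(chars)))):
            assert queries.characteristics_of(graph, a, type_filter) \
                == oracle.filtered_profile(a, type_filter)
            assert queries.algorithms_with_same_characteristics(graph, a, type_filter) \
                == oracle.same_characteristics(a, type_filter)
            n = rng.randint(0, 6)
            got = queries.n_most_similar(graph, a, n, type_filter)
            assert [(r.algorithm, r.distance) for r in got] \
                == oracle.n_most_similar(a, n, type_filter)
        if chars:
            selection = rng.sample(chars, rng.randint(1, min(3, len(chars))))
            assert queries.has_characteristic(graph, a, selection) \
                == all(c in oracle.characteristics(a) for c in selection)
        if params:
            wanted = [rng.choice(params)]
            assert queries.has_parameter(graph, a, wanted) \
                == (set(wanted) <= oracle.parameters(a))

    for tid in sample_terms[:15]:
        label = manifest.terms[tid].label
        if label:
            assert tid in {t.id for t in queries.search_by_name(graph, label.upper())}
        for text, _scope in manifest.terms[tid].synonyms:
            assert tid in {t.id for t in queries.search_by_name(graph, text)}

    if chars or params:
        for _ in range(5):
            expr = random_expression(rng, chars[:10], params[:10])
            assert queries.algorithms_by_query(graph, expr.render()) \
                == oracle.evaluate_query(expr)
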