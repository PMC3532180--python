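"""The query API: paper-fixture facts, the boolean query language, result
invariants, and full agreement with the brute-force manifest oracles."""

import random

import pytest

from kisaoquery import (
    QuerySyntaxError,
    TermId,
    UnknownTermError,
    WrongBranchError,
    fixtures,
    inference,
    queries,
)
from kisaoquery.fixtures import FixtureManifest, TermRecord, write_owl
from kisaoquery.owl_io import load_ontology

from checks import check_queries_against_oracle
from oracles import ManifestOracle

TAU_FAMILY = {
    fixtures.TAU_LEAPING,
    fixtures.POISSON_TAU_LEAPING,
    fixtures.BINOMIAL_TAU_LEAPING,
    fixtures.MULTINOMIAL_TAU_LEAPING,
    fixtures.IMPLICIT_TAU_LEAPING,
}


# -- taxonomy level ----------------------------------------------------------


def test_list_algorithms_includes_tau_leaping_and_lsode(paper_case):
    listed = queries.list_terms(paper_case.graph, "algorithm")
    labels = {t.label for t in listed}
    assert "tau-leaping method" in labels
    assert "LSODE" in labels
    assert [t.id for t in listed] == sorted(t.id for t in listed)


def test_list_terms_empty_ontology():
    graph_manifest = fixtures.random_manifest(0, 0, 0, seed=1)
    import tempfile
    from pathlib import Path

    with tempfile.TemporaryDirectory() as tmp:
        graph = load_ontology(write_owl(graph_manifest, Path(tmp) / "roots.owl"))
    # only the branch roots themselves remain
    assert [t.id for t in queries.list_terms(graph, "algorithm")] \
        == [graph.config.algorithm_root]


def test_term_kind_of_paper_terms(paper_case):
    graph = paper_case.graph
    assert queries.term_kind(graph, fixtures.TAU_LEAPING) == "algorithm"
    assert queries.term_kind(graph, fixtures.TAU_LEAPING_EPSILON) == "parameter"
    assert queries.is_characteristic(graph, fixtures.STOCHASTIC_BEHAVIOUR)
    # branch roots belong to their own branch
    assert queries.is_algorithm(graph, graph.config.algorithm_root)
    assert queries.is_parameter(graph, graph.config.parameter_root)


def test_search_by_id_accepts_every_form(paper_case):
    graph = paper_case.graph
    for text in (
        "KISAO:0000039",
        "kisao:0000039",
        "KISAO_0000039",
        "urn:miriam:biomodels.kisao:KISAO_0000039",
        "http://www.biomodels.net/kisao/KISAO#KISAO_0000039",
    ):
        assert queries.search_by_id(graph, text).label == "tau-leaping method"
    with pytest.raises(UnknownTermError):
        queries.search_by_id(graph, "kisao:7654321")


def test_search_by_name_matches_labels_and_synonyms(paper_case):
    graph = paper_case.graph
    assert {t.id for t in queries.search_by_name(graph, "tauL")} == {fixtures.TAU_LEAPING}
    assert {t.id for t in queries.search_by_name(graph, "TAU-LEAPING METHOD")} \
        == {fixtures.TAU_LEAPING}
    assert queries.search_by_name(graph, "no such algorithm") == set()
    substr = {t.id for t in queries.search_by_name(graph, "tau-leaping", substring=True)}
    assert TAU_FAMILY | {fixtures.TAU_LEAPING_EPSILON} <= substr


def test_annotations_bundle(paper_case):
    graph = paper_case.graph
    bundle = queries.annotations(graph, fixtures.TAU_LEAPING)
    assert bundle.label == "tau-leaping method"
    assert "tauL" in {s.text for s in bundle.synonyms}
    assert bundle.definition and "tau" in bundle.definition
    assert bundle.links == {"doi:10.1063/1.1378322"}
    assert bundle.deprecated is False
    assert queries.synonyms(graph, fixtures.TAU_LEAPING, "exact") == {"tauL"}
    assert queries.synonyms(graph, fixtures.TAU_LEAPING, "broad") == frozenset()
    # a bare term has empty annotations and is not deprecated
    plain = queries.annotations(graph, fixtures.BINOMIAL_TAU_LEAPING)
    assert plain.definition is None and plain.links == frozenset()
    assert plain.deprecated is False


# -- characteristics ---------------------------------------------------------


def test_characteristics_of_with_type_filter(paper_case):
    graph = paper_case.graph
    filtered = queries.characteristics_of(
        graph, fixtures.POISSON_TAU_LEAPING, [fixtures.TYPE_OF_SYSTEM_BEHAVIOUR]
    )
    assert filtered == {fixtures.STOCHASTIC_BEHAVIOUR}
    assert queries.characteristics_of(graph, fixtures.POISSON_TAU_LEAPING, []) == frozenset()
    with pytest.raises(UnknownTermError):
        queries.characteristics_of(graph, fixtures.POISSON_TAU_LEAPING, [TermId("1234567")])
    with pytest.raises(WrongBranchError):
        queries.characteristics_of(graph, fixtures.POISSON_TAU_LEAPING, [fixtures.LSODE])


def test_has_characteristic(paper_case):
    graph = paper_case.graph
    assert queries.has_characteristic(
        graph, fixtures.POISSON_TAU_LEAPING, fixtures.STOCHASTIC_BEHAVIOUR
    )
    assert not queries.has_characteristic(
        graph, fixtures.LSODE, fixtures.STOCHASTIC_BEHAVIOUR
    )
    # vacuous conjunction
    assert queries.has_characteristic(graph, fixtures.LSODE, [])


def test_algorithms_by_characteristics_possess_and_lack(paper_case):
    graph = paper_case.graph
    stochastic = queries.algorithms_by_characteristics(
        graph, [fixtures.STOCHASTIC_BEHAVIOUR], "possess"
    )
    assert stochastic == TAU_FAMILY
    lacking = queries.algorithms_by_characteristics(
        graph, [fixtures.STOCHASTIC_BEHAVIOUR], "lack"
    )
    live = {t.id for t in queries.list_terms(graph, "algorithm") if not t.deprecated}
    assert stochastic | lacking == live
    assert stochastic & lacking == set()
    # having a child characteristic counts as having the parent
    behaved = queries.algorithms_by_characteristics(
        graph, [fixtures.TYPE_OF_SYSTEM_BEHAVIOUR], "possess"
    )
    assert behaved == TAU_FAMILY | {fixtures.LSODE}


def test_same_characteristics_finds_the_tau_family(paper_case):
    graph = paper_case.graph
    same = queries.algorithms_with_same_characteristics(
        graph,
        fixtures.POISSON_TAU_LEAPING,
        [fixtures.TYPE_OF_SYSTEM_BEHAVIOUR, fixtures.TYPE_OF_VARIABLE],
    )
    assert same == TAU_FAMILY - {fixtures.POISSON_TAU_LEAPING}
    # LSODE's deterministic/continuous profile is unique in the fixture
    assert queries.algorithms_with_same_characteristics(graph, fixtures.LSODE) == set()


def test_n_most_similar_reproduces_worked_example(paper_case):
    graph = paper_case.graph
    ranked = queries.n_most_similar(
        graph,
        fixtures.POISSON_TAU_LEAPING,
        4,
        [fixtures.TYPE_OF_SYSTEM_BEHAVIOUR, fixtures.TYPE_OF_VARIABLE],
    )
    assert len(ranked) == 4
    assert ranked[0].algorithm == fixtures.TAU_LEAPING and ranked[0].distance == 1
    assert {(r.algorithm, r.distance) for r in ranked[1:]} == {
        (fixtures.BINOMIAL_TAU_LEAPING, 2),
        (fixtures.MULTINOMIAL_TAU_LEAPING, 2),
        (fixtures.IMPLICIT_TAU_LEAPING, 2),
    }
    assert queries.n_most_similar(graph, fixtures.POISSON_TAU_LEAPING, 0) == []
    with pytest.raises(ValueError):
        queries.n_most_similar(graph, fixtures.POISSON_TAU_LEAPING, -1)


def test_similarity_self_exclusion_and_ranking_soundness(small_fleet):
    rng = random.Random(99)
    for case in small_fleet:
        algorithms = sorted(
            t for t, term in case.graph.terms.items() if term.branch == "algorithm"
        )
        for alg in algorithms[:8]:
            full = queries.n_most_similar(case.graph, alg, len(algorithms))
            assert all(r.algorithm != alg for r in full)
            keys = [r.sort_key for r in full]
            assert keys == sorted(keys)
            n = rng.randint(0, max(0, len(full) - 1))
            truncated = queries.n_most_similar(case.graph, alg, n)
            assert [r.algorithm for r in truncated] == [r.algorithm for r in full[:n]]


# -- boolean queries ---------------------------------------------------------


def test_query_atom_equals_possess(paper_case):
    graph = paper_case.graph
    by_query = queries.algorithms_by_query(
        graph, f"has_characteristic({fixtures.STOCHASTIC_BEHAVIOUR.short})"
    )
    assert by_query == queries.algorithms_by_characteristics(
        graph, [fixtures.STOCHASTIC_BEHAVIOUR], "possess"
    )


def test_query_not_is_closed_world_complement(paper_case):
    graph = paper_case.graph
    atom = f"has_characteristic({fixtures.STOCHASTIC_BEHAVIOUR.short})"
    live = {t.id for t in queries.list_terms(graph, "algorithm") if not t.deprecated}
    assert queries.algorithms_by_query(graph, f"NOT {atom}") \
        == live - queries.algorithms_by_query(graph, atom)


def test_query_grammar_accepts_labels_keywords_and_parens(paper_case):
    graph = paper_case.graph
    result = queries.algorithms_by_query(
        graph,
        '( has_characteristic("stochastic system behaviour") '
        f"and has_parameter({fixtures.TAU_LEAPING_EPSILON.short}) ) "
        f"OR has_characteristic({fixtures.DETERMINISTIC_BEHAVIOUR.short})",
    )
    assert result == TAU_FAMILY | {fixtures.LSODE}
    # AND binds tighter than OR
    a = f"has_characteristic({fixtures.DETERMINISTIC_BEHAVIOUR.short})"
    b = f"has_characteristic({fixtures.STOCHASTIC_BEHAVIOUR.short})"
    c = f"has_parameter({fixtures.TAU_LEAPING_EPSILON.short})"
    assert queries.algorithms_by_query(graph, f"{a} OR {b} AND {c}") \
        == queries.algorithms_by_query(graph, f"{a} OR ({b} AND {c})")


@pytest.mark.parametrize(
    "bad",
    [
        "",
        "AND has_characteristic(kisao:9100002)",
        "has_characteristic(kisao:9100002",
        "has_characteristic(kisao:1234567)",  # unknown term
        "has_characteristic(kisao:0000071)",  # wrong branch
        'has_characteristic("no such label")',
        "frobnicate(kisao:9100002)",
        "has_characteristic(kisao:9100002) extra",
    ],
)
def test_query_grammar_rejects_malformed(paper_case, bad):
    with pytest.raises(QuerySyntaxError):
        queries.algorithms_by_query(paper_case.graph, bad)


# -- parameters and hybrids --------------------------------------------------


def test_parameters_and_types(paper_case):
    graph = paper_case.graph
    assert queries.parameters_of(graph, fixtures.TAU_LEAPING) \
        == {fixtures.TAU_LEAPING_EPSILON}
    assert queries.parameter_type(graph, fixtures.TAU_LEAPING_EPSILON) == "double"
    assert queries.parameters_of(graph, fixtures.LSODE) == frozenset()
    with pytest.raises(WrongBranchError):
        queries.parameter_type(graph, fixtures.TAU_LEAPING)


def test_untyped_parameter_reports_absent_type(tmp_path):
    cfg_manifest = fixtures.random_manifest(1, 0, 1, seed=5)
    # strip any has_type axioms
    stripped = FixtureManifest(
        terms=cfg_manifest.terms,
        edges=cfg_manifest.edges,
        links=frozenset(row for row in cfg_manifest.links if row[1] != "has_type"),
        config=cfg_manifest.config,
    )
    graph = load_ontology(write_owl(stripped, tmp_path / "untyped.owl"))
    parameter = next(
        t for t, term in graph.terms.items()
        if term.branch == "parameter" and t != graph.config.parameter_root
    )
    assert queries.parameter_type(graph, parameter) is None


def test_parameters_by_characteristics_and_has_parameter(paper_case):
    graph = paper_case.graph
    tau_profile = [fixtures.STOCHASTIC_BEHAVIOUR, fixtures.DISCRETE_VARIABLE]
    assert queries.parameters_by_characteristics(graph, tau_profile) \
        == {fixtures.TAU_LEAPING_EPSILON}
    # no algorithm possesses both stochastic and deterministic behaviour
    assert queries.parameters_by_characteristics(
        graph, [fixtures.STOCHASTIC_BEHAVIOUR, fixtures.DETERMINISTIC_BEHAVIOUR]
    ) == frozenset()
    assert queries.parameters_by_characteristics(
        graph, tau_profile, ancestor=fixtures.TAU_LEAPING
    ) == {fixtures.TAU_LEAPING_EPSILON}
    assert queries.has_parameter(graph, fixtures.TAU_LEAPING, fixtures.TAU_LEAPING_EPSILON)
    assert not queries.has_parameter(graph, fixtures.LSODE, fixtures.TAU_LEAPING_EPSILON)
    assert queries.has_parameter(graph, tau_profile, fixtures.TAU_LEAPING_EPSILON)


def test_hybrid_links_are_inherited(tmp_path):
    from kisaoquery.config import OntologyConfig

    cfg = OntologyConfig()
    a, b, c, child = (TermId(f"900000{i}") for i in range(1, 5))
    manifest = FixtureManifest(
        terms={
            cfg.algorithm_root: TermRecord("simulation algorithm"),
            cfg.characteristic_root: TermRecord("simulation algorithm characteristic"),
            cfg.parameter_root: TermRecord("simulation algorithm parameter"),
            a: TermRecord("hybrid solver"),
            b: TermRecord("part one"),
            c: TermRecord("part two"),
            child: TermRecord("specialised hybrid solver"),
        },
        edges=frozenset({
            (a, cfg.algorithm_root), (b, cfg.algorithm_root),
            (c, cfg.algorithm_root), (child, a),
        }),
        links=frozenset({(a, "is_hybrid_of", b), (a, "is_hybrid_of", c)}),
        config=cfg,
    )
    graph = load_ontology(write_owl(manifest, tmp_path / "hybrid.owl"))
    assert queries.is_hybrid(graph, a)
    assert queries.hybrid_of(graph, a) == {b, c}
    # subclasses inherit the hybrid decomposition
    assert queries.hybrid_of(graph, child) == {b, c}
    assert not queries.is_hybrid(graph, b)
    assert queries.hybrid_of(graph, b) == frozenset()


def test_paper_fixture_has_no_hybrids(paper_case):
    assert not queries.is_hybrid(paper_case.graph, fixtures.TAU_LEAPING)


# -- deprecated handling -----------------------------------------------------


def test_deprecated_algorithms_resolvable_but_never_candidates(tmp_path):
    from kisaoquery.config import OntologyConfig

    cfg = OntologyConfig()
    live, dead = TermId("9000001"), TermId("9000002")
    char = TermId("9100001")
    manifest = FixtureManifest(
        terms={
            cfg.algorithm_root: TermRecord("simulation algorithm"),
            cfg.characteristic_root: TermRecord("simulation algorithm characteristic"),
            cfg.parameter_root: TermRecord("simulation algorithm parameter"),
            live: TermRecord("live solver"),
            dead: TermRecord("legacy solver", deprecated=True),
            char: TermRecord("some characteristic"),
        },
        edges=frozenset({
            (live, cfg.algorithm_root), (dead, cfg.algorithm_root),
            (char, cfg.characteristic_root),
        }),
        links=frozenset({
            (live, "has_characteristic", char), (dead, "has_characteristic", char),
        }),
        config=cfg,
    )
    graph = load_ontology(write_owl(manifest, tmp_path / "dep.owl"))
    # still resolvable, flagged
    assert queries.search_by_id(graph, dead.short).deprecated
    assert dead in {t.id for t in queries.list_terms(graph, "algorithm")}
    # excluded from every application-level result set
    assert dead not in queries.algorithms_by_characteristics(graph, [char], "possess")
    assert dead not in queries.algorithms_by_characteristics(graph, [char], "lack")
    assert queries.algorithms_with_same_characteristics(graph, live) == set()
    assert queries.algorithms_by_query(graph, f"has_characteristic({char.short})") == {live}


# -- the central oracle check ------------------------------------------------


def test_every_query_matches_manifest_oracle_on_small_fleet(small_fleet):
    for case in small_fleet:
        check_queries_against_oracle(case.manifest, case.graph, seed=case.manifest.seed or 0)


def test_possess_lack_partition_on_small_fleet(small_fleet):
    rng = random.Random(13)
    for case in small_fleet:
        oracle = ManifestOracle(case.manifest)
        chars = sorted(oracle.branch_members("characteristic"))
        live = oracle.live_algorithms()
        for _ in range(5):
            selection = rng.sample(chars, rng.randint(0, min(3, len(chars))))
            possess = queries.algorithms_by_characteristics(case.graph, selection, "possess")
            lack = queries.algorithms_by_characteristics(case.graph, selection, "lack")
            assert possess | lack == live
            assert possess & lack == set()


def test_filter_monotonicity_against_bruteforce(small_fleet):
    # enlarging the type filter refines the profile, so the candidate set can
    # only shrink or stay equal when computed by brute force on both sides
    rng = random.Random(31)
    for case in small_fleet:
        oracle = ManifestOracle(case.manifest)
        algorithms = sorted(oracle.branch_members("algorithm"))
        chars = sorted(oracle.branch_members("characteristic"))
        if not algorithms or len(chars) < 2:
            continue
        for _ in range(5):
            alg = rng.choice(algorithms)
            base = rng.sample(chars, 1)
            bigger = base + [c for c in rng.sample(chars, 2) if c not in base]
            with_base = queries.algorithms_with_same_characteristics(case.graph, alg, base)
            with_more = queries.algorithms_with_same_characteristics(case.graph, alg, bigger)
            assert with_base == oracle.same_characteristics(alg, base)
            assert with_more == oracle.same_characteristics(alg, bigger)
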