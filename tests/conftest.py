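"""Shared fixtures: the deterministic tau-leaping/LSODE ontology and a fleet
of seeded random ontologies (each with its ground-truth manifest), all written
to disk and re-loaded through the OWL parser so every test exercises the full
serialize → parse path."""

from __future__ import annotations

import random
from typing import NamedTuple

import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, max_examples=150)
settings.load_profile("deterministic")

from kisaoquery import fixtures, load_ontology  # noqa: E402
from kisaoquery.fixtures import FixtureManifest  # noqa: E402
from kisaoquery.model import OntologyGraph  # noqa: E402


class Case(NamedTuple):
    manifest: FixtureManifest
    graph: OntologyGraph
    path: object  # pathlib.Path of the OWL file


def fleet_specs() -> list[tuple]:
    """(seed, n_alg, n_char, n_par, max_parents, link_density, deprecated_fraction)
    for 50 random fixtures: mostly small, a few at the large end."""
    specs = []
    for seed in range(50):
        rng = random.Random(9000 + seed)
        if seed < 42:
            sizes = (rng.randint(0, 30), rng.randint(0, 10), rng.randint(0, 8))
            density = rng.choice((0.05, 0.1, 0.2, 0.3))
        elif seed < 47:
            sizes = (rng.randint(40, 120), rng.randint(10, 30), rng.randint(5, 15))
            density = rng.choice((0.05, 0.1))
        elif seed < 49:
            sizes = (150, 40, 25)
            density = 0.05
        else:
            sizes = (200, 60, 40)
            density = 0.05
        specs.append(
            (seed, *sizes, rng.randint(1, 3), density, rng.choice((0.0, 0.1, 0.2)))
        )
    return specs


def build_case(spec: tuple, directory) -> Case:
    seed, n_alg, n_char, n_par, max_parents, density, deprecated = spec
    manifest = fixtures.random_manifest(
        n_alg, n_char, n_par,
        max_parents=max_parents, link_density=density,
        deprecated_fraction=deprecated, seed=seed,
    )
    path = directory / f"fixture_{seed}.owl"
    fixtures.write_owl(manifest, path)
    return Case(manifest, load_ontology(path), path)


@pytest.fixture(scope="session")
def paper_case(tmp_path_factory) -> Case:
    directory = tmp_path_factory.mktemp("paper")
    path = directory / "paper.owl"
    manifest = fixtures.generate_paper_fixture(path)
    return Case(manifest, load_ontology(path), path)


@pytest.fixture(scope="session")
def fleet(tmp_path_factory) -> list[Case]:
    directory = tmp_path_factory.mktemp("fleet")
    return [build_case(spec, directory) for spec in fleet_specs()]


@pytest.fixture(scope="session")
def small_fleet(fleet) -> list[Case]:
    """The first dozen (small) fixtures, for cheaper per-module tests."""
    return fleet[:12]
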