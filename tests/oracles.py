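"""Brute-force oracles computed straight from a FixtureManifest.

`ManifestOracle` answers every query the package implements using only the
generator's ground-truth tables (term records, subclass-edge pairs, link
rows) via naive repeated expansion, breadth-first search and truth-table
evaluation — deliberately independent of the package's networkx-backed
index, so agreement is evidence, not tautology.  Results are memoized per
oracle instance; memoization changes speed, not the algorithm.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

from kisaoquery.fixtures import FixtureManifest
from kisaoquery.identifiers import TermId


class ManifestOracle:
    def __init__(self, manifest: FixtureManifest):
        self.m = manifest
        self._up: dict[TermId, frozenset[TermId]] = {}
        self._down: dict[TermId, frozenset[TermId]] = {}
        self._chars: dict[TermId, frozenset[TermId]] = {}
        self._branches: dict[str, frozenset[TermId]] | None = None
        self._adjacency: dict[TermId, set[TermId]] | None = None

    # -- hierarchy ----------------------------------------------------------

    def reach_up(self, node: TermId) -> frozenset[TermId]:
        """Transitive superclasses by repeated edge expansion to a fixpoint."""
        if node not in self._up:
            found: set[TermId] = set()
            frontier = {node}
            while frontier:
                step = {p for c, p in self.m.edges if c in frontier}
                frontier = step - found
                found |= step
            self._up[node] = frozenset(found - {node})
        return self._up[node]

    def reach_down(self, node: TermId) -> frozenset[TermId]:
        if node not in self._down:
            found: set[TermId] = set()
            frontier = {node}
            while frontier:
                step = {c for c, p in self.m.edges if p in frontier}
                frontier = step - found
                found |= step
            self._down[node] = frozenset(found - {node})
        return self._down[node]

    def direct_parents(self, node: TermId) -> set[TermId]:
        return {p for c, p in self.m.edges if c == node}

    def direct_children(self, node: TermId) -> set[TermId]:
        return {c for c, p in self.m.edges if p == node}

    def is_a(self, descendant: TermId, ancestor: TermId) -> bool:
        return descendant == ancestor or ancestor in self.reach_up(descendant)

    # -- branches -----------------------------------------------------------

    def branch_of(self, node: TermId) -> str:
        above = set(self.reach_up(node)) | {node}
        hits = [
            name
            for name, root in (
                ("algorithm", self.m.config.algorithm_root),
                ("characteristic", self.m.config.characteristic_root),
                ("parameter", self.m.config.parameter_root),
            )
            if root in above
        ]
        assert len(hits) <= 1, f"{node} reaches two branch roots"
        return hits[0] if hits else "other"

    def branch_members(self, branch: str) -> frozenset[TermId]:
        if self._branches is None:
            table: dict[str, set[TermId]] = {
                "algorithm": set(), "characteristic": set(), "parameter": set(), "other": set()
            }
            for t in self.m.terms:
                table[self.branch_of(t)].add(t)
            self._branches = {k: frozenset(v) for k, v in table.items()}
        return self._branches[branch]

    def live_algorithms(self) -> set[TermId]:
        return {t for t in self.branch_members("algorithm") if not self.m.terms[t].deprecated}

    # -- inferred links -----------------------------------------------------

    def characteristics(self, algorithm: TermId) -> frozenset[TermId]:
        """Fixpoint inference: asserted on the algorithm or any superclass,
        then closed upward within the characteristic branch."""
        if algorithm not in self._chars:
            subjects = set(self.reach_up(algorithm)) | {algorithm}
            asserted = {
                o for s, rel, o in self.m.links
                if rel == "has_characteristic" and s in subjects
            }
            char_branch = self.branch_members("characteristic")
            closed = set(asserted)
            for c in asserted:
                closed |= self.reach_up(c) & char_branch
            self._chars[algorithm] = frozenset(closed)
        return self._chars[algorithm]

    def parameters(self, algorithm: TermId) -> set[TermId]:
        subjects = set(self.reach_up(algorithm)) | {algorithm}
        return {o for s, rel, o in self.m.links if rel == "has_parameter" and s in subjects}

    def hybrid_parts(self, algorithm: TermId) -> set[TermId]:
        subjects = set(self.reach_up(algorithm)) | {algorithm}
        return {o for s, rel, o in self.m.links if rel == "is_hybrid_of" and s in subjects}

    def parameter_type(self, parameter: TermId) -> str | None:
        declared = sorted(
            o for s, rel, o in self.m.links if rel == "has_type" and s == parameter
        )
        return declared[0] if declared else None

    # -- distance -----------------------------------------------------------

    def distance(self, a: TermId, b: TermId) -> int | None:
        """BFS shortest undirected subclass path within the algorithm branch."""
        if self._adjacency is None:
            nodes = self.branch_members("algorithm")
            self._adjacency = {n: set() for n in nodes}
            for c, p in self.m.edges:
                if c in nodes and p in nodes:
                    self._adjacency[c].add(p)
                    self._adjacency[p].add(c)
        seen = {a: 0}
        queue = deque([a])
        while queue:
            cur = queue.popleft()
            if cur == b:
                return seen[cur]
            for nxt in self._adjacency[cur]:
                if nxt not in seen:
                    seen[nxt] = seen[cur] + 1
                    queue.append(nxt)
        return None

    # -- application-level queries ------------------------------------------

    def filtered_profile(self, algorithm: TermId, type_filter) -> set[TermId]:
        profile = set(self.characteristics(algorithm))
        if type_filter is None:
            return profile
        allowed: set[TermId] = set()
        for t in type_filter:
            allowed |= self.reach_down(t)
        return profile & allowed

    def possess(self, chars) -> set[TermId]:
        return {
            a for a in self.live_algorithms()
            if all(c in self.characteristics(a) for c in chars)
        }

    def lack(self, chars) -> set[TermId]:
        return {
            a for a in self.live_algorithms()
            if any(c not in self.characteristics(a) for c in chars)
        }

    def same_characteristics(self, algorithm: TermId, type_filter) -> set[TermId]:
        reference = self.filtered_profile(algorithm, type_filter)
        return {
            a for a in self.live_algorithms()
            if a != algorithm and self.filtered_profile(a, type_filter) == reference
        }

    def n_most_similar(self, algorithm: TermId, n: int, type_filter):
        candidates = self.same_characteristics(algorithm, type_filter)
        ranked = sorted(
            ((self.distance(algorithm, c), c) for c in candidates),
            key=lambda pair: (pair[0] is None, pair[0] or 0, int(pair[1])),
        )
        return [(c, d) for d, c in ranked[:n]]

    def parameters_by_characteristics(self, chars, ancestor=None) -> set[TermId]:
        matching = self.possess(chars)
        if ancestor is not None:
            matching = {a for a in matching if self.is_a(a, ancestor)}
        out: set[TermId] = set()
        for a in matching:
            out |= self.parameters(a)
        return out

    def evaluate_query(self, expr) -> set[TermId]:
        return {a for a in self.live_algorithms() if expr.truth(self, a)}


# -- random boolean query expressions ---------------------------------------


@dataclass(frozen=True)
class QAtom:
    kind: str  # "characteristic" | "parameter"
    term: TermId

    def truth(self, oracle: ManifestOracle, algorithm: TermId) -> bool:
        pool = (
            oracle.characteristics(algorithm)
            if self.kind == "characteristic"
            else oracle.parameters(algorithm)
        )
        return self.term in pool

    def render(self) -> str:
        return f"has_{self.kind}({self.term.short})"


@dataclass(frozen=True)
class QNot:
    operand: object

    def truth(self, oracle, algorithm) -> bool:
        return not self.operand.truth(oracle, algorithm)

    def render(self) -> str:
        return f"NOT ({self.operand.render()})"


@dataclass(frozen=True)
class QBin:
    op: str  # "AND" | "OR"
    left: object
    right: object

    def truth(self, oracle, algorithm) -> bool:
        left = self.left.truth(oracle, algorithm)
        right = self.right.truth(oracle, algorithm)
        return (left and right) if self.op == "AND" else (left or right)

    def render(self) -> str:
        return f"({self.left.render()}) {self.op} ({self.right.render()})"


def random_expression(rng, chars: list[TermId], params: list[TermId], depth: int = 3):
    """A random query AST over the given characteristic/parameter pools."""
    atoms = [("characteristic", c) for c in chars] + [("parameter", p) for p in params]
    assert atoms
    if depth == 0 or rng.random() < 0.3:
        kind, term = rng.choice(atoms)
        return QAtom(kind, term)
    choice = rng.random()
    if choice < 0.3:
        return QNot(random_expression(rng, chars, params, depth - 1))
    op = "AND" if choice < 0.65 else "OR"
    return QBin(
        op,
        random_expression(rng, chars, params, depth - 1),
        random_expression(rng, chars, params, depth - 1),
    )
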