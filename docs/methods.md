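# Methods

## The ontology model

A KiSAO-shaped ontology has three class branches — simulation algorithms,
algorithm characteristics, algorithm parameters — connected by subclass
axioms and by existential restrictions: `algorithm subClassOf
(hasCharacteristic some characteristic)`, `... hasParameter some parameter`,
`... isHybridOf some algorithm`, and `parameter subClassOf (hasType some
xsd:datatype)`. Terms carry OBO-in-OWL annotations: a label, synonyms in
four scopes (exact, related, broad, narrow), a definition, literature
cross-references and an `owl:deprecated` flag.

`load_ontology` parses RDF/XML (Turtle is accepted too, since the RDF
parser handles it transparently) and indexes exactly these constructs.
Branch membership is structural: a class belongs to the branch whose
configured root it reaches by following `subClassOf` upward; roots belong to
their own branch; a class reaching no root is branch `other`; a class
reaching two roots is a hard format error, as are subclass cycles. Branch
roots, link-property IRIs and annotation-property IRIs are configuration
(INI file, documented in `config.py`) with defaults matching KiSAO releases;
anything else found in the file — restrictions over unlisted properties,
unions, non-KiSAO IRIs — is logged with its subject IRI and skipped, so the
loader degrades gracefully as the ontology evolves.

Identifiers are strict: exactly seven decimal digits, accepted in four
interchangeable spellings with case-insensitive prefixes. Ids with extra or
missing digits are rejected, never truncated, because truncation can alias
distinct terms.

## Reasoning

Full OWL 2 DL reasoning is unnecessary for this fragment; the package
computes the entailments the structure licenses directly (networkx supplies
the graph algorithms):

* **Closures.** Ancestor/descendant sets are transitive closures of the
  subclass DAG. Multiple superclasses are permitted throughout.
* **Inheritance.** An existential restriction asserted on a class holds for
  all its subclasses, so an algorithm's inferred characteristics, parameters
  and hybrid parts are the union of the assertions on it and on all its
  ancestors.
* **Upward entailment of characteristics.** Possessing a characteristic
  entails possessing every characteristic-branch superclass of it
  (stochastic system behaviour ⟹ type of system behaviour). Parameters are
  deliberately *not* generalised upward: using a specific parameter does not
  mean the algorithm uses every generalisation of it.
* **Closed-world negation.** "Lacks characteristic c" and query `NOT` mean
  "c is not in the inferred set", evaluated over non-deprecated algorithms.
  Open-world negation would require full DL reasoning and answers the wrong
  question for tool-capability matching.

All indexes are computed eagerly when a file is loaded and cached;
KiSAO-sized ontologies (hundreds of classes) make this negligible.

## Similarity and substitute selection

Candidate substitutes for algorithm *a* are the non-deprecated algorithms
whose inferred characteristic profile — optionally restricted to the
descendants of chosen characteristic *types*, e.g. "compare only behaviour
and variable type" — is set-equal to *a*'s. Equality rather than overlap is
used because a method differing in any considered characteristic is not an
equivalent for the simulation at hand; subset-style matching is available
separately through `algorithms_by_characteristics`.

Candidates are ranked by **hierarchy distance**: the length of the shortest
undirected `subClassOf` path between the two classes, restricted to the
algorithm branch (including its root). On a DAG with multiple parents the
minimum over paths is taken; two algorithms in disconnected components are
reported unreachable and sort last. This makes a direct parent (distance 1)
rank above a sibling (distance 2), matching the intuition that the parent
class is the most faithful generalisation. Ties at equal distance are broken
by ascending numeric id — a documented, deterministic choice; nothing deeper
than determinism is claimed for it. The query algorithm itself is never
returned. All characteristics are weighted equally; prioritising
characteristic types is out of scope.

Deprecated terms participate in closures and stay resolvable by id and name
(legacy simulation descriptions must keep working) but are excluded from
every candidate or result set, since a proposed substitute must be a live
term.

The CLI's `resolve-substitute` takes the requested algorithm plus a file of
locally implemented ones. If the requested method is itself available it is
returned (distance 0). Otherwise profile-matching candidates are preferred;
when none of the available methods matches the profile, the command falls
back to the nearest available algorithm by hierarchy distance alone and says
so on stderr — a pragmatic default for the case the selection workflow
leaves open, chosen so the tool always proposes something actionable rather
than failing.

## The query language

`algorithms_by_query` evaluates infix boolean expressions:
`has_characteristic(ref)` and `has_parameter(ref)` atoms (`ref` is any
identifier form or a double-quoted label resolving to exactly one term of
the right branch), `AND`/`OR`/`NOT` case-insensitive with the usual
precedence (NOT > AND > OR), and parentheses; whitespace is free. Atoms are
resolved at parse time so unknown or wrong-branch references fail fast.

## Fixture generators

The package ships two generators rather than bundling ontology files.

The **deterministic fixture** encodes the tau-leaping/LSODE scenario: the
tau-leaping method (`kisao:0000039`, exact synonym `tauL`) with Poisson,
binomial, multinomial and implicit subclasses, characteristics *type of
system behaviour* ⊇ {stochastic, deterministic} and *type of variable* ⊇
{discrete, continuous}, the tau-leaping family linked (on the parent, so the
variants inherit) to stochastic/discrete, LSODE to
deterministic/continuous, and the `tau-leaping epsilon` parameter
(`has_parameter` from 0000039, `has_type double`). Classes without an
established public id use a reserved synthetic range (9000001+ algorithms,
9100001+ characteristics, 9200001+ parameters) so nothing real is shadowed.

The **random generator** builds each branch as a rooted DAG (every class
reaches its root; up to `max_parents` superclasses, default 2), links each
algorithm to each characteristic with probability `link_density` (default
0.15; parameters at 70 % of that), makes ~15 % of algorithms hybrids, types
80 % of parameters, and samples labels, typed synonyms, definitions,
cross-references and a `deprecated_fraction` (default 0.1) of deprecated
terms. The same seed always yields the same manifest and — because the OWL
writer emits fully sorted RDF/XML — byte-identical files. The writer is
deliberately template-based for this reason; parsing always goes through
rdflib, so writer and parser check each other.

Both generators return a *manifest*: the exact term/edge/link tables the
file encodes, also writable as TSV. The manifests are what the test suite's
brute-force oracles (naive reachability fixpoints, BFS distances,
truth-table query evaluation — independent of the package's index) compute
from.

What the random fixtures do **not** emulate: the real KiSAO's class names,
its specific topology and annotation style, multilingual labels, or any
OWL construct outside the fragment above. Passing tests therefore
demonstrate correctness of parsing, inference and querying on
KiSAO-*shaped* inputs, not coverage of every artefact a real release might
contain; loading a real release remains subject to the skip-and-log policy.

## Problem sizes and numerical choices

The oracle suite checks 50 seeded fixtures — most with up to 30 algorithms,
several in the 40–150 range, one at 200 algorithms / 60 characteristics /
40 parameters — chosen as comfortably bracketing real KiSAO's size while
keeping the whole suite in seconds. Exhaustive checks are used on small
fixtures and deterministic random samples on large ones. Distances are exact
integers and set comparisons are exact, so there are no tolerances anywhere;
the only ordering freedom (similarity ties) is fixed by the id tie-break.
Degenerate inputs are defined rather than rejected: `n = 0` similar returns
an empty list, an empty characteristic conjunction is vacuously true, an
empty type filter yields an empty profile, an untyped parameter reports an
absent type rather than an error.

## Known limitations

* No tableau reasoning: only the constructs listed above are interpreted.
* Hierarchy distance counts subclass edges only; it does not use shared
  characteristics as a secondary signal beyond the candidate filter.
* `resolve-substitute`'s fallback ranking ignores characteristics entirely;
  the warning on stderr is the only indication that the profile match
  failed.
* Remote loading (URL sources) is supported but intentionally never
  implicit, and the test suite uses generated local files only.
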