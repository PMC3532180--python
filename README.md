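# kisaoquery

A Python library and CLI for querying KiSAO-shaped OWL ontologies — the
Kinetic Simulation Algorithm Ontology and files structured like it, which
classify the algorithms used to simulate systems-biology models, the
characteristics those algorithms exhibit, and the parameters they take.

Simulation experiment descriptions (e.g. SED-ML files) reference algorithms
by KiSAO identifier, such as `KISAO:0000039` for the tau-leaping method. A
simulation tool that receives such a description needs to answer questions
like:

* *What is `KISAO:0000039`?* — map any identifier form (short id, OWL IRI,
  MIRIAM URN, identifiers.org URL) to the term's name, synonyms, definition
  and literature links;
* *What kind of method is it?* — navigate the subclass hierarchy of
  algorithms, characteristics and parameters;
* *I haven't implemented it — what can I run instead?* — find the
  algorithms with the same characteristic profile (e.g. stochastic system
  behaviour, discrete variables) and rank them by how close they sit to the
  requested method in the hierarchy.

The package parses OWL 2 RDF/XML with rdflib and performs the reasoning the
ontology's structure requires itself: transitive subclass closures,
inheritance of existential `has characteristic` / `has parameter` /
`is hybrid of` restrictions down the hierarchy, upward entailment of
characteristics (a stochastic method *has* a type of system behaviour), and
the hierarchy distance d(a, b) = length of the shortest undirected
`subClassOf` path between two algorithm classes, used to rank substitutes.
Negation ("which algorithms lack this characteristic") is closed-world,
which is the right reading when matching tool capabilities.

## Worked example

The repository can generate a small, fully deterministic ontology holding
the tau-leaping family and the LSODE solver:

```bash
kisao-query gen-fixture --paper --out demo.owl
kisao-query -o demo.owl info KISAO:0000039
```

```
id      kisao:0000039
label   tau-leaping method
branch  algorithm
synonyms        tauL
...
miriam_urn      urn:miriam:biomodels.kisao:KISAO_0000039
```

Asking for substitutes for the Poisson tau-leaping variant, considering only
the type-of-system-behaviour and type-of-variable characteristics:

```bash
kisao-query -o demo.owl similar kisao:9000001 -n 10 \
    --by kisao:9100001 --by kisao:9100004
```

```
kisao:0000039   tau-leaping method      1
kisao:9000002   binomial tau-leaping method     2
kisao:9000003   multinomial tau-leaping method  2
kisao:9000004   implicit tau-leaping method     2
```

Four algorithms share the Poisson variant's stochastic/discrete profile: its
direct parent, the tau-leaping method, at hierarchy distance 1, and the
three sibling variants at distance 2. LSODE (deterministic, continuous) is
correctly excluded. The end-to-end tool-selection workflow picks the best
*implemented* method:

```bash
printf 'kisao:0000071\nkisao:9000002\n' > avail.txt   # LSODE + binomial
kisao-query -o demo.owl --format json \
    resolve-substitute kisao:9000001 --available avail.txt
```

```
{"distance": 2, "id": "kisao:9000002", "label": "binomial tau-leaping method"}
```

The same operations are available as plain functions
(`kisaoquery.queries.n_most_similar`, `search_by_id`,
`algorithms_by_characteristics`, `algorithms_by_query`, ...) on the graph
returned by `kisaoquery.load_ontology(path_or_url)`.

## Scope

The loader handles the OWL constructs KiSAO-shaped files use (named
subclass axioms, existential restrictions over the configured link
properties, datatype restrictions, OBO-in-OWL annotations); it is not a
general OWL 2 DL reasoner, and unknown constructs are logged and skipped.
Branch roots and property IRIs are configurable via a small INI file (see
`kisaoquery/config.py` for the documented keys and KiSAO defaults).
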