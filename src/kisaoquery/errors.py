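"""Exception hierarchy.

Every error raised by the library derives from :class:`KisaoQueryError`, so
callers (notably the CLI) can distinguish library failures from bugs and map
them to exit codes.
"""


class KisaoQueryError(Exception):
    """Base class for all kisaoquery errors."""


class OntologyIOError(KisaoQueryError):
    """The ontology source could not be read (missing file, unreachable URL)."""


class OntologyFormatError(KisaoQueryError):
    """The source was readable but is not a KiSAO-shaped OWL document
    (unparseable RDF, cyclic subclass graph, a class claimed by two branch
    roots, a link axiom on a wrong-branch subject)."""


class IdentifierFormatError(KisaoQueryError, ValueError):
    """A string matched none of the accepted identifier forms."""


class UnknownTermError(KisaoQueryError, LookupError):
    """A well-formed identifier that names no term in the loaded ontology."""


class WrongBranchError(KisaoQueryError):
    """A term from the wrong ontology branch was supplied (e.g. a parameter
    where an algorithm is required)."""


class QuerySyntaxError(KisaoQueryError, ValueError):
    """A boolean characteristic query could not be parsed or resolved."""
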