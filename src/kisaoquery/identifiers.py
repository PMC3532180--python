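"""Canonical KiSAO term identifiers and their four textual forms.

A KiSAO class is identified by a 7-digit number which circulates in four
interchangeable spellings::

    kisao:0000039                                       (short / CURIE)
    http://www.biomodels.net/kisao/KISAO#KISAO_0000039  (OWL class IRI)
    urn:miriam:biomodels.kisao:KISAO_0000039            (MIRIAM URN)
    http://identifiers.org/biomodels.kisao/KISAO_0000039

:func:`normalize_identifier` maps any of them (prefix case-insensitive) onto a
:class:`TermId`; :meth:`TermId.render` goes the other way.  Normalisation is
strict about the digit count: ids with extra or missing digits are rejected
rather than silently truncated, since truncation can alias distinct terms.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from .errors import IdentifierFormatError

KISAO_IRI_PREFIX = "http://www.biomodels.net/kisao/KISAO#KISAO_"
MIRIAM_URN_PREFIX = "urn:miriam:biomodels.kisao:KISAO_"
IDENTIFIERS_ORG_PREFIX = "http://identifiers.org/biomodels.kisao/KISAO_"

#: the four renderable forms, in the order they are documented
IDENTIFIER_FORMS = ("short", "iri", "miriam_urn", "identifiers_org_url")

_PATTERNS = (
    re.compile(r"(?i:kisao):([0-9]{7})"),
    re.compile(r"(?i:KISAO)_([0-9]{7})"),
    re.compile(r"(?i:http://www\.biomodels\.net/kisao/KISAO#KISAO)_([0-9]{7})"),
    re.compile(r"(?i:urn:miriam:biomodels\.kisao:KISAO)_([0-9]{7})"),
    re.compile(r"(?i:https?://identifiers\.org/biomodels\.kisao/KISAO)_([0-9]{7})"),
)


@dataclass(frozen=True, order=True)
class TermId:
    """A KiSAO term identifier: exactly seven decimal digits.

    Equality and ordering are by the numeric part, so the same term is equal
    no matter which textual form it was parsed from.
    """

    numeric_part: str

    def __post_init__(self) -> None:
        if not re.fullmatch(r"[0-9]{7}", self.numeric_part):
            raise IdentifierFormatError(
                f"TermId numeric part must be exactly 7 decimal digits, got {self.numeric_part!r}"
            )

    @property
    def short(self) -> str:
        return f"kisao:{self.numeric_part}"

    @property
    def iri(self) -> str:
        return KISAO_IRI_PREFIX + self.numeric_part

    @property
    def miriam_urn(self) -> str:
        return MIRIAM_URN_PREFIX + self.numeric_part

    @property
    def identifiers_org_url(self) -> str:
        return IDENTIFIERS_ORG_PREFIX + self.numeric_part

    def render(self, form: str = "short") -> str:
        """Render this id in one of the four textual forms."""
        try:
            return getattr(self, _FORM_ATTRS[form])
        except KeyError:
            raise ValueError(
                f"unknown identifier form {form!r}; expected one of {IDENTIFIER_FORMS}"
            ) from None

    def __str__(self) -> str:
        return self.short

    def __int__(self) -> int:
        return int(self.numeric_part)


_FORM_ATTRS = {
    "short": "short",
    "iri": "iri",
    "miriam_urn": "miriam_urn",
    "identifiers_org_url": "identifiers_org_url",
}


def normalize_identifier(text: str) -> TermId:
    """Parse any accepted identifier form into a canonical :class:`TermId`.

    Raises :class:`IdentifierFormatError` for anything else, echoing the
    offending input.
    """
    if isinstance(text, TermId):
        return text
    stripped = text.strip()
    for pattern in _PATTERNS:
        m = pattern.fullmatch(stripped)
        if m:
            return TermId(m.group(1))
    raise IdentifierFormatError(f"not a recognised KiSAO identifier: {text!r}")


def render_identifier(term_id: TermId, form: str = "short") -> str:
    """Functional alias for :meth:`TermId.render`."""
    return term_id.render(form)
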