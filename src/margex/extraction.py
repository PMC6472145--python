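"""Regular-expression extraction of reported p-values with bounded context.

The grammar recognizes a standalone ``p``/``P`` token (optionally plural
``ps`` when enabled), optional whitespace and markup remnants (``*``/``_``
left over from HTML-to-text conversion), a comparison sign, and a numeric
literal.  Each non-overlapping match yields one :class:`PValueMention`
carrying the verbatim matched substring, the normalized comparison symbol,
the numeric text as printed, its decimal value (or ``None`` when the number
fails to parse, e.g. a bare "."), the 0-based match offset, and up to
``window`` characters of context on each side.

Windows are counted in characters on the decoded text and truncated (never
padded) at document boundaries.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import Decimal, InvalidOperation
from typing import Optional

from .corpus_io import ArticleDocument, RecordRow

#: Numeric literal: optional integer part, optional decimal point and
#: fraction, optional exponent.  A bare "." is deliberately accepted so the
#: downstream non-numeric filter can count broken reports.
_NUMBER = r"(?:\d+\.?\d*|\.\d*)(?:[eE][+-]?\d+)?"

# Two-character signs must precede their one-character prefixes.
_SIGNS_EXTENDED = ["<=", ">=", "=<", "=>", "≤", "≥", "<", ">", "="]
_SIGNS_BASIC = ["<", ">", "="]

_SIGN_CANONICAL = {
    "<": "<",
    ">": ">",
    "=": "=",
    "<=": "≤",
    "=<": "≤",
    "≤": "≤",
    ">=": "≥",
    "=>": "≥",
    "≥": "≥",
}

_MARKUP = r"[ \t\r\n\f\v*_]*"


@dataclass(frozen=True)
class PValueMention:
    """One textual p-value report with its bounded context."""

    article_id: str
    raw: str
    comparison: str
    value_text: str
    value: Optional[Decimal]
    offset: int
    context_before: str
    context_after: str


def build_pattern(match_plural_ps: bool = False, extended_signs: bool = True) -> re.Pattern[str]:
    """Compile the p-value grammar with the given dialect options."""
    token = r"[pP]s?" if match_plural_ps else r"[pP]"
    signs = _SIGNS_EXTENDED if extended_signs else _SIGNS_BASIC
    sign_alt = "|".join(re.escape(s) for s in signs)
    return re.compile(
        rf"(?<![A-Za-z0-9])(?:{token}){_MARKUP}(?P<sign>{sign_alt}){_MARKUP}(?P<val>{_NUMBER})"
    )


def parse_value(value_text: str) -> Optional[Decimal]:
    """Decimal interpretation of the printed numeric text, or ``None``.

    Values above 1 (misreports like "1.2") parse as printed; the range
    filter excludes them later.  Never raises.
    """
    try:
        v = Decimal(value_text)
    except (InvalidOperation, ValueError):
        return None
    if not v.is_finite():
        return None
    return v


def extract_pvalues(
    document: ArticleDocument,
    window: int = 200,
    *,
    match_plural_ps: bool = False,
    extended_signs: bool = True,
) -> list[PValueMention]:
    """Scan a document and emit one mention per reported p-value, in order.

    Matches are non-overlapping and resolved left to right.  Identical text
    always yields an identical mention sequence.
    """
    if window < 0:
        raise ValueError("window must be >= 0")
    pattern = build_pattern(match_plural_ps=match_plural_ps, extended_signs=extended_signs)
    text = document.text
    mentions = []
    for m in pattern.finditer(text):
        start, end = m.span()
        mentions.append(
            PValueMention(
                article_id=document.article_id,
                raw=m.group(0),
                comparison=_SIGN_CANONICAL[m.group("sign")],
                value_text=m.group("val"),
                value=parse_value(m.group("val")),
                offset=start,
                context_before=text[max(0, start - window) : start],
                context_after=text[end : end + window],
            )
        )
    return mentions


def mention_to_record(mention: PValueMention, document: ArticleDocument) -> RecordRow:
    """Flatten a mention into a record row, attaching document metadata."""
    return RecordRow(
        article_id=mention.article_id,
        doi=document.doi,
        journal_raw=document.journal_raw,
        year=document.year,
        raw=mention.raw,
        comparison=mention.comparison,
        value_text=mention.value_text,
        value=mention.value,
        offset=mention.offset,
        context_before=mention.context_before,
        context_after=mention.context_after,
    )


def extract_corpus(
    documents,
    window: int = 200,
    *,
    match_plural_ps: bool = False,
    extended_signs: bool = True,
) -> list[RecordRow]:
    """Extract every document in a corpus into record rows."""
    rows = []
    for doc in documents:
        for m in extract_pvalues(
            doc, window, match_plural_ps=match_plural_ps, extended_signs=extended_signs
        ):
            rows.append(mention_to_record(m, doc))
    return rows
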