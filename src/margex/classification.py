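"""Stem-based marginal-significance classification of p-value mentions.

A mention counts as "reported as marginally significant" when either of the
stems ``margin`` or ``approach`` occurs word-initially in its captured
context windows (the up-to-200-character spans on each side of the match).
The classifier is a pure function of the two context strings: text outside
the captured windows can never change the verdict.

A stem matches at the start of the context or after any non-letter, and may
continue with any letters — so "marginal", "marginally", "margins",
"approached" and "approaching" all match, and so do semantically unrelated
uses like "profit margins" (a known false positive of the method, which the
synthetic corpus quantifies).  Matching is case-insensitive by default.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .corpus_io import RecordRow
from .extraction import PValueMention

DEFAULT_STEMS = ("margin", "approach")


@dataclass(frozen=True)
class StemMatch:
    stem: str
    matched_text: str
    where: str  # "before" | "after"
    offset: int  # 0-based index in the context string searched


@dataclass(frozen=True)
class MarginalLabel:
    is_marginal: bool
    matched_stems: tuple[StemMatch, ...] = ()

    def __post_init__(self) -> None:
        if self.is_marginal != bool(self.matched_stems):
            raise ValueError("is_marginal must hold exactly when matched_stems is non-empty")


def _stem_pattern(stem: str, case_sensitive: bool) -> re.Pattern[str]:
    flags = 0 if case_sensitive else re.IGNORECASE
    return re.compile(rf"(?<![A-Za-z]){re.escape(stem)}[A-Za-z]*", flags)


def find_stem_matches(
    text: str,
    stems: Sequence[str] = DEFAULT_STEMS,
    where: str = "before",
    case_sensitive: bool = False,
) -> list[StemMatch]:
    """All word-initial stem occurrences in one context string."""
    out = []
    for stem in stems:
        for m in _stem_pattern(stem, case_sensitive).finditer(text):
            out.append(StemMatch(stem=stem, matched_text=m.group(0), where=where, offset=m.start()))
    out.sort(key=lambda s: (s.offset, s.stem))
    return out


def classify_contexts(
    context_before: str,
    context_after: str,
    stems: Sequence[str] = DEFAULT_STEMS,
    case_sensitive: bool = False,
) -> MarginalLabel:
    matches = find_stem_matches(context_before, stems, "before", case_sensitive)
    matches += find_stem_matches(context_after, stems, "after", case_sensitive)
    return MarginalLabel(is_marginal=bool(matches), matched_stems=tuple(matches))


def classify_marginal(
    mention: PValueMention | RecordRow,
    stems: Sequence[str] = DEFAULT_STEMS,
    case_sensitive: bool = False,
) -> MarginalLabel:
    """Classify one mention from its captured contexts and nothing else."""
    return classify_contexts(mention.context_before, mention.context_after, stems, case_sensitive)


def label_records(
    rows: Iterable[RecordRow],
    stems: Sequence[str] = DEFAULT_STEMS,
    case_sensitive: bool = False,
    only_retained: bool = True,
) -> list[RecordRow]:
    """Fill ``is_marginal`` in place for (by default) retained rows.

    Rows excluded by the filter cascade keep ``is_marginal = None`` so the
    aggregation denominators stay honest.
    """
    rows = list(rows)
    for r in rows:
        if only_retained and r.filter_status != "retained":
            continue
        r.is_marginal = classify_marginal(r, stems, case_sensitive).is_marginal
    return rows
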