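"""Filter cascade, journal standardization, metadata completion, sampling.

The cascade applies four mutually exclusive exclusion stages in order; each
row is counted at the first stage that applies:

1. ``missing_metadata`` — DOI, journal name AND year all absent;
2. ``nonnumeric``       — the printed value failed to parse (e.g. ".");
3. ``core_excluded``    — the journal belongs only to the general
   interdisciplinary category, which is not treated as a discipline;
4. ``out_of_range``     — the value is not in (.05, .10].

Range boundaries compare exact decimal representations of the printed
value, so .05 is excluded and .10 included with no binary-float slack.
"""

from __future__ import annotations

import csv
import json
import logging
import zlib
from dataclasses import dataclass
from decimal import Decimal
from importlib import resources
from pathlib import Path
from typing import Callable, Iterable, Mapping, Optional, Sequence

import numpy as np

from .corpus_io import RecordRow
from .rounding import round_half_up, round_ratio

log = logging.getLogger(__name__)

RANGE_LOW = Decimal("0.05")
RANGE_HIGH = Decimal("0.10")

#: Row exclusion stages, in application order, plus the terminal state.
FILTER_STAGES = ("missing_metadata", "nonnumeric", "core_excluded", "out_of_range", "retained")


def in_analysis_range(value: Optional[Decimal]) -> bool:
    """Exact boundary rule: retained iff .05 < value <= .10."""
    return value is not None and RANGE_LOW < value <= RANGE_HIGH


# ---------------------------------------------------------------------------
# journal registry


@dataclass(frozen=True)
class RegistryEntry:
    canonical_name: str
    disciplines: frozenset[str]
    core_only: bool = False

    def __post_init__(self) -> None:
        if not self.disciplines and not self.core_only:
            raise ValueError(f"{self.canonical_name}: entry needs >=1 discipline or core_only")


def _norm_name(name: str) -> str:
    return " ".join(name.split()).casefold()


class JournalRegistry:
    """Raw journal name -> canonical name, disciplines and core-only status.

    Lookup is case- and whitespace-insensitive.  Canonical names resolve to
    their own entries, so standardization is idempotent.
    """

    def __init__(self, entries: Mapping[str, RegistryEntry]):
        self._by_norm: dict[str, RegistryEntry] = {}
        for raw, entry in entries.items():
            self._by_norm[_norm_name(raw)] = entry
            self._by_norm.setdefault(_norm_name(entry.canonical_name), entry)
        canon = [e.canonical_name for e in set(self._by_norm.values())]
        if len(canon) != len(set(canon)):
            raise ValueError("canonical names must be unique")

    def lookup(self, name: Optional[str]) -> Optional[RegistryEntry]:
        if name is None:
            return None
        return self._by_norm.get(_norm_name(name))

    @property
    def disciplines(self) -> tuple[str, ...]:
        out: set[str] = set()
        for e in self._by_norm.values():
            out.update(e.disciplines)
        return tuple(sorted(out))

    @classmethod
    def from_csv(cls, path: str | Path) -> "JournalRegistry":
        with Path(path).open(newline="", encoding="utf-8") as fh:
            return cls(_parse_registry_rows(csv.DictReader(fh)))

    @classmethod
    def from_json(cls, path: str | Path) -> "JournalRegistry":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        entries = {
            raw: RegistryEntry(
                canonical_name=obj["canonical_name"],
                disciplines=frozenset(obj.get("disciplines", [])),
                core_only=bool(obj.get("core_only", False)),
            )
            for raw, obj in data.items()
        }
        return cls(entries)

    @classmethod
    def default(cls) -> "JournalRegistry":
        """The registry shipped with the package (editable seed, not a claim
        of completeness; users studying other corpora supply their own)."""
        ref = resources.files("margex.data").joinpath("apa_registry.csv")
        with ref.open(newline="", encoding="utf-8") as fh:
            return cls(_parse_registry_rows(csv.DictReader(fh)))


def _parse_registry_rows(rows: Iterable[Mapping[str, str]]) -> dict[str, RegistryEntry]:
    entries: dict[str, RegistryEntry] = {}
    for row in rows:
        disciplines = frozenset(
            d.strip() for d in (row.get("disciplines") or "").split(";") if d.strip()
        )
        entries[row["raw_name"]] = RegistryEntry(
            canonical_name=row["canonical_name"],
            disciplines=disciplines,
            core_only=(row.get("core_only") or "").strip().lower() in ("true", "1", "yes"),
        )
    return entries


def standardize_journal(name: str, registry: JournalRegistry) -> str:
    """Map aliases to the canonical name; unknown names pass through logged."""
    entry = registry.lookup(name)
    if entry is None:
        log.warning("unknown journal name (left unchanged): %r", name)
        return name
    return entry.canonical_name


def assign_disciplines(row: RecordRow, registry: JournalRegistry) -> RecordRow:
    """Set one boolean per registry discipline on the row (multi-membership)."""
    journal = row.journal_canonical or row.journal_raw
    entry = registry.lookup(journal)
    if entry is None:
        if journal is not None:
            log.warning("journal %r not in registry; all discipline flags false", journal)
        row.discipline_flags = {d: False for d in registry.disciplines}
    else:
        row.discipline_flags = {d: d in entry.disciplines for d in registry.disciplines}
    return row


# ---------------------------------------------------------------------------
# metadata completion

Resolver = Callable[[str], Mapping[str, object]]


def complete_metadata(rows: Iterable[RecordRow], resolver: Resolver) -> int:
    """Fill missing journal/year from the caller-supplied DOI resolver.

    Only gaps are overwritten; rows without a DOI are untouched; a resolver
    failure affects only its own row.  Returns the number of rows on which
    at least one field was filled.
    """
    resolved = 0
    for row in rows:
        if row.doi is None or (row.journal_raw is not None and row.year is not None):
            continue
        try:
            meta = resolver(row.doi)
        except Exception as exc:  # resolver contract: failures are per-row
            log.warning("resolver failed for DOI %s: %s", row.doi, exc)
            continue
        touched = False
        if row.journal_raw is None and meta.get("journal") is not None:
            row.journal_raw = str(meta["journal"])
            touched = True
        if row.year is None and meta.get("year") is not None:
            row.year = int(meta["year"])  # type: ignore[arg-type]
            touched = True
        if touched:
            resolved += 1
    return resolved


def table_resolver(path: str | Path) -> Resolver:
    """Resolver backed by a CSV fixture with columns doi, journal, year."""
    table: dict[str, dict] = {}
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            table[row["doi"]] = {
                "journal": row.get("journal") or None,
                "year": int(row["year"]) if (row.get("year") or "").strip() else None,
            }

    def resolve(doi: str) -> Mapping[str, object]:
        if doi not in table:
            raise KeyError(f"unknown DOI: {doi}")
        return table[doi]

    return resolve


# ---------------------------------------------------------------------------
# filter cascade


@dataclass
class FilterReport:
    """Per-stage exclusion counts; the stages partition the input."""

    n_input: int
    n_missing_metadata: int
    n_nonnumeric: int
    n_core_excluded: int
    n_out_of_range: int
    n_retained: int

    def __post_init__(self) -> None:
        total = (
            self.n_missing_metadata
            + self.n_nonnumeric
            + self.n_core_excluded
            + self.n_out_of_range
            + self.n_retained
        )
        if total != self.n_input:
            raise ValueError(f"stage counts sum to {total}, expected n_input={self.n_input}")

    def percentage(self, stage: str, ndigits: int = 2) -> Optional[float]:
        """Half-up rounded percentage of n_input counted at ``stage``."""
        if self.n_input == 0:
            return None
        count = getattr(self, f"n_{stage}")
        return round_ratio(count, self.n_input, ndigits=ndigits, scale=100)

    def as_dict(self) -> dict:
        d = {
            "n_input": self.n_input,
            "n_missing_metadata": self.n_missing_metadata,
            "n_nonnumeric": self.n_nonnumeric,
            "n_core_excluded": self.n_core_excluded,
            "n_out_of_range": self.n_out_of_range,
            "n_retained": self.n_retained,
        }
        if self.n_input:
            d["percentages"] = {
                s: self.percentage(s)
                for s in ("missing_metadata", "nonnumeric", "core_excluded", "out_of_range", "retained")
            }
        return d


def apply_filters(
    rows: Iterable[RecordRow], registry: JournalRegistry
) -> tuple[list[RecordRow], FilterReport]:
    """Annotate every row with its filter stage; return retained rows + report."""
    rows = list(rows)
    counts = {s: 0 for s in FILTER_STAGES}
    retained = []
    for row in rows:
        journal = row.journal_canonical or row.journal_raw
        entry = registry.lookup(journal)
        if row.doi is None and journal is None and row.year is None:
            row.filter_status = "missing_metadata"
        elif row.value is None:
            row.filter_status = "nonnumeric"
        elif entry is not None and entry.core_only:
            row.filter_status = "core_excluded"
        elif not in_analysis_range(row.value):
            row.filter_status = "out_of_range"
        else:
            row.filter_status = "retained"
            retained.append(row)
        counts[row.filter_status] += 1
    report = FilterReport(
        n_input=len(rows),
        n_missing_metadata=counts["missing_metadata"],
        n_nonnumeric=counts["nonnumeric"],
        n_core_excluded=counts["core_excluded"],
        n_out_of_range=counts["out_of_range"],
        n_retained=counts["retained"],
    )
    return retained, report


# ---------------------------------------------------------------------------
# stratified test sample


def stratified_sample(
    rows: Sequence[RecordRow],
    fraction: float = 0.06,
    seed: int = 0,
    stratum_key: Callable[[RecordRow], Optional[str]] = lambda r: r.journal_canonical
    or r.journal_raw,
) -> list[RecordRow]:
    """Draw round(fraction * n) rows per stratum, without replacement.

    The per-stratum target uses half-up rounding; draws are reproducible for
    a fixed seed regardless of input order.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    strata: dict[str, list[int]] = {}
    for i, row in enumerate(rows):
        strata.setdefault(stratum_key(row) or "", []).append(i)
    picked: list[int] = []
    for name in sorted(strata):
        # per-stratum substream: sample composition in one stratum does not
        # depend on which other strata are present
        rng = np.random.default_rng([seed, zlib.crc32(name.encode("utf-8"))])
        idx = sorted(strata[name], key=lambda i: (rows[i].article_id, rows[i].offset))
        k = int(round_half_up(fraction * len(idx), 0))
        if k > 0:
            chosen = rng.choice(len(idx), size=k, replace=False)
            picked.extend(idx[int(c)] for c in sorted(chosen))
    picked.sort()
    return [rows[i] for i in picked]


def clean_records(
    rows: Iterable[RecordRow],
    registry: JournalRegistry,
    resolver: Optional[Resolver] = None,
) -> tuple[list[RecordRow], FilterReport, int]:
    """Full cleaning pass: complete metadata, standardize, assign disciplines,
    then run the cascade.  Returns (retained rows, report, n rows resolved)."""
    rows = list(rows)
    n_resolved = complete_metadata(rows, resolver) if resolver is not None else 0
    for row in rows:
        if row.journal_raw is not None:
            row.journal_canonical = standardize_journal(row.journal_raw, registry)
        assign_disciplines(row, registry)
    retained, report = apply_filters(rows, registry)
    return retained, report, n_resolved
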