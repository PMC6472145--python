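"""Synthetic article corpus with known per-mention ground truth.

Each generated article is filler prose interleaved with p-value sentences.
Every report is emitted inside the extraction grammar, and every inserted
stem phrase is placed at an exactly controlled character distance from the
report, so extraction recall/precision and classifier agreement can be
scored against truth without approximation:

* marginal phrases (and in-window decoys) sit entirely inside the
  200-character window on one side of the report;
* out-of-window decoys start at least 201 characters away, entirely
  outside it;
* consecutive reports are separated by >400 characters of stem-free
  filler, so no window ever captures a neighbouring report's phrase.

Filler text is drawn from a fixed word list containing no stem-bearing
words, no standalone "p" token and no comparison signs, so false positives
are fully controlled by the decoy configuration.  A fixed seed yields a
byte-identical corpus.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from decimal import Decimal
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .cleaning import JournalRegistry, RegistryEntry, in_analysis_range
from .corpus_io import ArticleDocument, RecordRow

_FILLER_WORDS = (
    "the results of study two showed that condition group mean scores were "
    "higher than control while earlier tests indicated no reliable difference "
    "between conditions and the overall model described the data well with "
    "further analysis revealing an effect of the second factor on outcomes "
    "participants completed the task under both settings before ratings were "
    "collected across sessions"
).split()

MARGINAL_PHRASES = (
    ("a marginally significant effect emerged", "margin"),
    ("results were marginally significant overall", "margin"),
    ("the effect approached significance", "approach"),
    ("this difference approaches significance", "approach"),
)

DECOY_PHRASES = (
    ("profit margins remained stable", "margin"),
    ("the approach corridor stayed closed", "approach"),
)

_RAW_STYLES = ("p {s} {v}", "p{s}{v}", "p {s} {v}", "*p* {s} {v}")

_WINDOW = 200
_SEPARATION = 450  # > window + max out-of-window decoy reach safety margin


@dataclass(frozen=True)
class JournalSpec:
    name: str
    disciplines: tuple[str, ...]
    core_only: bool = False
    aliases: tuple[str, ...] = ()


def default_journals() -> tuple[JournalSpec, ...]:
    return (
        JournalSpec("Journal of Applied Things", ("organizational",), aliases=("J Appl Things",)),
        JournalSpec("Child Growth Quarterly", ("developmental",)),
        JournalSpec("Social Behavior Letters", ("social", "experimental")),
        JournalSpec("Clinical Outcomes Review", ("clinical",)),
        JournalSpec("General Psychology Omnibus", (), core_only=True),
    )


@dataclass
class SimConfig:
    """Generator parameters; every probability lives in [0, 1]."""

    n_articles: int = 100
    journals: tuple[JournalSpec, ...] = field(default_factory=default_journals)
    year_range: tuple[int, int] = (1985, 2016)
    pvalues_per_article_mean: float = 8.0
    inrange_fraction: float = 0.3
    theta_marginal: float = 0.4
    theta_trend: float = 0.0  # additive drift in theta per year past year_range[0]
    decoy_rate: float = 0.0
    decoy_in_window: bool = False
    broken_rate: float = 0.0  # probability of a non-numeric report like "p = ."
    doi_missing_rate: float = 0.001
    missing_metadata_rate: float = 0.0  # article lacks DOI, journal and year
    sign_mix: dict[str, float] = field(default_factory=lambda: {"<": 0.35, "=": 0.5, ">": 0.15})
    seed: int = 0

    def validate(self) -> None:
        if self.n_articles < 0:
            raise ValueError("n_articles must be >= 0")
        if not self.journals:
            raise ValueError("journals must be non-empty")
        if self.year_range[0] > self.year_range[1]:
            raise ValueError("year_range must be (low, high) with low <= high")
        if self.pvalues_per_article_mean <= 0:
            raise ValueError("pvalues_per_article_mean must be positive")
        for name in (
            "inrange_fraction",
            "theta_marginal",
            "decoy_rate",
            "broken_rate",
            "doi_missing_rate",
            "missing_metadata_rate",
        ):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if not self.sign_mix or any(w < 0 for w in self.sign_mix.values()):
            raise ValueError("sign_mix must have non-negative weights")
        if set(self.sign_mix) - {"<", ">", "="}:
            raise ValueError("sign_mix keys must be a subset of {<, >, =}")

    def theta_at(self, year: int) -> float:
        t = self.theta_marginal + self.theta_trend * (year - self.year_range[0])
        return min(1.0, max(0.0, t))


def registry_for(config: SimConfig) -> JournalRegistry:
    """Registry matching the generated corpus (aliases map to canonical)."""
    entries = {}
    for j in config.journals:
        entry = RegistryEntry(
            canonical_name=j.name, disciplines=frozenset(j.disciplines), core_only=j.core_only
        )
        entries[j.name] = entry
        for a in j.aliases:
            entries[a] = entry
    return JournalRegistry(entries)


@dataclass(frozen=True)
class TruthRow:
    """Ground truth for one generated p-value report."""

    article_id: str
    offset: int
    raw: str
    sign: str
    value_text: str
    value: Optional[Decimal]
    in_range: bool
    intended_marginal: bool
    phrase: Optional[str]
    phrase_distance: Optional[int]  # characters between phrase and report
    phrase_where: Optional[str]  # "before" | "after"
    is_decoy: bool
    journal: Optional[str]
    year: Optional[int]


class _Filler:
    """Deterministic stem-free filler text with exact-length slicing."""

    def __init__(self, rng: np.random.Generator):
        words = list(_FILLER_WORDS)
        self._base = " ".join(words[int(i)] for i in rng.integers(0, len(words), size=4000))
        self._rng = rng

    def exact(self, n: int) -> str:
        """Exactly ``n`` characters, starting and ending with a space (n >= 2)."""
        if n <= 0:
            return ""
        if n == 1:
            return " "
        start = int(self._rng.integers(0, len(self._base) - n))
        return " " + self._base[start : start + n - 2] + " "

    def about(self, n: int) -> str:
        return self.exact(int(n))


def _draw_value(rng: np.random.Generator, cfg: SimConfig) -> tuple[str, Optional[Decimal], bool]:
    """(value_text, value, in_range) per the configured mixture."""
    u = rng.random()
    if u < cfg.broken_rate:
        return ".", None, False
    if rng.random() < cfg.inrange_fraction:
        k = int(rng.integers(51, 101))  # .051 ... .100, all in (.05, .10]
        text = f".{k:03d}"
    else:
        branch = rng.random()
        if branch < 0.55:
            k = int(rng.integers(1, 51))  # .001 ... .050 (boundary .05 excluded)
            text = f".{k:03d}"
        elif branch < 0.92:
            k = int(rng.integers(101, 1000))  # .101 ... .999
            text = f".{k:03d}"
        else:
            text = f"{int(rng.integers(1, 10))}.{int(rng.integers(1, 10))}"  # misreport, e.g. 1.2
    value = Decimal(text)
    return text, value, in_analysis_range(value)


def _draw_sign(rng: np.random.Generator, cfg: SimConfig) -> str:
    signs = sorted(cfg.sign_mix)
    weights = np.array([cfg.sign_mix[s] for s in signs], dtype=float)
    weights /= weights.sum()
    return signs[int(rng.choice(len(signs), p=weights))]


def generate_corpus(
    config: SimConfig,
) -> tuple[list[ArticleDocument], list[TruthRow]]:
    """Generate (articles, per-mention ground truth) for the configuration."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    filler = _Filler(rng)
    y0, y1 = config.year_range

    articles: list[ArticleDocument] = []
    truth: list[TruthRow] = []
    for a in range(config.n_articles):
        article_id = f"art{a:05d}"
        journal = config.journals[int(rng.integers(0, len(config.journals)))]
        raw_names = (journal.name,) + journal.aliases
        journal_raw: Optional[str] = raw_names[int(rng.integers(0, len(raw_names)))]
        year: Optional[int] = int(rng.integers(y0, y1 + 1))
        doi: Optional[str] = f"10.9999/margex.{article_id}"
        if rng.random() < config.missing_metadata_rate:
            doi, journal_raw, year = None, None, None
        elif rng.random() < config.doi_missing_rate:
            doi = None

        theta = config.theta_at(year if year is not None else y0)
        n_reports = int(rng.poisson(config.pvalues_per_article_mean))

        parts: list[str] = []
        pos = 0

        def _add(s: str) -> None:
            nonlocal pos
            parts.append(s)
            pos += len(s)

        _add(filler.about(int(rng.integers(80, 160))))
        for _ in range(n_reports):
            value_text, value, in_range = _draw_value(rng, config)
            sign = _draw_sign(rng, config)
            style = _RAW_STYLES[int(rng.integers(0, len(_RAW_STYLES)))]
            raw = style.format(s=sign, v=value_text)
            # the extractor's match begins at the "p" token, not at leading
            # markup; truth records the match-aligned raw and offset
            tok_idx = raw.index("p")

            phrase = distance = where = None
            intended = is_decoy = False
            if in_range and rng.random() < theta:
                phrase, _stem = MARGINAL_PHRASES[int(rng.integers(0, len(MARGINAL_PHRASES)))]
                intended = True
            elif rng.random() < config.decoy_rate:
                phrase, _stem = DECOY_PHRASES[int(rng.integers(0, len(DECOY_PHRASES)))]
                is_decoy = True

            if phrase is not None:
                where = "before" if rng.random() < 0.5 else "after"
                if is_decoy and not config.decoy_in_window:
                    distance = int(rng.integers(_WINDOW + 1, 2 * _WINDOW + 1))
                else:
                    # leave one character of slack so the phrase stays fully
                    # inside the window for every report style (the match may
                    # start one character past the block's first character)
                    distance = int(rng.integers(1, _WINDOW - len(phrase)))

            if phrase is not None and where == "before":
                _add(phrase)
                _add(filler.exact(distance))
            raw_offset = pos
            _add(raw)
            if phrase is not None and where == "after":
                _add(filler.exact(distance))
                _add(phrase)
            _add(filler.exact(_SEPARATION))

            truth.append(
                TruthRow(
                    article_id=article_id,
                    offset=raw_offset + tok_idx,
                    raw=raw[tok_idx:],
                    sign=sign,
                    value_text=value_text,
                    value=value,
                    in_range=in_range,
                    intended_marginal=intended,
                    phrase=phrase,
                    phrase_distance=distance,
                    phrase_where=where,
                    is_decoy=is_decoy,
                    journal=journal_raw,
                    year=year,
                )
            )
        _add(filler.about(int(rng.integers(60, 120))))

        articles.append(
            ArticleDocument(
                article_id=article_id,
                text="".join(parts),
                doi=doi,
                journal_raw=journal_raw,
                year=year,
            )
        )
    return articles, truth


# ---------------------------------------------------------------------------
# truth serialization and scoring


_TRUTH_COLUMNS = [
    "article_id",
    "offset",
    "raw",
    "sign",
    "value_text",
    "value",
    "in_range",
    "intended_marginal",
    "phrase",
    "phrase_distance",
    "phrase_where",
    "is_decoy",
    "journal",
    "year",
]


def write_truth(truth: Sequence[TruthRow], path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, quoting=csv.QUOTE_ALL, lineterminator="\n")
        w.writerow(_TRUTH_COLUMNS)
        for t in truth:
            w.writerow(
                [
                    t.article_id,
                    t.offset,
                    t.raw,
                    t.sign,
                    t.value_text,
                    "" if t.value is None else str(t.value),
                    t.in_range,
                    t.intended_marginal,
                    t.phrase or "",
                    "" if t.phrase_distance is None else t.phrase_distance,
                    t.phrase_where or "",
                    t.is_decoy,
                    t.journal or "",
                    "" if t.year is None else t.year,
                ]
            )


def read_truth(path: str | Path) -> list[TruthRow]:
    out = []
    with Path(path).open(newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            out.append(
                TruthRow(
                    article_id=row["article_id"],
                    offset=int(row["offset"]),
                    raw=row["raw"],
                    sign=row["sign"],
                    value_text=row["value_text"],
                    value=Decimal(row["value"]) if row["value"] else None,
                    in_range=row["in_range"] == "True",
                    intended_marginal=row["intended_marginal"] == "True",
                    phrase=row["phrase"] or None,
                    phrase_distance=int(row["phrase_distance"]) if row["phrase_distance"] else None,
                    phrase_where=row["phrase_where"] or None,
                    is_decoy=row["is_decoy"] == "True",
                    journal=row["journal"] or None,
                    year=int(row["year"]) if row["year"] else None,
                )
            )
    return out


def truth_compare(truth: Sequence[TruthRow], records: Iterable[RecordRow]) -> dict:
    """Score a pipeline run against ground truth by matching offsets.

    * extraction recall/precision over all generated/extracted reports;
    * label_agreement: among matched in-range mentions with a classifier
      verdict, the fraction where the verdict equals intended-marginal;
    * decoy_false_positive_rate: among matched in-range decoy-bearing
      mentions, the fraction labeled marginal (None when no such mentions).
    """
    records = list(records)
    truth_by_key = {(t.article_id, t.offset): t for t in truth}
    rec_by_key = {(r.article_id, r.offset): r for r in records}
    matched = truth_by_key.keys() & rec_by_key.keys()

    recall = len(matched) / len(truth_by_key) if truth_by_key else 1.0
    precision = len(matched) / len(rec_by_key) if rec_by_key else 1.0

    agree_n = agree_hits = 0
    decoy_n = decoy_fp = 0
    for key in matched:
        t, r = truth_by_key[key], rec_by_key[key]
        if not t.in_range or r.is_marginal is None:
            continue
        agree_n += 1
        if bool(r.is_marginal) == t.intended_marginal:
            agree_hits += 1
        if t.is_decoy:
            decoy_n += 1
            if r.is_marginal:
                decoy_fp += 1
    return {
        "extraction_recall": recall,
        "extraction_precision": precision,
        "label_agreement": (agree_hits / agree_n) if agree_n else None,
        "decoy_false_positive_rate": (decoy_fp / decoy_n) if decoy_n else None,
        "n_truth": len(truth_by_key),
        "n_extracted": len(rec_by_key),
        "n_matched": len(matched),
    }
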