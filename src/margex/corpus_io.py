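"""Corpus and record-level dataset I/O.

Two kinds of objects move through the pipeline:

* :class:`ArticleDocument` — one article body plus its metadata (DOI,
  journal, year).  A corpus is either a directory of ``.txt`` files with a
  metadata sidecar table, or a single ``.jsonl`` file with one document per
  line.

* :class:`RecordRow` — one extracted p-value report, flattened for the
  record-level dataset (one row per p-value).  Rows round-trip losslessly
  through both the JSONL and the CSV serializations, including missing
  values and arbitrary context text.

CSV missing-value convention: ``None`` is written as the sentinel ``\\N``
(backslash-N).  A string field whose literal content is backslashes followed
by ``N`` gains one extra leading backslash on write and loses it on read, so
the encoding is bijective.  JSONL uses native ``null`` and needs no
sentinel.
"""

from __future__ import annotations

import csv
import json
import logging
import re
from dataclasses import dataclass, field, fields
from decimal import Decimal
from pathlib import Path
from typing import Callable, Iterable, Optional, Sequence

log = logging.getLogger(__name__)

SCHEMA_VERSION = "1"

#: Maximum captured context length, in characters.
MAX_CONTEXT = 200

_NULL_SENTINEL = "\\N"
_SENTINEL_RE = re.compile(r"\\+N\Z")

COMPARISONS = ("<", ">", "=", "≤", "≥")


@dataclass(frozen=True)
class ArticleDocument:
    """One article: an opaque unique id, the full body text, and metadata."""

    article_id: str
    text: str
    doi: Optional[str] = None
    journal_raw: Optional[str] = None
    year: Optional[int] = None

    def __post_init__(self) -> None:
        if self.year is not None and not (1000 <= int(self.year) <= 9999):
            raise ValueError(f"year must be a 4-digit integer, got {self.year!r}")


@dataclass
class RecordRow:
    """One extracted p-value report, flattened for the record dataset."""

    article_id: str
    raw: str
    comparison: str
    value_text: str
    value: Optional[Decimal]
    offset: int
    context_before: str
    context_after: str
    doi: Optional[str] = None
    journal_raw: Optional[str] = None
    journal_canonical: Optional[str] = None
    year: Optional[int] = None
    discipline_flags: dict[str, bool] = field(default_factory=dict)
    is_marginal: Optional[bool] = None
    filter_status: str = "retained"

    def validate(self, max_context: int = MAX_CONTEXT) -> None:
        """Raise ``ValueError`` naming the offending field on invariant breach."""
        if len(self.context_before) > max_context:
            raise ValueError("context_before exceeds %d characters" % max_context)
        if len(self.context_after) > max_context:
            raise ValueError("context_after exceeds %d characters" % max_context)
        if self.comparison not in COMPARISONS:
            raise ValueError(f"comparison must be one of {COMPARISONS}, got {self.comparison!r}")
        if self.offset < 0:
            raise ValueError("offset must be non-negative")
        if self.value is not None and self.value != Decimal(self.value_text):
            raise ValueError("value does not equal the decimal interpretation of value_text")


# ---------------------------------------------------------------------------
# corpus reading


def read_corpus(path: str | Path) -> list[ArticleDocument]:
    """Read a corpus from a directory of text files or a ``.jsonl`` file.

    Directory layout: one UTF-8 ``.txt`` file per article (the stem is the
    article id) plus an optional sidecar ``metadata.csv`` with columns
    ``article_id, doi, journal, year``.  Missing metadata stays missing.
    Decoding errors are replaced, not fatal — scraped text is dirty.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"corpus path does not exist: {path}")
    if path.is_dir():
        return _read_corpus_dir(path)
    if path.suffix == ".jsonl":
        return _read_corpus_jsonl(path)
    raise ValueError(f"unsupported corpus path (need a directory or .jsonl): {path}")


def _read_corpus_dir(path: Path) -> list[ArticleDocument]:
    meta: dict[str, dict] = {}
    sidecar = path / "metadata.csv"
    if sidecar.exists():
        with sidecar.open(newline="", encoding="utf-8") as fh:
            for lineno, row in enumerate(csv.DictReader(fh), start=2):
                aid = row.get("article_id")
                if not aid:
                    raise ValueError(f"{sidecar}: line {lineno}: missing article_id")
                meta[aid] = row
    docs = []
    for txt in sorted(path.glob("*.txt")):
        aid = txt.stem
        m = meta.get(aid, {})
        year_s = (m.get("year") or "").strip()
        docs.append(
            ArticleDocument(
                article_id=aid,
                text=txt.read_text(encoding="utf-8", errors="replace"),
                doi=m.get("doi") or None,
                journal_raw=m.get("journal") or None,
                year=int(year_s) if year_s else None,
            )
        )
    return docs


def _read_corpus_jsonl(path: Path) -> list[ArticleDocument]:
    docs = []
    seen: set[str] = set()
    with path.open(encoding="utf-8", errors="replace") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}: malformed JSON on line {lineno}: {exc}") from exc
            aid = obj.get("article_id")
            if aid is None:
                raise ValueError(f"{path}: line {lineno}: missing article_id")
            if aid in seen:
                raise ValueError(f"{path}: line {lineno}: duplicate article_id {aid!r}")
            seen.add(aid)
            docs.append(
                ArticleDocument(
                    article_id=aid,
                    text=obj.get("text", ""),
                    doi=obj.get("doi"),
                    journal_raw=obj.get("journal"),
                    year=obj.get("year"),
                )
            )
    return docs


def write_corpus(docs: Sequence[ArticleDocument], path: str | Path) -> None:
    """Write a corpus as line-delimited JSON (inverse of the jsonl reader)."""
    path = Path(path)
    with path.open("w", encoding="utf-8") as fh:
        for d in docs:
            fh.write(
                json.dumps(
                    {
                        "article_id": d.article_id,
                        "doi": d.doi,
                        "journal": d.journal_raw,
                        "year": d.year,
                        "text": d.text,
                    },
                    ensure_ascii=False,
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# record-level dataset


_BASE_COLUMNS = [
    "article_id",
    "doi",
    "journal_raw",
    "journal_canonical",
    "year",
    "raw",
    "comparison",
    "value_text",
    "value",
    "offset",
    "context_before",
    "context_after",
    "is_marginal",
    "filter_status",
]


def _enc_str(s: Optional[str]) -> str:
    if s is None:
        return _NULL_SENTINEL
    if _SENTINEL_RE.fullmatch(s):
        return "\\" + s
    return s


def _dec_str(s: str) -> Optional[str]:
    if s == _NULL_SENTINEL:
        return None
    if _SENTINEL_RE.fullmatch(s):
        return s[1:]
    return s


def _enc_opt(v) -> str:
    return _NULL_SENTINEL if v is None else str(v)


def _enc_bool(v: Optional[bool]) -> str:
    if v is None:
        return _NULL_SENTINEL
    return "true" if v else "false"


def _dec_bool(s: str) -> Optional[bool]:
    if s == _NULL_SENTINEL:
        return None
    return s == "true"


def _discipline_columns(rows: Iterable[RecordRow]) -> list[str]:
    names: set[str] = set()
    for r in rows:
        names.update(r.discipline_flags)
    return sorted(names)


def write_records(rows: Sequence[RecordRow], path: str | Path) -> None:
    """Write the record-level dataset; format chosen by suffix (.csv / .jsonl)."""
    path = Path(path)
    for i, r in enumerate(rows):
        try:
            r.validate()
        except ValueError as exc:
            raise ValueError(f"row {i}: {exc}") from exc
    if path.suffix == ".jsonl":
        _write_records_jsonl(rows, path)
    elif path.suffix == ".csv":
        _write_records_csv(rows, path)
    else:
        raise ValueError(f"unsupported record file suffix: {path}")


def read_records(path: str | Path) -> list[RecordRow]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"record file does not exist: {path}")
    if path.suffix == ".jsonl":
        return _read_records_jsonl(path)
    if path.suffix == ".csv":
        return _read_records_csv(path)
    raise ValueError(f"unsupported record file suffix: {path}")


def _write_records_csv(rows: Sequence[RecordRow], path: Path) -> None:
    disc_cols = _discipline_columns(rows)
    header = _BASE_COLUMNS + [f"disc_{d}" for d in disc_cols]
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, quoting=csv.QUOTE_ALL, lineterminator="\n")
        w.writerow(header)
        for r in rows:
            rec = [
                r.article_id,
                _enc_str(r.doi),
                _enc_str(r.journal_raw),
                _enc_str(r.journal_canonical),
                _enc_opt(r.year),
                r.raw,
                r.comparison,
                r.value_text,
                _enc_opt(r.value),
                str(r.offset),
                _enc_str(r.context_before),
                _enc_str(r.context_after),
                _enc_bool(r.is_marginal),
                r.filter_status,
            ]
            rec += [_enc_bool(bool(r.discipline_flags.get(d, False))) for d in disc_cols]
            w.writerow(rec)


def _read_records_csv(path: Path) -> list[RecordRow]:
    rows = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty record file (missing header)")
        disc_cols = [c[len("disc_"):] for c in header if c.startswith("disc_")]
        idx = {c: header.index(c) for c in header}
        for lineno, rec in enumerate(reader, start=2):
            if len(rec) != len(header):
                raise ValueError(f"{path}: line {lineno}: expected {len(header)} fields, got {len(rec)}")
            year = _dec_str(rec[idx["year"]])
            value = _dec_str(rec[idx["value"]])
            rows.append(
                RecordRow(
                    article_id=rec[idx["article_id"]],
                    doi=_dec_str(rec[idx["doi"]]),
                    journal_raw=_dec_str(rec[idx["journal_raw"]]),
                    journal_canonical=_dec_str(rec[idx["journal_canonical"]]),
                    year=int(year) if year is not None else None,
                    raw=rec[idx["raw"]],
                    comparison=rec[idx["comparison"]],
                    value_text=rec[idx["value_text"]],
                    value=Decimal(value) if value is not None else None,
                    offset=int(rec[idx["offset"]]),
                    context_before=_dec_str(rec[idx["context_before"]]) or "",
                    context_after=_dec_str(rec[idx["context_after"]]) or "",
                    is_marginal=_dec_bool(rec[idx["is_marginal"]]),
                    filter_status=rec[idx["filter_status"]],
                    discipline_flags={
                        d: rec[idx[f"disc_{d}"]] == "true" for d in disc_cols
                    },
                )
            )
    return rows


def _write_records_jsonl(rows: Sequence[RecordRow], path: Path) -> None:
    with path.open("w", encoding="utf-8") as fh:
        for r in rows:
            obj = {
                "article_id": r.article_id,
                "doi": r.doi,
                "journal_raw": r.journal_raw,
                "journal_canonical": r.journal_canonical,
                "year": r.year,
                "raw": r.raw,
                "comparison": r.comparison,
                "value_text": r.value_text,
                "value": str(r.value) if r.value is not None else None,
                "offset": r.offset,
                "context_before": r.context_before,
                "context_after": r.context_after,
                "is_marginal": r.is_marginal,
                "filter_status": r.filter_status,
                "discipline_flags": r.discipline_flags,
            }
            fh.write(json.dumps(obj, ensure_ascii=False) + "\n")


def _read_records_jsonl(path: Path) -> list[RecordRow]:
    rows = []
    with path.open(encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ValueError(f"{path}: malformed JSON on line {lineno}: {exc}") from exc
            rows.append(
                RecordRow(
                    article_id=obj["article_id"],
                    doi=obj.get("doi"),
                    journal_raw=obj.get("journal_raw"),
                    journal_canonical=obj.get("journal_canonical"),
                    year=obj.get("year"),
                    raw=obj["raw"],
                    comparison=obj["comparison"],
                    value_text=obj["value_text"],
                    value=Decimal(obj["value"]) if obj.get("value") is not None else None,
                    offset=obj["offset"],
                    context_before=obj.get("context_before", ""),
                    context_after=obj.get("context_after", ""),
                    is_marginal=obj.get("is_marginal"),
                    filter_status=obj.get("filter_status", "retained"),
                    discipline_flags=dict(obj.get("discipline_flags", {})),
                )
            )
    return rows
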