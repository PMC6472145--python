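from decimal import Decimal

import pytest

from margex.cleaning import JournalRegistry, RegistryEntry
from margex.corpus_io import RecordRow
from margex.extraction import parse_value


def make_row(
    article_id="a1",
    value_text=".072",
    doi="10.1/x",
    journal="Journal A",
    year=2000,
    **kwargs,
) -> RecordRow:
    defaults = dict(
        article_id=article_id,
        raw=f"p = {value_text}",
        comparison="=",
        value_text=value_text,
        value=parse_value(value_text),
        offset=0,
        context_before="",
        context_after="",
        doi=doi,
        journal_raw=journal,
        year=year,
    )
    defaults.update(kwargs)
    return RecordRow(**defaults)


def make_registry() -> JournalRegistry:
    a = RegistryEntry("Journal A", frozenset({"social"}))
    b = RegistryEntry("Journal B", frozenset({"social", "clinical"}))
    core = RegistryEntry("Omnibus Review", frozenset(), core_only=True)
    return JournalRegistry(
        {
            "Journal A": a,
            "J of A": a,  # historical alias
            "Journal B": b,
            "Omnibus Review": core,
        }
    )


@pytest.fixture
def registry() -> JournalRegistry:
    return make_registry()
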