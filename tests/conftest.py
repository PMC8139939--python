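import itertools
from pathlib import Path

import pytest
from hypothesis import settings

from splitcover import SplitSystem, TaxaSet, make_split

settings.register_profile("ci", derandomize=True, deadline=None, max_examples=60)
settings.load_profile("ci")

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def taxa5() -> TaxaSet:
    return TaxaSet.range(5)


@pytest.fixture(scope="session")
def example21(taxa5) -> SplitSystem:
    """The printed five-split system {12|345, 23|145, 34|125, 45|123, 15|234}."""
    sides = [{"1", "2"}, {"2", "3"}, {"3", "4"}, {"4", "5"}, {"1", "5"}]
    return SplitSystem(taxa5, [make_split(s, taxa5) for s in sides])


@pytest.fixture(scope="session")
def example21_path() -> str:
    return str(DATA / "example21.nex")


def brute_compatible(a_labels, b_labels, all_labels):
    """Independent Buneman check straight from label sets."""
    a = frozenset(a_labels)
    b = frozenset(all_labels) - a
    c = frozenset(b_labels)
    d = frozenset(all_labels) - c
    return any(not (x & y) for x, y in ((a, c), (a, d), (b, c), (b, d)))


def all_sides(n):
    """Every canonical split side (subsets avoiding taxon index 1)."""
    rest = range(2, n + 1)
    for r in range(1, n):
        yield from map(frozenset, itertools.combinations(rest, r))
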