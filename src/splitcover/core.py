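"""Taxa sets, splits and split systems with Buneman compatibility.

A *split* ``A|B`` is a bipartition of a taxa set ``X`` into two non-empty
parts; its *size* is ``min(|A|, |B|)`` and splits of size 1 are *trivial*.
Two splits ``A|B`` and ``C|D`` on the same taxa set are *compatible*
(displayable on one tree) exactly when at least one of the four
intersections ``A∩C, A∩D, B∩C, B∩D`` is empty.

Splits are stored canonically by the part that does **not** contain the
first taxon, so a bipartition and its mirror image compare equal and hash
identically.
"""

from __future__ import annotations

from functools import total_ordering
from typing import FrozenSet, Iterable, Iterator, Sequence

__all__ = [
    "TaxaSet",
    "Split",
    "SplitSystem",
    "make_split",
    "split_from_indices",
    "are_compatible",
    "is_pairwise_compatible",
]


class TaxaSet:
    """An ordered set of distinct taxon labels.

    The order is fixed and defines the 1-based index of each taxon; index 1
    anchors the canonical side of every :class:`Split`.
    """

    __slots__ = ("labels", "_index")

    def __init__(self, labels: Iterable[object]):
        labs = tuple(str(lab) for lab in labels)
        if len(labs) < 2:
            raise ValueError(f"a taxa set needs at least 2 labels, got {len(labs)}")
        if any(not lab for lab in labs):
            raise ValueError("empty taxon label")
        if len(set(labs)) != len(labs):
            seen: set[str] = set()
            dup = next(lab for lab in labs if lab in seen or seen.add(lab))
            raise ValueError(f"duplicate taxon label: {dup!r}")
        self.labels = labs
        self._index = {lab: i + 1 for i, lab in enumerate(labs)}

    @classmethod
    def range(cls, n: int) -> "TaxaSet":
        """Taxa labelled ``'1' .. 'n'`` in numeric order."""
        return cls(str(i) for i in range(1, n + 1))

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def indices(self) -> FrozenSet[int]:
        return frozenset(range(1, self.n + 1))

    def index(self, label: object) -> int:
        """1-based index of a label; accepts anything whose str() is a label."""
        key = str(label)
        try:
            return self._index[key]
        except KeyError:
            raise KeyError(f"unknown taxon label: {label!r}") from None

    def label(self, index: int) -> str:
        if not 1 <= index <= self.n:
            raise IndexError(f"taxon index {index} out of range 1..{self.n}")
        return self.labels[index - 1]

    def __len__(self) -> int:
        return self.n

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)

    def __contains__(self, label: object) -> bool:
        return str(label) in self._index

    def __eq__(self, other: object) -> bool:
        return isinstance(other, TaxaSet) and self.labels == other.labels

    def __hash__(self) -> int:
        return hash(self.labels)

    def __repr__(self) -> str:
        return f"TaxaSet({list(self.labels)!r})"


@total_ordering
class Split:
    """A canonical bipartition of a :class:`TaxaSet`.

    ``side`` is the set of 1-based indices of the part not containing
    taxon 1. Equality, hashing and ordering all go through that canonical
    side, so ``A|B`` and ``B|A`` are one object.
    """

    __slots__ = ("taxa", "side")

    def __init__(self, taxa: TaxaSet, side: Iterable[int]):
        side = frozenset(side)
        all_idx = taxa.indices
        if not side or not side < all_idx:
            bad = sorted(side - all_idx)
            if bad:
                raise ValueError(f"taxon indices out of range: {bad}")
            raise ValueError(
                "a split side must be a non-empty proper subset of the taxa"
            )
        if 1 in side:
            side = all_idx - side
        object.__setattr__(self, "taxa", taxa)
        object.__setattr__(self, "side", side)

    def __setattr__(self, name: str, value: object) -> None:  # immutability
        raise AttributeError("Split is immutable")

    @property
    def size(self) -> int:
        return min(len(self.side), self.taxa.n - len(self.side))

    @property
    def trivial(self) -> bool:
        return self.size == 1

    def parts(self) -> tuple[FrozenSet[int], FrozenSet[int]]:
        """(canonical side, complement) as index sets."""
        return self.side, self.taxa.indices - self.side

    @property
    def small_side(self) -> FrozenSet[int]:
        """The part of size ``size``; canonical side wins ties (even n)."""
        comp = self.taxa.indices - self.side
        return self.side if len(self.side) <= len(comp) else comp

    @property
    def big_side(self) -> FrozenSet[int]:
        comp = self.taxa.indices - self.side
        return comp if len(self.side) <= len(comp) else self.side

    def side_labels(self) -> tuple[str, ...]:
        return tuple(self.taxa.label(i) for i in sorted(self.side))

    def _key(self) -> tuple:
        return (self.size, tuple(sorted(self.small_side)), tuple(sorted(self.side)))

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, Split)
            and self.taxa == other.taxa
            and self.side == other.side
        )

    def __lt__(self, other: "Split") -> bool:
        if not isinstance(other, Split):
            return NotImplemented
        return self._key() < other._key()

    def __hash__(self) -> int:
        return hash((self.taxa, self.side))

    def __str__(self) -> str:
        a = sorted(self.small_side)
        b = sorted(self.taxa.indices - frozenset(a))
        fmt = lambda part: ",".join(self.taxa.label(i) for i in part)
        return f"{fmt(a)}|{fmt(b)}"

    def __repr__(self) -> str:
        return f"Split({self})"


def make_split(members: Iterable[object], taxa: TaxaSet) -> Split:
    """Canonical split separating ``members`` from the rest of ``taxa``.

    Idempotent under complementation: the member set and its complement
    yield the same :class:`Split`.
    """
    idx = frozenset(taxa.index(m) for m in members)
    if not idx:
        raise ValueError("split side is empty")
    if idx == taxa.indices:
        raise ValueError(f"split side equals the whole taxa set: {sorted(idx)}")
    return Split(taxa, idx)


def split_from_indices(indices: Iterable[int], taxa: TaxaSet) -> Split:
    """As :func:`make_split` but from 1-based taxon indices."""
    return Split(taxa, indices)


def are_compatible(s1: Split, s2: Split) -> bool:
    """Buneman four-intersection test.

    True iff at least one of ``A∩C, A∩D, B∩C, B∩D`` is empty; symmetric,
    and every split is compatible with itself.
    """
    if s1.taxa != s2.taxa:
        raise ValueError("splits live on different taxa sets")
    a, b = s1.parts()
    c, d = s2.parts()
    return not (a & c) or not (a & d) or not (b & c) or not (b & d)


class SplitSystem:
    """A finite set of distinct splits over one taxa set."""

    __slots__ = ("taxa", "splits")

    def __init__(self, taxa: TaxaSet, splits: Iterable[Split] = ()):
        splits = frozenset(splits)
        for s in splits:
            if s.taxa != taxa:
                raise ValueError(f"split {s} is not on the system's taxa set")
        self.taxa = taxa
        self.splits = splits

    @classmethod
    def from_members(
        cls, taxa: TaxaSet, sides: Iterable[Iterable[object]]
    ) -> "SplitSystem":
        return cls(taxa, (make_split(side, taxa) for side in sides))

    @classmethod
    def all_splits(cls, taxa: TaxaSet) -> "SplitSystem":
        """The full split space S(X): 2^(n-1) - 1 splits."""
        rest = sorted(taxa.indices - {1})
        splits = []
        for mask in range(1, 1 << len(rest)):
            side = [rest[i] for i in range(len(rest)) if mask >> i & 1]
            if len(side) < taxa.n:  # always proper: taxon 1 excluded
                splits.append(Split(taxa, side))
        return cls(taxa, splits)

    def nontrivial(self) -> tuple[Split, ...]:
        return tuple(sorted(s for s in self.splits if not s.trivial))

    def trivial_splits(self) -> tuple[Split, ...]:
        return tuple(sorted(s for s in self.splits if s.trivial))

    def with_trivial(self) -> "SplitSystem":
        """This system plus all n trivial splits."""
        extra = (Split(self.taxa, {i}) for i in range(1, self.taxa.n + 1))
        return SplitSystem(self.taxa, set(self.splits) | set(extra))

    def union(self, other: "SplitSystem") -> "SplitSystem":
        if other.taxa != self.taxa:
            raise ValueError("cannot union systems on different taxa sets")
        return SplitSystem(self.taxa, self.splits | other.splits)

    def sorted_splits(self) -> tuple[Split, ...]:
        return tuple(sorted(self.splits))

    def __len__(self) -> int:
        return len(self.splits)

    def __iter__(self) -> Iterator[Split]:
        return iter(sorted(self.splits))

    def __contains__(self, split: Split) -> bool:
        return split in self.splits

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, SplitSystem)
            and self.taxa == other.taxa
            and self.splits == other.splits
        )

    def __hash__(self) -> int:
        return hash((self.taxa, self.splits))

    def __repr__(self) -> str:
        inner = ", ".join(str(s) for s in sorted(self.splits))
        return f"SplitSystem(n={self.taxa.n}, {{{inner}}})"


def is_pairwise_compatible(system: SplitSystem) -> bool:
    """True iff every unordered pair of member splits is compatible.

    Vacuously true for empty and singleton systems.
    """
    splits: Sequence[Split] = tuple(system.splits)
    for i in range(len(splits)):
        for j in range(i + 1, len(splits)):
            if not are_compatible(splits[i], splits[j]):
                return False
    return True


def find_incompatible_pair(system: SplitSystem) -> tuple[Split, Split] | None:
    """First incompatible pair in canonical order, or None."""
    splits = system.sorted_splits()
    for i in range(len(splits)):
        for j in range(i + 1, len(splits)):
            if not are_compatible(splits[i], splits[j]):
                return splits[i], splits[j]
    return None
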