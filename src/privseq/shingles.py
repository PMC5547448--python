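"""w-shingling of nucleotide sequences and shingle-space accounting.

A w-shingle is any length-w substring of a sequence; the shingle set keeps each
distinct substring once (set semantics — repeats carry no weight).  Over the
four-letter alphabet the shingle space is bounded by 4^w, so a whole cohort's
shingles can be stored as one union database of at most 4^w strings of w bytes.
The similarity proxy used downstream is the size of the intersection between
two shingle sets, which is what the private set intersection step computes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .seqdata import SequenceDataset, _ALPHABET_SET


class ShingleWidthError(ValueError):
    """A record is shorter than the shingle width w."""


@dataclass(frozen=True)
class ShingleSet:
    """Set of distinct length-w substrings of one sequence."""

    w: int
    items: frozenset[str]

    def __init__(self, w: int, items):
        if w < 1:
            raise ValueError("shingle width w must be >= 1")
        items = frozenset(items)
        for it in items:
            if len(it) != w or set(it) - _ALPHABET_SET:
                raise ValueError(f"invalid shingle {it!r} for w={w}")
        object.__setattr__(self, "w", w)
        object.__setattr__(self, "items", items)

    def __len__(self) -> int:
        return len(self.items)

    def __contains__(self, item) -> bool:
        return item in self.items

    def intersection(self, other: "ShingleSet") -> "ShingleSet":
        if other.w != self.w:
            raise ValueError(f"shingle widths differ: {self.w} vs {other.w}")
        return ShingleSet(self.w, self.items & other.items)


@dataclass(frozen=True)
class ShingleDB:
    """Per-record shingle sets plus their union over the whole dataset."""

    w: int
    per_record: dict[str, ShingleSet]
    union: ShingleSet

    def __post_init__(self):
        for rid, ss in self.per_record.items():
            if ss.w != self.w:
                raise ValueError(f"record {rid}: w={ss.w} != db w={self.w}")


def shingle_set(seq: str, w: int) -> ShingleSet:
    """All distinct length-w windows of ``seq``.

    A sequence shorter than w is an error: a silently empty set would zero the
    record's similarity and corrupt rankings downstream.
    """
    if w < 1:
        raise ValueError("shingle width w must be >= 1")
    if len(seq) < w:
        raise ShingleWidthError(
            f"sequence of length {len(seq)} is shorter than shingle width w={w}"
        )
    return ShingleSet(w, {seq[i : i + w] for i in range(len(seq) - w + 1)})


def optimal_w(seq_length: int) -> int:
    """Shingle width log_4(l), rounded up (integer-exact, no floating point).

    Rounding up rather than down: smaller widths make shingle matches too
    common and inflate false positives in the ranking.
    """
    if seq_length < 1:
        raise ValueError("sequence length must be >= 1")
    w = 1
    while 4**w < seq_length:
        w += 1
    return w


def build_shingle_db(dataset: SequenceDataset, w: int) -> ShingleDB:
    """Shingle every record and form the union database."""
    short = [r.id for r in dataset if len(r) < w]
    if short:
        raise ShingleWidthError(
            f"records shorter than w={w}: {short[:10]}"
            + ("..." if len(short) > 10 else "")
        )
    per_record = {r.id: shingle_set(r.residues, w) for r in dataset}
    union_items = set()
    for ss in per_record.values():
        union_items |= ss.items
    return ShingleDB(w=w, per_record=per_record, union=ShingleSet(w, union_items))


def shingle_space_stats(db: ShingleDB) -> tuple[int, int, int]:
    """(unique shingle count, theoretical max 4^w, storage in bytes at 1 B/char)."""
    unique_count = len(db.union)
    return unique_count, 4**db.w, unique_count * db.w


def write_shingle_db(db: ShingleDB, path) -> None:
    """Persist as sorted plain text: ``#w=<w>`` header, ``><id>`` sections,
    one shingle per line — so the storage accounting is auditable with wc."""
    with open(path, "w") as fh:
        fh.write(f"#w={db.w}\n")
        for rid in sorted(db.per_record):
            fh.write(f">{rid}\n")
            for s in sorted(db.per_record[rid].items):
                fh.write(s + "\n")


def read_shingle_db(path) -> ShingleDB:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if not header.startswith("#w="):
            raise ValueError(f"{path}: missing '#w=' header")
        w = int(header[3:])
        per_record: dict[str, ShingleSet] = {}
        rid, items = None, set()
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                if rid is not None:
                    per_record[rid] = ShingleSet(w, items)
                rid, items = line[1:], set()
            else:
                items.add(line)
        if rid is not None:
            per_record[rid] = ShingleSet(w, items)
    union = set()
    for ss in per_record.values():
        union |= ss.items
    return ShingleDB(w=w, per_record=per_record, union=ShingleSet(w, union))
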