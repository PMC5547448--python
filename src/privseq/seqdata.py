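"""Sequence data model, FASTA/TSV I/O, and the synthetic corpus generator.

Sequences are plain ACGT strings with identifiers; a dataset is an ordered,
id-unique collection.  The synthetic generator emulates SNP-array-style
corpora: every site of every individual is drawn independently from a per-site
allele-frequency vector (the accumulated population frequencies of a reference
panel), so a cohort shares the same marginal structure at each position while
individuals differ by allele draws.  Length variation between individuals is
produced by a separate, explicit indel-perturbation step so that the per-site
sampler stays exactly i.i.d. per column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

ALPHABET = "ACGT"
_ALPHABET_SET = frozenset(ALPHABET)
_NUC_INDEX = {c: i for i, c in enumerate(ALPHABET)}


class FastaParseError(ValueError):
    """Raised for structurally malformed FASTA input (names the offending line)."""


class AlphabetError(ValueError):
    """Raised when a sequence contains a character outside {A,C,G,T}."""


class ValidationError(ValueError):
    """Raised for inconsistent allele-frequency tables."""


@dataclass(frozen=True)
class NucleotideSequence:
    """An identified DNA string over the four-letter nucleotide alphabet."""

    id: str
    residues: str

    def __post_init__(self):
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        bad = set(self.residues) - _ALPHABET_SET
        if bad:
            raise AlphabetError(
                f"record {self.id!r} contains characters outside ACGT: "
                f"{sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class SequenceDataset:
    """Ordered collection of nucleotide sequences with pairwise-distinct ids."""

    records: tuple[NucleotideSequence, ...]

    def __init__(self, records):
        object.__setattr__(self, "records", tuple(records))
        ids = [r.id for r in self.records]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate record ids in dataset: {dupes}")

    @property
    def n(self) -> int:
        return len(self.records)

    @property
    def length_range(self) -> tuple[int, int]:
        if not self.records:
            return (0, 0)
        lengths = [len(r) for r in self.records]
        return (min(lengths), max(lengths))

    @property
    def ids(self) -> tuple[str, ...]:
        return tuple(r.id for r in self.records)

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return self.n

    def __getitem__(self, key):
        if isinstance(key, str):
            for r in self.records:
                if r.id == key:
                    return r
            raise KeyError(key)
        return self.records[key]


@dataclass(frozen=True)
class AlleleFrequencyTable:
    """Per-site nucleotide probability vectors, column order A, C, G, T."""

    sites: np.ndarray  # shape (n_sites, 4), rows sum to 1
    _TOL = 1e-9

    def __init__(self, sites):
        sites = np.asarray(sites, dtype=float)
        if sites.ndim != 2 or sites.shape[1] != 4:
            raise ValidationError("frequency table must have shape (n_sites, 4)")
        if sites.shape[0] < 1:
            raise ValidationError("frequency table needs at least one site")
        if (sites < 0).any():
            idx = int(np.argwhere(sites < 0)[0, 0])
            raise ValidationError(f"negative probability at site {idx + 1}")
        bad = np.abs(sites.sum(axis=1) - 1.0) > self._TOL
        if bad.any():
            idx = int(np.argmax(bad))
            raise ValidationError(
                f"site {idx + 1} probabilities sum to {sites[idx].sum():.12g}, not 1"
            )
        sites.setflags(write=False)
        object.__setattr__(self, "sites", sites)

    @property
    def n_sites(self) -> int:
        return int(self.sites.shape[0])


# ----------------------------------------------------------------------------- I/O


def read_fasta(path) -> SequenceDataset:
    """Read a FASTA file into a dataset; residues are uppercased and validated.

    Raises :class:`FastaParseError` naming the line for structural problems and
    :class:`AlphabetError` naming the record for non-ACGT characters.
    """
    path = Path(path)
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise FastaParseError(
                        f"{path}: line {lineno}: expected FASTA header '>', "
                        f"got {line.strip()[:30]!r}"
                    )
                break
        else:
            return SequenceDataset([])
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(NucleotideSequence(id=rec.id, residues=str(rec.seq).upper()))
    return SequenceDataset(records)


def write_fasta(dataset: SequenceDataset, path) -> None:
    """Write a dataset as FASTA, wrapped at 80 columns.

    Per FASTA convention the id is the first whitespace-delimited token of the
    header, so an id containing whitespace will be truncated on re-read.
    """
    recs = [
        SeqRecord(Seq(r.residues), id=r.id, description="") for r in dataset
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=80)
        writer.write_file(recs)


def read_frequency_table(path) -> AlleleFrequencyTable:
    """Read a per-site allele-frequency TSV with header ``site A C G T``."""
    df = pd.read_csv(path, sep="\t")
    expected = ["site", "A", "C", "G", "T"]
    if list(df.columns) != expected:
        raise ValidationError(
            f"{path}: expected header {expected}, got {list(df.columns)}"
        )
    return AlleleFrequencyTable(df[["A", "C", "G", "T"]].to_numpy(dtype=float))


def write_frequency_table(freqs: AlleleFrequencyTable, path) -> None:
    df = pd.DataFrame(freqs.sites, columns=list("ACGT"))
    df.insert(0, "site", np.arange(1, freqs.n_sites + 1))
    df.to_csv(path, sep="\t", index=False)


# --------------------------------------------------------------- synthetic corpora


def synthetic_frequency_table(n_sites: int, seed: int) -> AlleleFrequencyTable:
    """Biallelic-SNP-style frequency table.

    Each site gets a major and a minor allele (distinct, uniformly chosen) with
    minor-allele frequency drawn uniformly on [0.01, 0.5] — the shape of
    accumulated population allele frequencies from a reference panel, where most
    sites are strongly skewed toward the major allele.
    """
    rng = np.random.default_rng(seed)
    major = rng.integers(0, 4, size=n_sites)
    shift = rng.integers(1, 4, size=n_sites)
    minor = (major + shift) % 4
    maf = rng.uniform(0.01, 0.5, size=n_sites)
    sites = np.zeros((n_sites, 4))
    sites[np.arange(n_sites), major] = 1.0 - maf
    sites[np.arange(n_sites), minor] = maf
    return AlleleFrequencyTable(sites)


def generate_dataset(
    freqs: AlleleFrequencyTable,
    n_records: int,
    n_queries: int,
    seed: int,
    id_prefix: str = "seq",
) -> tuple[SequenceDataset, SequenceDataset]:
    """Sample ``n_records + n_queries`` sequences site-by-site from ``freqs``.

    Every sequence is drawn independently; site ``s`` of every sequence follows
    ``freqs.sites[s]``.  The first ``n_records`` sequences form the data owner's
    dataset, the remainder the held-out query set.  Identical seeds give
    byte-identical output.
    """
    if n_records < 0 or n_queries < 0:
        raise ValueError("counts must be non-negative")
    rng = np.random.default_rng(seed)
    total = n_records + n_queries
    m = freqs.n_sites
    if total == 0:
        return SequenceDataset([]), SequenceDataset([])
    # inverse-CDF sampling per column: idx = #{cutpoints < u}
    cum = np.cumsum(freqs.sites, axis=1)[:, :3]  # (m, 3)
    u = rng.random((total, m))
    idx = (u[:, :, None] >= cum[None, :, :]).sum(axis=2)  # (total, m) in {0..3}
    lut = np.frombuffer(ALPHABET.encode(), dtype=np.uint8)
    chars = lut[idx]
    seqs = [bytes(row).decode() for row in chars]
    records = [
        NucleotideSequence(f"{id_prefix}{i:05d}", seqs[i]) for i in range(n_records)
    ]
    queries = [
        NucleotideSequence(f"query{i:04d}", seqs[n_records + i])
        for i in range(n_queries)
    ]
    return SequenceDataset(records), SequenceDataset(queries)


def perturb_lengths(
    dataset: SequenceDataset, max_indels: int, seed: int
) -> SequenceDataset:
    """Apply a uniform number of random single-base indels to each record.

    Each record independently receives ``U{0..max_indels}`` edits, each an
    insertion or deletion (fair coin) at a uniform position.  Produces the
    length spread seen in real cohorts from the fixed-length sampler.  Ids are
    preserved; a deletion drawn against an empty sequence is skipped and logged.
    """
    if max_indels < 0:
        raise ValueError("max_indels must be >= 0")
    if max_indels == 0:
        return dataset
    rng = np.random.default_rng(seed)
    out = []
    for rec in dataset:
        chars = list(rec.residues)
        for _ in range(int(rng.integers(0, max_indels + 1))):
            if rng.random() < 0.5:
                if chars:
                    del chars[int(rng.integers(0, len(chars)))]
                else:
                    logger.info(
                        "record %s: deletion clamped on empty sequence", rec.id
                    )
            else:
                pos = int(rng.integers(0, len(chars) + 1))
                chars.insert(pos, ALPHABET[int(rng.integers(0, 4))])
        out.append(NucleotideSequence(rec.id, "".join(chars)))
    return SequenceDataset(out)


def dataset2_profile(
    seed: int, n_records: int = 2000, n_queries: int = 50, n_sites: int = 9500,
    max_indels: int = 500,
) -> tuple[SequenceDataset, SequenceDataset]:
    """Synthetic cohort shaped like a reference-panel-derived SNP corpus:
    2000 records + 50 queries, lengths within [9000, 10000]."""
    freqs = synthetic_frequency_table(n_sites, seed)
    data, queries = generate_dataset(freqs, n_records, n_queries, seed + 1)
    data = perturb_lengths(data, max_indels, seed + 2)
    queries = perturb_lengths(queries, max_indels, seed + 3)
    return data, queries


def dataset1_profile(
    seed: int, n_records: int = 500, n_queries: int = 1, n_sites: int = 3450,
    max_indels: int = 50,
) -> tuple[SequenceDataset, SequenceDataset]:
    """Synthetic cohort shaped like a small SNP-challenge corpus:
    500 records, lengths within [3400, 3500], a single query."""
    return dataset2_profile(
        seed, n_records=n_records, n_queries=n_queries, n_sites=n_sites,
        max_indels=max_indels,
    )


def encode_residues(residues: str) -> np.ndarray:
    """Encode an ACGT string as a uint8 index array (A=0, C=1, G=2, T=3)."""
    arr = np.frombuffer(residues.encode(), dtype=np.uint8)
    out = np.empty(arr.shape, dtype=np.uint8)
    for ch, i in _NUC_INDEX.items():
        out[arr == ord(ch)] = i
    return out
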