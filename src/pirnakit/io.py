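"""Reading and writing small-RNA read libraries and transposon consensus sets.

A *read library* is the collapsed form of a sequencing library: each distinct
sequence appears once, carrying the number of raw reads that had it. The
internal alphabet is DNA (``T``); RNA input (``U``) is converted on read, and
the bias statistics re-label ``T`` as ``U`` on output so the reported numbers
speak the small-RNA vocabulary (1U-bias etc.).

Pre-collapsed FASTA input is recognized through the two common header count
dialects ``name_xN`` and ``name_N``; when both match, ``xN`` wins. Records
containing ``N`` are dropped with a warning; records with characters outside
``{A,C,G,T,U,N}`` (any case) are rejected with a warning and the run continues.
"""

from __future__ import annotations

import gzip
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

from Bio import SeqIO

__all__ = [
    "ParseError",
    "ReadLibrary",
    "ConsensusEntry",
    "ConsensusSet",
    "revcomp",
    "normalize_sequence",
    "read_fasta",
    "read_fastq",
    "write_collapsed",
    "read_consensus_fasta",
    "write_consensus_fasta",
]


class ParseError(ValueError):
    """Raised when an input file violates its declared format."""


_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID = frozenset("ACGT")
_ACCEPTED = frozenset("ACGTUN")
_COUNT_X = re.compile(r"_x(\d+)$")
_COUNT_PLAIN = re.compile(r"_(\d+)$")


def revcomp(sequence: str) -> str:
    """Reverse complement of a DNA string over {A,C,G,T}."""
    return sequence.translate(_COMPLEMENT)[::-1]


def normalize_sequence(raw: str) -> str:
    """Uppercase and convert U to T; no validation."""
    return raw.upper().replace("U", "T")


@dataclass(frozen=True)
class ReadLibrary:
    """Collapsed small-RNA library: unique sequences with abundance counts.

    Parameters
    ----------
    name
        Library label, used in output headers and reports.
    records
        Mapping of unique sequence -> positive read count.
    """

    name: str
    records: Mapping[str, int]

    def __post_init__(self) -> None:
        frozen: dict[str, int] = {}
        for seq, count in self.records.items():
            if not seq or not _VALID.issuperset(seq):
                raise ValueError(f"invalid sequence in library {self.name!r}: {seq!r}")
            if not isinstance(count, (int,)) or count <= 0:
                raise ValueError(f"count for {seq!r} must be a positive integer, got {count!r}")
            frozen[seq] = int(count)
        object.__setattr__(self, "records", frozen)

    @property
    def total_count(self) -> int:
        return sum(self.records.values())

    @property
    def n_unique(self) -> int:
        return len(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[tuple[str, int]]:
        return iter(self.records.items())

    @classmethod
    def from_sequences(cls, name: str, sequences: Iterable[str]) -> "ReadLibrary":
        """Collapse an iterable of (already normalized) sequences, count 1 each."""
        counts: dict[str, int] = {}
        for seq in sequences:
            counts[seq] = counts.get(seq, 0) + 1
        return cls(name=name, records=counts)


@dataclass(frozen=True)
class ConsensusEntry:
    """One transposon consensus sequence."""

    name: str
    sequence: str


@dataclass(frozen=True)
class ConsensusSet:
    """Ordered collection of transposon consensus sequences with unique names."""

    entries: tuple[ConsensusEntry, ...]

    def __post_init__(self) -> None:
        entries = tuple(self.entries)
        names = [e.name for e in entries]
        if len(set(names)) != len(names):
            raise ValueError("duplicate consensus names")
        for e in entries:
            if not e.sequence:
                raise ValueError(f"empty consensus sequence: {e.name!r}")
        object.__setattr__(self, "entries", entries)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self) -> Iterator[ConsensusEntry]:
        return iter(self.entries)

    def get(self, name: str) -> ConsensusEntry:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)


def _open_text(path: str | Path):
    """Open a possibly gzip-compressed text file transparently."""
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(2)
    if magic == b"\x1f\x8b":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _check_fasta_preamble(path: str | Path) -> None:
    """Reject files whose first non-blank line is not a FASTA header."""
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.strip():
                if not line.startswith(">"):
                    raise ParseError(f"{path}: line {lineno}: expected FASTA header '>', got {line.strip()[:30]!r}")
                return
    # entirely blank/empty file: fine, yields an empty library


def _parse_count(header_id: str) -> int:
    """Pre-collapsed count from a header id; '_xN' preferred over '_N', else 1."""
    m = _COUNT_X.search(header_id)
    if m is None:
        m = _COUNT_PLAIN.search(header_id)
    return int(m.group(1)) if m else 1


def _normalize_record(header: str, raw_seq: str, counts: dict[str, int], count: int) -> None:
    up = raw_seq.upper()
    if not _ACCEPTED.issuperset(up):
        bad = sorted(set(up) - _ACCEPTED)
        warnings.warn(f"record {header!r} rejected: characters {bad} outside ACGTUN")
        return
    if "N" in up:
        warnings.warn(f"record {header!r} dropped: contains N")
        return
    seq = up.replace("U", "T")
    if not seq:
        warnings.warn(f"record {header!r} dropped: empty sequence")
        return
    counts[seq] = counts.get(seq, 0) + count


def read_fasta(path: str | Path, name: str | None = None) -> ReadLibrary:
    """Read a (possibly gzipped) FASTA file into a collapsed :class:`ReadLibrary`.

    Identical sequences are merged with summed counts; header suffixes
    ``_xN`` or ``_N`` are interpreted as pre-collapsed counts.
    """
    path = Path(path)
    if name is None:
        name = path.name.removesuffix(".gz").rsplit(".", 1)[0]
    _check_fasta_preamble(path)
    counts: dict[str, int] = {}
    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            _normalize_record(record.id, str(record.seq), counts, _parse_count(record.id))
    return ReadLibrary(name=name, records=counts)


def read_fastq(path: str | Path, name: str | None = None) -> ReadLibrary:
    """Read a (possibly gzipped) FASTQ file into a collapsed :class:`ReadLibrary`.

    Qualities are ignored. Truncated records or sequence/quality length
    mismatches raise :class:`ParseError`.
    """
    path = Path(path)
    if name is None:
        name = path.name.removesuffix(".gz").rsplit(".", 1)[0]
    counts: dict[str, int] = {}
    with _open_text(path) as fh:
        try:
            for record in SeqIO.parse(fh, "fastq"):
                _normalize_record(record.id, str(record.seq), counts, _parse_count(record.id))
        except ValueError as exc:  # Biopython signals malformed FASTQ this way
            raise ParseError(f"{path}: malformed FASTQ: {exc}") from exc
    return ReadLibrary(name=name, records=counts)


def read_library(path: str | Path, name: str | None = None) -> ReadLibrary:
    """Dispatch on extension: .fq/.fastq(.gz) as FASTQ, everything else as FASTA."""
    stem = Path(path).name.removesuffix(".gz")
    if stem.endswith((".fq", ".fastq")):
        return read_fastq(path, name=name)
    return read_fasta(path, name=name)


def write_collapsed(library: ReadLibrary, path: str | Path) -> None:
    """Write a library as collapsed FASTA, headers ``><name>_<i>_x<count>``.

    Records are ordered by descending count then sequence, so output is
    deterministic; ``read_fasta`` on the result reproduces the records exactly.
    """
    items = sorted(library.records.items(), key=lambda kv: (-kv[1], kv[0]))
    with open(path, "wt") as fh:
        for i, (seq, count) in enumerate(items, start=1):
            fh.write(f">{library.name}_{i}_x{count}\n{seq}\n")


def read_consensus_fasta(path: str | Path) -> ConsensusSet:
    """Read transposon consensus sequences from FASTA (names = header ids)."""
    _check_fasta_preamble(path)
    entries = []
    with _open_text(path) as fh:
        for record in SeqIO.parse(fh, "fasta"):
            entries.append(ConsensusEntry(record.id, normalize_sequence(str(record.seq))))
    if not entries:
        raise ParseError(f"{path}: no consensus sequences found")
    return ConsensusSet(entries=tuple(entries))


def write_consensus_fasta(consensus_set: ConsensusSet, path: str | Path) -> None:
    with open(path, "wt") as fh:
        for entry in consensus_set:
            fh.write(f">{entry.name}\n{entry.sequence}\n")
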