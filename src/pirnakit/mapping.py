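"""Exact-match placement of collapsed reads onto transposon consensus sequences.

Coordinates are 0-based half-open on the consensus as written in the input
FASTA ("sense" strand). An antisense hit is an exact occurrence of the read's
reverse complement; its biological 5' nucleotide then sits at ``end - 1`` on
consensus coordinates. Multimapping reads are weighted fractionally
(count / number of hits) so per-transposon totals conserve library counts.

Matching is exact with no mismatches or indels: reads either are substrings
of a consensus strand or they are unmapped. The index is a k-mer seed table
(first k nucleotides of the query) with full verification; queries shorter
than k fall back to a direct scan.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

from .io import ConsensusSet, ReadLibrary, revcomp

__all__ = [
    "SENSE",
    "ANTISENSE",
    "MappedHit",
    "MappedLibrary",
    "ConsensusIndex",
    "build_index",
    "map_sequence",
    "map_library",
    "write_bed",
    "write_hits_tsv",
]

SENSE = "sense"
ANTISENSE = "antisense"


@dataclass(frozen=True)
class MappedHit:
    """One exact placement of a read on a consensus sequence.

    ``five_prime`` is the consensus coordinate of the read's 5' nucleotide:
    ``start`` for a sense hit, ``end - 1`` for an antisense hit. ``weight`` is
    ``None`` for weightless hits from :func:`map_sequence` and
    ``count / n_hits`` after :func:`map_library`.
    """

    sequence: str
    transposon: str
    start: int
    end: int
    strand: str
    five_prime: int
    weight: float | None = None

    def __post_init__(self) -> None:
        if self.end - self.start != len(self.sequence):
            raise ValueError("end - start must equal read length")
        expected = self.start if self.strand == SENSE else self.end - 1
        if self.five_prime != expected:
            raise ValueError(f"five_prime {self.five_prime} inconsistent with {self.strand} hit")


@dataclass
class MappedLibrary:
    """All hits of a library plus the count of reads that did not map."""

    name: str
    hits: list[MappedHit]
    unmapped_count: int

    @property
    def mapped_weight(self) -> float:
        return sum(h.weight for h in self.hits if h.weight is not None)


class ConsensusIndex:
    """k-mer seed table over the sense strand of every consensus sequence.

    Antisense occurrences are found by querying the reverse complement of the
    read against the same sense-strand table.
    """

    def __init__(self, consensus_set: ConsensusSet, k: int = 12):
        if len(consensus_set) == 0:
            raise ValueError("empty consensus set")
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.sequences: dict[str, str] = {e.name: e.sequence for e in consensus_set}
        self._seeds: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for entry in consensus_set:
            seq = entry.sequence
            if len(seq) < k:
                warnings.warn(f"consensus {entry.name!r} shorter than k={k}: contributes no seeds")
                continue
            for i in range(len(seq) - k + 1):
                self._seeds[seq[i : i + k]].append((entry.name, i))

    @property
    def n_seeds(self) -> int:
        """Total number of indexed sense-strand k-mer positions."""
        return sum(len(v) for v in self._seeds.values())

    def _occurrences(self, query: str) -> set[tuple[str, int]]:
        """All (transposon, start) sense-strand occurrences of ``query``."""
        hits: set[tuple[str, int]] = set()
        n = len(query)
        if n >= self.k:
            for name, pos in self._seeds.get(query[: self.k], ()):
                if self.sequences[name][pos : pos + n] == query:
                    hits.add((name, pos))
        else:  # shorter than the seed length: direct scan
            for name, seq in self.sequences.items():
                pos = seq.find(query)
                while pos != -1:
                    hits.add((name, pos))
                    pos = seq.find(query, pos + 1)
        return hits


def build_index(consensus_set: ConsensusSet, k: int = 12) -> ConsensusIndex:
    """Build an exact-match index over a consensus set."""
    return ConsensusIndex(consensus_set, k=k)


def map_sequence(index: ConsensusIndex, sequence: str) -> list[MappedHit]:
    """All exact occurrences of ``sequence`` on both strands, weightless.

    Returned hits are deduplicated and sorted by (transposon, start, strand),
    sense before antisense.
    """
    n = len(sequence)
    hits: set[MappedHit] = set()
    for query, strand in ((sequence, SENSE), (revcomp(sequence), ANTISENSE)):
        for name, pos in index._occurrences(query):
            end = pos + n
            hits.add(
                MappedHit(
                    sequence=sequence,
                    transposon=name,
                    start=pos,
                    end=end,
                    strand=strand,
                    five_prime=pos if strand == SENSE else end - 1,
                )
            )
    return sorted(hits, key=lambda h: (h.transposon, h.start, h.strand != SENSE))


def map_library(index: ConsensusIndex, library: ReadLibrary) -> MappedLibrary:
    """Map every unique sequence of a library, weighting multimappers 1/n.

    Each hit of a sequence with library count ``c`` and ``n`` total hits
    (across all consensus entries and strands) receives weight ``c / n``, so
    mapped weight plus ``unmapped_count`` equals the library total.
    """
    all_hits: list[MappedHit] = []
    unmapped = 0
    for seq in sorted(library.records):
        count = library.records[seq]
        hits = map_sequence(index, seq)
        if not hits:
            unmapped += count
            continue
        w = count / len(hits)
        all_hits.extend(replace(h, weight=w) for h in hits)
    return MappedLibrary(name=library.name, hits=all_hits, unmapped_count=unmapped)


def write_bed(mapped: MappedLibrary, path: str | Path) -> None:
    """Write hits as BED6: score = weight * 1000 rounded, strand +/-."""
    with open(path, "wt") as fh:
        for h in mapped.hits:
            score = 0 if h.weight is None else round(h.weight * 1000)
            strand = "+" if h.strand == SENSE else "-"
            fh.write(f"{h.transposon}\t{h.start}\t{h.end}\t{h.sequence}\t{score}\t{strand}\n")


def write_hits_tsv(mapped: MappedLibrary, path: str | Path) -> None:
    """Write hits as TSV including the 5'-coordinate column."""
    with open(path, "wt") as fh:
        fh.write("transposon\tstart\tend\tstrand\tfive_prime\tweight\tsequence\n")
        for h in mapped.hits:
            w = "" if h.weight is None else f"{h.weight:.6g}"
            fh.write(
                f"{h.transposon}\t{h.start}\t{h.end}\t{h.strand}\t{h.five_prime}\t{w}\t{h.sequence}\n"
            )
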