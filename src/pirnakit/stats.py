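"""Library-level descriptive statistics: read lengths, positional
nucleotide biases (1U, 10A), and per-transposon strand bias.

Positional biases are reported in RNA vocabulary (``U`` rather than ``T``)
because that is how the field labels them (1U-bias of primary piRNAs, 10A-bias
of ping-pong secondaries). By default every statistic is weighted by read
abundance; ``weighted=False`` switches to unique-sequence mode.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd

from .io import ConsensusSet, ReadLibrary
from .mapping import ANTISENSE, SENSE, MappedLibrary

__all__ = [
    "LengthHistogram",
    "PositionalBias",
    "StrandBiasRow",
    "length_histogram",
    "positional_base_fraction",
    "u1_bias",
    "a10_bias",
    "strand_bias_table",
    "write_length_tsv",
    "write_bias_tsv",
    "write_strand_tsv",
]

_BASES = ("A", "C", "G", "U")  # output labels; U stands for internal T


@dataclass(frozen=True)
class LengthHistogram:
    """Weighted read-length histogram."""

    counts: dict[int, float]

    @property
    def modal_length(self) -> int:
        """Length with the largest weight; ties break toward the smaller length."""
        peak = max(self.counts.values())
        return min(length for length, c in self.counts.items() if c == peak)


@dataclass(frozen=True)
class PositionalBias:
    """Base composition at one 1-based read position.

    ``n_eligible`` is the (weighted) number of reads long enough to have the
    position; fractions are taken over those reads and sum to 1.
    """

    position: int
    fractions: dict[str, float]
    n_eligible: float


@dataclass(frozen=True)
class StrandBiasRow:
    """Sense/antisense weight balance of one transposon.

    ``score = 2*sense_fraction - 1`` lies in [-1, +1]: +1 all sense, -1 all
    antisense. Both are ``None`` for transposons with no mapped weight.
    """

    transposon: str
    sense_weight: float
    antisense_weight: float
    sense_fraction: float | None
    score: float | None


def length_histogram(library: ReadLibrary, weighted: bool = True) -> LengthHistogram:
    """Count-weighted histogram of read lengths."""
    if len(library) == 0:
        raise ValueError(f"empty library {library.name!r}")
    counts: dict[int, float] = {}
    for seq, count in library:
        w = count if weighted else 1
        counts[len(seq)] = counts.get(len(seq), 0) + w
    return LengthHistogram(counts=counts)


def positional_base_fraction(
    library: ReadLibrary, position: int, weighted: bool = True
) -> PositionalBias:
    """Base fractions at a 1-based position over reads of length >= position."""
    if position < 1:
        raise ValueError("position must be >= 1")
    totals = {b: 0.0 for b in "ACGT"}
    n = 0.0
    for seq, count in library:
        if len(seq) < position:
            continue
        w = count if weighted else 1
        totals[seq[position - 1]] += w
        n += w
    if n == 0:
        raise ValueError(f"no read long enough for position {position} in {library.name!r}")
    fractions = {("U" if b == "T" else b): totals[b] / n for b in "ACGT"}
    return PositionalBias(position=position, fractions=fractions, n_eligible=n)


def u1_bias(library: ReadLibrary, weighted: bool = True) -> float:
    """Fraction of reads whose first (5') nucleotide is U."""
    return positional_base_fraction(library, 1, weighted=weighted).fractions["U"]


def a10_bias(library: ReadLibrary, weighted: bool = True) -> float:
    """Fraction of reads (length >= 10) with A at position 10."""
    return positional_base_fraction(library, 10, weighted=weighted).fractions["A"]


def strand_bias_table(
    mapped: MappedLibrary, consensus_set: ConsensusSet
) -> list[StrandBiasRow]:
    """Per-transposon sense/antisense weight balance from mapped hits.

    One row per consensus entry, in consensus order; entries with zero mapped
    weight get ``sense_fraction = score = None``.
    """
    sense: dict[str, float] = {name: 0.0 for name in consensus_set.names}
    anti: dict[str, float] = {name: 0.0 for name in consensus_set.names}
    for h in mapped.hits:
        w = h.weight if h.weight is not None else 1.0
        if h.strand == SENSE:
            sense[h.transposon] += w
        elif h.strand == ANTISENSE:
            anti[h.transposon] += w
        else:
            raise ValueError(f"unknown strand {h.strand!r}")
    rows = []
    for name in consensus_set.names:
        s, a = sense[name], anti[name]
        if s + a > 0:
            f = s / (s + a)
            rows.append(StrandBiasRow(name, s, a, f, 2 * f - 1))
        else:
            rows.append(StrandBiasRow(name, s, a, None, None))
    return rows


def write_length_tsv(hist: LengthHistogram, path: str | Path) -> None:
    df = pd.DataFrame(
        sorted(hist.counts.items()), columns=["length", "count"]
    )
    df.to_csv(path, sep="\t", index=False)


def write_bias_tsv(biases: Iterable[PositionalBias], path: str | Path) -> None:
    rows = [
        {"position": b.position, **{base: b.fractions[base] for base in _BASES}, "n": b.n_eligible}
        for b in biases
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_strand_tsv(rows: Iterable[StrandBiasRow], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "transposon": r.transposon,
                "sense_weight": r.sense_weight,
                "antisense_weight": r.antisense_weight,
                "sense_fraction": r.sense_fraction,
                "score": r.score,
            }
            for r in rows
        ]
    )
    df.to_csv(path, sep="\t", index=False)
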