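"""Generative simulator of piRNA biogenesis with per-read ground truth.

The model mirrors the two-branch biogenesis picture in the silkworm BmN4
system. *Primary* piRNAs are fragments of antisense transcripts: each read
sits on the antisense strand of a transposon consensus with a preference for
starting on a 5' uridine (1U-bias). *Secondary* piRNAs are slicer products of
the ping-pong cycle: each one picks a primary partner (abundance-weighted)
and lands on the opposite (sense) strand with its 5' end placed so the two
reads overlap across their 5' ends by exactly ``overlap`` nucleotides
(default 10). Because a 1U primary pairs its first base with the secondary's
tenth, an A10-bias of the secondaries *emerges* from complementarity rather
than being a generator parameter. *Mixture* libraries resample reads from
parent libraries at given proportions plus a fraction of novel random
sequences, emulating a chimera-bound population.

The 5'-U preference parameter ``p_1U`` is the target marginal: the generator
mixes U-conditioned and unconditioned start draws with a weight calibrated
per read length against the consensus background, so the expected 1U
fraction of the library equals ``p_1U`` whenever ``p_1U`` is at or above the
background U frequency (requests below background fall back to unconditioned
sampling). :func:`expected_u1` returns the exact expectation either way.

Randomness: each operation consumes a single ``numpy`` Generator seeded from
its config. Draw order is documented per operation and fixed, so outputs are
byte-identical across runs for a given seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import ConsensusEntry, ReadLibrary, revcomp
from .mapping import ANTISENSE, SENSE

__all__ = [
    "SimulatorConfig",
    "TruthRecord",
    "SimTruth",
    "triangular_length_law",
    "PRIMARY_LENGTH_LAW",
    "SECONDARY_LENGTH_LAW",
    "random_consensus",
    "simulate_primary",
    "expected_u1",
    "simulate_secondary",
    "simulate_mixture",
]


def triangular_length_law(lo: int = 24, hi: int = 32, mode: int = 28) -> dict[int, float]:
    """Discrete triangular length distribution on [lo, hi] peaking at ``mode``.

    Unnormalized weight ``min((l-lo+1)*(hi-mode+1), (hi-l+1)*(mode-lo+1))``
    rises linearly to the mode and falls linearly after it.
    """
    if not lo <= mode <= hi:
        raise ValueError("need lo <= mode <= hi")
    weights = {
        l: float(min((l - lo + 1) * (hi - mode + 1), (hi - l + 1) * (mode - lo + 1)))
        for l in range(lo, hi + 1)
    }
    total = sum(weights.values())
    return {l: w / total for l, w in weights.items()}


# Siwi-bound primary piRNAs peak at 28 nt, Ago3-bound secondaries at 27 nt.
PRIMARY_LENGTH_LAW = triangular_length_law(24, 32, 28)
SECONDARY_LENGTH_LAW = triangular_length_law(24, 32, 27)


@dataclass(frozen=True)
class SimulatorConfig:
    """Parameters of one simulation stage.

    Parameters
    ----------
    n_reads
        Number of reads to draw.
    seed
        Seed for this stage's Generator.
    p_1U
        Target marginal probability that a primary read starts with U.
    length_law
        Discrete read-length distribution (nt -> probability); defaults to
        the triangular law with mode 28 for primaries and 27 for secondaries.
    overlap
        5'-5' overlap (nt) enforced between a secondary and its partner.
    gc_content
        GC fraction for random consensus / novel-read generation.
    """

    n_reads: int
    seed: int
    p_1U: float = 0.8
    length_law: Mapping[int, float] | None = None
    overlap: int = 10
    gc_content: float = 0.5

    def __post_init__(self) -> None:
        if self.n_reads < 1:
            raise ValueError("n_reads must be >= 1")
        if not 0.0 <= self.p_1U <= 1.0:
            raise ValueError("p_1U must be in [0, 1]")
        if self.overlap < 1:
            raise ValueError("overlap must be >= 1")
        if not 0.0 <= self.gc_content <= 1.0:
            raise ValueError("gc_content must be in [0, 1]")
        if self.length_law is not None:
            probs = np.array(list(self.length_law.values()), dtype=float)
            if (probs < 0).any() or abs(probs.sum() - 1.0) > 1e-9:
                raise ValueError("length_law must be a probability distribution")

    def law(self, default: Mapping[int, float]) -> tuple[np.ndarray, np.ndarray]:
        law = self.length_law if self.length_law is not None else default
        lengths = np.array(sorted(law), dtype=int)
        probs = np.array([law[int(l)] for l in lengths], dtype=float)
        return lengths, probs / probs.sum()


@dataclass(frozen=True)
class TruthRecord:
    """Ground truth for one simulated read (one raw read, pre-collapsing)."""

    read_id: str
    sequence: str
    origin: str  # primary | secondary | novel | <parent library name>
    transposon: str | None = None
    five_prime: int | None = None
    strand: str | None = None
    partner_id: str | None = None


@dataclass
class SimTruth:
    """Per-read ground-truth records for a simulated library."""

    records: list[TruthRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.records)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "read_id": r.read_id,
                    "sequence": r.sequence,
                    "transposon": r.transposon,
                    "five_prime": r.five_prime,
                    "strand": r.strand,
                    "origin": r.origin,
                    "partner_id": r.partner_id,
                }
                for r in self.records
            ]
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def random_consensus(
    length: int, gc_content: float, seed: int, name: str = "consensus"
) -> ConsensusEntry:
    """Random transposon-consensus stand-in: i.i.d. bases at the given GC.

    P(G) = P(C) = gc/2 and P(A) = P(T) = (1-gc)/2; reproducible under seed.
    """
    if length < 50:
        raise ValueError("consensus length must be >= 50")
    if not 0.0 <= gc_content <= 1.0:
        raise ValueError("gc_content must be in [0, 1]")
    rng = np.random.default_rng(seed)
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    bases = rng.choice(np.array(["A", "C", "G", "T"]), size=length, p=[at, gc, gc, at])
    return ConsensusEntry(name=name, sequence="".join(bases))


def _u_start_positions(consensus: str) -> np.ndarray:
    """Sorted antisense 5' coordinates where the read would start with U.

    An antisense read with 5' end at consensus coordinate q begins with the
    complement of consensus[q], so a U start requires consensus base A.
    """
    return np.flatnonzero(np.frombuffer(consensus.encode(), dtype=np.uint8) == ord("A"))


def simulate_primary(
    consensus: ConsensusEntry, config: SimulatorConfig, name: str = "primary"
) -> tuple[ReadLibrary, SimTruth]:
    """Draw primary piRNAs from the antisense strand of a consensus.

    Per read: length L from the length law, then the 5' coordinate q — with
    the calibrated mixing probability for L, uniformly over eligible positions
    (q >= L-1) whose antisense base is U, otherwise uniformly over all
    eligible positions. The read is the reverse complement of
    consensus[q-L+1 : q+1]. Draw order: all lengths, then all mixing coins,
    then one position draw per read.
    """
    seq = consensus.sequence
    c_len = len(seq)
    lengths, probs = config.law(PRIMARY_LENGTH_LAW)
    if c_len < int(lengths.max()):
        raise ValueError("consensus shorter than the longest read length")
    u_positions = _u_start_positions(seq)

    # per-length eligible sets, background U frequency, calibrated mix weight
    per_length: dict[int, tuple[np.ndarray, float, float]] = {}
    for L in lengths:
        L = int(L)
        n_eligible = c_len - L + 1
        u_elig = u_positions[u_positions >= L - 1]
        f_bg = len(u_elig) / n_eligible
        if f_bg >= 1.0:
            q_mix = 1.0
        else:
            q_mix = min(1.0, max(0.0, (config.p_1U - f_bg) / (1.0 - f_bg)))
        if q_mix > 0 and len(u_elig) == 0:
            raise ValueError(f"no U-start position for length {L} on consensus {consensus.name!r}")
        per_length[L] = (u_elig, f_bg, q_mix)

    rng = np.random.default_rng(config.seed)
    n = config.n_reads
    draw_lengths = rng.choice(lengths, size=n, p=probs)
    coins = rng.random(n)
    reads: list[str] = []
    records: list[TruthRecord] = []
    for i in range(n):
        L = int(draw_lengths[i])
        u_elig, _, q_mix = per_length[L]
        if coins[i] < q_mix:
            q = int(u_elig[rng.integers(len(u_elig))])
        else:
            q = int(rng.integers(L - 1, c_len))
        read = revcomp(seq[q - L + 1 : q + 1])
        reads.append(read)
        records.append(
            TruthRecord(
                read_id=f"{name}_{i}",
                sequence=read,
                origin="primary",
                transposon=consensus.name,
                five_prime=q,
                strand=ANTISENSE,
            )
        )
    return ReadLibrary.from_sequences(name, reads), SimTruth(records)


def expected_u1(consensus: ConsensusEntry, config: SimulatorConfig) -> float:
    """Exact expected 1U fraction of :func:`simulate_primary` output.

    Sum over lengths of P(L) * (q_mix(L) + (1 - q_mix(L)) * f_bg(L)), with
    f_bg(L) the U-start frequency among eligible positions, computed by
    direct enumeration of the consensus.
    """
    seq = consensus.sequence
    c_len = len(seq)
    lengths, probs = config.law(PRIMARY_LENGTH_LAW)
    u_positions = _u_start_positions(seq)
    expectation = 0.0
    for L, p in zip(lengths, probs):
        L = int(L)
        n_eligible = c_len - L + 1
        f_bg = int((u_positions >= L - 1).sum()) / n_eligible
        if f_bg >= 1.0:
            q_mix = 1.0
        else:
            q_mix = min(1.0, max(0.0, (config.p_1U - f_bg) / (1.0 - f_bg)))
        expectation += p * (q_mix + (1.0 - q_mix) * f_bg)
    return expectation


def simulate_secondary(
    primary_truth: SimTruth,
    consensus: ConsensusEntry,
    config: SimulatorConfig,
    name: str = "secondary",
) -> tuple[ReadLibrary, SimTruth]:
    """Draw slicer-coupled secondary piRNAs from a primary ground truth.

    Per read (repeating until the read fits the consensus): pick a partner
    uniformly over primary truth records (records are per raw read, so this
    is abundance-weighted), draw a length L, and place the read on the sense
    strand with 5' coordinate p = q - (overlap - 1), where q is the partner's
    antisense 5' coordinate — a 5'-5' overlap of exactly ``overlap`` nt.
    The 3' end is independent of the partner (length drawn fresh).
    """
    partners = [
        r
        for r in primary_truth.records
        if r.strand == ANTISENSE and r.transposon == consensus.name and r.five_prime is not None
    ]
    if not partners:
        raise ValueError("no antisense primary records to partner with")
    seq = consensus.sequence
    c_len = len(seq)
    lengths, probs = config.law(SECONDARY_LENGTH_LAW)
    rng = np.random.default_rng(config.seed)
    reads: list[str] = []
    records: list[TruthRecord] = []
    max_attempts = 10_000
    for i in range(config.n_reads):
        for _ in range(max_attempts):
            partner = partners[int(rng.integers(len(partners)))]
            L = int(rng.choice(lengths, p=probs))
            p = partner.five_prime - (config.overlap - 1)
            if p >= 0 and p + L <= c_len:
                break
        else:
            raise ValueError("overlap geometry impossible for every primary partner")
        read = seq[p : p + L]
        reads.append(read)
        records.append(
            TruthRecord(
                read_id=f"{name}_{i}",
                sequence=read,
                origin="secondary",
                transposon=consensus.name,
                five_prime=p,
                strand=SENSE,
                partner_id=partner.read_id,
            )
        )
    return ReadLibrary.from_sequences(name, reads), SimTruth(records)


def simulate_mixture(
    libraries: Sequence[ReadLibrary],
    proportions: Sequence[float],
    n_reads: int,
    novel_fraction: float,
    seed: int,
    length_law: Mapping[int, float] | None = None,
    gc_content: float = 0.5,
    name: str = "mixture",
) -> tuple[ReadLibrary, SimTruth]:
    """Resample a chimera-like library from parent libraries plus novel reads.

    Per read: with probability ``novel_fraction`` a novel random sequence
    (uniform over the parent-free sequence space at the given GC, length from
    ``length_law``, default primary law); otherwise a parent library chosen
    by ``proportions`` and a sequence drawn abundance-weighted from it.
    Draw order: novel mask for all reads, parent choices for all reads, then
    bulk per-parent sequence draws (parents in input order), then novel reads.
    """
    if len(libraries) != len(proportions) or not libraries:
        raise ValueError("need one proportion per parent library")
    props = np.asarray(proportions, dtype=float)
    if (props < 0).any() or abs(props.sum() - 1.0) > 1e-6:
        raise ValueError("proportions must be nonnegative and sum to 1")
    if not 0.0 <= novel_fraction <= 1.0:
        raise ValueError("novel_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    novel_mask = rng.random(n_reads) < novel_fraction
    parent_choice = rng.choice(len(libraries), size=n_reads, p=props / props.sum())

    sequences: list[str | None] = [None] * n_reads
    origins: list[str] = [""] * n_reads
    parent_seqs = set()
    for lib in libraries:
        parent_seqs.update(lib.records)
    for k, lib in enumerate(libraries):
        idx = np.flatnonzero(~novel_mask & (parent_choice == k))
        if len(idx) == 0:
            continue
        seqs = sorted(lib.records)
        counts = np.array([lib.records[s] for s in seqs], dtype=float)
        picks = rng.choice(len(seqs), size=len(idx), p=counts / counts.sum())
        for j, pick in zip(idx, picks):
            sequences[j] = seqs[int(pick)]
            origins[j] = lib.name

    law = dict(length_law) if length_law is not None else PRIMARY_LENGTH_LAW
    lengths = np.array(sorted(law), dtype=int)
    probs = np.array([law[int(l)] for l in lengths], dtype=float)
    probs = probs / probs.sum()
    at = (1.0 - gc_content) / 2.0
    gc = gc_content / 2.0
    alphabet = np.array(["A", "C", "G", "T"])
    for j in np.flatnonzero(novel_mask):
        while True:
            L = int(rng.choice(lengths, p=probs))
            novel = "".join(rng.choice(alphabet, size=L, p=[at, gc, gc, at]))
            if novel not in parent_seqs:
                break
        sequences[j] = novel
        origins[j] = "novel"

    records = [
        TruthRecord(read_id=f"{name}_{i}", sequence=sequences[i], origin=origins[i])
        for i in range(n_reads)
    ]
    return ReadLibrary.from_sequences(name, sequences), SimTruth(records)
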