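"""The ping-pong signature: 5'-5' overlap distances between opposite-strand
read populations on a shared consensus, and a z-score for the 10-nt peak.

For a pair of hits on the same transposon and opposite strands, with ``p`` the
5' coordinate of the sense-strand hit and ``q`` the 5' coordinate of the
antisense-strand hit, the overlap distance is ``d = q - p + 1``: two reads
whose 5' ends are 9 nt apart overlap by 10 nt, the hallmark of slicer-coupled
secondary biogenesis. Pairs contribute the product of their hit weights;
pairs with ``d`` outside the requested range (including 3'-side
configurations, ``d < 1``) are ignored.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .mapping import ANTISENSE, SENSE, MappedLibrary

__all__ = [
    "OverlapHistogram",
    "PingPongScore",
    "overlap_histogram",
    "pingpong_zscore",
    "write_overlap_tsv",
    "write_score_tsv",
]


@dataclass(frozen=True)
class OverlapHistogram:
    """Weighted counts of 5'-5' overlap distances within [dmin, dmax]."""

    dmin: int
    dmax: int
    counts: dict[int, float]

    @property
    def total_pairs(self) -> float:
        return sum(self.counts.values())

    @property
    def modal_distance(self) -> int | None:
        """Distance with the largest weight, or None for an empty histogram."""
        if not self.counts or self.total_pairs == 0:
            return None
        peak = max(self.counts.values())
        return min(d for d, c in self.counts.items() if c == peak)


@dataclass(frozen=True)
class PingPongScore:
    """z-score of the target overlap bin against the other bins.

    ``z`` is ``None`` when the background sample standard deviation is zero
    (e.g. all mass in the target bin).
    """

    target_bin: int
    z: float | None
    background_mean: float
    background_sd: float


def _strand_profiles(
    mapped: MappedLibrary,
) -> tuple[dict[str, dict[int, float]], dict[str, dict[int, float]]]:
    """Per-transposon 5'-coordinate weight profiles, split by strand."""
    sense: dict[str, dict[int, float]] = defaultdict(lambda: defaultdict(float))
    anti: dict[str, dict[int, float]] = defaultdict(lambda: defaultdict(float))
    for h in mapped.hits:
        w = h.weight if h.weight is not None else 1.0
        target = sense if h.strand == SENSE else anti
        target[h.transposon][h.five_prime] += w
    return sense, anti


def overlap_histogram(
    mapped_a: MappedLibrary,
    mapped_b: MappedLibrary,
    dmin: int = 1,
    dmax: int = 30,
) -> OverlapHistogram:
    """5'-5' overlap histogram between two mapped libraries.

    Every pair of hits (one from each library) on the same transposon and on
    opposite strands contributes ``weight_a * weight_b`` to the bin of its
    overlap distance. The histogram is symmetric in its two arguments.
    """
    if dmin < 1 or dmax < dmin:
        raise ValueError("require 1 <= dmin <= dmax")
    if not mapped_a.hits or not mapped_b.hits:
        warnings.warn("empty mapped library: overlap histogram has no pairs")
        return OverlapHistogram(dmin, dmax, {d: 0.0 for d in range(dmin, dmax + 1)})
    sense_a, anti_a = _strand_profiles(mapped_a)
    sense_b, anti_b = _strand_profiles(mapped_b)
    counts = {d: 0.0 for d in range(dmin, dmax + 1)}
    for sense, anti in ((sense_a, anti_b), (sense_b, anti_a)):
        for transposon, s_prof in sense.items():
            a_prof = anti.get(transposon)
            if not a_prof:
                continue
            for p, ws in s_prof.items():
                for d in range(dmin, dmax + 1):
                    wa = a_prof.get(p + d - 1)
                    if wa:
                        counts[d] += ws * wa
    return OverlapHistogram(dmin, dmax, counts)


def pingpong_zscore(histogram: OverlapHistogram, target_bin: int = 10) -> PingPongScore:
    """z-score of the target bin against all other bins of the histogram.

    Background is every bin in [dmin, dmax] except the target; the z-score
    uses the sample (n-1) standard deviation of the background.
    """
    if not histogram.dmin <= target_bin <= histogram.dmax:
        raise ValueError(f"target bin {target_bin} outside [{histogram.dmin}, {histogram.dmax}]")
    background = np.array(
        [histogram.counts.get(d, 0.0) for d in range(histogram.dmin, histogram.dmax + 1) if d != target_bin]
    )
    if background.size < 3:
        raise ValueError("need at least 3 background bins for a z-score")
    mean = float(background.mean())
    sd = float(background.std(ddof=1))
    target = histogram.counts.get(target_bin, 0.0)
    if sd > 0:
        z = (target - mean) / sd
    elif target == mean:  # perfectly flat histogram: no enrichment by definition
        z = 0.0
    else:  # all mass in the target bin: undefined, not infinite
        z = None
    return PingPongScore(target_bin=target_bin, z=z, background_mean=mean, background_sd=sd)


def write_overlap_tsv(histogram: OverlapHistogram, path: str | Path) -> None:
    total = histogram.total_pairs
    with open(path, "wt") as fh:
        fh.write("distance\tweighted_count\tfraction\n")
        for d in range(histogram.dmin, histogram.dmax + 1):
            c = histogram.counts.get(d, 0.0)
            frac = c / total if total > 0 else 0.0
            fh.write(f"{d}\t{c:.6g}\t{frac:.6g}\n")


def write_score_tsv(score: PingPongScore, path: str | Path) -> None:
    with open(path, "wt") as fh:
        fh.write("target_bin\tz\tbackground_mean\tbackground_sd\n")
        z = "NA" if score.z is None else f"{score.z:.6g}"
        fh.write(f"{score.target_bin}\t{z}\t{score.background_mean:.6g}\t{score.background_sd:.6g}\n")
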