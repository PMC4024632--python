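"""Cross-library read sharing and fold-enrichment classification.

Two immunoprecipitation libraries rarely partition their reads cleanly: an
abundant read in one library often appears at least as a singleton in the
other. Reads are therefore attributed by a fold-enrichment rule on
depth-normalized abundances (reads per million): a sequence at least
``fold`` times more abundant in library A than in B is called A-only, the
mirror case B-only, and anything in between shared. A third ("chimera")
library is then partitioned by looking each of its sequences up in the two
parents and inheriting that class; sequences absent from both parents are
"only in chimera".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .io import ReadLibrary

__all__ = [
    "A_ONLY",
    "B_ONLY",
    "SHARED",
    "ABSENT",
    "EnrichmentClassification",
    "ChimeraPartition",
    "normalize_rpm",
    "classify_sequences",
    "partition_chimera",
]

A_ONLY = "A_only"
B_ONLY = "B_only"
SHARED = "shared_AB"
ABSENT = "absent"


@dataclass(frozen=True)
class EnrichmentClassification:
    """Per-sequence enrichment classes over the union of two libraries."""

    classes: dict[str, str]
    fold_threshold: float
    normalization: str

    def counts(self) -> dict[str, int]:
        out = {A_ONLY: 0, B_ONLY: 0, SHARED: 0}
        for c in self.classes.values():
            out[c] += 1
        return out


@dataclass(frozen=True)
class ChimeraPartition:
    """Attribution of a chimera library's reads to its two parent libraries.

    All fractions are weighted by chimera read counts and taken over the whole
    chimera library, so ``fraction_in_parents + fraction_only_in_chimera = 1``
    and the class fractions sum to ``fraction_in_parents``.
    """

    fraction_in_parents: float
    fraction_only_in_chimera: float
    class_fractions: dict[str, float]
    per_sequence: pd.DataFrame

    def write_tsv(self, reads_path: str | Path, summary_path: str | Path) -> None:
        self.per_sequence.to_csv(reads_path, sep="\t", index=False)
        summary = pd.DataFrame(
            [
                {"metric": "fraction_in_parents", "value": self.fraction_in_parents},
                {"metric": "fraction_only_in_chimera", "value": self.fraction_only_in_chimera},
                *[
                    {"metric": f"fraction_{k}", "value": v}
                    for k, v in self.class_fractions.items()
                ],
            ]
        )
        summary.to_csv(summary_path, sep="\t", index=False)


def normalize_rpm(library: ReadLibrary) -> dict[str, float]:
    """Reads-per-million for every sequence: count * 1e6 / total_count."""
    total = library.total_count
    if total == 0:
        raise ValueError(f"empty library {library.name!r}")
    return {seq: count * 1e6 / total for seq, count in library}


def classify_sequences(
    lib_a: ReadLibrary,
    lib_b: ReadLibrary,
    fold: float = 5.0,
    normalization: str = "rpm",
) -> EnrichmentClassification:
    """Classify every sequence in the union of two libraries by fold enrichment.

    With per-sequence abundances ``a`` and ``b`` (rpm by default, raw counts
    with ``normalization="raw"``): ``a >= fold*b`` -> A-only, ``b >= fold*a``
    -> B-only, otherwise shared. Absence means abundance 0, so a sequence seen
    in only one library is always that side's exclusive class. Ties at exactly
    the threshold count as enriched.
    """
    if fold <= 1:
        raise ValueError("fold threshold must be > 1")
    if normalization == "rpm":
        a_vals = normalize_rpm(lib_a)
        b_vals = normalize_rpm(lib_b)
    elif normalization == "raw":
        a_vals = {s: float(c) for s, c in lib_a}
        b_vals = {s: float(c) for s, c in lib_b}
    else:
        raise ValueError(f"unknown normalization {normalization!r}")
    classes: dict[str, str] = {}
    for seq in set(a_vals) | set(b_vals):
        a = a_vals.get(seq, 0.0)
        b = b_vals.get(seq, 0.0)
        if a >= fold * b and a > 0:
            classes[seq] = A_ONLY
        elif b >= fold * a and b > 0:
            classes[seq] = B_ONLY
        else:
            classes[seq] = SHARED
    return EnrichmentClassification(classes=classes, fold_threshold=fold, normalization=normalization)


def partition_chimera(
    chimera: ReadLibrary,
    lib_a: ReadLibrary,
    lib_b: ReadLibrary,
    fold: float = 5.0,
    normalization: str = "rpm",
) -> ChimeraPartition:
    """Attribute chimera reads to the parent libraries under the fold rule.

    Each chimera sequence found in either parent is labeled with its
    :func:`classify_sequences` class; the rest are "only in chimera"
    (class ``absent``). Fractions are weighted by chimera counts.
    """
    classification = classify_sequences(lib_a, lib_b, fold=fold, normalization=normalization)
    a_rpm = normalize_rpm(lib_a)
    b_rpm = normalize_rpm(lib_b)
    total = chimera.total_count
    if total == 0:
        raise ValueError(f"empty chimera library {chimera.name!r}")
    weight_in_parents = 0.0
    class_weights = {A_ONLY: 0.0, B_ONLY: 0.0, SHARED: 0.0}
    rows = []
    for seq, count in chimera:
        cls = classification.classes.get(seq, ABSENT)
        if cls != ABSENT:
            weight_in_parents += count
            class_weights[cls] += count
        rows.append(
            {
                "sequence": seq,
                "count_chimera": count,
                "rpm_A": a_rpm.get(seq, 0.0),
                "rpm_B": b_rpm.get(seq, 0.0),
                "class": cls,
            }
        )
    frac_parents = weight_in_parents / total
    return ChimeraPartition(
        fraction_in_parents=frac_parents,
        fraction_only_in_chimera=1.0 - frac_parents,
        class_fractions={k: v / total for k, v in class_weights.items()},
        per_sequence=pd.DataFrame(rows),
    )
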