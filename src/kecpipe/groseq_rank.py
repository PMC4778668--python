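"""Ranking genes by nascent transcription and reordering ChIP matrices.

GRO-seq coverage is ingested as two bedGraph tracks (plus- and
minus-strand reads).  For each gene the sense-strand signal is summed over
a strand-oriented window around the TSS (default -250..+1000, the same
window used for the co-occupancy analysis); genes are then ranked by
decreasing sense signal — by default restricted to plus-strand genes —
and ChIP signal matrices are reordered to that ranking.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .annotation import TSSRecord
from .interval_io import SignalTrack
from .metagene import SignalMatrix

__all__ = [
    "StrandedCoverage",
    "GeneRanking",
    "sense_tss_signal",
    "rank_genes",
    "reorder_by_ranking",
]

logger = logging.getLogger(__name__)


@dataclass
class StrandedCoverage:
    """Plus- and minus-strand nascent-transcription coverage tracks."""

    plus: SignalTrack
    minus: SignalTrack

    def sense(self, strand: str) -> SignalTrack:
        if strand == "+":
            return self.plus
        if strand == "-":
            return self.minus
        raise ValueError(f"bad strand {strand!r}")


@dataclass
class GeneRanking:
    """Genes ordered by decreasing sense signal."""

    entries: list[tuple[str, float]]  # (gene_id, signal), non-increasing

    def __post_init__(self) -> None:
        ids = [g for g, _ in self.entries]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate gene ids in ranking")
        values = [v for _, v in self.entries]
        if any(a < b for a, b in zip(values, values[1:])):
            raise ValueError("ranking values not non-increasing")

    @property
    def gene_ids(self) -> list[str]:
        return [g for g, _ in self.entries]

    def __len__(self) -> int:
        return len(self.entries)


def sense_tss_signal(
    coverage: StrandedCoverage,
    tss: TSSRecord,
    window_up: int = 250,
    window_down: int = 1000,
) -> float:
    """Total sense-strand signal in the strand-oriented TSS window.

    The window covers signed offsets [-window_up, +window_down] inclusive.
    A chromosome absent from the sense track yields 0 with a warning.
    """
    if window_up < 0 or window_down < 0:
        raise ValueError("window bounds must be non-negative")
    track = coverage.sense(tss.strand)
    if not track.has_chrom(tss.chrom):
        logger.warning("chromosome %s absent from sense track; signal 0", tss.chrom)
        return 0.0
    if tss.strand == "+":
        lo, hi = tss.tss - window_up, tss.tss + window_down + 1
    else:
        lo, hi = tss.tss - window_down, tss.tss + window_up + 1
    return track.interval_sum(tss.chrom, max(lo, 0), hi)


def rank_genes(
    coverage: StrandedCoverage,
    tss_set: Sequence[TSSRecord],
    window_up: int = 250,
    window_down: int = 1000,
    plus_strand_only: bool = True,
) -> GeneRanking:
    """Rank genes by decreasing sense TSS signal; ties broken by gene id.

    The default restricts the ranking to plus-strand genes;
    ``plus_strand_only=False`` ranks both strands sense-aware.
    """
    selected = [
        t for t in tss_set if (t.strand == "+" or not plus_strand_only)
    ]
    if not selected:
        raise ValueError("no genes to rank (empty or all filtered by strand)")
    scored = [
        (t.gene_id, sense_tss_signal(coverage, t, window_up, window_down))
        for t in selected
    ]
    scored.sort(key=lambda e: (-e[1], e[0]))
    return GeneRanking(entries=scored)


def reorder_by_ranking(matrix: SignalMatrix, ranking: GeneRanking) -> SignalMatrix:
    """Permute matrix rows into ranking order.

    Ranking entries absent from the matrix are skipped; matrix anchors
    absent from the ranking are dropped (count logged).  Row contents are
    never modified.
    """
    index_of = {a.gene_id: i for i, a in enumerate(matrix.anchors)}
    order = [index_of[g] for g in ranking.gene_ids if g in index_of]
    if not order:
        raise ValueError("ranking and matrix share no gene ids")
    dropped = len(matrix.anchors) - len(order)
    if dropped:
        logger.info("%d matrix anchors absent from ranking dropped", dropped)
    return SignalMatrix(
        anchors=[matrix.anchors[i] for i in order],
        half_width=matrix.half_width,
        bin_size=matrix.bin_size,
        values=matrix.values[np.asarray(order)].copy(),
    )
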