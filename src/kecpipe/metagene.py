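"""TSS-anchored signal matrices, metagene profiles and density ranking.

A :class:`SignalMatrix` holds, for each anchor TSS, the mean per-bp pileup
signal in consecutive fixed-width bins spanning [-half_width, +half_width)
around the anchor.  Rows are strand-oriented — bin 0 is always the most
upstream bin, so the TSS sits exactly on the boundary between the two
central bins.  The cell statistic is the mean per-bp value (not the sum),
which makes profiles invariant to the choice of bin size.

From the matrix: column means give the metagene (average) profile, either
in RPKM (per-million pileup x 1000/kb) or normalized to percent of the
profile maximum; the offset of the profile maximum estimates the average
Pol II pause site; and rows can be rank-ordered by decreasing total
density to build heatmap matrices, with the Pol II ordering applied to
every other factor's matrix.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .annotation import TSSRecord
from .interval_io import SignalTrack

__all__ = [
    "SignalMatrix",
    "MetageneProfile",
    "matrix_from_track",
    "average_profile",
    "max_normalize",
    "peak_offset",
    "sort_by_density",
    "apply_order",
]

logger = logging.getLogger(__name__)


@dataclass
class SignalMatrix:
    """Anchors x bins matrix of strand-oriented mean per-bp signal."""

    anchors: list[TSSRecord]
    half_width: int
    bin_size: int
    values: np.ndarray

    def __post_init__(self) -> None:
        expected = 2 * self.half_width // self.bin_size
        if self.values.shape != (len(self.anchors), expected):
            raise ValueError(
                f"matrix shape {self.values.shape} != "
                f"({len(self.anchors)}, {expected})"
            )

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def bin_centers(self) -> np.ndarray:
        """Signed offset of each bin's center (bp from TSS)."""
        return -self.half_width + (np.arange(self.n_bins) + 0.5) * self.bin_size

    @property
    def anchor_ids(self) -> list[str]:
        return [a.gene_id for a in self.anchors]

    def row_sums(self) -> np.ndarray:
        return self.values.sum(axis=1)


@dataclass
class MetageneProfile:
    """Average signal per bin across anchors."""

    bin_centers: np.ndarray
    values: np.ndarray
    mode: str  # "rpkm", "track", or "percent_of_max"

    def __post_init__(self) -> None:
        if self.bin_centers.shape != self.values.shape:
            raise ValueError("bin_centers and values length mismatch")


def matrix_from_track(
    track: SignalTrack,
    anchors: Sequence[TSSRecord],
    half_width: int = 1000,
    bin_size: int = 50,
) -> SignalMatrix:
    """Bin the pileup track around each anchor into a strand-oriented matrix.

    Cell (i, j) is the mean per-bp track value over bin j's genomic span
    for anchor i.  Minus-strand rows are reversed so bins run upstream to
    downstream.  Genomic positions beyond chromosome/track bounds
    contribute 0.  Anchors on chromosomes absent from the track yield a
    zero row with a logged warning.
    """
    if bin_size <= 0 or half_width <= 0:
        raise ValueError("half_width and bin_size must be positive")
    if (2 * half_width) % bin_size != 0:
        raise ValueError(
            f"bin_size {bin_size} must divide window width {2 * half_width}"
        )
    n_bins = 2 * half_width // bin_size
    values = np.zeros((len(anchors), n_bins), dtype=float)
    missing = 0
    for i, tss in enumerate(anchors):
        if not track.has_chrom(tss.chrom):
            missing += 1
            continue
        if tss.strand == "+":
            # offsets [-hw, +hw) map to genomic [tss-hw, tss+hw)
            lo = tss.tss - half_width
            hi = tss.tss + half_width
        else:
            # offset d maps to genomic tss-d; offsets [-hw, +hw) map to
            # genomic (tss-hw, tss+hw], i.e. [tss-hw+1, tss+hw+1)
            lo = tss.tss - half_width + 1
            hi = tss.tss + half_width + 1
        clip_lo, clip_hi = max(lo, 0), hi
        row = np.zeros(2 * half_width, dtype=float)
        if clip_hi > clip_lo:
            row[clip_lo - lo : clip_hi - lo] = track.per_bp(
                tss.chrom, clip_lo, clip_hi
            )
        if tss.strand == "-":
            row = row[::-1]
        values[i] = row.reshape(n_bins, bin_size).mean(axis=1)
    if missing:
        logger.warning(
            "%d/%d anchors on chromosomes absent from track; rows zero-filled",
            missing,
            len(anchors),
        )
    return SignalMatrix(
        anchors=list(anchors), half_width=half_width, bin_size=bin_size, values=values
    )


def average_profile(matrix: SignalMatrix, mode: str = "rpkm") -> MetageneProfile:
    """Column means across anchors; the metagene profile.

    ``mode="rpkm"`` scales the mean per-bp per-million signal by 1000
    (per-kb), assuming per-million-normalized input tracks; ``"track"``
    leaves values in raw track units.
    """
    if len(matrix.anchors) == 0:
        raise ValueError("cannot average an empty matrix")
    if mode not in ("rpkm", "track"):
        raise ValueError(f"bad profile mode {mode!r}")
    means = matrix.values.mean(axis=0)
    if mode == "rpkm":
        means = means * 1000.0
    return MetageneProfile(bin_centers=matrix.bin_centers.copy(), values=means, mode=mode)


def max_normalize(profile: MetageneProfile) -> MetageneProfile:
    """Rescale a profile to percent of its maximum (max bin = 100)."""
    peak = float(profile.values.max())
    if peak <= 0:
        raise ValueError("cannot max-normalize an all-zero profile")
    return MetageneProfile(
        bin_centers=profile.bin_centers.copy(),
        values=profile.values * (100.0 / peak),
        mode="percent_of_max",
    )


def peak_offset(profile: MetageneProfile) -> float:
    """Signed bp offset of the profile maximum (bin-center convention).

    Ties are broken toward the bin center closest to the TSS, then
    upstream (more negative).
    """
    values = profile.values
    if values.max() <= 0:
        raise ValueError("all-zero profile has no peak")
    top = np.flatnonzero(values == values.max())
    centers = profile.bin_centers[top]
    best = min(centers.tolist(), key=lambda c: (abs(c), c))
    return float(best)


def sort_by_density(matrix: SignalMatrix) -> np.ndarray:
    """Row ordering by decreasing total density; equal sums keep input order."""
    sums = matrix.row_sums()
    return np.argsort(-sums, kind="stable")


def apply_order(matrix: SignalMatrix, ordering: np.ndarray) -> SignalMatrix:
    """Permute matrix rows (and anchors) to the given ordering."""
    ordering = np.asarray(ordering)
    if sorted(ordering.tolist()) != list(range(len(matrix.anchors))):
        raise ValueError("ordering is not a permutation of the row indices")
    return SignalMatrix(
        anchors=[matrix.anchors[i] for i in ordering],
        half_width=matrix.half_width,
        bin_size=matrix.bin_size,
        values=matrix.values[ordering].copy(),
    )
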