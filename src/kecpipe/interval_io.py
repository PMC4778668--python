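"""Readers and writers for the genomic text formats the pipeline touches.

Supported formats: ENCODE narrowPeak (BED6+4), UCSC bedGraph, chrom.sizes
and Cluster 3.0 CDT matrices.  Readers reject malformed records (naming the
line) rather than silently repairing them; every writer emits files its
paired reader accepts.

bedGraph signal is assumed to be already normalized per million mapped
reads (MACS2 ``--SPMR`` semantics): tracks are comparable across samples
and this package never rescales them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "GenomicInterval",
    "Peak",
    "SignalTrack",
    "read_narrowpeak",
    "write_narrowpeak",
    "read_bedgraph",
    "write_bedgraph",
    "write_cdt",
    "read_cdt",
]


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    lo: int
    hi: int

    def __post_init__(self) -> None:
        if self.lo < 0:
            raise ValueError(f"negative start {self.lo}")
        if self.hi <= self.lo:
            raise ValueError(f"empty/inverted interval [{self.lo}, {self.hi})")

    def __len__(self) -> int:
        return self.hi - self.lo

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom and self.lo < other.hi and other.lo < self.hi
        )


@dataclass(frozen=True)
class Peak:
    """A called peak with narrowPeak semantics.

    ``summit_offset`` is the distance in bp from ``interval.lo`` to the
    single-bp position of maximal signal.  ``summit_imputed`` flags peaks
    whose input summit column was -1 (no summit refinement); those fall
    back to the interval midpoint.
    """

    interval: GenomicInterval
    name: str = "."
    score: float = 0.0
    strand: str = "."
    signal: float = 0.0
    pvalue_neglog10: float = -1.0
    qvalue_neglog10: float = -1.0
    summit_offset: int = 0
    summit_imputed: bool = False

    def __post_init__(self) -> None:
        if self.summit_offset < 0:
            raise ValueError(f"negative summit offset {self.summit_offset}")
        if self.interval.lo + self.summit_offset >= self.interval.hi:
            raise ValueError(
                f"summit offset {self.summit_offset} outside interval "
                f"[{self.interval.lo}, {self.interval.hi})"
            )

    @property
    def chrom(self) -> str:
        return self.interval.chrom

    @property
    def summit(self) -> int:
        """Absolute genomic position of the summit."""
        return self.interval.lo + self.summit_offset


def read_narrowpeak(path: str | Path) -> list[Peak]:
    """Parse a 10-column ENCODE narrowPeak file.

    A summit column of -1 (peak caller emitted no point-source) is mapped
    to the interval midpoint and flagged via ``summit_imputed``.
    """
    path = str(path)
    peaks: list[Peak] = []
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 10:
                raise ValueError(
                    f"{path}:{lineno}: narrowPeak needs 10 columns, got {len(fields)}"
                )
            try:
                lo, hi = int(fields[1]), int(fields[2])
                score = float(fields[4])
                signal = float(fields[6])
                pval = float(fields[7])
                qval = float(fields[8])
                summit = int(fields[9])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field") from exc
            interval = GenomicInterval(fields[0], lo, hi)
            imputed = summit == -1
            if imputed:
                summit = (hi - lo) // 2
            if summit >= hi - lo:
                raise ValueError(
                    f"{path}:{lineno}: summit offset {summit} >= peak length {hi - lo}"
                )
            peaks.append(
                Peak(
                    interval=interval,
                    name=fields[3],
                    score=score,
                    strand=fields[5],
                    signal=signal,
                    pvalue_neglog10=pval,
                    qvalue_neglog10=qval,
                    summit_offset=summit,
                    summit_imputed=imputed,
                )
            )
    return peaks


def write_narrowpeak(peaks: Iterable[Peak], path: str | Path) -> None:
    with open(path, "w") as handle:
        for p in peaks:
            handle.write(
                f"{p.chrom}\t{p.interval.lo}\t{p.interval.hi}\t{p.name}\t"
                f"{p.score:g}\t{p.strand}\t{p.signal:g}\t{p.pvalue_neglog10:g}\t"
                f"{p.qvalue_neglog10:g}\t{p.summit_offset}\n"
            )


@dataclass
class SignalTrack:
    """Sparse per-chromosome step function: value 0 outside stored segments.

    Segments within a chromosome are sorted and non-overlapping; stored as
    parallel numpy arrays (starts, ends, values).
    """

    _chroms: dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]] = field(
        default_factory=dict
    )

    @classmethod
    def from_segments(
        cls, segments: Iterable[tuple[str, int, int, float]]
    ) -> "SignalTrack":
        """Build a track from (chrom, lo, hi, value) tuples.

        Raises on overlapping segments within a chromosome.
        """
        by_chrom: dict[str, list[tuple[int, int, float]]] = {}
        for chrom, lo, hi, value in segments:
            if hi <= lo:
                raise ValueError(f"empty segment [{lo}, {hi}) on {chrom}")
            if not np.isfinite(value):
                raise ValueError(f"non-finite value {value} on {chrom}:{lo}-{hi}")
            by_chrom.setdefault(chrom, []).append((int(lo), int(hi), float(value)))
        track = cls()
        for chrom, segs in by_chrom.items():
            segs.sort()
            for (lo1, hi1, _), (lo2, hi2, _) in zip(segs, segs[1:]):
                if lo2 < hi1:
                    raise ValueError(
                        f"overlapping segments on {chrom}: "
                        f"[{lo1}, {hi1}) and [{lo2}, {hi2})"
                    )
            arr = np.asarray(segs, dtype=float)
            track._chroms[chrom] = (
                arr[:, 0].astype(np.int64),
                arr[:, 1].astype(np.int64),
                arr[:, 2],
            )
        return track

    @property
    def chroms(self) -> list[str]:
        return sorted(self._chroms)

    def has_chrom(self, chrom: str) -> bool:
        return chrom in self._chroms

    def segments(self, chrom: str) -> Iterable[tuple[int, int, float]]:
        if chrom not in self._chroms:
            return
        starts, ends, values = self._chroms[chrom]
        for lo, hi, v in zip(starts.tolist(), ends.tolist(), values.tolist()):
            yield lo, hi, v

    def total(self) -> float:
        """Integrated signal: sum over segments of value * length."""
        out = 0.0
        for starts, ends, values in self._chroms.values():
            out += float(np.sum((ends - starts) * values))
        return out

    def interval_sum(self, chrom: str, lo: int, hi: int) -> float:
        """Sum of per-bp signal over [lo, hi)."""
        if hi <= lo or chrom not in self._chroms:
            return 0.0
        starts, ends, values = self._chroms[chrom]
        i = int(np.searchsorted(ends, lo, side="right"))
        j = int(np.searchsorted(starts, hi, side="left"))
        if i >= j:
            return 0.0
        ov = np.minimum(ends[i:j], hi) - np.maximum(starts[i:j], lo)
        return float(np.sum(ov * values[i:j]))

    def per_bp(self, chrom: str, lo: int, hi: int) -> np.ndarray:
        """Dense per-bp value array over [lo, hi); zeros where no segment."""
        out = np.zeros(hi - lo, dtype=float)
        if chrom not in self._chroms or hi <= lo:
            return out
        starts, ends, values = self._chroms[chrom]
        i = int(np.searchsorted(ends, lo, side="right"))
        j = int(np.searchsorted(starts, hi, side="left"))
        for k in range(i, j):
            a = max(int(starts[k]), lo) - lo
            b = min(int(ends[k]), hi) - lo
            out[a:b] = values[k]
        return out


def read_bedgraph(path: str | Path, merge_adjacent: bool = False) -> SignalTrack:
    """Parse a 4-column bedGraph file into a :class:`SignalTrack`.

    Overlapping input intervals are an error (the offending lines are
    named).  With ``merge_adjacent`` True, touching equal-valued segments
    are coalesced.
    """
    path = str(path)
    segments: list[tuple[str, int, int, float]] = []
    seen_lines: dict[tuple[str, int, int], int] = {}
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if len(fields) != 4:
                raise ValueError(
                    f"{path}:{lineno}: bedGraph needs 4 columns, got {len(fields)}"
                )
            try:
                lo, hi = int(fields[1]), int(fields[2])
                value = float(fields[3])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed numeric field") from exc
            if not np.isfinite(value):
                raise ValueError(f"{path}:{lineno}: non-finite value")
            segments.append((fields[0], lo, hi, value))
            seen_lines[(fields[0], lo, hi)] = lineno
    try:
        track = SignalTrack.from_segments(segments)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc
    if merge_adjacent:
        track = _merge_adjacent(track)
    return track


def _merge_adjacent(track: SignalTrack) -> SignalTrack:
    merged: list[tuple[str, int, int, float]] = []
    for chrom in track.chroms:
        cur: list[int | float] | None = None
        for lo, hi, v in track.segments(chrom):
            if cur is not None and cur[1] == lo and cur[2] == v:
                cur[1] = hi
            else:
                if cur is not None:
                    merged.append((chrom, int(cur[0]), int(cur[1]), float(cur[2])))
                cur = [lo, hi, v]
        if cur is not None:
            merged.append((chrom, int(cur[0]), int(cur[1]), float(cur[2])))
    return SignalTrack.from_segments(merged)


def write_bedgraph(track: SignalTrack, path: str | Path, skip_zero: bool = True) -> None:
    with open(path, "w") as handle:
        for chrom in track.chroms:
            for lo, hi, v in track.segments(chrom):
                if skip_zero and v == 0.0:
                    continue
                handle.write(f"{chrom}\t{lo}\t{hi}\t{v:.6g}\n")


# --- Cluster 3.0 CDT matrices -------------------------------------------------

_CDT_PRECISION = 6


def write_cdt(
    values: np.ndarray,
    row_ids: Sequence[str],
    path: str | Path,
    column_labels: Sequence[str] | None = None,
) -> None:
    """Write an anchors x bins matrix as a Cluster 3.0 CDT file.

    Layout: header row GID/UNIQID/NAME/GWEIGHT followed by one column per
    bin; one data row per anchor with GWEIGHT fixed at 1.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError(f"matrix must be 2-D, got shape {values.shape}")
    if values.shape[0] != len(row_ids):
        raise ValueError(
            f"{values.shape[0]} matrix rows but {len(row_ids)} row ids"
        )
    n_bins = values.shape[1]
    if column_labels is None:
        column_labels = [f"BIN{i}" for i in range(n_bins)]
    if len(column_labels) != n_bins:
        raise ValueError(
            f"{n_bins} matrix columns but {len(column_labels)} column labels"
        )
    with open(path, "w") as handle:
        handle.write("GID\tUNIQID\tNAME\tGWEIGHT\t" + "\t".join(column_labels) + "\n")
        for i, rid in enumerate(row_ids):
            row = "\t".join(f"{v:.{_CDT_PRECISION}f}" for v in values[i])
            handle.write(f"GENE{i}X\t{rid}\t{rid}\t1\t{row}\n")


def read_cdt(path: str | Path) -> tuple[np.ndarray, list[str], list[str]]:
    """Read back a CDT file: (values, row ids, column labels)."""
    path = str(path)
    with open(path) as handle:
        header = handle.readline().rstrip("\n").split("\t")
        if header[:4] != ["GID", "UNIQID", "NAME", "GWEIGHT"]:
            raise ValueError(f"{path}: not a CDT header: {header[:4]}")
        column_labels = header[4:]
        row_ids: list[str] = []
        rows: list[list[float]] = []
        for lineno, raw in enumerate(handle, start=2):
            line = raw.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4 + len(column_labels):
                raise ValueError(
                    f"{path}:{lineno}: expected {4 + len(column_labels)} columns, "
                    f"got {len(fields)}"
                )
            row_ids.append(fields[1])
            rows.append([float(v) for v in fields[4:]])
    values = (
        np.asarray(rows, dtype=float)
        if rows
        else np.empty((0, len(column_labels)), dtype=float)
    )
    return values, row_ids, column_labels
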