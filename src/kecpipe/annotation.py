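"""TSS annotations and strand-aware promoter-proximal windows.

Every downstream computation in this package is anchored on a transcription
start site (TSS).  This module parses TSS annotations from refFlat or BED6
files, collapses them to unique sites, and builds the promoter-proximal
windows used for Pol II summit search (narrow: -250..+250, broad:
-250..+1000, both strand-oriented and inclusive on the offset scale).

Coordinates are 0-based.  Intervals on disk (BED, refFlat) are half-open;
window *membership* is defined on signed base-pair offsets from the TSS with
inclusive bounds, so a window described as -250..+1000 contains exactly the
positions p with -250 <= offset(p) <= +1000.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "TSSRecord",
    "PromoterWindow",
    "ChromSizes",
    "load_tss",
    "load_chrom_sizes",
    "dedupe_tss",
    "promoter_window",
    "signed_offset",
]

STRANDS = ("+", "-")


@dataclass(frozen=True)
class TSSRecord:
    """A single transcription start site.

    ``tss`` is the 0-based coordinate of the first transcribed base; for a
    minus-strand transcript spanning [start, end) that is ``end - 1``.
    """

    gene_id: str
    chrom: str
    tss: int
    strand: str

    def __post_init__(self) -> None:
        if self.tss < 0:
            raise ValueError(f"negative TSS coordinate: {self.tss}")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.tss, self.strand)


@dataclass(frozen=True)
class PromoterWindow:
    """A resolved, clipped promoter-proximal interval around one TSS.

    ``lo``/``hi`` are 0-based half-open genomic coordinates covering every
    position whose strand-signed offset d from the TSS satisfies
    -upstream_bp <= d <= +downstream_bp (before clipping).
    """

    tss: TSSRecord
    upstream_bp: int
    downstream_bp: int
    chrom: str
    lo: int
    hi: int

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError(f"window lo {self.lo} > hi {self.hi}")

    def __contains__(self, position: int) -> bool:
        return self.lo <= position < self.hi

    def __len__(self) -> int:
        return self.hi - self.lo


class ChromSizes(dict):
    """Chromosome name -> length map (plain dict with validation)."""

    def __setitem__(self, chrom: str, length: int) -> None:
        if length <= 0:
            raise ValueError(f"chromosome {chrom!r} has non-positive length {length}")
        super().__setitem__(chrom, int(length))

    @classmethod
    def from_mapping(cls, mapping: Mapping[str, int]) -> "ChromSizes":
        out = cls()
        for chrom, length in mapping.items():
            out[chrom] = length
        return out


def load_chrom_sizes(path: str | Path) -> ChromSizes:
    """Read a two-column whitespace-separated ``chrom.sizes`` file."""
    sizes = ChromSizes()
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split()
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 columns, got {len(fields)}"
                )
            try:
                length = int(fields[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-integer length {fields[1]!r}") from exc
            sizes[fields[0]] = length
    return sizes


def _parse_bed6_line(fields: list[str], path: str, lineno: int) -> TSSRecord:
    chrom, start_s, end_s, name = fields[0], fields[1], fields[2], fields[3]
    strand = fields[5]
    try:
        start, end = int(start_s), int(end_s)
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-integer coordinates") from exc
    if strand not in STRANDS:
        raise ValueError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
    if end <= start:
        raise ValueError(f"{path}:{lineno}: end {end} <= start {start}")
    tss = start if strand == "+" else end - 1
    return TSSRecord(gene_id=name, chrom=chrom, tss=tss, strand=strand)


def _parse_refflat_line(fields: list[str], path: str, lineno: int) -> TSSRecord:
    # refFlat: geneName name chrom strand txStart txEnd cdsStart cdsEnd ...
    gene_name, chrom, strand = fields[0], fields[2], fields[3]
    try:
        tx_start, tx_end = int(fields[4]), int(fields[5])
    except ValueError as exc:
        raise ValueError(f"{path}:{lineno}: non-integer txStart/txEnd") from exc
    if strand not in STRANDS:
        raise ValueError(f"{path}:{lineno}: unknown strand symbol {strand!r}")
    if tx_end <= tx_start:
        raise ValueError(f"{path}:{lineno}: txEnd {tx_end} <= txStart {tx_start}")
    tss = tx_start if strand == "+" else tx_end - 1
    return TSSRecord(gene_id=gene_name, chrom=chrom, tss=tss, strand=strand)


def load_tss(path: str | Path, fmt: str = "auto") -> list[TSSRecord]:
    """Parse a TSS annotation into one :class:`TSSRecord` per transcript.

    Parameters
    ----------
    path
        A BED6 (6+ columns, strand in column 6) or refFlat (11 columns,
        strand in column 4) file.
    fmt
        ``"bed6"``, ``"refflat"`` or ``"auto"``.  Auto-detection inspects
        the first data line: strand symbol in column 4 means refFlat.

    The TSS of a plus-strand transcript is the interval start; for a
    minus-strand transcript it is ``end - 1`` (the last base of the
    half-open interval).
    """
    path = str(path)
    records: list[TSSRecord] = []
    mode = fmt
    with open(path) as handle:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            if mode == "auto":
                if len(fields) >= 11 and fields[3] in STRANDS:
                    mode = "refflat"
                elif len(fields) >= 6:
                    mode = "bed6"
                else:
                    raise ValueError(
                        f"{path}:{lineno}: cannot auto-detect format "
                        f"({len(fields)} columns)"
                    )
            if mode == "refflat":
                if len(fields) < 11:
                    raise ValueError(
                        f"{path}:{lineno}: refFlat needs 11 columns, got {len(fields)}"
                    )
                records.append(_parse_refflat_line(fields, path, lineno))
            elif mode == "bed6":
                if len(fields) < 6:
                    raise ValueError(
                        f"{path}:{lineno}: BED6 needs 6 columns, got {len(fields)}"
                    )
                records.append(_parse_bed6_line(fields, path, lineno))
            else:
                raise ValueError(f"unknown annotation format {fmt!r}")
    return records


def dedupe_tss(records: Iterable[TSSRecord]) -> list[TSSRecord]:
    """Collapse records to unique (chrom, tss, strand) sites.

    The first record seen for each site supplies the retained ``gene_id``.
    Output is sorted by (chrom, tss, strand); idempotent.
    """
    first: dict[tuple[str, int, str], TSSRecord] = {}
    for rec in records:
        first.setdefault(rec.key, rec)
    return sorted(first.values(), key=lambda r: r.key)


def promoter_window(
    tss: TSSRecord,
    upstream_bp: int,
    downstream_bp: int,
    sizes: ChromSizes,
    stranded: bool = True,
) -> PromoterWindow:
    """Resolve the strand-oriented window [-upstream, +downstream] around a TSS.

    Offsets are inclusive on both ends; the resolved half-open interval is
    clipped to [0, chromosome length).  With ``stranded=False`` the window is
    laid out in reference coordinates regardless of strand (upstream = lower
    coordinates).
    """
    if upstream_bp < 0 or downstream_bp < 0:
        raise ValueError("window extents must be non-negative")
    if tss.chrom not in sizes:
        raise KeyError(f"chromosome {tss.chrom!r} absent from chrom sizes")
    length = sizes[tss.chrom]
    if tss.strand == "+" or not stranded:
        lo = tss.tss - upstream_bp
        hi = tss.tss + downstream_bp + 1
    else:
        lo = tss.tss - downstream_bp
        hi = tss.tss + upstream_bp + 1
    lo = max(0, lo)
    hi = min(length, hi)
    if hi < lo:  # window entirely off-chromosome after clipping
        hi = lo
    return PromoterWindow(
        tss=tss,
        upstream_bp=upstream_bp,
        downstream_bp=downstream_bp,
        chrom=tss.chrom,
        lo=lo,
        hi=hi,
    )


def signed_offset(tss: TSSRecord, position: int, chrom: str | None = None) -> int:
    """Strand-signed base-pair offset of ``position`` relative to the TSS.

    Positive offsets point downstream (in the direction of transcription).
    """
    if chrom is not None and chrom != tss.chrom:
        raise ValueError(
            f"chromosome mismatch: position on {chrom!r}, TSS on {tss.chrom!r}"
        )
    if tss.strand == "+":
        return position - tss.tss
    return tss.tss - position
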