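"""Summit-anchored target-gene classification.

The classification proceeds TSS by TSS:

1. Find a promoter-proximal RNA Pol II peak summit.  A summit with
   strand-signed offset in [-250, +250] qualifies directly ("narrow").  A
   summit in (+250, +1000] qualifies only when an H3K4me3 peak interval
   overlaps that downstream sub-window, rescuing genes whose annotated TSS
   sits upstream of the real initiation site ("rescued").  Genes with
   either kind of summit carry promoter-proximal paused Pol II.
2. Test each factor (KAP1, Cdk9, Hexim1, Larp7) for a peak summit within
   +/- 250 bp of the assigned Pol II summit (reference coordinates; no
   strand flip around a point anchor).
3. Derive the nested target sets: 7SK snRNP targets require all three of
   Cdk9, Hexim1 and Larp7; KAP1-7SK targets additionally require KAP1; KEC
   (KAP1-7SK snRNP early elongation complex) targets additionally require
   paused Pol II — which the summit-anchored procedure already guarantees,
   giving the strict nesting KEC <= KAP1-7SK <= 7SK <= paused.

An alternative TSS-anchored mode tests factor summits directly against the
strand-oriented -250..+1000 promoter window with no Pol II requirement.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .annotation import TSSRecord, signed_offset
from .interval_io import Peak

__all__ = [
    "ClassifyConfig",
    "GeneTargetCall",
    "TargetSetCounts",
    "PeakIndex",
    "SEVEN_SK_FACTORS",
    "assign_pol2_summit",
    "factor_cooccupied",
    "classify_all",
    "tally",
    "tally_from_counts",
]

SEVEN_SK_FACTORS = ("cdk9", "hexim1", "larp7")


@dataclass(frozen=True)
class ClassifyConfig:
    """Window geometry and anchoring mode for target classification."""

    narrow_up: int = 250
    narrow_down: int = 250
    broad_up: int = 250
    broad_down: int = 1000
    cooccupancy_halfwidth: int = 250
    anchor: str = "summit"  # "summit" (Pol II summit first) or "tss"
    cooccupancy_mode: str = "summit"  # "summit" or "overlap" (any peak-bp)
    use_rescue: bool = True
    stranded: bool = True

    def __post_init__(self) -> None:
        if self.anchor not in ("summit", "tss"):
            raise ValueError(f"anchor must be 'summit' or 'tss', got {self.anchor!r}")
        if self.cooccupancy_mode not in ("summit", "overlap"):
            raise ValueError(f"bad cooccupancy_mode {self.cooccupancy_mode!r}")


@dataclass
class GeneTargetCall:
    """Per-TSS classification outcome."""

    tss: TSSRecord
    pol2_summit: int | None = None
    summit_offset_bp: int | None = None
    paused: bool = False
    rescue_used: bool = False
    factor_flags: dict[str, bool] = field(default_factory=dict)
    is_7sk: bool = False
    is_kap1_7sk: bool = False
    is_kec: bool = False

    def validate(self) -> None:
        if self.is_7sk and not all(
            self.factor_flags.get(f, False) for f in SEVEN_SK_FACTORS
        ):
            raise AssertionError("7SK flag without all three snRNP components")
        if self.is_kap1_7sk and not (self.is_7sk and self.factor_flags.get("kap1")):
            raise AssertionError("KAP1-7SK flag without 7SK+KAP1")
        if self.is_kec and not (self.is_kap1_7sk and self.paused):
            raise AssertionError("KEC flag without KAP1-7SK and paused Pol II")
        if self.paused and self.pol2_summit is None:
            raise AssertionError("paused without an assigned Pol II summit")


@dataclass
class TargetSetCounts:
    """Tallies of the nested target sets with the reported percentages."""

    n_universe: int
    n_paused: int
    n_narrow: int
    n_rescued: int
    n_7sk: int
    n_kap1_7sk: int
    n_kec: int
    frac_kec_of_universe: float | None
    frac_kec_of_paused: float | None

    def as_dict(self) -> dict:
        return dict(self.__dict__)


class PeakIndex:
    """Per-chromosome sorted summit/interval lookup for one factor's peaks."""

    def __init__(self, peaks: Iterable[Peak]):
        by_chrom: dict[str, list[Peak]] = {}
        for p in peaks:
            by_chrom.setdefault(p.chrom, []).append(p)
        self._summits: dict[str, list[int]] = {}
        self._peaks: dict[str, list[Peak]] = {}
        self._starts: dict[str, list[int]] = {}
        self._by_start: dict[str, list[Peak]] = {}
        self._mw: dict[str, int] = {}
        for chrom, ps in by_chrom.items():
            ps.sort(key=lambda p: (p.summit, p.interval.lo))
            self._peaks[chrom] = ps
            self._summits[chrom] = [p.summit for p in ps]
            by_start = sorted(ps, key=lambda p: p.interval.lo)
            self._starts[chrom] = [p.interval.lo for p in by_start]
            self._by_start[chrom] = by_start

    def summits_in(self, chrom: str, lo: int, hi: int) -> list[Peak]:
        """Peaks whose summit lies in the half-open range [lo, hi)."""
        if chrom not in self._summits:
            return []
        summits = self._summits[chrom]
        i = bisect_left(summits, lo)
        j = bisect_left(summits, hi)
        return self._peaks[chrom][i:j]

    def any_summit_in(self, chrom: str, lo: int, hi: int) -> bool:
        return bool(self.summits_in(chrom, lo, hi))

    def any_interval_overlap(self, chrom: str, lo: int, hi: int) -> bool:
        """True iff some peak interval overlaps [lo, hi) by >= 1 bp."""
        if chrom not in self._by_start:
            return False
        starts = self._starts[chrom]
        j = bisect_left(starts, hi)
        # starts are sorted but ends are not; scan left from j and stop once
        # starts drop more than the widest peak below lo (no overlap possible)
        for p in reversed(self._by_start[chrom][:j]):
            if p.interval.hi > lo:
                return True
            if p.interval.lo < lo - self._max_width(chrom):
                break
        return False

    def _max_width(self, chrom: str) -> int:
        if chrom not in self._mw:
            self._mw[chrom] = max(
                (len(p.interval) for p in self._peaks.get(chrom, [])), default=0
            )
        return self._mw[chrom]


def _oriented_subwindow(
    tss: TSSRecord, lo_off: int, hi_off: int, stranded: bool = True
) -> tuple[int, int]:
    """Half-open genomic range of inclusive offsets [lo_off, hi_off]."""
    if tss.strand == "+" or not stranded:
        return tss.tss + lo_off, tss.tss + hi_off + 1
    return tss.tss - hi_off, tss.tss - lo_off + 1


def assign_pol2_summit(
    tss: TSSRecord,
    pol2: PeakIndex,
    h3k4me3: PeakIndex | None,
    config: ClassifyConfig = ClassifyConfig(),
) -> tuple[int | None, bool]:
    """Assign a promoter-proximal Pol II summit to one TSS.

    Returns ``(summit position or None, rescue_used)``.  Candidates in the
    narrow window [-250, +250] win outright; failing that, candidates in
    the rescue zone (+250, +1000] are considered only when an H3K4me3 peak
    interval overlaps that zone.  Among candidates the tie-break is highest
    peak signal, then smallest absolute offset, then smaller coordinate.
    """
    lo, hi = _oriented_subwindow(
        tss, -config.narrow_up, config.narrow_down, config.stranded
    )
    narrow = pol2.summits_in(tss.chrom, max(lo, 0), hi)
    if narrow:
        return _best_candidate(tss, narrow), False
    if not config.use_rescue:
        return None, False
    # rescue zone: offsets strictly above narrow_down, up to broad_down
    lo, hi = _oriented_subwindow(
        tss, config.narrow_down + 1, config.broad_down, config.stranded
    )
    lo = max(lo, 0)
    rescue = pol2.summits_in(tss.chrom, lo, hi)
    if not rescue:
        return None, False
    if h3k4me3 is None or not h3k4me3.any_interval_overlap(tss.chrom, lo, hi):
        return None, False
    return _best_candidate(tss, rescue), True


def _best_candidate(tss: TSSRecord, candidates: Sequence[Peak]) -> int:
    return min(
        candidates,
        key=lambda p: (-p.signal, abs(signed_offset(tss, p.summit)), p.summit),
    ).summit


def factor_cooccupied(
    summit: int,
    chrom: str,
    factor: PeakIndex,
    halfwidth: int = 250,
    mode: str = "summit",
) -> bool:
    """Is a factor present within +/- halfwidth bp of a Pol II summit?

    ``mode="summit"`` (default) tests factor peak *summits*; ``"overlap"``
    accepts any >= 1 bp peak-interval overlap with the window.  The window
    is symmetric in reference coordinates (a point anchor has no strand).
    """
    lo = max(summit - halfwidth, 0)
    hi = summit + halfwidth + 1  # inclusive bound
    if mode == "summit":
        return factor.any_summit_in(chrom, lo, hi)
    if mode == "overlap":
        return factor.any_interval_overlap(chrom, lo, hi)
    raise ValueError(f"bad co-occupancy mode {mode!r}")


def classify_all(
    tss_set: Sequence[TSSRecord],
    peaks: Mapping[str, Sequence[Peak] | PeakIndex],
    config: ClassifyConfig = ClassifyConfig(),
) -> list[GeneTargetCall]:
    """Classify every TSS against the supplied factor peak sets.

    ``peaks`` maps factor names (lower-case: ``pol2``, ``kap1``, ``cdk9``,
    ``hexim1``, ``larp7``, ``h3k4me3``) to peak lists or prebuilt
    :class:`PeakIndex` objects.  ``pol2`` is required; ``h3k4me3`` is
    required only when the rescue rule is enabled.  Missing 7SK-component
    or KAP1 files are an error (a co-occupancy call needs all of them).
    """
    required = ["pol2", "kap1", *SEVEN_SK_FACTORS]
    if config.use_rescue and config.anchor == "summit":
        required.append("h3k4me3")
    indexes: dict[str, PeakIndex] = {}
    for name in set(required) | set(peaks):
        if name not in peaks:
            raise ValueError(f"missing required peak set for factor {name!r}")
        src = peaks[name]
        indexes[name] = src if isinstance(src, PeakIndex) else PeakIndex(src)

    calls: list[GeneTargetCall] = []
    for tss in tss_set:
        call = GeneTargetCall(tss=tss)
        summit, rescued = assign_pol2_summit(
            tss, indexes["pol2"], indexes.get("h3k4me3"), config
        )
        if summit is not None:
            call.pol2_summit = summit
            call.summit_offset_bp = signed_offset(tss, summit)
            call.paused = True
            call.rescue_used = rescued

        if config.anchor == "summit":
            if summit is not None:
                for name in ("kap1", *SEVEN_SK_FACTORS):
                    call.factor_flags[name] = factor_cooccupied(
                        summit,
                        tss.chrom,
                        indexes[name],
                        config.cooccupancy_halfwidth,
                        config.cooccupancy_mode,
                    )
            else:
                for name in ("kap1", *SEVEN_SK_FACTORS):
                    call.factor_flags[name] = False
        else:  # TSS-anchored: factor summit in the broad promoter window
            lo, hi = _oriented_subwindow(
                tss, -config.broad_up, config.broad_down, config.stranded
            )
            lo = max(lo, 0)
            for name in ("kap1", *SEVEN_SK_FACTORS):
                idx = indexes[name]
                if config.cooccupancy_mode == "summit":
                    call.factor_flags[name] = idx.any_summit_in(tss.chrom, lo, hi)
                else:
                    call.factor_flags[name] = idx.any_interval_overlap(
                        tss.chrom, lo, hi
                    )

        call.is_7sk = all(call.factor_flags[f] for f in SEVEN_SK_FACTORS)
        if config.anchor == "summit":
            # summit-anchored calls are conditional on paused Pol II
            call.is_7sk = call.is_7sk and call.paused
        call.is_kap1_7sk = call.is_7sk and call.factor_flags["kap1"]
        call.is_kec = call.is_kap1_7sk and call.paused
        call.validate()
        calls.append(call)
    return calls


def tally(calls: Sequence[GeneTargetCall]) -> TargetSetCounts:
    """Count the nested target sets and the headline percentages.

    Percentages are reported to one decimal; the fraction of paused genes
    is absent when no gene is paused.
    """
    n_universe = len(calls)
    n_paused = sum(c.paused for c in calls)
    n_rescued = sum(c.paused and c.rescue_used for c in calls)
    n_narrow = sum(c.paused and not c.rescue_used for c in calls)
    n_7sk = sum(c.is_7sk for c in calls)
    n_kap1_7sk = sum(c.is_kap1_7sk for c in calls)
    n_kec = sum(c.is_kec for c in calls)
    assert n_paused == n_narrow + n_rescued
    frac_univ = round(100.0 * n_kec / n_universe, 1) if n_universe else None
    frac_paused = round(100.0 * n_kec / n_paused, 1) if n_paused else None
    return TargetSetCounts(
        n_universe=n_universe,
        n_paused=n_paused,
        n_narrow=n_narrow,
        n_rescued=n_rescued,
        n_7sk=n_7sk,
        n_kap1_7sk=n_kap1_7sk,
        n_kec=n_kec,
        frac_kec_of_universe=frac_univ,
        frac_kec_of_paused=frac_paused,
    )


def tally_from_counts(
    n_universe: int,
    n_narrow: int,
    n_rescued: int,
    n_7sk: int,
    n_kap1_7sk: int,
    n_kec: int,
) -> TargetSetCounts:
    """Recompute derived quantities (paused total, percentages) from raw counts.

    Useful for checking published tallies without per-gene calls.
    """
    n_paused = n_narrow + n_rescued
    frac_univ = round(100.0 * n_kec / n_universe, 1) if n_universe else None
    frac_paused = round(100.0 * n_kec / n_paused, 1) if n_paused else None
    return TargetSetCounts(
        n_universe=n_universe,
        n_paused=n_paused,
        n_narrow=n_narrow,
        n_rescued=n_rescued,
        n_7sk=n_7sk,
        n_kap1_7sk=n_kap1_7sk,
        n_kec=n_kec,
        frac_kec_of_universe=frac_univ,
        frac_kec_of_paused=frac_paused,
    )
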