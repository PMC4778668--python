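"""Exact hypergeometric co-occupancy tests on gene sets and genome bins.

The genome (minus promoter-proximal regions, -250..+1000 bp around every
TSS) is collapsed into fixed-width bins (default 250 bp); each bin is
marked occupied by a factor when >= 1 bp of a called peak overlaps it.
Overlap between two factors' occupancy vectors is then tested with the
hypergeometric distribution — the same test applies unchanged to gene-set
indicators, the universe simply being genes instead of bins.

Tail probabilities are accumulated in log space (log-gamma for the pmf,
log-sum-exp for the tails), so overlaps that are "machine zero" in double
precision (p < 2.2204e-16) still report a finite log10 p alongside the
below-machine-epsilon flag.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .annotation import ChromSizes
from .interval_io import GenomicInterval, Peak

__all__ = [
    "MACHINE_EPS",
    "BinUniverse",
    "HypergeomResult",
    "build_bins",
    "occupy",
    "log_hypergeom_pmf",
    "hypergeom_upper",
    "hypergeom_lower",
    "cooccupancy_test",
]

#: double-precision epsilon; p-values below this are "machine zero"
MACHINE_EPS = 2.220446049250313e-16
_LOG10_EPS = float(np.log10(MACHINE_EPS))


@dataclass
class BinUniverse:
    """Equal-width genome bins surviving promoter exclusion.

    ``bin_starts`` maps chromosome -> sorted array of kept bin start
    coordinates (each bin spans [start, start + bin_size)).  Bins are
    non-overlapping by construction; trailing partial bins are dropped so
    every unit of the universe has identical size.
    """

    bin_size: int
    bin_starts: dict[str, np.ndarray]
    excluded_regions: list[GenomicInterval]

    @property
    def n_bins(self) -> int:
        return sum(len(v) for v in self.bin_starts.values())

    def chrom_offsets(self) -> dict[str, int]:
        """Start index of each chromosome's bins in the flat vector."""
        out: dict[str, int] = {}
        acc = 0
        for chrom in sorted(self.bin_starts):
            out[chrom] = acc
            acc += len(self.bin_starts[chrom])
        return out

    def bins(self) -> Iterable[GenomicInterval]:
        for chrom in sorted(self.bin_starts):
            for start in self.bin_starts[chrom].tolist():
                yield GenomicInterval(chrom, start, start + self.bin_size)


def build_bins(
    sizes: ChromSizes,
    bin_size: int = 250,
    exclusions: Sequence[GenomicInterval] = (),
    exclusion_mode: str = "any",
) -> BinUniverse:
    """Tile every chromosome into bins and drop promoter-overlapping ones.

    Each chromosome is tiled from coordinate 0 in ``bin_size`` steps; the
    trailing partial bin is dropped.  A bin is excluded when it overlaps an
    exclusion region by >= 1 bp (``exclusion_mode="any"``, the default) or
    by more than half its width (``"majority"``).
    """
    if bin_size <= 0:
        raise ValueError(f"bin_size must be positive, got {bin_size}")
    if exclusion_mode not in ("any", "majority"):
        raise ValueError(f"bad exclusion_mode {exclusion_mode!r}")
    excl_by_chrom: dict[str, list[GenomicInterval]] = {}
    for region in exclusions:
        excl_by_chrom.setdefault(region.chrom, []).append(region)

    bin_starts: dict[str, np.ndarray] = {}
    for chrom in sorted(sizes):
        length = sizes[chrom]
        n_full = length // bin_size
        starts = np.arange(n_full, dtype=np.int64) * bin_size
        regions = excl_by_chrom.get(chrom, [])
        if regions and len(starts):
            overlap = np.zeros(len(starts), dtype=np.int64)
            ends = starts + bin_size
            for r in regions:
                ov = np.minimum(ends, r.hi) - np.maximum(starts, r.lo)
                np.maximum(ov, 0, out=ov)
                overlap += ov
            if exclusion_mode == "any":
                # per-region >=1bp is what matters; summed overlap >=1 is
                # equivalent since overlaps are non-negative
                keep = overlap == 0
            else:
                keep = overlap <= bin_size // 2
            starts = starts[keep]
        bin_starts[chrom] = starts
    return BinUniverse(
        bin_size=bin_size, bin_starts=bin_starts, excluded_regions=list(exclusions)
    )


def occupy(universe: BinUniverse, peaks: Iterable[Peak | GenomicInterval]) -> np.ndarray:
    """Boolean occupancy vector: bin marked iff >= 1 bp of a peak overlaps it.

    The vector is ordered chromosome-by-chromosome (sorted names), matching
    :meth:`BinUniverse.chrom_offsets`.  Peaks on chromosomes outside the
    universe are ignored.
    """
    offsets = universe.chrom_offsets()
    marks = np.zeros(universe.n_bins, dtype=bool)
    bs = universe.bin_size
    for p in peaks:
        interval = p.interval if isinstance(p, Peak) else p
        chrom = interval.chrom
        if chrom not in offsets:
            continue
        starts = universe.bin_starts[chrom]
        if not len(starts):
            continue
        first = (interval.lo // bs) * bs
        last = ((interval.hi - 1) // bs) * bs
        i = int(np.searchsorted(starts, first, side="left"))
        j = int(np.searchsorted(starts, last, side="right"))
        marks[offsets[chrom] + i : offsets[chrom] + j] = True
    return marks


@dataclass
class HypergeomResult:
    """Hypergeometric test outcome in the (N, K, n, k) parameterization.

    N: universe size, K: marked units (set A), n: draws (set B),
    k: observed overlap.  ``log10_p_upper`` is the enrichment tail
    log10 P[X >= k]; ``log10_p_lower`` the depletion tail log10 P[X <= k].
    """

    N: int
    K: int
    n: int
    k: int
    log10_p_upper: float
    log10_p_lower: float

    @property
    def p_upper(self) -> float:
        return 10.0 ** self.log10_p_upper

    @property
    def p_lower(self) -> float:
        return 10.0 ** self.log10_p_lower

    @property
    def below_machine_eps_upper(self) -> bool:
        return bool(self.log10_p_upper < _LOG10_EPS)

    @property
    def below_machine_eps_lower(self) -> bool:
        return bool(self.log10_p_lower < _LOG10_EPS)

    def as_dict(self) -> dict:
        return {
            "N": self.N,
            "K": self.K,
            "n": self.n,
            "k": self.k,
            "log10_p_upper": self.log10_p_upper,
            "log10_p_lower": self.log10_p_lower,
            "below_machine_eps_upper": self.below_machine_eps_upper,
            "below_machine_eps_lower": self.below_machine_eps_lower,
        }


def _check_params(K: int, n: int, N: int) -> None:
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"parameters out of range: K={K}, n={n}, N={N}")


def _check_support(k: int, K: int, n: int, N: int) -> None:
    _check_params(K, n, N)
    k_min, k_max = max(0, n + K - N), min(n, K)
    if not (k_min <= k <= k_max):
        raise ValueError(
            f"k={k} outside support [{k_min}, {k_max}] for K={K}, n={n}, N={N}"
        )


def log_hypergeom_pmf(k: int, K: int, n: int, N: int) -> float:
    """Natural-log hypergeometric pmf ln C(K,k) C(N-K,n-k) / C(N,n)."""
    _check_support(k, K, n, N)
    return float(
        _log_binom(K, k) + _log_binom(N - K, n - k) - _log_binom(N, n)
    )


def _log_binom(a: int, b: int) -> float:
    return float(gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1))


def _tail_logsum(ks: np.ndarray, K: int, n: int, N: int) -> float:
    logs = (
        gammaln(K + 1)
        - gammaln(ks + 1)
        - gammaln(K - ks + 1)
        + gammaln(N - K + 1)
        - gammaln(n - ks + 1)
        - gammaln(N - K - n + ks + 1)
        - _log_binom(N, n)
    )
    return float(logsumexp(logs))


def hypergeom_upper(k: int, K: int, n: int, N: int) -> float:
    """log10 of the enrichment tail P[X >= k], summed exactly in log space.

    ``k`` may lie outside the support; the tail is then the CDF extension
    (1 below the support minimum, exact 0 above the maximum, matching R's
    ``phyper``), with log10(0) = -inf.
    """
    _check_params(K, n, N)
    k_min, k_max = max(0, n + K - N), min(n, K)
    if k <= k_min:
        return 0.0
    if k > k_max:
        return float("-inf")
    ks = np.arange(k, k_max + 1)
    return float(_tail_logsum(ks, K, n, N) / np.log(10.0))


def hypergeom_lower(k: int, K: int, n: int, N: int) -> float:
    """log10 of the depletion tail P[X <= k]; CDF extension as above."""
    _check_params(K, n, N)
    k_min, k_max = max(0, n + K - N), min(n, K)
    if k >= k_max:
        return 0.0
    if k < k_min:
        return float("-inf")
    ks = np.arange(k_min, k + 1)
    return float(_tail_logsum(ks, K, n, N) / np.log(10.0))


def cooccupancy_test(
    a: np.ndarray | Sequence[bool], b: np.ndarray | Sequence[bool]
) -> HypergeomResult:
    """Hypergeometric overlap test of two indicator vectors on one universe.

    N = universe size, K = |A|, n = |B|, k = |A intersect B|.  Both tails
    are reported: enrichment P[X >= k] and depletion P[X <= k].
    """
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError(f"indicator shape mismatch: {a.shape} vs {b.shape}")
    N = int(a.size)
    if N == 0:
        raise ValueError("empty universe")
    K = int(a.sum())
    n = int(b.sum())
    k = int((a & b).sum())
    return HypergeomResult(
        N=N,
        K=K,
        n=n,
        k=k,
        log10_p_upper=hypergeom_upper(k, K, n, N),
        log10_p_lower=hypergeom_lower(k, K, n, N),
    )
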