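"""Seeded synthetic genome generator with a ground-truth table.

Generates everything the pipeline consumes — chromosome sizes, a TSS
annotation on both strands, per-factor narrowPeak files, per-million
pileup bedGraphs and strand-specific nascent-transcription coverage —
from an explicit configuration whose defaults encode the promoter
geometry the analysis is built around:

* paused Pol II summits centered near +100 bp downstream of the TSS;
* KAP1 and 7SK snRNP component summits a further ~125 bp downstream of
  the Pol II summit (within the +/-250 bp co-occupancy window);
* genes whose Pol II summit falls in the (+250, +1000] rescue zone carry
  an H3K4me3 peak there;
* sense-strand GRO-seq signal proportional to Pol II peak height plus
  Gaussian noise, antisense-free.

Target-set membership is drawn per gene from configured conditional
probabilities (paused, 7SK given paused, KAP1 given 7SK), and the
realized flags are recorded in a truth table against which the
classification modules are tested.  Offset draws use truncated normals
implemented by resampling (no boundary atoms).  All randomness flows
from a single mandatory seed; output is deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .annotation import ChromSizes, TSSRecord
from .interval_io import (
    GenomicInterval,
    Peak,
    SignalTrack,
    write_bedgraph,
    write_narrowpeak,
)
from .groseq_rank import StrandedCoverage

__all__ = [
    "SimConfig",
    "GeneTruth",
    "SimulatedDataset",
    "simulate_annotation",
    "simulate_peaks",
    "simulate_pileup",
    "simulate_groseq",
    "simulate_dataset",
    "write_dataset",
    "FACTORS",
]

FACTORS = ("pol2", "kap1", "cdk9", "hexim1", "larp7", "h3k4me3")

#: minimum TSS-to-TSS spacing guaranteeing that promoter windows, factor
#: summit windows and pileup kernels of neighbouring genes never interact
_MIN_SPACING = 3500
_EDGE_MARGIN = 2500


@dataclass(frozen=True)
class SimConfig:
    """Synthetic dataset configuration.  ``seed`` is mandatory.

    Probabilities are per gene: ``fraction_paused`` genes carry a Pol II
    peak; of those, ``fraction_narrow`` have their summit in the narrow
    [-250, +250] window (the rest in the rescue zone, with H3K4me3);
    ``p_7sk_given_paused`` of paused genes carry all three 7SK snRNP
    components; ``p_kap1_given_7sk`` of those additionally carry KAP1.
    Offsets are bp; heights are arbitrary pileup units.
    """

    seed: int
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    n_genes: int = 200
    plus_strand_fraction: float = 0.5
    fraction_paused: float = 0.6
    fraction_narrow: float = 0.75
    p_7sk_given_paused: float = 0.9
    p_kap1_given_7sk: float = 0.9
    pol2_offset_mean: float = 100.0
    pol2_offset_sd: float = 50.0
    factor_shift_mean: float = 125.0
    factor_shift_sd: float = 40.0
    peak_halfwidth: int = 150
    pileup_kernel_halfwidth: int = 150
    height_lo: float = 5.0
    height_hi: float = 50.0
    groseq_gain: float = 1.0
    groseq_noise_sd: float = 3.0
    groseq_extent: int = 1000
    max_placement_tries: int = 1000

    def __post_init__(self) -> None:
        for name in (
            "plus_strand_fraction",
            "fraction_paused",
            "fraction_narrow",
            "p_7sk_given_paused",
            "p_kap1_given_7sk",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if self.pileup_kernel_halfwidth <= 0 or self.peak_halfwidth <= 0:
            raise ValueError("kernel/peak widths must be positive")


@dataclass
class GeneTruth:
    """Ground-truth record for one simulated gene."""

    gene_id: str
    chrom: str
    tss: int
    strand: str
    paused: bool
    rescue: bool
    is_7sk: bool
    has_kap1: bool
    is_kap1_7sk: bool
    is_kec: bool
    pol2_offset: int | None
    pol2_height: float | None
    groseq_level: float


@dataclass
class SimulatedDataset:
    """Everything one simulation run produces, in memory."""

    config: SimConfig
    sizes: ChromSizes
    tss: list[TSSRecord]
    peaks: dict[str, list[Peak]]
    pileups: dict[str, SignalTrack]
    groseq: StrandedCoverage
    truth: list[GeneTruth]

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([t.__dict__ for t in self.truth])


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float) -> float:
    """Truncated-normal draw by resampling; exact-mean degenerate at sd=0."""
    if sd == 0.0:
        if not lo <= mean <= hi:
            raise ValueError(f"degenerate draw {mean} outside [{lo}, {hi}]")
        return mean
    for _ in range(10000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return x
    raise RuntimeError("truncated-normal resampling failed to land in window")


def simulate_annotation(config: SimConfig) -> tuple[ChromSizes, list[TSSRecord]]:
    """Place ``n_genes`` TSS without promoter-window collisions.

    Genes are assigned round-robin to chromosomes and positioned by
    rejection sampling so that TSS on the same chromosome are at least
    3.5 kb apart — far enough that no gene's peaks, windows or pileup
    kernels reach a neighbour.  Deterministic per seed.
    """
    rng = np.random.default_rng(config.seed)
    sizes = ChromSizes.from_mapping(
        {f"chr{i + 1}": config.chrom_length for i in range(config.n_chroms)}
    )
    per_chrom: dict[str, list[int]] = {c: [] for c in sizes}
    chrom_names = sorted(sizes)
    records: list[TSSRecord] = []
    lo_bound = _EDGE_MARGIN
    hi_bound = config.chrom_length - _EDGE_MARGIN
    if hi_bound <= lo_bound:
        raise ValueError("chromosome too short for gene placement margins")
    for g in range(config.n_genes):
        chrom = chrom_names[g % len(chrom_names)]
        placed = None
        for _ in range(config.max_placement_tries):
            pos = int(rng.integers(lo_bound, hi_bound))
            if all(abs(pos - q) >= _MIN_SPACING for q in per_chrom[chrom]):
                placed = pos
                break
        if placed is None:
            raise RuntimeError(
                "could not place genes without promoter-window collisions; "
                "increase chrom_length or reduce n_genes"
            )
        per_chrom[chrom].append(placed)
        strand = "+" if rng.random() < config.plus_strand_fraction else "-"
        records.append(
            TSSRecord(gene_id=f"gene{g:05d}", chrom=chrom, tss=placed, strand=strand)
        )
    return sizes, records


def _make_peak(chrom: str, summit: int, height: float, halfwidth: int,
               name: str) -> Peak:
    lo = max(0, summit - halfwidth)
    hi = summit + halfwidth + 1
    return Peak(
        interval=GenomicInterval(chrom, lo, hi),
        name=name,
        score=min(1000.0, height * 10),
        strand=".",
        signal=height,
        pvalue_neglog10=10.0,
        qvalue_neglog10=8.0,
        summit_offset=summit - lo,
    )


def simulate_peaks(
    tss_set: list[TSSRecord], config: SimConfig
) -> tuple[dict[str, list[Peak]], list[GeneTruth]]:
    """Draw per-gene flags and emit narrowPeak-style peaks per factor.

    Paused genes get a Pol II peak: narrow genes with summit offset ~
    Normal(+100, sd) truncated to [-250, +250]; rescued genes with a
    uniform offset in (+250, +1000] and an H3K4me3 peak covering it.
    When a gene's 7SK (resp. KAP1) flag is true, each component summit is
    the Pol II summit shifted downstream by Normal(+125, sd) truncated to
    +/-250 bp of the summit.  GRO-seq levels are drawn here too so the
    truth table is complete in one pass.
    """
    rng = np.random.default_rng((config.seed * 2654435761 + 1) % 2**31)
    peaks: dict[str, list[Peak]] = {f: [] for f in FACTORS}
    truth: list[GeneTruth] = []
    for tss in tss_set:
        sign = 1 if tss.strand == "+" else -1
        paused = rng.random() < config.fraction_paused
        rescue = False
        is_7sk = has_kap1 = False
        pol2_offset: int | None = None
        pol2_height: float | None = None
        groseq_level = 0.0
        if paused:
            rescue = rng.random() >= config.fraction_narrow
            if rescue:
                pol2_offset = int(rng.integers(251, 1001))
            else:
                pol2_offset = int(
                    round(
                        _trunc_normal(
                            rng, config.pol2_offset_mean, config.pol2_offset_sd,
                            -250, 250,
                        )
                    )
                )
            pol2_height = float(rng.uniform(config.height_lo, config.height_hi))
            summit = tss.tss + sign * pol2_offset
            peaks["pol2"].append(
                _make_peak(tss.chrom, summit, pol2_height,
                           config.peak_halfwidth, f"{tss.gene_id}_pol2")
            )
            if rescue:
                # H3K4me3 interval centered on the downstream summit so it
                # overlaps the (+250, +1000] rescue zone
                peaks["h3k4me3"].append(
                    _make_peak(tss.chrom, summit, pol2_height * 0.8,
                               config.peak_halfwidth, f"{tss.gene_id}_h3k4me3")
                )
            is_7sk = rng.random() < config.p_7sk_given_paused
            if is_7sk:
                has_kap1 = rng.random() < config.p_kap1_given_7sk
                components = ["cdk9", "hexim1", "larp7"] + (
                    ["kap1"] if has_kap1 else []
                )
                for factor in components:
                    shift = int(
                        round(
                            _trunc_normal(
                                rng, config.factor_shift_mean,
                                config.factor_shift_sd, -250, 250,
                            )
                        )
                    )
                    fsummit = summit + sign * shift
                    fheight = float(
                        rng.uniform(config.height_lo, config.height_hi)
                    )
                    peaks[factor].append(
                        _make_peak(tss.chrom, fsummit, fheight,
                                   config.peak_halfwidth,
                                   f"{tss.gene_id}_{factor}")
                    )
            groseq_level = max(
                0.0,
                config.groseq_gain * pol2_height
                + (rng.normal(0.0, config.groseq_noise_sd)
                   if config.groseq_noise_sd > 0 else 0.0),
            )
        truth.append(
            GeneTruth(
                gene_id=tss.gene_id,
                chrom=tss.chrom,
                tss=tss.tss,
                strand=tss.strand,
                paused=paused,
                rescue=rescue,
                is_7sk=is_7sk,
                has_kap1=has_kap1,
                is_kap1_7sk=is_7sk and has_kap1,
                is_kec=is_7sk and has_kap1 and paused,
                pol2_offset=pol2_offset,
                pol2_height=pol2_height,
                groseq_level=groseq_level,
            )
        )
    return peaks, truth


def simulate_pileup(peaks: Iterable[Peak], config: SimConfig) -> SignalTrack:
    """Per-million pileup: a triangular kernel per peak summit.

    Each peak contributes value ``height * (1 - |p - summit| / w)`` at
    position p within ``w = pileup_kernel_halfwidth`` of its summit; the
    whole track is then rescaled so the integrated signal is 1e6 (one
    million unit-length reads).  The kernel is symmetric, so the track
    argmax of every peak is exactly its narrowPeak summit.
    """
    w = config.pileup_kernel_halfwidth
    by_chrom: dict[str, list[tuple[int, int, float]]] = {}
    total = 0.0
    for p in peaks:
        s, h = p.summit, p.signal
        for d in range(-(w - 1), w):
            pos = s + d
            if pos < 0:
                continue
            v = h * (1.0 - abs(d) / w)
            by_chrom.setdefault(p.chrom, []).append((pos, pos + 1, v))
            total += v
    if total == 0.0:
        return SignalTrack()
    scale = 1e6 / total
    track = SignalTrack()
    for chrom, segs in by_chrom.items():
        segs.sort()
        arr = np.asarray(segs, dtype=float)
        starts = arr[:, 0].astype(np.int64)
        ends = arr[:, 1].astype(np.int64)
        if np.any(starts[1:] < ends[:-1]):
            raise ValueError(
                f"overlapping pileup kernels on {chrom}; genes too close"
            )
        track._chroms[chrom] = (starts, ends, arr[:, 2] * scale)
    return track


def simulate_groseq(
    truth: list[GeneTruth], config: SimConfig
) -> StrandedCoverage:
    """Strand-specific nascent coverage from the truth table's levels.

    Each paused gene contributes a constant block of its (noisy) GRO-seq
    level on its own strand, covering the first ``groseq_extent`` bp
    downstream of the TSS; the antisense strand receives nothing.
    """
    plus_segs: list[tuple[str, int, int, float]] = []
    minus_segs: list[tuple[str, int, int, float]] = []
    for t in truth:
        if not t.paused or t.groseq_level <= 0:
            continue
        if t.strand == "+":
            plus_segs.append(
                (t.chrom, t.tss, t.tss + config.groseq_extent, t.groseq_level)
            )
        else:
            lo = max(0, t.tss - config.groseq_extent + 1)
            minus_segs.append((t.chrom, lo, t.tss + 1, t.groseq_level))
    return StrandedCoverage(
        plus=SignalTrack.from_segments(plus_segs),
        minus=SignalTrack.from_segments(minus_segs),
    )


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Run the full generator: annotation, peaks, pileups, GRO-seq, truth."""
    sizes, tss_set = simulate_annotation(config)
    peaks, truth = simulate_peaks(tss_set, config)
    pileups = {f: simulate_pileup(peaks[f], config) for f in FACTORS}
    groseq = simulate_groseq(truth, config)
    return SimulatedDataset(
        config=config,
        sizes=sizes,
        tss=tss_set,
        peaks=peaks,
        pileups=pileups,
        groseq=groseq,
        truth=truth,
    )


def write_dataset(dataset: SimulatedDataset, outdir: str | Path) -> dict[str, Path]:
    """Write every simulated artifact to ``outdir``; returns path map."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    paths["chrom_sizes"] = outdir / "genome.chrom.sizes"
    with open(paths["chrom_sizes"], "w") as handle:
        for chrom in sorted(dataset.sizes):
            handle.write(f"{chrom}\t{dataset.sizes[chrom]}\n")

    paths["annotation"] = outdir / "tss.bed"
    with open(paths["annotation"], "w") as handle:
        for t in dataset.tss:
            if t.strand == "+":
                lo, hi = t.tss, t.tss + 1000
            else:
                lo, hi = max(0, t.tss - 999), t.tss + 1
            handle.write(f"{t.chrom}\t{lo}\t{hi}\t{t.gene_id}\t0\t{t.strand}\n")

    for factor in FACTORS:
        p = outdir / f"{factor}.narrowPeak"
        write_narrowpeak(dataset.peaks[factor], p)
        paths[f"peaks_{factor}"] = p
        b = outdir / f"{factor}.pileup.bedGraph"
        write_bedgraph(dataset.pileups[factor], b)
        paths[f"pileup_{factor}"] = b

    paths["groseq_plus"] = outdir / "groseq.plus.bedGraph"
    paths["groseq_minus"] = outdir / "groseq.minus.bedGraph"
    write_bedgraph(dataset.groseq.plus, paths["groseq_plus"])
    write_bedgraph(dataset.groseq.minus, paths["groseq_minus"])

    paths["truth"] = outdir / "truth.tsv"
    dataset.truth_frame().to_csv(paths["truth"], sep="\t", index=False)
    return paths
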