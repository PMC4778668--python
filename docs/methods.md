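# Methods

This note records the models, conventions and design choices behind
`kecpipe`, in the order the pipeline runs.

## Coordinates, windows and strand handling

All coordinates are 0-based; intervals on disk (BED, narrowPeak, bedGraph)
are half-open, following the formats themselves. Promoter windows are
defined on strand-signed offsets from the TSS with **inclusive** bounds: the
broad window is −250 ≤ d ≤ +1000 and the narrow window −250 ≤ d ≤ +250,
where d = p − tss on the plus strand and tss − p on the minus strand. The
TSS of a minus-strand transcript spanning [start, end) is end − 1. Windows
are clipped to chromosome bounds rather than rejected, so genes near
chromosome ends still classify.

Windows are strand-oriented by default; a `stranded=False` switch lays them
out in reference coordinates instead, since published window definitions of
this kind do not always state their strand handling. The co-occupancy
window around a Pol II *summit* is deliberately not strand-flipped — a
single-bp anchor has no orientation, and ±250 bp is symmetric anyway.

Unique TSS are deduplicated on (chrom, position, strand), not on gene name:
the gene universe is a set of distinct start sites, and two transcripts
sharing a start are one pausing observation. Dedupe keeps the first gene id
seen and sorts by coordinate, making every downstream run deterministic.

## Summit assignment and the H3K4me3 rescue

The classification is summit-anchored: a gene must first have a Pol II peak
summit in the promoter-proximal region before factor co-occupancy is
evaluated around that summit. The boundary case d = +250 belongs to the
narrow window; the rescue zone is the half-open offset range (+250, +1000],
so no summit can be counted twice. A rescue-zone summit counts only when an
H3K4me3 peak **interval** overlaps the zone by at least 1 bp — the active
promoter mark validates that pausing is genuinely downstream of an
imprecisely annotated TSS; the factor co-occupancy test, by contrast, uses
factor **summits**, because summits are the single most confident position
in a peak call and keep the ±250 bp interaction-distance argument honest.
An "any-overlap" co-occupancy mode is available behind a flag.

When several Pol II summits are candidates, the highest peak signal wins,
then the smallest |offset|, then the smaller coordinate — a deterministic
total order. Each TSS is classified independently even when two TSS share
one peak: the tallies count genes, not peaks.

The summit-anchored procedure makes the 7SK/KAP1-7SK sets conditional on
paused Pol II, so the nesting KEC ⊆ KAP1-7SK ⊆ 7SK ⊆ paused holds by
construction and is asserted on every run. A TSS-anchored mode (factor
summits anywhere in the −250..+1000 TSS window, no Pol II requirement) is
provided for sensitivity analysis; its sets need not nest inside the paused
set and the package does not claim either mode matches any particular
published count.

## Hypergeometric co-occupancy tests

Enrichment and depletion of the overlap k between K marked and n drawn
units of an N-unit universe are the two tails of
Hypergeometric(N, K, n). The pmf is computed from log-gamma functions and
tails are summed with log-sum-exp, so the result is exact in log space —
overlaps whose p-value underflows double precision (the "machine zero"
2.2204e−16, i.e. the double-precision epsilon) still report a finite
log10 p, alongside a below-machine-epsilon flag. Tail queries with k
outside the distribution's support follow the CDF extension (P[X ≤ k] = 0
below the support minimum, 1 above the maximum), matching R's `phyper`;
the pmf itself rejects out-of-support k. Tests against exact integer
combinatorics (all parameterizations with N ≤ 25), full subset enumeration,
and an independent survival-function implementation at N = 30,180 guard the
numerics.

The same test runs on two universes: gene sets (indicator vectors over the
deduplicated TSS universe) and 250-bp genome bins. Bins tile each
chromosome from coordinate 0; the trailing partial bin is dropped so every
unit of the universe has the same size (unequal units would break the
exchangeability the hypergeometric assumes). Any bin overlapping a
promoter window by ≥ 1 bp is removed — the strictest reading of "remove the
promoter-proximal region" — with a majority-overlap mode behind a flag. A
bin is occupied by a factor when ≥ 1 bp of any peak interval overlaps it.

## Metagene matrices and profiles

The signal matrix cell is the **mean per-bp** pileup value in the bin, not
the sum, making profile heights independent of bin size. The window is
[−half_width, +half_width) in offsets, so the TSS sits exactly on the
boundary between the two central bins and a 50-bp-binned ±1 kb window has
40 bins with centers at ±25, ±75, … bp. Minus-strand rows are reversed so
bin 0 is always the most upstream; positions beyond chromosome or track
bounds contribute 0, and anchors on chromosomes absent from a track yield
zero rows with a logged warning (partial inputs flow; they do not crash).

Input bedGraphs are assumed already normalized per million mapped reads
(the `--SPMR` convention of common peak callers); the package never
rescales a track. The RPKM profile mode multiplies the mean per-bp
per-million value by 1000 (per-kb scaling); percent-of-max mode rescales a
profile so its maximum is 100. The average pause site is the bin-center
offset of the profile maximum; ties break toward the TSS, then upstream.
With 50-bp bins this estimator is only bin-resolution accurate — a true
+100 bp pause site legitimately reports as +75 or +125.

Heatmap ordering sorts rows by decreasing total density with a stable sort
(equal densities keep input order), and the Pol II ordering is applied
verbatim to every other factor's matrix — reordering is a pure row
permutation, checked as such.

## GRO-seq ranking

Sense transcription per gene is the summed coverage of the gene's own
strand track over the strand-oriented −250..+1000 TSS window — the same
window as the co-occupancy analysis, chosen because "surrounding the TSS"
needs a concrete definition and reusing the promoter window keeps the
pipeline's geometry consistent; window and statistic are configurable. The
default ranking is restricted to plus-strand genes (matching the analysis
this reproduces); a both-strand sense-aware mode exists. Ties rank by gene
id.

## Synthetic data generator

The generator emulates the statistical structure the analysis is designed
to detect, with defaults encoding the expected promoter geometry:

| parameter | default | meaning |
|---|---|---|
| `fraction_paused` | 0.6 | P(gene has promoter-proximal Pol II) |
| `fraction_narrow` | 0.75 | P(summit in narrow window \| paused); the rest are H3K4me3-rescued |
| `p_7sk_given_paused` | 0.9 | P(all three 7SK components \| paused) |
| `p_kap1_given_7sk` | 0.9 | P(KAP1 \| 7SK) |
| `pol2_offset_mean/sd` | +100 / 50 bp | truncated normal on [−250, +250] |
| `factor_shift_mean/sd` | +125 / 40 bp | downstream shift of factor summits from the Pol II summit, truncated to ±250 |
| `pileup_kernel_halfwidth` | 150 bp | triangular kernel per summit |
| `groseq_gain` / `groseq_noise_sd` | 1.0 / 3.0 | sense GRO-seq level = gain·(Pol II height) + N(0, sd), floored at 0 |

Offset draws resample until inside their window (truncated normal) rather
than clipping, which would pile probability mass on the boundary and bias
recovery tests. The pileup kernel is triangular, not Gaussian: finite
support makes kernel masses exact and guarantees the track argmax is the
narrowPeak summit. Tracks are globally rescaled so the integrated signal is
10⁶ (one million unit-length reads), mimicking per-million normalization.
Rescued genes draw their Pol II offset uniformly on (+250, +1000] and get
an H3K4me3 peak centered on that summit; unpaused genes emit no peaks and
no nascent transcription.

TSS are placed by rejection sampling with a 3.5-kb minimum spacing, which
keeps every gene's windows, factor summits and kernels disjoint from its
neighbours'. Consequently classification on synthetic data is exact
gene-by-gene (the truth table is recovered with zero error even at nonzero
offset noise), and the recovered target-set *fractions* differ from the
configured probabilities only by binomial sampling noise — which is what
the recovery tests check, at three binomial standard errors.

What the generator does **not** emulate: background/noise peaks, duplicate
reads, input-control tracks, overlapping genes and bidirectional promoters,
chromatin domain structure, divergent antisense transcription, or
mappability artifacts. Passing recovery tests therefore demonstrates the
pipeline's correctness on clean, collision-free inputs, not robustness to
the full messiness of real ChIP-seq.

## Problem sizes and numerical conventions

The test suite and the reproduction script run the synthetic pipeline at
120–2,000 genes on 1–8 Mb toy chromosomes; the 2,000-gene setting makes
three binomial standard errors about ±3 percentage points on the recovered
fractions, tight enough to catch classification defects while keeping a
full run in seconds. Hypergeometric oracle checks enumerate universes up to
N = 25 exactly (rational arithmetic) and to N = 10 by brute-force subset
enumeration. Tail identities are asserted to 1e−12, conservation of matrix
mass to 1e−9 relative. Readers reject malformed records with the offending
line number; writers emit files their paired reader round-trips to the
stated formatting precision (CDT values at six decimals). narrowPeak
summits of −1 are salvaged as interval midpoints and flagged rather than
dropped, so unrefined toy peak files still flow.

## Known limitations

- The classification consumes peak calls as given; it does not model peak-
  calling uncertainty, nor the signal-threshold variant of "devoid" genes.
- The pause-offset estimate is bin-quantized (±half a bin).
- Gene-level and bin-level hypergeometric universes answer subtly different
  questions; the package exposes both and leaves the choice to the user.
- BigWig I/O and image rendering are out of scope; CDT files are emitted
  for external viewers.
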