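import numpy as np
import pytest

from kecpipe.annotation import TSSRecord, signed_offset
from kecpipe.interval_io import GenomicInterval, Peak
from kecpipe.target_classification import (
    ClassifyConfig,
    PeakIndex,
    SEVEN_SK_FACTORS,
    assign_pol2_summit,
    classify_all,
    factor_cooccupied,
    tally,
    tally_from_counts,
)

ALL_FACTORS = ("pol2", "kap1", "cdk9", "hexim1", "larp7", "h3k4me3")


def make_peak(chrom, summit, signal=1.0, halfwidth=100, name="p"):
    lo = max(0, summit - halfwidth)
    return Peak(
        interval=GenomicInterval(chrom, lo, summit + halfwidth + 1),
        name=name,
        signal=signal,
        summit_offset=summit - lo,
    )


def peaks_for(tss, factor_offsets):
    """Build a factor->peaks map from strand-signed offsets per factor."""
    sign = 1 if tss.strand == "+" else -1
    out = {f: [] for f in ALL_FACTORS}
    for factor, offsets in factor_offsets.items():
        for off in offsets:
            if isinstance(off, tuple):
                off, signal = off
            else:
                signal = 1.0
            out[factor].append(make_peak(tss.chrom, tss.tss + sign * off, signal))
    return out


# ---------------------------------------------------------------- oracle ----

def brute_assign_summit(tss, pol2_peaks, h3k4me3_peaks, use_rescue=True):
    """Independent per-pair scan implementing the same contract."""
    def best(cands):
        return min(
            cands, key=lambda p: (-p.signal, abs(signed_offset(tss, p.summit)), p.summit)
        ).summit

    narrow = [
        p for p in pol2_peaks
        if p.chrom == tss.chrom and -250 <= signed_offset(tss, p.summit) <= 250
    ]
    if narrow:
        return best(narrow), False
    if not use_rescue:
        return None, False
    rescue = [
        p for p in pol2_peaks
        if p.chrom == tss.chrom and 250 < signed_offset(tss, p.summit) <= 1000
    ]
    if not rescue:
        return None, False
    zone = {
        p for p in range(max(0, tss.tss - 1000), tss.tss + 1001)
        if 250 < signed_offset(tss, p) <= 1000
    }
    if not any(
        h.chrom == tss.chrom and zone & set(range(h.interval.lo, h.interval.hi))
        for h in h3k4me3_peaks
    ):
        return None, False
    return best(rescue), True


def brute_classify(tss_set, peaks):
    calls = []
    for tss in tss_set:
        summit, rescued = brute_assign_summit(tss, peaks["pol2"], peaks["h3k4me3"])
        flags = {}
        for f in ("kap1",) + SEVEN_SK_FACTORS:
            flags[f] = summit is not None and any(
                p.chrom == tss.chrom and abs(p.summit - summit) <= 250
                for p in peaks[f]
            )
        is_7sk = summit is not None and all(flags[f] for f in SEVEN_SK_FACTORS)
        calls.append(
            {
                "summit": summit,
                "rescued": rescued,
                "paused": summit is not None,
                "is_7sk": is_7sk,
                "is_kap1_7sk": is_7sk and flags["kap1"],
                "is_kec": is_7sk and flags["kap1"] and summit is not None,
            }
        )
    return calls


# ----------------------------------------------------------------- tests ----

class TestAssignSummit:
    def test_narrow_summit_no_rescue(self):
        t = TSSRecord("g", "chr1", 10_000, "+")
        pk = peaks_for(t, {"pol2": [100]})
        summit, rescued = assign_pol2_summit(t, PeakIndex(pk["pol2"]), PeakIndex([]))
        assert summit == 10_100 and not rescued

    def test_downstream_summit_without_h3k4me3_is_absent(self):
        t = TSSRecord("g", "chr1", 10_000, "+")
        pk = peaks_for(t, {"pol2": [500]})
        summit, rescued = assign_pol2_summit(t, PeakIndex(pk["pol2"]), PeakIndex([]))
        assert summit is None and not rescued

    def test_downstream_summit_rescued_by_h3k4me3(self):
        t = TSSRecord("g", "chr1", 10_000, "-")
        pk = peaks_for(t, {"pol2": [500], "h3k4me3": [500]})
        summit, rescued = assign_pol2_summit(
            t, PeakIndex(pk["pol2"]), PeakIndex(pk["h3k4me3"])
        )
        assert summit == 9_500 and rescued

    def test_tiebreak_highest_signal_wins(self):
        t = TSSRecord("g", "chr1", 10_000, "+")
        pk = peaks_for(t, {"pol2": [(100, 5.0), (40, 9.0)]})
        summit, _ = assign_pol2_summit(t, PeakIndex(pk["pol2"]), PeakIndex([]))
        assert summit == 10_040

    def test_boundary_offset_250_is_narrow(self):
        t = TSSRecord("g", "chr1", 10_000, "+")
        pk = peaks_for(t, {"pol2": [250]})
        summit, rescued = assign_pol2_summit(t, PeakIndex(pk["pol2"]), PeakIndex([]))
        assert summit == 10_250 and not rescued


class TestFactorCooccupied:
    def test_inclusive_bound(self):
        idx = PeakIndex([make_peak("chr1", 10_250)])
        assert factor_cooccupied(10_000, "chr1", idx)

    def test_exclusive_beyond_bound(self):
        idx = PeakIndex([make_peak("chr1", 10_251)])
        assert not factor_cooccupied(10_000, "chr1", idx)

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(5)
        summits = rng.integers(0, 20_000, size=50)
        idx = PeakIndex([make_peak("chr1", int(s)) for s in summits])
        for anchor in rng.integers(0, 20_000, size=200):
            expected = bool(np.any(np.abs(summits - anchor) <= 250))
            assert factor_cooccupied(int(anchor), "chr1", idx) == expected


class TestClassifyAll:
    def test_full_kec_call(self):
        t = TSSRecord("g", "chr1", 10_000, "+")
        pk = peaks_for(
            t, {"pol2": [100], "kap1": [225], "cdk9": [225], "hexim1": [225], "larp7": [225]}
        )
        (call,) = classify_all([t], pk)
        assert call.paused and call.is_7sk and call.is_kap1_7sk and call.is_kec

    def test_missing_larp7_peak_blocks_7sk(self):
        t = TSSRecord("g", "chr1", 10_000, "+")
        pk = peaks_for(t, {"pol2": [100], "kap1": [225], "cdk9": [225], "hexim1": [225]})
        (call,) = classify_all([t], pk)
        assert call.paused and not call.is_7sk and not call.is_kec

    def test_no_pol2_all_flags_false(self):
        t = TSSRecord("g", "chr1", 10_000, "+")
        pk = peaks_for(t, {"kap1": [100], "cdk9": [100], "hexim1": [100], "larp7": [100]})
        (call,) = classify_all([t], pk)
        assert call.pol2_summit is None
        assert not any([call.paused, call.is_7sk, call.is_kap1_7sk, call.is_kec])

    def test_missing_factor_file_names_factor(self):
        t = TSSRecord("g", "chr1", 10_000, "+")
        with pytest.raises(ValueError, match="larp7"):
            classify_all([t], {f: [] for f in ALL_FACTORS if f != "larp7"})

    def test_matches_brute_force_oracle_random_instance(self):
        rng = np.random.default_rng(17)
        tss_set = [
            TSSRecord(f"g{i}", "chr1", int(rng.integers(2000, 200_000)),
                      "+" if rng.random() < 0.5 else "-")
            for i in range(200)
        ]
        peaks = {
            f: [
                make_peak("chr1", int(rng.integers(1000, 201_000)),
                          signal=float(rng.uniform(1, 10)))
                for _ in range(int(rng.integers(50, 170)))
            ]
            for f in ALL_FACTORS
        }
        calls = classify_all(tss_set, peaks)
        expected = brute_classify(tss_set, peaks)
        for call, exp in zip(calls, expected):
            assert call.pol2_summit == exp["summit"]
            assert call.rescue_used == exp["rescued"]
            assert call.paused == exp["paused"]
            assert call.is_7sk == exp["is_7sk"]
            assert call.is_kap1_7sk == exp["is_kap1_7sk"]
            assert call.is_kec == exp["is_kec"]

    def test_disabling_rescue_only_shrinks_paused_set(self, small_dataset):
        with_rescue = classify_all(small_dataset.tss, small_dataset.peaks)
        without = classify_all(
            small_dataset.tss, small_dataset.peaks, ClassifyConfig(use_rescue=False)
        )
        paused_with = {c.tss.gene_id for c in with_rescue if c.paused}
        paused_without = {c.tss.gene_id for c in without if c.paused}
        assert paused_without <= paused_with
        assert len(paused_without) < len(paused_with)  # dataset contains rescued genes

    def test_nesting_invariant_on_synthetic_run(self, small_dataset):
        calls = classify_all(small_dataset.tss, small_dataset.peaks)
        kec = {c.tss.gene_id for c in calls if c.is_kec}
        kap = {c.tss.gene_id for c in calls if c.is_kap1_7sk}
        svk = {c.tss.gene_id for c in calls if c.is_7sk}
        paused = {c.tss.gene_id for c in calls if c.paused}
        assert kec <= kap <= svk <= paused

    def test_tss_anchored_mode_needs_no_pol2_summit(self):
        t = TSSRecord("g", "chr1", 10_000, "+")
        pk = peaks_for(t, {"kap1": [500], "cdk9": [500], "hexim1": [500], "larp7": [500]})
        (call,) = classify_all([t], pk, ClassifyConfig(anchor="tss", use_rescue=False))
        assert call.is_7sk and call.is_kap1_7sk and not call.is_kec


class TestTally:
    def test_counts_and_fractions_from_calls(self, small_dataset):
        calls = classify_all(small_dataset.tss, small_dataset.peaks)
        counts = tally(calls)
        assert counts.n_paused == counts.n_narrow + counts.n_rescued
        assert counts.n_paused >= counts.n_7sk >= counts.n_kap1_7sk >= counts.n_kec

    def test_injected_count_arithmetic(self):
        counts = tally_from_counts(
            n_universe=30_180, n_narrow=13_048, n_rescued=4_268,
            n_7sk=15_850, n_kap1_7sk=14_203, n_kec=12_211,
        )
        assert counts.n_paused == 17_316
        assert counts.frac_kec_of_universe == 40.5
        assert counts.frac_kec_of_paused == 70.5

    def test_empty_calls(self):
        counts = tally([])
        assert counts.n_universe == 0 and counts.n_kec == 0
        assert counts.frac_kec_of_paused is None
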