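"""Assay selection, PRT suitability filtering, annotation, multi-target."""

import dataclasses
import itertools

import pytest

from prtdesign.filters import (
    Candidate,
    FilterParams,
    Rejection,
    annotate,
    apply_filters,
    count_mispriming,
    deduplicate_assays,
    select_multi_target,
    select_two_exact,
)
from prtdesign.ispcr import AmpliconMatch, PrimingSite
from prtdesign.primers import PrimerPair
from prtdesign.reference import IntervalTrack


def make_pair(pid="p1"):
    return PrimerPair(
        id=pid,
        window=(0, 2000),
        fwd_seq="ACGTGCATGCATCGATCGAT",
        rev_seq="TTGCACTGATCGACGGTACT",
        fwd_start=100,
        rev_end=300,
        designed_product_size=200,
        tm_f=60.0,
        tm_r=60.0,
        gc_f=50.0,
        gc_r=50.0,
        relaxation_round=0,
    )


def amp(chrom, start, size, mism=(0, 0), pid="p1"):
    fwd = PrimingSite(chrom, "+", start, start + 20, mism[0])
    rev = PrimingSite(chrom, "-", start + size - 20, start + size, mism[1])
    total = sum(mism)
    return AmpliconMatch(
        pair_id=pid,
        chrom=chrom,
        start=start,
        end=start + size,
        product_size=size,
        fwd_site=fwd,
        rev_site=rev,
        score=round(1000 * (1 - total / 40)),
        exact=total == 0,
    )


TARGET = ("chr1", 0, 10_000)


class TestSelectTwoExact:
    def test_target_plus_external_reference(self):
        amps = [amp("chr1", 500, 100), amp("chr2", 99_000, 120)]
        cand = select_two_exact(make_pair(), amps, TARGET)
        assert isinstance(cand, Candidate)
        assert cand.target.chrom == "chr1" and cand.reference.chrom == "chr2"

    def test_unique_amplicon_rejected(self):
        out = select_two_exact(make_pair(), [amp("chr1", 500, 100)], TARGET)
        assert isinstance(out, Rejection) and out.reason == "unique"

    def test_multicopy_rejected(self):
        amps = [amp("chr1", 500, 100), amp("chr2", 0, 100), amp("chr3", 0, 100)]
        out = select_two_exact(make_pair(), amps, TARGET)
        assert isinstance(out, Rejection) and out.reason == "multicopy"

    def test_both_in_target_rejected(self):
        amps = [amp("chr1", 500, 100), amp("chr1", 2000, 120)]
        out = select_two_exact(make_pair(), amps, TARGET)
        assert isinstance(out, Rejection) and out.reason == "no external reference"

    def test_mispriming_matches_ignored_for_copy_count(self):
        amps = [
            amp("chr1", 500, 100),
            amp("chr2", 99_000, 120),
            amp("chr3", 5_000, 150, mism=(1, 1)),
        ]
        assert isinstance(select_two_exact(make_pair(), amps, TARGET), Candidate)


def make_candidate(
    target_size=100,
    ref_size=120,
    ref_chrom="chr2",
    ref_start=2_000_000,
    extra_amps=(),
):
    t = amp("chr1", 500, target_size)
    r = amp(ref_chrom, ref_start, ref_size)
    return Candidate(make_pair(), t, r, (t, r) + tuple(extra_amps))


class TestApplyFilters:
    def test_size_difference_passes(self):
        assay = apply_filters(make_candidate(100, 120), FilterParams())
        assert assay.size_diff == 20 and assay.misprime == 0

    def test_zero_size_difference_mode(self):
        """RFLP/probe searches may explicitly allow identical sizes."""
        cand = make_candidate(100, 100)
        assert isinstance(apply_filters(cand, FilterParams()), Rejection)
        assay = apply_filters(cand, FilterParams(min_size_diff=0))
        assert assay.size_diff == 0

    def test_reference_too_close_on_same_chromosome(self):
        cand = make_candidate(ref_chrom="chr1", ref_start=400_600)  # 400 kb gap
        out = apply_filters(cand, FilterParams())
        assert isinstance(out, Rejection) and out.reason == "reference too close"

    def test_distance_rule_passes_far_same_chromosome(self):
        cand = make_candidate(ref_chrom="chr1", ref_start=600_000)
        assert not isinstance(apply_filters(cand, FilterParams()), Rejection)

    def test_different_chromosome_always_passes_distance(self):
        cand = make_candidate(ref_chrom="chr2", ref_start=700)
        assert not isinstance(apply_filters(cand, FilterParams()), Rejection)

    def test_reference_size_bounds(self):
        cand = make_candidate(ref_size=350)
        out = apply_filters(cand, FilterParams(max_ref_size=300))
        assert isinstance(out, Rejection)

    def test_misprime_threshold(self):
        noisy = [amp("chr5", i * 10_000, 150, mism=(1, 1)) for i in range(3)]
        cand = make_candidate(extra_amps=noisy)
        out = apply_filters(cand, FilterParams())  # max_misprime 2 < 3
        assert isinstance(out, Rejection)
        assay = apply_filters(cand, FilterParams(max_misprime=3))
        assert assay.misprime == 3

    def test_order_invariance(self):
        """Filtering is pure: amplicon order never changes the outcome."""
        noisy = [amp("chr5", i * 10_000, 150, mism=(1, 1)) for i in range(2)]
        t = amp("chr1", 500, 100)
        r = amp("chr2", 2_000_000, 120)
        results = []
        for perm in itertools.permutations([t, r] + noisy):
            cand = Candidate(make_pair(), t, r, tuple(perm))
            results.append(apply_filters(cand, FilterParams()))
        assert all(res == results[0] for res in results)

    def test_tightening_never_accepts_more(self, rng):
        """Monotone screening: tightening any bound only removes assays."""
        base = FilterParams()
        for _ in range(50):
            cand = make_candidate(
                target_size=int(rng.integers(80, 200)),
                ref_size=int(rng.integers(80, 200)),
                ref_chrom="chr1" if rng.random() < 0.5 else "chr2",
                ref_start=int(rng.integers(0, 2_000_000)),
                extra_amps=tuple(
                    amp("chr9", int(rng.integers(0, 10**6)), 150, mism=(1, 1))
                    for _ in range(int(rng.integers(0, 4)))
                ),
            )
            loose = apply_filters(cand, base)
            tighter = [
                dataclasses.replace(base, min_size_diff=base.min_size_diff + 5),
                dataclasses.replace(base, max_size_diff=10),
                dataclasses.replace(base, min_distance=base.min_distance * 2),
                dataclasses.replace(base, max_misprime=0),
                dataclasses.replace(base, min_ref_size=150, max_ref_size=160),
            ]
            for params in tighter:
                tight = apply_filters(cand, params)
                if isinstance(loose, Rejection):
                    assert isinstance(tight, Rejection)


class TestCountMispriming:
    def test_only_exact(self):
        assert count_mispriming([amp("chr1", 0, 100), amp("chr2", 0, 120)]) == 0

    def test_counts_above_threshold(self):
        amps = [
            amp("chr1", 0, 100),
            amp("chr2", 0, 120),
            amp("chr3", 0, 100, mism=(1, 0)),  # 975
            amp("chr4", 0, 100, mism=(2, 0)),  # 950
            amp("chr5", 0, 100, mism=(2, 1)),  # 925
        ]
        assert count_mispriming(amps) == 3

    def test_boundary_score_excluded(self):
        amps = [
            amp("chr1", 0, 100),
            amp("chr2", 0, 120),
            amp("chr3", 0, 100, mism=(2, 2)),  # exactly 900
        ]
        assert count_mispriming(amps) == 0


class TestAnnotate:
    def test_reference_in_cnv_flagged(self):
        assay = apply_filters(make_candidate(), FilterParams())
        cnv = IntervalTrack("CNV_INDEL", [("chr2", 1_999_000, 2_001_000, "dgv1")])
        out = annotate(assay, cnv_track=cnv)
        assert out.dgv_reference == "dgv1" and out.dgv_target == "."

    def test_no_tracks(self):
        assay = annotate(apply_filters(make_candidate(), FilterParams()))
        assert assay.dgv_target == "." and assay.fsnp == 0 and assay.rsnp == 0

    def test_snp_under_reverse_primer_at_reference_locus(self):
        assay = apply_filters(make_candidate(), FilterParams())
        rev_site = assay.reference.rev_site
        snp = IntervalTrack(
            "SNP_ANNOT", [("chr2", rev_site.start + 3, rev_site.start + 4, "rs9")]
        )
        out = annotate(assay, snp_track=snp)
        assert out.rsnp == 1 and out.fsnp == 0


def region(chrom, start, end):
    return (chrom, start, end)


class TestSelectMultiTarget:
    TARGETS = [region("chr1", 0, 10_000), region("chr2", 0, 10_000), region("chr3", 0, 10_000)]

    def test_one_per_target_plus_distinct_reference(self):
        amps = [
            amp("chr1", 500, 100),
            amp("chr2", 600, 100),
            amp("chr3", 700, 100),
            amp("chr4", 800, 120),
        ]
        cand = select_multi_target(make_pair(), amps, self.TARGETS)
        assert isinstance(cand, Candidate)
        assert cand.reference.chrom == "chr4"
        assert len(cand.extra_targets) == 2

    def test_reference_size_must_differ(self):
        amps = [
            amp("chr1", 500, 100),
            amp("chr2", 600, 100),
            amp("chr3", 700, 100),
            amp("chr4", 800, 100),
        ]
        out = select_multi_target(make_pair(), amps, self.TARGETS)
        assert isinstance(out, Rejection)
        assert out.reason == "reference size equals target size"

    def test_two_copies_in_one_target_rejected(self):
        amps = [
            amp("chr1", 500, 100),
            amp("chr1", 5_000, 100),
            amp("chr3", 700, 100),
            amp("chr4", 800, 120),
        ]
        out = select_multi_target(make_pair(), amps, self.TARGETS)
        assert isinstance(out, Rejection) and out.reason == "one-per-target violated"

    def test_wrong_exact_count_rejected(self):
        amps = [amp("chr1", 500, 100), amp("chr2", 600, 100), amp("chr4", 800, 120)]
        out = select_multi_target(make_pair(), amps, self.TARGETS)
        assert isinstance(out, Rejection)

    def test_too_many_targets(self):
        with pytest.raises(ValueError):
            select_multi_target(
                make_pair(), [], [region(f"chr{i}", 0, 10) for i in range(5)]
            )


def test_deduplicate_keeps_first_in_genomic_order():
    a1 = apply_filters(make_candidate(), FilterParams())
    a2 = dataclasses.replace(a1, id="p9")
    out = deduplicate_assays([a2, a1])
    assert len(out) == 1 and out[0].id == "p1"
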