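"""In-silico PCR: index construction, mismatch-tolerant site search,
amplicon enumeration and match scoring."""

import numpy as np
import pytest

from _helpers import (
    mutate,
    naive_priming_sites,
    random_dna,
    rc,
    site_tuples,
)
from prtdesign.ispcr import (
    IndexParams,
    build_index,
    enumerate_amplicons,
    find_priming_sites,
    score_match,
    single_primer_amplicons,
)
from prtdesign.reference import Genome


def make_genome(**seqs):
    return Genome({k: v for k, v in seqs.items()})


class TestBuildIndex:
    def test_tiles_at_strides(self):
        g = make_genome(chr1="ACGTACGTACGT")
        idx = build_index(g, IndexParams(tile_size=4, step_size=4, min_perfect=4))
        assert sorted(p for _c, p in idx.tiles["ACGT"]) == [0, 4, 8]

    def test_n_tiles_skipped(self):
        g = make_genome(chr1="ACGTNACGTACG")
        idx = build_index(g, IndexParams(tile_size=4, step_size=1, min_perfect=4))
        assert all("N" not in tile for tile in idx.tiles)

    def test_step_one_indexes_every_position(self):
        g = make_genome(chr1=random_dna(np.random.default_rng(0), 200))
        idx = build_index(g, IndexParams(tile_size=10, step_size=1, min_perfect=5))
        assert idx.n_tiles() == 200 - 10 + 1

    def test_short_chromosome_skipped(self):
        g = make_genome(chr1="ACGT", chr2=random_dna(np.random.default_rng(0), 100))
        idx = build_index(g, IndexParams(tile_size=11, step_size=5))
        assert all(c == "chr2" for tile in idx.tiles.values() for c, _p in tile)

    def test_params_validation(self):
        with pytest.raises(ValueError):
            IndexParams(tile_size=5, step_size=9)


class TestFindPrimingSites:
    def test_planted_exact_copy(self, rng):
        seq = random_dna(rng, 5000)
        primer = seq[1200:1220]
        g = make_genome(chr1=seq)
        idx = build_index(g, IndexParams())
        sites = [s for s in find_priming_sites(primer, idx) if s.start == 1200]
        assert len(sites) == 1 and sites[0].mismatches == 0

    def test_five_prime_mismatch_reported(self, rng):
        genome_seq = random_dna(rng, 3000)
        primer = random_dna(rng, 20)
        # plant a copy with one substitution in the 5' half
        planted = mutate(rng, primer, 1, lo=0, hi=5)
        seq = genome_seq[:1000] + planted + genome_seq[1000:]
        idx = build_index(make_genome(chr1=seq), IndexParams.sensitive())
        hits = [
            s
            for s in find_priming_sites(primer, idx, max_mismatch=2)
            if s.start == 1000 and s.strand == "+"
        ]
        assert len(hits) == 1 and hits[0].mismatches == 1

    def test_three_prime_mismatch_disqualifies(self, rng):
        genome_seq = random_dna(rng, 3000)
        primer = random_dna(rng, 20)
        broken = mutate(rng, primer, 1, lo=18, hi=20)  # inside min_perfect=5 window
        seq = genome_seq[:1000] + broken + genome_seq[1000:]
        idx = build_index(make_genome(chr1=seq), IndexParams.sensitive())
        hits = [
            s
            for s in find_priming_sites(primer, idx, max_mismatch=6)
            if s.start == 1000 and s.strand == "+"
        ]
        assert hits == []

    def test_reverse_strand_found(self, rng):
        seq = random_dna(rng, 4000)
        primer = rc(seq[2000:2020])
        idx = build_index(make_genome(chr1=seq), IndexParams())
        hits = [s for s in find_priming_sites(primer, idx) if s.strand == "-"]
        assert any(s.start == 2000 and s.exact for s in hits)

    def test_primer_shorter_than_min_perfect(self, rng):
        idx = build_index(make_genome(chr1=random_dna(rng, 100)), IndexParams())
        with pytest.raises(ValueError):
            find_priming_sites("ACGTACGTAC", idx)  # 10 < minPerfect 15

    def test_sensitive_equals_full_scan_oracle(self, rng):
        """Exhaustive mode reproduces the naive every-offset scan exactly."""
        for trial in range(3):
            seq = random_dna(rng, 8000)
            primer = seq[3000:3020]
            seq = (
                seq[:500]
                + mutate(rng, primer, 2, hi=14)
                + seq[520:6000]
                + mutate(rng, primer, 4, hi=14)
                + seq[6020:]
            )
            g = make_genome(chr1=seq)
            params = IndexParams.sensitive()
            idx = build_index(g, params)
            got = site_tuples(find_priming_sites(primer, idx, max_mismatch=6))
            expected = naive_priming_sites(g, primer, params.min_perfect, 6)
            assert got == expected and len(got) >= 3

    def test_default_subset_of_oracle_with_all_exact(self, rng):
        seq = random_dna(rng, 8000)
        primer = seq[3000:3020]
        seq = seq[:500] + primer + seq[520:]  # second exact copy
        g = make_genome(chr1=seq)
        params = IndexParams()
        idx = build_index(g, params)
        got = set(site_tuples(find_priming_sites(primer, idx, max_mismatch=6)))
        oracle = set(naive_priming_sites(g, primer, params.min_perfect, 6))
        exact = {t for t in oracle if t[4] == 0}
        assert got <= oracle
        assert exact <= got and len(exact) == 2

    def test_sensitive_superset_of_default(self, rng):
        seq = random_dna(rng, 6000)
        primer = seq[2000:2020]
        seq = seq[:100] + mutate(rng, primer, 3, hi=14) + seq[120:]
        g = make_genome(chr1=seq)
        def_sites = set(
            site_tuples(find_priming_sites(primer, build_index(g, IndexParams()), max_mismatch=6))
        )
        # sensitive qualification (min_perfect 5) is weaker than default (15),
        # so compare on the default rule: re-filter sensitive hits
        sens = find_priming_sites(
            primer, build_index(g, IndexParams.sensitive()), max_mismatch=6
        )
        sens_sites = set(site_tuples(sens))
        assert def_sites <= sens_sites


class TestScoreMatch:
    @pytest.mark.parametrize(
        "fwd,rev,total,expected",
        [
            (0, 0, 40, 1000),
            (2, 2, 40, 900),  # four mismatches over a 40 nt pair sit at 900
            (1, 0, 36, 972),
            (0, 1, 40, 975),
        ],
    )
    def test_examples(self, fwd, rev, total, expected):
        assert score_match(fwd, rev, total) == expected

    def test_monotone_and_exact_iff_1000(self):
        scores = [score_match(m, 0, 40) for m in range(0, 41)]
        assert scores == sorted(scores, reverse=True)
        assert all(a > b for a, b in zip(scores, scores[1:]))
        assert scores[0] == 1000 and all(s < 1000 for s in scores[1:])

    def test_errors(self):
        with pytest.raises(ValueError):
            score_match(30, 30, 40)
        with pytest.raises(ValueError):
            score_match(0, 0, 0)


class _FakePair:
    def __init__(self, fwd, rev, pid="pair1"):
        self.id = pid
        self.fwd_seq = fwd
        self.rev_seq = rev


class TestEnumerateAmplicons:
    def test_productive_orientation(self, rng):
        seq = random_dna(rng, 2000)
        fwd = seq[100:120]
        rev = rc(seq[200:220])
        g = make_genome(chr1=seq)
        idx = build_index(g, IndexParams())
        fs = find_priming_sites(fwd, idx)
        rs = find_priming_sites(rev, idx)
        amps = enumerate_amplicons(_FakePair(fwd, rev), fs, rs, idx.params)
        spans = [(a.start, a.end, a.product_size, a.exact) for a in amps]
        assert (100, 220, 120, True) in spans

    def test_different_chromosomes_do_not_pair(self, rng):
        c1, c2 = random_dna(rng, 1000), random_dna(rng, 1000)
        fwd, rev = c1[100:120], rc(c2[300:320])
        g = make_genome(chr1=c1, chr2=c2)
        idx = build_index(g, IndexParams())
        amps = enumerate_amplicons(
            _FakePair(fwd, rev),
            find_priming_sites(fwd, idx),
            find_priming_sites(rev, idx),
            idx.params,
        )
        assert amps == []

    def test_reverse_upstream_is_unproductive(self, rng):
        seq = random_dna(rng, 2000)
        fwd = seq[500:520]
        rev = rc(seq[100:120])  # upstream of the forward site
        g = make_genome(chr1=seq)
        idx = build_index(g, IndexParams())
        amps = enumerate_amplicons(
            _FakePair(fwd, rev),
            find_priming_sites(fwd, idx),
            find_priming_sites(rev, idx),
            idx.params,
        )
        assert amps == []

    def test_product_size_cap(self, rng):
        seq = random_dna(rng, 9000)
        fwd = seq[100:120]
        rev = rc(seq[8000:8020])  # 7.9 kb product exceeds the 4 kb ceiling
        g = make_genome(chr1=seq)
        idx = build_index(g, IndexParams())
        amps = enumerate_amplicons(
            _FakePair(fwd, rev),
            find_priming_sites(fwd, idx),
            find_priming_sites(rev, idx),
            idx.params,
        )
        assert amps == []

    def test_mirrored_orientation(self, rng):
        """A pair also amplifies when the 'reverse' primer sits on the plus
        strand upstream of the 'forward' primer's minus-strand site."""
        seq = random_dna(rng, 2000)
        rev = seq[100:120]
        fwd = rc(seq[250:270])
        g = make_genome(chr1=seq)
        idx = build_index(g, IndexParams())
        amps = enumerate_amplicons(
            _FakePair(fwd, rev),
            find_priming_sites(fwd, idx),
            find_priming_sites(rev, idx),
            idx.params,
        )
        assert any(a.start == 100 and a.end == 270 and a.exact for a in amps)


class TestSinglePrimerAmplicons:
    def test_inverted_copy_amplifies(self, rng):
        seq = random_dna(rng, 3000)
        primer = seq[1000:1020]
        seq = seq[:1200] + rc(primer) + seq[1220:]
        idx = build_index(make_genome(chr1=seq), IndexParams())
        amps = single_primer_amplicons(primer, idx)
        assert len(amps) == 1
        assert amps[0].start == 1000 and amps[0].end == 1220

    def test_no_inverted_copy(self, rng):
        seq = random_dna(rng, 3000)
        primer = seq[1000:1020]
        idx = build_index(make_genome(chr1=seq), IndexParams())
        assert single_primer_amplicons(primer, idx) == []

    def test_palindromic_self_site_excluded(self, rng):
        half = "ACGTGCATGC"
        primer = half + rc(half)  # perfect palindrome, 20 nt
        seq = random_dna(rng, 2000)[:900] + primer + random_dna(rng, 1100)
        idx = build_index(make_genome(chr1=seq), IndexParams())
        amps = single_primer_amplicons(primer, idx)
        # its own footprint primes both strands but overlaps itself
        assert all(a.rev_site.start >= a.fwd_site.end for a in amps)
        assert amps == []
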