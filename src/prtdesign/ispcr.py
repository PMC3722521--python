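"""In-silico PCR: mismatch-tolerant priming-site search and amplicon
enumeration over a k-mer indexed genome.

A genomic footprint qualifies as a priming site for an oligo iff

* the 3'-terminal ``min_perfect`` bases of the oligo match the template
  perfectly (polymerase extension requires an annealed 3' end), and
* the total number of primer/template mismatches is at most
  ``max_mismatch`` (substitutions only; indels are not modeled).

Candidate footprints are seeded differently per mode. In default mode
(tile 11, stride 5, min_perfect 15) seeds are index tiles shared verbatim
between oligo and genome; this finds every exact site of an oligo of
>= tile+stride-1 nt and a proportion of mismatched (mispriming) sites. In
sensitive mode (stride 1, min_perfect 5) seeds are all exact genomic
occurrences of the oligo's 3'-terminal ``min_perfect``-mer, which by the
qualification rule every priming site must contain — so the sensitive
search is exhaustive (equal to a naive full scan), at higher cost.

Match quality is summarized on a 0–1000 scale:
``score = round(1000 * (1 - mismatches / primer_bases))``, anchored so
that 4 mismatches over a 40-base primer pair score exactly 900.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from ._seq import encode, revcomp
from .reference import Genome

log = logging.getLogger(__name__)

DEFAULT_MAX_MISMATCH = 6
MISPRIME_SCORE_THRESHOLD = 900


@dataclass(frozen=True)
class IndexParams:
    """Genome index / priming-model parameters.

    Defaults mirror common in-silico PCR practice: tile 11 sampled every
    5 bp with a 15 nt perfect 3' requirement; ``sensitive()`` trades speed
    for an exhaustive mispriming census (tile 10, stride 1, perfect 5).
    """

    tile_size: int = 11
    step_size: int = 5
    min_perfect: int = 15
    max_product_size: int = 4000
    mode: str = "default"

    def __post_init__(self) -> None:
        if not 1 <= self.step_size <= self.tile_size:
            raise ValueError("need 1 <= step_size <= tile_size")
        if self.min_perfect < 1:
            raise ValueError("min_perfect must be >= 1")

    @classmethod
    def default(cls) -> "IndexParams":
        return cls()

    @classmethod
    def sensitive(cls) -> "IndexParams":
        return cls(tile_size=10, step_size=1, min_perfect=5, mode="sensitive")


@dataclass(frozen=True)
class PrimingSite:
    """A genomic location where a primer may anneal.

    ``start``/``end`` delimit the footprint (0-based half-open) on the
    forward genome string; ``strand`` is the strand the primer would prime
    ('+' = primer sequence matches the forward strand, extension to the
    right; '−' sites extend leftward).
    """

    chrom: str
    strand: str
    start: int
    end: int
    mismatches: int

    @property
    def exact(self) -> bool:
        return self.mismatches == 0


@dataclass(frozen=True)
class AmpliconMatch:
    """A predicted PCR product: two priming sites in productive orientation."""

    pair_id: str
    chrom: str
    start: int
    end: int
    product_size: int
    fwd_site: PrimingSite
    rev_site: PrimingSite
    score: int
    exact: bool


class KmerIndex:
    """Tile index over the forward strand of a genome.

    Tiles of ``tile_size`` are sampled every ``step_size`` bp; tiles
    containing N are skipped. Encoded chromosome arrays are cached here for
    vectorized mismatch verification.
    """

    def __init__(self, genome: Genome, params: IndexParams):
        self.genome = genome
        self.params = params
        self.tiles: dict[str, list[tuple[str, int]]] = {}
        k, step = params.tile_size, params.step_size
        for chrom, seq in genome.sequences.items():
            if len(seq) < k:
                log.warning("chromosome %s shorter than tile size; skipped", chrom)
                continue
            for pos in range(0, len(seq) - k + 1, step):
                tile = seq[pos : pos + k]
                if "N" in tile:
                    continue
                self.tiles.setdefault(tile, []).append((chrom, pos))

    def n_tiles(self) -> int:
        return sum(len(v) for v in self.tiles.values())


def build_index(genome: Genome, params: IndexParams | None = None) -> KmerIndex:
    """Index a genome for priming-site search."""
    return KmerIndex(genome, params or IndexParams())


def _find_all(haystack: str, needle: str) -> list[int]:
    """All (overlapping) occurrence starts of ``needle`` in ``haystack``."""
    out = []
    i = haystack.find(needle)
    while i != -1:
        out.append(i)
        i = haystack.find(needle, i + 1)
    return out


def _verify(
    chrom_codes: np.ndarray,
    query: np.ndarray,
    starts: np.ndarray,
    perfect_at_start: bool,
    min_perfect: int,
    max_mismatch: int,
) -> list[tuple[int, int]]:
    """Check candidate footprints; return (start, mismatches) for survivors.

    ``perfect_at_start`` selects which end of the *genomic* footprint must
    match perfectly (the primer 3' end sits at the left end of the
    footprint for '−'-strand sites).
    """
    if starts.size == 0:
        return []
    L = query.size
    windows = chrom_codes[starts[:, None] + np.arange(L)[None, :]]
    mism = windows != query[None, :]
    if perfect_at_start:
        zone_ok = ~mism[:, :min_perfect].any(axis=1)
    else:
        zone_ok = ~mism[:, L - min_perfect :].any(axis=1)
    total = mism.sum(axis=1)
    keep = zone_ok & (total <= max_mismatch)
    return [(int(s), int(m)) for s, m in zip(starts[keep], total[keep])]


def find_priming_sites(
    primer: str,
    index: KmerIndex,
    genome: Genome | None = None,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> list[PrimingSite]:
    """All qualifying priming sites of ``primer`` on both strands.

    Results are deduplicated by (chrom, strand, start) and sorted.
    """
    genome = genome or index.genome
    params = index.params
    if len(primer) < params.min_perfect:
        raise ValueError("primer shorter than min_perfect")
    L = len(primer)
    k = params.tile_size
    sites: list[PrimingSite] = []
    for strand, query in (("+", primer), ("-", revcomp(primer))):
        qcodes = encode(query)
        # the primer 3' end maps to the left end of the genomic footprint
        # on the '-' strand
        perfect_at_start = strand == "-"
        for chrom, seq in genome.sequences.items():
            clen = len(seq)
            if clen < L:
                continue
            cand: set[int] = set()
            if params.step_size == 1:
                # exhaustive mode: seed from the obligatory exact 3' anchor
                if perfect_at_start:
                    anchor = query[: params.min_perfect]
                    for pos in _find_all(seq, anchor):
                        cand.add(pos)
                else:
                    anchor = query[L - params.min_perfect :]
                    for pos in _find_all(seq, anchor):
                        cand.add(pos - (L - params.min_perfect))
            else:
                for off in range(0, L - k + 1):
                    tile = query[off : off + k]
                    for tchrom, tpos in index.tiles.get(tile, ()):
                        if tchrom == chrom:
                            cand.add(tpos - off)
            starts = np.fromiter(
                (s for s in cand if 0 <= s <= clen - L), dtype=np.int64
            )
            starts.sort()
            for s, m in _verify(
                genome.encoded(chrom),
                qcodes,
                starts,
                perfect_at_start,
                params.min_perfect,
                max_mismatch,
            ):
                sites.append(PrimingSite(chrom, strand, s, s + L, m))
    sites.sort(key=lambda x: (x.chrom, x.strand, x.start))
    return sites


def score_match(fwd_mismatches: int, rev_mismatches: int, total_primer_bases: int) -> int:
    """0–1000 match score for an amplicon given per-primer mismatch counts."""
    if total_primer_bases < 1:
        raise ValueError("total_primer_bases must be >= 1")
    mm = fwd_mismatches + rev_mismatches
    if mm < 0 or mm > total_primer_bases:
        raise ValueError("mismatch sum out of range")
    return int(round(1000.0 * (1.0 - mm / total_primer_bases)))


def enumerate_amplicons(
    pair,
    fwd_sites: list[PrimingSite],
    rev_sites: list[PrimingSite],
    params: IndexParams,
) -> list[AmpliconMatch]:
    """All productive amplicons of a primer pair.

    A product forms when one primer primes the forward strand upstream of
    the other primer priming the reverse strand, within
    ``max_product_size``; both (fwd+, rev−) and the mirrored (rev+, fwd−)
    orientations are enumerated.
    """
    total = len(pair.fwd_seq) + len(pair.rev_seq)
    out: list[AmpliconMatch] = []
    for left_sites, right_sites in (
        (fwd_sites, rev_sites),
        (rev_sites, fwd_sites),
    ):
        lefts = [s for s in left_sites if s.strand == "+"]
        rights = [s for s in right_sites if s.strand == "-"]
        for ls in lefts:
            for rs in rights:
                if ls.chrom != rs.chrom:
                    continue
                size = rs.end - ls.start
                if size <= 0 or size > params.max_product_size:
                    continue
                if rs.start < ls.end:  # overlapping footprints cannot extend
                    continue
                if left_sites is fwd_sites:
                    f_site, r_site = ls, rs
                else:
                    f_site, r_site = rs, ls
                out.append(
                    AmpliconMatch(
                        pair_id=pair.id,
                        chrom=ls.chrom,
                        start=ls.start,
                        end=rs.end,
                        product_size=size,
                        fwd_site=f_site,
                        rev_site=r_site,
                        score=score_match(f_site.mismatches, r_site.mismatches, total),
                        exact=f_site.exact and r_site.exact,
                    )
                )
    out.sort(key=lambda a: (a.chrom, a.start, a.end, -a.score))
    # mirrored orientations of a palindromic-ish pair can duplicate a product
    seen: set[tuple] = set()
    uniq = []
    for a in out:
        key = (a.chrom, a.start, a.end, a.fwd_site.strand)
        if key not in seen:
            seen.add(key)
            uniq.append(a)
    return uniq


@dataclass(frozen=True)
class _SoloPair:
    id: str
    fwd_seq: str
    rev_seq: str


def single_primer_amplicons(
    primer: str,
    index: KmerIndex,
    genome: Genome | None = None,
    params: IndexParams | None = None,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
    pair_id: str = "single",
) -> list[AmpliconMatch]:
    """Products the SAME primer could amplify by priming both strands.

    Requires two distinct, non-overlapping inverted sites; a palindromic
    primer sitting over its own footprint is degenerate and excluded.
    """
    params = params or index.params
    sites = find_priming_sites(primer, index, genome, max_mismatch)
    plus = [s for s in sites if s.strand == "+"]
    minus = [s for s in sites if s.strand == "-"]
    pseudo = _SoloPair(pair_id, primer, primer)
    out: list[AmpliconMatch] = []
    total = 2 * len(primer)
    for ls in plus:
        for rs in minus:
            if ls.chrom != rs.chrom or rs.start < ls.end:
                continue
            size = rs.end - ls.start
            if size > params.max_product_size:
                continue
            out.append(
                AmpliconMatch(
                    pair_id=pseudo.id,
                    chrom=ls.chrom,
                    start=ls.start,
                    end=rs.end,
                    product_size=size,
                    fwd_site=ls,
                    rev_site=rs,
                    score=score_match(ls.mismatches, rs.mismatches, total),
                    exact=ls.exact and rs.exact,
                )
            )
    out.sort(key=lambda a: (a.chrom, a.start, a.end))
    return out
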