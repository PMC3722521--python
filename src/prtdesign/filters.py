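"""PRT assay selection and filtering.

A primer pair becomes a candidate paralogue-ratio-test assay when its
exact (zero-mismatch) amplicons number exactly two in the whole genome:
the one inside the queried target region is the CNV target amplicon, the
other is the fixed-copy reference. Filters then enforce the properties a
usable PRT needs — a resolvable size difference, a reference outside the
putative CNV (different chromosome, or >= 500 kb away by default), an
acceptable reference product size, and a low mispriming census (amplicons
with match score above 900, i.e. only a few primer/template mismatches).

Multi-target mode handles CNVs whose target sequence occurs 2–4 times per
haploid reference genome: acceptance then requires one exact amplicon per
specified target plus one size-distinct reference outside all of them.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .ispcr import AmpliconMatch, MISPRIME_SCORE_THRESHOLD
from .primers import PrimerPair
from .reference import Region, VariantTrack


@dataclass(frozen=True)
class FilterParams:
    """Assay acceptance thresholds.

    ``max_misprime`` follows the laboratory-validated rule of thumb that
    assays with fewer than three >900-score mispriming products convert
    well, hence default 2.
    """

    min_size_diff: int = 2
    max_size_diff: int | None = None
    min_ref_size: int | None = None
    max_ref_size: int | None = None
    min_distance: int = 500_000
    max_misprime: int = 2

    def __post_init__(self) -> None:
        if self.max_size_diff is not None and self.min_size_diff > self.max_size_diff:
            raise ValueError("size difference bounds out of order")
        if (
            self.min_ref_size is not None
            and self.max_ref_size is not None
            and self.min_ref_size > self.max_ref_size
        ):
            raise ValueError("reference size bounds out of order")
        if self.min_size_diff < 0 or self.min_distance < 0 or self.max_misprime < 0:
            raise ValueError("thresholds must be non-negative")


@dataclass(frozen=True)
class Rejection:
    pair_id: str
    stage: str
    reason: str


@dataclass(frozen=True)
class Candidate:
    """A pair that passed the exactly-two (or multi-target) test."""

    pair: PrimerPair
    target: AmpliconMatch
    reference: AmpliconMatch
    amplicons: tuple[AmpliconMatch, ...]
    extra_targets: tuple[AmpliconMatch, ...] = ()


@dataclass(frozen=True)
class PRTAssay:
    """An accepted target/reference amplicon pair with report annotations."""

    id: str
    pair: PrimerPair
    target: AmpliconMatch
    reference: AmpliconMatch
    size_diff: int
    misprime: int
    dgv_target: str = "."
    dgv_reference: str = "."
    fsnp: int = 0
    rsnp: int = 0
    extra_targets: tuple[AmpliconMatch, ...] = ()

    @property
    def fwd_seq(self) -> str:
        return self.pair.fwd_seq

    @property
    def rev_seq(self) -> str:
        return self.pair.rev_seq


def _contains(region: Region, amp: AmpliconMatch) -> bool:
    chrom, start, end = region
    return amp.chrom == chrom and amp.start >= start and amp.end <= end


def select_two_exact(
    pair: PrimerPair,
    amplicons: list[AmpliconMatch],
    target_region: Region,
) -> Candidate | Rejection:
    """Accept a pair iff its exact amplicons number exactly two genome-wide.

    The exact amplicon inside ``target_region`` becomes the target, the
    other the reference. Anything else is a rejection with a
    machine-readable reason.
    """
    exact = [a for a in amplicons if a.exact]
    if len(exact) == 0:
        return Rejection(pair.id, "select", "no exact amplicon")
    if len(exact) == 1:
        return Rejection(pair.id, "select", "unique")
    if len(exact) > 2:
        return Rejection(pair.id, "select", "multicopy")
    inside = [a for a in exact if _contains(target_region, a)]
    if len(inside) == 2:
        return Rejection(pair.id, "select", "no external reference")
    if len(inside) == 0:
        return Rejection(pair.id, "select", "no target amplicon")
    target = inside[0]
    reference = exact[0] if exact[1] is target else exact[1]
    return Candidate(pair, target, reference, tuple(amplicons))


def count_mispriming(
    amplicons: list[AmpliconMatch],
    score_threshold: int = MISPRIME_SCORE_THRESHOLD,
) -> int:
    """Number of non-exact amplicons scoring strictly above the threshold."""
    return sum(1 for a in amplicons if not a.exact and a.score > score_threshold)


def _distance(a: AmpliconMatch, b: AmpliconMatch) -> int | None:
    """Gap in bp between two amplicons, None if on different chromosomes."""
    if a.chrom != b.chrom:
        return None
    if a.end <= b.start:
        return b.start - a.end
    if b.end <= a.start:
        return a.start - b.end
    return 0  # overlapping


def apply_filters(candidate: Candidate, params: FilterParams) -> PRTAssay | Rejection:
    """Screen a candidate against the PRT suitability filters."""
    pid = candidate.pair.id
    target, ref = candidate.target, candidate.reference
    targets = (target,) + candidate.extra_targets
    size_diff = min(abs(t.product_size - ref.product_size) for t in targets)
    if size_diff < params.min_size_diff:
        return Rejection(pid, "filter", "size difference below minimum")
    if params.max_size_diff is not None and size_diff > params.max_size_diff:
        return Rejection(pid, "filter", "size difference above maximum")
    if params.min_ref_size is not None and ref.product_size < params.min_ref_size:
        return Rejection(pid, "filter", "reference product too small")
    if params.max_ref_size is not None and ref.product_size > params.max_ref_size:
        return Rejection(pid, "filter", "reference product too large")
    for t in targets:
        gap = _distance(t, ref)
        if gap is not None and gap < params.min_distance:
            return Rejection(pid, "filter", "reference too close")
    misprime = count_mispriming(list(candidate.amplicons))
    if misprime > params.max_misprime:
        return Rejection(pid, "filter", "too many potential misprimed amplicons")
    return PRTAssay(
        id=pid,
        pair=candidate.pair,
        target=target,
        reference=ref,
        size_diff=size_diff,
        misprime=misprime,
        extra_targets=candidate.extra_targets,
    )


def _snp_count(track: VariantTrack | None, site) -> int:
    if track is None:
        return 0
    return len(track.overlapping(site.chrom, site.start, site.end))


def _dgv_flag(track: VariantTrack | None, amp: AmpliconMatch) -> str:
    if track is None:
        return "."
    hits = track.overlapping(amp.chrom, amp.start, amp.end)
    if not hits:
        return "."
    return ",".join(sorted({name for _s, _e, name in hits}))


def annotate(
    assay: PRTAssay,
    cnv_track: VariantTrack | None = None,
    snp_track: VariantTrack | None = None,
) -> PRTAssay:
    """Attach CNV/indel overlap flags and per-primer SNP counts.

    DGV flags use any-overlap semantics (a reference amplicon overlapping a
    known CNV should be avoided). FSNP/RSNP report, for each primer, the
    maximum number of covered SNP positions across the two loci.
    """
    loci = (assay.target, assay.reference) + assay.extra_targets
    fsnp = max(_snp_count(snp_track, amp.fwd_site) for amp in loci)
    rsnp = max(_snp_count(snp_track, amp.rev_site) for amp in loci)
    return replace(
        assay,
        dgv_target=_dgv_flag(cnv_track, assay.target),
        dgv_reference=_dgv_flag(cnv_track, assay.reference),
        fsnp=fsnp,
        rsnp=rsnp,
    )


def select_multi_target(
    pair: PrimerPair,
    amplicons: list[AmpliconMatch],
    targets: list[Region],
    params: FilterParams | None = None,
) -> Candidate | Rejection:
    """Acceptance rule for targets present 2–4 times in the reference.

    Requires exactly ``len(targets) + 1`` exact amplicons: one inside each
    target interval, one outside all of them, and the outside amplicon's
    size differing from every target amplicon's size.
    """
    if not 2 <= len(targets) <= 4:
        raise ValueError("multi-target mode requires 2 to 4 target intervals")
    pid = pair.id
    exact = [a for a in amplicons if a.exact]
    if len(exact) != len(targets) + 1:
        return Rejection(
            pid, "select", f"expected {len(targets) + 1} exact amplicons, found {len(exact)}"
        )
    per_target: list[AmpliconMatch] = []
    remaining = list(exact)
    for region in targets:
        inside = [a for a in remaining if _contains(region, a)]
        if len(inside) != 1:
            return Rejection(pid, "select", "one-per-target violated")
        per_target.append(inside[0])
        remaining.remove(inside[0])
    if len(remaining) != 1:
        return Rejection(pid, "select", "no external reference")
    reference = remaining[0]
    if any(_contains(r, reference) for r in targets):
        return Rejection(pid, "select", "no external reference")
    if any(reference.product_size == t.product_size for t in per_target):
        return Rejection(pid, "select", "reference size equals target size")
    return Candidate(
        pair,
        per_target[0],
        reference,
        tuple(amplicons),
        extra_targets=tuple(per_target[1:]),
    )


def deduplicate_assays(assays: list[PRTAssay]) -> list[PRTAssay]:
    """Drop re-designed duplicates, keeping the first in genomic order.

    Overlapping design windows re-emit identical oligo pairs; identity is
    by (fwd_seq, rev_seq).
    """
    ordered = sorted(
        assays,
        key=lambda a: (a.target.chrom, a.target.start, a.target.end, a.id),
    )
    seen: set[tuple[str, str]] = set()
    out = []
    for a in ordered:
        key = (a.fwd_seq, a.rev_seq)
        if key not in seen:
            seen.add(key)
            out.append(a)
    return out
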