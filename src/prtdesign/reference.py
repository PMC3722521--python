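"""Reference genome and interval-track handling.

The genome is held in memory as uppercase A/C/G/T/N strings. All internal
coordinates are 0-based half-open; conversion to the 1-based inclusive
convention happens only at the report/CLI boundary.

Masking tracks (SNP positions, Alu/SINE elements, simple tandem repeats)
restrict where primers may be placed: no primer base may cover a masked
position. Variant tracks (CNV/indel catalogues, SNP annotation) are used
downstream to annotate accepted assays, never to mask.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from intervaltree import IntervalTree

from ._seq import encode

log = logging.getLogger(__name__)

MASK_KINDS = ("SNP", "ALU", "STR")
VARIANT_KINDS = ("CNV_INDEL", "SNP_ANNOT")
TRACK_KINDS = MASK_KINDS + VARIANT_KINDS

#: region tuple (chrom, start, end), 0-based half-open
Region = tuple[str, int, int]


@dataclass
class Genome:
    """In-memory reference genome.

    ``sequences`` maps chromosome name to an uppercase A/C/G/T/N string;
    ``lengths`` is kept consistent with it by construction.
    """

    sequences: dict[str, str]
    _encoded: dict[str, np.ndarray] = field(
        default_factory=dict, repr=False, compare=False
    )

    @property
    def lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.sequences.items()}

    def encoded(self, chrom: str) -> np.ndarray:
        """uint8-encoded chromosome, cached (A=0,C=1,G=2,T=3,N=4)."""
        if chrom not in self._encoded:
            self._encoded[chrom] = encode(self.sequences[chrom])
        return self._encoded[chrom]

    def slice(self, chrom: str, start: int, end: int) -> str:
        return self.sequences[chrom][start:end]


@dataclass
class IntervalTrack:
    """A BED-derived set of intervals of one kind.

    Intervals are (chrom, start, end, name) with 0-based half-open
    coordinates; overlapping intervals are kept as-is (union semantics are
    applied at query time) so per-interval identifiers survive for
    annotation.
    """

    kind: str
    intervals: list[tuple[str, int, int, str]]
    _trees: dict[str, IntervalTree] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.kind not in TRACK_KINDS:
            raise ValueError(f"unknown track kind {self.kind!r}")

    def _tree(self, chrom: str) -> IntervalTree:
        if not self._trees:
            for c, s, e, name in self.intervals:
                self._trees.setdefault(c, IntervalTree()).addi(s, e, name)
        return self._trees.get(chrom, IntervalTree())

    def overlapping(self, chrom: str, start: int, end: int) -> list[tuple[int, int, str]]:
        """Intervals overlapping [start, end), sorted by (start, end, name)."""
        hits = self._tree(chrom).overlap(start, end)
        return sorted((iv.begin, iv.end, iv.data) for iv in hits)


# Backwards-friendly aliases matching the two track roles.
MaskTrack = IntervalTrack
VariantTrack = IntervalTrack


def normalize_sequence(seq: str) -> tuple[str, int]:
    """Uppercase ``seq`` and replace non-ACGTN symbols with N.

    Returns the normalized string and the number of replacements.
    """
    up = seq.upper()
    codes = np.frombuffer(up.encode("ascii"), dtype=np.uint8)
    allowed = np.isin(codes, np.frombuffer(b"ACGTN", dtype=np.uint8))
    n_bad = int((~allowed).sum())
    if n_bad:
        fixed = codes.copy()
        fixed[~allowed] = ord("N")
        up = fixed.tobytes().decode("ascii")
    return up, n_bad


def load_genome(fasta_path: str | Path) -> Genome:
    """Load a (multi-)FASTA reference into memory.

    Lowercase is folded to uppercase and any symbol outside {A,C,G,T,N} is
    replaced by N (replacement count is logged).
    """
    path = Path(fasta_path)
    if not path.exists():
        raise FileNotFoundError(f"genome FASTA not found: {path}")
    sequences: dict[str, str] = {}
    replaced = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        seq, n_bad = normalize_sequence(str(rec.seq))
        replaced += n_bad
        sequences[rec.id] = seq
    if not sequences:
        raise ValueError(f"no FASTA records in {path}")
    if replaced:
        log.info("replaced %d non-ACGTN symbols with N", replaced)
    return Genome(sequences)


def load_track(
    bed_path: str | Path, kind: str, genome: Genome | None = None
) -> IntervalTrack:
    """Load a BED3/BED4 file as an :class:`IntervalTrack`.

    Intervals are validated (start < end; SNP intervals must have length 1;
    within chromosome bounds when a genome is supplied) and sorted by
    (chrom, start). Malformed lines raise with the offending line number.
    """
    path = Path(bed_path)
    if not path.exists():
        raise FileNotFoundError(f"track file not found: {path}")
    intervals: list[tuple[str, int, int, str]] = []
    errors: list[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split()
            if len(fields) < 3:
                errors.append(f"line {lineno}: fewer than 3 columns")
                continue
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError:
                errors.append(f"line {lineno}: non-integer coordinates")
                continue
            name = fields[3] if len(fields) > 3 else "."
            if start < 0 or start >= end:
                errors.append(f"line {lineno}: start must satisfy 0 <= start < end")
                continue
            if kind == "SNP" and end - start != 1:
                errors.append(f"line {lineno}: SNP intervals must have length 1")
                continue
            if genome is not None:
                if chrom not in genome.sequences:
                    errors.append(f"line {lineno}: unknown chromosome {chrom!r}")
                    continue
                if end > genome.lengths[chrom]:
                    errors.append(f"line {lineno}: interval beyond end of {chrom}")
                    continue
            intervals.append((chrom, start, end, name))
    if errors:
        raise ValueError(f"invalid intervals in {path}: " + "; ".join(errors))
    intervals.sort(key=lambda iv: (iv[0], iv[1], iv[2], iv[3]))
    return IntervalTrack(kind=kind, intervals=intervals)


def save_track(track: IntervalTrack, path: str | Path) -> None:
    """Write a track back out as BED4 (inverse of :func:`load_track`)."""
    with open(path, "w") as fh:
        for chrom, start, end, name in track.intervals:
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")


def masked_positions(
    genome: Genome,
    tracks: list[IntervalTrack],
    region: Region,
    mask_n: bool = True,
) -> set[int]:
    """Positions within ``region`` where no primer base may sit.

    Returns region-local offsets: the union of all track intervals clipped
    to the region, plus (by default) every N base — undefined sequence
    cannot be primed.
    """
    chrom, start, end = region
    if chrom not in genome.sequences:
        raise KeyError(f"unknown chromosome {chrom!r}")
    if not (0 <= start < end <= genome.lengths[chrom]):
        raise ValueError(f"region {region} out of bounds")
    masked: set[int] = set()
    for track in tracks:
        for s, e, _name in track.overlapping(chrom, start, end):
            masked.update(range(max(s, start) - start, min(e, end) - start))
    if mask_n:
        codes = genome.encoded(chrom)[start:end]
        masked.update(int(i) for i in np.flatnonzero(codes == 4))
    return masked


def parse_region(text: str, genome: Genome | None = None) -> Region:
    """Parse a 1-based inclusive region string like ``chr1:1,000-2,000``.

    Returns the 0-based half-open internal representation.
    """
    try:
        chrom, span = text.rsplit(":", 1)
        lo, hi = span.replace(",", "").split("-")
        start1, end1 = int(lo), int(hi)
    except ValueError as exc:
        raise ValueError(f"cannot parse region {text!r}") from exc
    if start1 < 1 or end1 < start1:
        raise ValueError(f"bad coordinates in region {text!r}")
    region = (chrom, start1 - 1, end1)
    if genome is not None:
        if chrom not in genome.sequences:
            raise ValueError(f"unknown chromosome {chrom!r}")
        if end1 > genome.lengths[chrom]:
            raise ValueError(f"region {text!r} beyond end of {chrom}")
    return region
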