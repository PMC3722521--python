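"""Synthetic genomes with planted structure, for exercising every pipeline
stage without external data.

The generator emulates the features the design pipeline reacts to:

* segment families — a core sequence copied to 1..k loci with identical
  primer-bearing flanks, diverged interiors, and per-copy interior length
  deltas (so a 2-copy family is a plantable paralogue pair whose target and
  reference amplicons differ by exactly the requested number of bp);
* SNP positions, STR runs and dispersed repeat families with matching mask
  tracks;
* extra tandem copies of a region on a decoy chromosome (copy-number
  ground truth, e.g. a trisomy analogue).

Background sequence is i.i.d. with configurable GC content; everything is
deterministic under the spec seed. A truth table records the planted loci
so downstream recovery can be asserted.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .reference import Genome, IntervalTrack

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

#: flank kept identical around planted primer sites (>= max primer length + margin)
DEFAULT_FLANK = 60
DEFAULT_INTERIOR = 140
#: diverged-copy interiors: deep divergence, so the only sequence shared
#: between copies is the engineered flank (a lightly diverged interior
#: would let primer pairs co-prime interiors and falsify the truth table's
#: copy counts)
DEFAULT_INTERIOR_SUBSTITUTION_RATE = 0.30
DEFAULT_GC = 0.41

#: designability requirement for planted flanks: number of anchor
#: positions offering an 18-27-mer with Tm inside the default design band
MIN_DESIGNABLE_ANCHORS = 8


@dataclass(frozen=True)
class SegmentCopy:
    """One planted copy of a segment family."""

    chrom: str
    pos: int
    interior_delta: int = 0
    flank_substitution_rate: float = 0.0


@dataclass(frozen=True)
class SegmentFamily:
    """A core segment (flank + interior + flank) planted at several loci.

    Flanks are copied verbatim (unless ``flank_substitution_rate`` breaks
    them on a copy), interiors diverge at ``interior_substitution_rate``
    and change length by each copy's ``interior_delta``. Flanks model the
    conserved primer sites of a designable paralogue locus, so they are
    drawn at balanced GC (``flank_gc``) rather than the genomic background
    composition — a locus whose flanks cannot carry primers would never
    yield an assay and is not what this plant emulates.
    """

    name: str
    copies: tuple[SegmentCopy, ...]
    flank: int = DEFAULT_FLANK
    interior: int = DEFAULT_INTERIOR
    interior_substitution_rate: float = DEFAULT_INTERIOR_SUBSTITUTION_RATE
    flank_gc: float = 0.55


@dataclass(frozen=True)
class SnpPlant:
    chrom: str
    pos: int
    name: str = "snp"


@dataclass(frozen=True)
class RepeatFamilyPlant:
    """A dispersed repeat family (Alu/SINE-like) with its mask intervals."""

    name: str
    chrom: str
    unit_length: int = 300
    copies: int = 50
    divergence: float = 0.1


@dataclass(frozen=True)
class StrPlant:
    """A simple tandem repeat run."""

    chrom: str
    pos: int
    unit: str = "AC"
    n_repeats: int = 30


@dataclass(frozen=True)
class SyntheticSpec:
    seed: int
    chrom_lengths: dict[str, int]
    gc_content: float = DEFAULT_GC
    families: tuple[SegmentFamily, ...] = ()
    snps: tuple[SnpPlant, ...] = ()
    repeats: tuple[RepeatFamilyPlant, ...] = ()
    strs: tuple[StrPlant, ...] = ()


@dataclass(frozen=True)
class TruthRow:
    family: str
    copy_index: int
    chrom: str
    start: int
    end: int
    length: int
    interior_delta: int
    role: str


@dataclass
class SyntheticResult:
    genome: Genome
    tracks: dict[str, IntervalTrack]
    truth: list[TruthRow]


def _random_seq(rng: np.random.Generator, length: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(BASES, size=length, p=p)


def _mutate(
    rng: np.random.Generator,
    seq: np.ndarray,
    rate: float,
    force: tuple[int, ...] = (),
) -> np.ndarray:
    """Substitute bases at the given per-base rate (always to a different
    base); positions in ``force`` are always substituted."""
    out = seq.copy()
    hits = set(np.flatnonzero(rng.random(seq.size) < rate)) if rate > 0 else set()
    hits.update(p % seq.size for p in force)
    for i in sorted(hits):
        choices = BASES[BASES != out[i]]
        out[i] = rng.choice(choices)
    return out


def _designable_anchors(flank: np.ndarray) -> int:
    """Anchor positions in a flank offering an oligo with Tm in the default
    design band (57-63 degC, lengths 18-27)."""
    from .primers import melting_temperature

    seq = flank.tobytes().decode("ascii")
    count = 0
    for start in range(len(seq) - 17):
        for length in range(18, 28):
            if start + length > len(seq):
                break
            if 57.0 <= melting_temperature(seq[start : start + length]) <= 63.0:
                count += 1
                break
    return count


def _primer_friendly_flank(
    rng: np.random.Generator, length: int, gc: float
) -> np.ndarray:
    """Draw a flank that genuinely supports primer design.

    Planted flanks model the conserved primer sites of a designable PRT
    locus; a flank whose oligos all melt outside the design band would
    contradict that role, so draws are rejected until enough anchors carry
    an in-band oligo (best draw kept as fallback).
    """
    best, best_count = None, -1
    for _ in range(200):
        flank = _random_seq(rng, length, gc)
        count = _designable_anchors(flank)
        if count >= MIN_DESIGNABLE_ANCHORS:
            return flank
        if count > best_count:
            best, best_count = flank, count
    return best


def _family_segments(
    rng: np.random.Generator, fam: SegmentFamily, gc: float
) -> list[np.ndarray]:
    left = _primer_friendly_flank(rng, fam.flank, fam.flank_gc)
    right = _primer_friendly_flank(rng, fam.flank, fam.flank_gc)
    interior = _random_seq(rng, fam.interior, gc)
    segments = []
    for i, copy in enumerate(fam.copies):
        # diverged copies always differ at the interior bases adjacent to
        # the flanks, so the identical region is exactly the planted flank
        core = interior.copy() if i == 0 else _mutate(
            rng, interior, fam.interior_substitution_rate, force=(0, 1, -2, -1)
        )
        delta = copy.interior_delta
        if delta > 0:
            mid = core.size // 2
            core = np.concatenate([core[:mid], _random_seq(rng, delta, gc), core[mid:]])
        elif delta < 0:
            if -delta >= core.size:
                raise ValueError(f"interior_delta {delta} deletes entire interior")
            mid = (core.size + delta) // 2
            core = np.concatenate([core[:mid], core[mid - delta :]])
        lf = left if copy.flank_substitution_rate <= 0 else _mutate(
            rng, left, copy.flank_substitution_rate
        )
        rf = right if copy.flank_substitution_rate <= 0 else _mutate(
            rng, right, copy.flank_substitution_rate
        )
        segments.append(np.concatenate([lf, core, rf]))
    return segments


def generate(spec: SyntheticSpec) -> SyntheticResult:
    """Build the genome, mask tracks and truth table for a spec.

    Deterministic under ``spec.seed``; overlapping plants are an error.
    """
    rng = np.random.default_rng(spec.seed)
    chroms: dict[str, np.ndarray] = {}
    for name in spec.chrom_lengths:
        chroms[name] = _random_seq(rng, spec.chrom_lengths[name], spec.gc_content)

    planted: dict[str, list[tuple[int, int, str]]] = {c: [] for c in chroms}

    def claim(chrom: str, start: int, end: int, label: str) -> None:
        if chrom not in chroms:
            raise ValueError(f"plant {label}: unknown chromosome {chrom!r}")
        if start < 0 or end > chroms[chrom].size:
            raise ValueError(f"plant {label} out of bounds on {chrom}")
        for s, e, other in planted[chrom]:
            if start < e and end > s:
                raise ValueError(f"plant {label} overlaps plant {other} on {chrom}")
        planted[chrom].append((start, end, label))

    truth: list[TruthRow] = []
    snp_iv: list[tuple[str, int, int, str]] = []
    alu_iv: list[tuple[str, int, int, str]] = []
    str_iv: list[tuple[str, int, int, str]] = []

    # copy-index-specific dinucleotides written just outside each planted
    # copy, so the region identical between copies ends exactly at the
    # plant boundary (background bases can otherwise agree by chance and
    # extend a primer footprint across copies)
    boundary_codes = [
        np.frombuffer(f"{a}{b}".encode(), dtype=np.uint8)
        for a in "ACGT"
        for b in "ACGT"
    ]

    for fam in spec.families:
        segments = _family_segments(rng, fam, spec.gc_content)
        for i, (copy, seg) in enumerate(zip(fam.copies, segments)):
            end = copy.pos + seg.size
            claim(copy.chrom, copy.pos, end, f"{fam.name}[{i}]")
            chroms[copy.chrom][copy.pos : end] = seg
            code = boundary_codes[i % len(boundary_codes)]
            if copy.pos >= 2:
                chroms[copy.chrom][copy.pos - 2 : copy.pos] = code
            if end + 2 <= chroms[copy.chrom].size:
                chroms[copy.chrom][end : end + 2] = code
            role = "target" if i == 0 else ("reference" if i == 1 else "paralog")
            truth.append(
                TruthRow(
                    family=fam.name,
                    copy_index=i,
                    chrom=copy.chrom,
                    start=copy.pos,
                    end=end,
                    length=seg.size,
                    interior_delta=copy.interior_delta,
                    role=role,
                )
            )

    for rep in spec.repeats:
        unit = _random_seq(rng, rep.unit_length, spec.gc_content)
        length = chroms[rep.chrom].size
        placed = 0
        attempts = 0
        while placed < rep.copies:
            attempts += 1
            if attempts > rep.copies * 200:
                raise ValueError(f"cannot place repeat family {rep.name}")
            pos = int(rng.integers(0, length - rep.unit_length))
            try:
                claim(rep.chrom, pos, pos + rep.unit_length, f"{rep.name}#{placed}")
            except ValueError:
                continue
            copy = _mutate(rng, unit, rep.divergence)
            chroms[rep.chrom][pos : pos + rep.unit_length] = copy
            alu_iv.append((rep.chrom, pos, pos + rep.unit_length, f"{rep.name}#{placed}"))
            placed += 1

    for st in spec.strs:
        run = (st.unit * st.n_repeats).encode("ascii")
        arr = np.frombuffer(run, dtype=np.uint8)
        claim(st.chrom, st.pos, st.pos + arr.size, f"STR@{st.chrom}:{st.pos}")
        chroms[st.chrom][st.pos : st.pos + arr.size] = arr
        str_iv.append((st.chrom, st.pos, st.pos + arr.size, st.unit))

    for snp in spec.snps:
        if snp.pos < 0 or snp.pos >= chroms[snp.chrom].size:
            raise ValueError(f"SNP {snp.name} out of bounds")
        snp_iv.append((snp.chrom, snp.pos, snp.pos + 1, snp.name))

    genome = Genome(
        {c: chroms[c].tobytes().decode("ascii") for c in spec.chrom_lengths}
    )
    tracks = {
        "SNP": IntervalTrack("SNP", sorted(snp_iv)),
        "ALU": IntervalTrack("ALU", sorted(alu_iv)),
        "STR": IntervalTrack("STR", sorted(str_iv)),
    }
    return SyntheticResult(genome=genome, tracks=tracks, truth=truth)


def trisomy_mix(
    genome: Genome,
    region: tuple[str, int, int],
    extra_copies: int,
    baseline_copies: int = 2,
    decoy_chrom: str = "chrDecoy",
    spacer: int = 500,
) -> tuple[Genome, int]:
    """Append extra tandem copies of ``region`` on a decoy chromosome.

    Returns the augmented genome and the resulting truth copy number
    (``baseline_copies + extra_copies``). With ``extra_copies == 0`` the
    genome is returned unchanged.
    """
    chrom, start, end = region
    if chrom not in genome.sequences or not 0 <= start < end <= genome.lengths[chrom]:
        raise ValueError(f"region {region} out of bounds")
    if extra_copies == 0:
        return genome, baseline_copies
    segment = genome.sequences[chrom][start:end]
    pad = "N" * spacer
    addition = (pad + segment) * extra_copies + pad
    sequences = dict(genome.sequences)
    sequences[decoy_chrom] = sequences.get(decoy_chrom, "") + addition
    return Genome(sequences), baseline_copies + extra_copies


def write_fixture(result: SyntheticResult, outdir: str | Path) -> dict[str, Path]:
    """Write FASTA + BED tracks + truth TSV; returns the emitted paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    fasta = outdir / "genome.fa"
    with open(fasta, "w") as fh:
        for name, seq in result.genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    paths["fasta"] = fasta
    for kind, track in result.tracks.items():
        p = outdir / f"{kind.lower()}.bed"
        with open(p, "w") as fh:
            for chrom, s, e, name in track.intervals:
                fh.write(f"{chrom}\t{s}\t{e}\t{name}\n")
        paths[kind] = p
    truth_path = outdir / "truth.tsv"
    with open(truth_path, "w") as fh:
        fh.write("family\tcopy_index\tchrom\tstart\tend\tlength\tinterior_delta\trole\n")
        for row in result.truth:
            fh.write(
                f"{row.family}\t{row.copy_index}\t{row.chrom}\t{row.start}\t"
                f"{row.end}\t{row.length}\t{row.interior_delta}\t{row.role}\n"
            )
    paths["truth"] = truth_path
    return paths
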