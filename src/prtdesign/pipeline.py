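"""Four-stage assay-design pipeline.

1. Design a large number of primer pairs across the target interval
   (overlapping windows, relaxation until the per-window quota is met).
2. Locate every plausible priming site of each pair genome-wide and
   enumerate the amplicons they could produce.
3. Keep pairs whose exact-match amplicons number exactly two (or, in
   multi-target mode, one per specified target plus one reference).
4. Filter for PRT suitability, annotate, and write report/track/stats.

Work is partitioned by window and by pair; results are merged in input
order before any global step, so output is identical for any worker
count. A manifest records the config digest and package version so a run
can be reproduced byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .filters import (
    FilterParams,
    PRTAssay,
    Rejection,
    annotate,
    apply_filters,
    deduplicate_assays,
    select_multi_target,
    select_two_exact,
)
from .ispcr import (
    DEFAULT_MAX_MISMATCH,
    IndexParams,
    build_index,
    enumerate_amplicons,
    find_priming_sites,
    single_primer_amplicons,
)
from .primers import DesignParams, PrimerPair, design_window, quota_for
from .reference import (
    Genome,
    IntervalTrack,
    Region,
    load_genome,
    load_track,
    masked_positions,
    parse_region,
)
from .stats import cluster_targets, summarize, write_stats
from .store import (
    ResultStore,
    sort_assays,
    write_audit,
    write_report,
    write_track,
)
from .windows import DEFAULT_OVERLAP, DEFAULT_WINDOW, plan_windows

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a pipeline run depends on.

    ``targets`` accepts 1-based inclusive region strings
    (``"chr1:1,000-2,000"``) or pre-parsed 0-based half-open tuples. With
    ``multi_target`` set, the 2–4 targets are treated as copies of one CNV
    and the multi-target acceptance rule applies.
    """

    genome_path: str | None = None
    targets: list = field(default_factory=list)
    snp_mask_path: str | None = None
    alu_mask_path: str | None = None
    str_mask_path: str | None = None
    cnv_track_path: str | None = None
    snp_annot_path: str | None = None
    mask_snp: bool = True
    mask_alu: bool = True
    mask_str: bool = True
    design: DesignParams = field(default_factory=DesignParams)
    index: IndexParams = field(default_factory=IndexParams)
    filters: FilterParams = field(default_factory=FilterParams)
    window_length: int = DEFAULT_WINDOW
    overlap: int = DEFAULT_OVERLAP
    max_mismatch: int = DEFAULT_MAX_MISMATCH
    multi_target: bool = False
    single_primer_check: bool = False
    out_dir: str = "prtdesign_out"
    threads: int = 1
    batch_size: int = 50_000_000
    # pre-loaded objects take precedence over paths (library use)
    genome: Genome | None = None
    mask_tracks: list[IntervalTrack] | None = None
    cnv_track: IntervalTrack | None = None
    snp_annot_track: IntervalTrack | None = None

    def digest(self) -> str:
        """Stable hash of the run parameters (paths and scalars)."""
        payload = {}
        for f in dataclasses.fields(self):
            if f.name in ("genome", "mask_tracks", "cnv_track", "snp_annot_track"):
                continue
            value = getattr(self, f.name)
            if dataclasses.is_dataclass(value):
                value = dataclasses.asdict(value)
            payload[f.name] = value
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


@dataclass
class RunResult:
    assays: list[PRTAssay]
    rejections: list[Rejection]
    counts: dict[str, int]
    summary: dict[str, float]
    out_dir: Path
    report_path: Path
    track_path: Path
    stats_path: Path
    audit_path: Path
    manifest_path: Path


def batch_regions(
    chrom_lengths: dict[str, int], batch_size: int = 50_000_000
) -> list[Region]:
    """Consecutive non-overlapping intervals covering each chromosome."""
    if batch_size < 1:
        raise ValueError("batch_size must be >= 1")
    out: list[Region] = []
    for chrom in chrom_lengths:
        length = chrom_lengths[chrom]
        for start in range(0, length, batch_size):
            out.append((chrom, start, min(start + batch_size, length)))
    return out


def _load_tracks(config: RunConfig, genome: Genome) -> list[IntervalTrack]:
    if config.mask_tracks is not None:
        return config.mask_tracks
    tracks = []
    for path, kind, enabled in (
        (config.snp_mask_path, "SNP", config.mask_snp),
        (config.alu_mask_path, "ALU", config.mask_alu),
        (config.str_mask_path, "STR", config.mask_str),
    ):
        if path and enabled:
            tracks.append(load_track(path, kind, genome))
    return tracks


def _design_pairs(
    genome: Genome,
    mask_tracks: list[IntervalTrack],
    regions: list[Region],
    config: RunConfig,
) -> list[PrimerPair]:
    jobs = []
    for ti, (chrom, rstart, rend) in enumerate(regions):
        plan = plan_windows(rend - rstart, config.window_length, config.overlap)
        for wi, (ws, we) in enumerate(plan.windows):
            gstart, gend = rstart + ws, rstart + we
            jobs.append((ti, wi, chrom, gstart, gend))

    def design(job):
        ti, wi, chrom, gstart, gend = job
        masked = masked_positions(genome, mask_tracks, (chrom, gstart, gend))
        quota = quota_for((gstart, gend), config.design.ppn)
        return design_window(
            genome.slice(chrom, gstart, gend),
            masked,
            config.design,
            quota,
            offset=gstart,
            window=(gstart, gend),
            id_prefix=f"T{ti}W{wi}_",
        )

    if config.threads > 1:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            per_window = list(pool.map(design, jobs))
    else:
        per_window = [design(j) for j in jobs]

    pairs: list[PrimerPair] = []
    seen: set[tuple[int, int, int, int]] = set()
    for job, plist in zip(jobs, per_window):
        chrom = job[2]
        for p in plist:
            key = (p.fwd_start, len(p.fwd_seq), p.rev_end, len(p.rev_seq))
            if key in seen:
                continue
            seen.add(key)
            pairs.append(p)
    return pairs


def run(config: RunConfig) -> RunResult:
    """Execute the pipeline and write all artifacts under ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    genome = config.genome if config.genome is not None else load_genome(
        config.genome_path
    )
    mask_tracks = _load_tracks(config, genome)
    cnv_track = config.cnv_track
    if cnv_track is None and config.cnv_track_path:
        cnv_track = load_track(config.cnv_track_path, "CNV_INDEL", genome)
    snp_annot = config.snp_annot_track
    if snp_annot is None and config.snp_annot_path:
        snp_annot = load_track(config.snp_annot_path, "SNP_ANNOT", genome)

    regions: list[Region] = [
        parse_region(t, genome) if isinstance(t, str) else tuple(t)
        for t in config.targets
    ]
    if not regions:
        raise ValueError("no target regions given")
    if config.multi_target and not 2 <= len(regions) <= 4:
        raise ValueError("multi-target mode requires 2 to 4 target regions")

    design_regions = regions[:1] if config.multi_target else regions
    pairs = _design_pairs(genome, mask_tracks, design_regions, config)
    log.info("designed %d primer pairs", len(pairs))

    index = build_index(genome, config.index)

    def align(pair: PrimerPair):
        fwd_sites = find_priming_sites(pair.fwd_seq, index, genome, config.max_mismatch)
        rev_sites = find_priming_sites(pair.rev_seq, index, genome, config.max_mismatch)
        return enumerate_amplicons(pair, fwd_sites, rev_sites, config.index)

    if config.threads > 1:
        with ThreadPoolExecutor(max_workers=config.threads) as pool:
            per_pair = list(pool.map(align, pairs))
    else:
        per_pair = [align(p) for p in pairs]

    store_path = out / "matches.sqlite"
    if store_path.exists():
        store_path.unlink()
    store = ResultStore(store_path)
    n_matches = 0
    for amps in per_pair:
        n_matches += store.ingest(amps)

    assays: list[PRTAssay] = []
    rejections: list[Rejection] = []
    target_region = regions[0]
    for pair in pairs:
        amps = store.matches_for(pair.id)
        if config.multi_target:
            picked = select_multi_target(pair, amps, regions, config.filters)
        else:
            picked = select_two_exact(pair, amps, target_region)
        if isinstance(picked, Rejection):
            rejections.append(picked)
            continue
        screened = apply_filters(picked, config.filters)
        if isinstance(screened, Rejection):
            rejections.append(screened)
            continue
        assay = annotate(screened, cnv_track, snp_annot)
        if config.single_primer_check:
            solo = single_primer_amplicons(
                pair.fwd_seq, index, genome, config.index, config.max_mismatch
            ) + single_primer_amplicons(
                pair.rev_seq, index, genome, config.index, config.max_mismatch
            )
            if solo:
                rejections.append(
                    Rejection(pair.id, "filter", "single-primer amplicon")
                )
                continue
        assays.append(assay)

    assays = deduplicate_assays(assays)
    assays = sort_assays(assays)

    report_path = out / "report.tsv"
    track_path = out / "assays.bed"
    stats_path = out / "stats.tsv"
    audit_path = out / "audit.tsv"
    manifest_path = out / "manifest.json"
    write_report(assays, report_path)
    write_track(assays, track_path)
    write_audit(rejections, audit_path)
    clusters = cluster_targets(assays)
    summary = summarize(clusters, genome.lengths)
    write_stats(summary, stats_path)

    counts = {
        "pairs_designed": len(pairs),
        "matches": n_matches,
        "assays": len(assays),
        "rejections": len(rejections),
    }
    manifest = {
        "tool": "prtdesign",
        "version": __version__,
        "config_digest": config.digest(),
        "counts": counts,
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    store.close()
    return RunResult(
        assays=assays,
        rejections=rejections,
        counts=counts,
        summary=summary,
        out_dir=out,
        report_path=report_path,
        track_path=track_path,
        stats_path=stats_path,
        audit_path=audit_path,
        manifest_path=manifest_path,
    )
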