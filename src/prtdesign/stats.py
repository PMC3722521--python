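"""Descriptive statistics over accepted assays.

Accepted assays are not uniformly spread: their target amplicons pile up
into clusters of mutually overlapping intervals. These operations compute
the cluster set (single-linkage merge of overlapping-or-touching target
intervals), the gap distribution between consecutive clusters, the chance
that a fixed-size genomic window contains at least one cluster, and the
fraction of annotated features (genes, CNVs) with an assay within a given
distance.
"""

from __future__ import annotations

from dataclasses import dataclass

from .filters import PRTAssay
from .reference import IntervalTrack


@dataclass(frozen=True)
class ClusterSet:
    """Merged target-amplicon clusters and inter-cluster gaps per chromosome."""

    clusters: list[tuple[str, int, int, int]]  # (chrom, start, end, n_assays)
    gaps: dict[str, list[int]]


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int, int]]:
    """Single-linkage merge of overlapping or touching intervals."""
    out: list[tuple[int, int, int]] = []
    for s, e in sorted(intervals):
        if out and s <= out[-1][1]:
            ps, pe, n = out[-1]
            out[-1] = (ps, max(pe, e), n + 1)
        else:
            out.append((s, e, 1))
    return out


def cluster_targets(assays: list[PRTAssay]) -> ClusterSet:
    """Cluster target amplicons; touching intervals (end == start) merge."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for a in assays:
        by_chrom.setdefault(a.target.chrom, []).append((a.target.start, a.target.end))
    clusters: list[tuple[str, int, int, int]] = []
    gaps: dict[str, list[int]] = {}
    for chrom in sorted(by_chrom):
        merged = _merge(by_chrom[chrom])
        clusters.extend((chrom, s, e, n) for s, e, n in merged)
        gaps[chrom] = [
            merged[i + 1][0] - merged[i][1] for i in range(len(merged) - 1)
        ]
    return ClusterSet(clusters, gaps)


def window_coverage(
    cluster_set: ClusterSet, chrom_lengths: dict[str, int], window: int
) -> float:
    """Fraction of tiling windows containing (part of) at least one cluster.

    Windows are non-overlapping tiles anchored at 0; a final partial tile
    counts as a window.
    """
    if window < 1:
        raise ValueError("window must be >= 1")
    total = 0
    hit = 0
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e, _n in cluster_set.clusters:
        by_chrom.setdefault(chrom, []).append((s, e))
    for chrom, length in chrom_lengths.items():
        n_win = (length + window - 1) // window
        total += n_win
        covered = [False] * n_win
        for s, e in by_chrom.get(chrom, []):
            for w in range(s // window, min((e - 1) // window, n_win - 1) + 1):
                covered[w] = True
        hit += sum(covered)
    return hit / total if total else 0.0


def feature_tagging(
    assays: list[PRTAssay],
    features: IntervalTrack,
    proximities: list[int] = (0, 10_000, 50_000),
) -> dict[int, float]:
    """Per-distance fraction of features with >= 1 assay within that distance.

    Distance 0 means the assay's target amplicon overlaps the feature.
    """
    targets: dict[str, list[tuple[int, int]]] = {}
    for a in assays:
        targets.setdefault(a.target.chrom, []).append((a.target.start, a.target.end))
    out: dict[int, float] = {}
    n_features = len(features.intervals)
    for d in proximities:
        if n_features == 0:
            out[d] = 0.0
            continue
        tagged = 0
        for chrom, fs, fe, _name in features.intervals:
            hit = False
            for ts, te in targets.get(chrom, []):
                if ts < fe + d and te > fs - d:
                    hit = True
                    break
            if hit:
                tagged += 1
        out[d] = tagged / n_features
    return out


def summarize(
    cluster_set: ClusterSet,
    chrom_lengths: dict[str, int],
    coverage_window: int = 50_000,
) -> dict[str, float]:
    """Headline numbers for the stats report."""
    all_gaps = [g for gs in cluster_set.gaps.values() for g in gs]
    n_assays = sum(n for _c, _s, _e, n in cluster_set.clusters)
    total_len = sum(chrom_lengths.values())
    summary = {
        "n_assays": float(n_assays),
        "n_clusters": float(len(cluster_set.clusters)),
        "bp_per_cluster": (
            total_len / len(cluster_set.clusters) if cluster_set.clusters else 0.0
        ),
        "mean_gap": sum(all_gaps) / len(all_gaps) if all_gaps else 0.0,
        "median_gap": float(sorted(all_gaps)[len(all_gaps) // 2]) if all_gaps else 0.0,
        "max_gap": float(max(all_gaps)) if all_gaps else 0.0,
        "coverage_fraction": window_coverage(
            cluster_set, chrom_lengths, coverage_window
        ),
    }
    return summary


def write_stats(summary: dict[str, float], path) -> None:
    with open(path, "w") as fh:
        fh.write("statistic\tvalue\n")
        for key in sorted(summary):
            fh.write(f"{key}\t{summary[key]:.6g}\n")
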