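"""Shared test utilities: independent oracles and fixture builders.

The priming-site oracle here deliberately avoids the package's seeded
search: it checks every genomic offset on both strands with numpy sliding
windows, applying the same qualification rule (perfect 3'-terminal
min_perfect window, total mismatches capped).
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

_COMP = str.maketrans("ACGTN", "TGCAN")
_CODE = {b: i for i, b in enumerate("ACGTN")}


def rc(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def enc(seq: str) -> np.ndarray:
    return np.array([_CODE.get(b, 4) for b in seq], dtype=np.uint8)


def naive_priming_sites(genome, primer: str, min_perfect: int, max_mismatch: int):
    """Full-scan priming-site oracle; returns sorted (chrom, strand, start,
    end, mismatches) tuples."""
    out = []
    for strand, query in (("+", primer), ("-", rc(primer))):
        q = enc(query)
        L = q.size
        for chrom, seq in genome.sequences.items():
            codes = enc(seq)
            if codes.size < L:
                continue
            w = sliding_window_view(codes, L)
            mism = (w != q[None, :]).sum(axis=1)
            if strand == "+":
                zone_bad = (w[:, L - min_perfect :] != q[L - min_perfect :]).any(axis=1)
            else:
                zone_bad = (w[:, :min_perfect] != q[:min_perfect]).any(axis=1)
            ok = (~zone_bad) & (mism <= max_mismatch)
            for s in np.flatnonzero(ok):
                out.append((chrom, strand, int(s), int(s) + L, int(mism[s])))
    return sorted(out)


def site_tuples(sites):
    return sorted((s.chrom, s.strand, s.start, s.end, s.mismatches) for s in sites)


def random_dna(rng: np.random.Generator, length: int, gc: float = 0.45) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def mutate(rng: np.random.Generator, seq: str, n_subs: int, lo: int = 0, hi: int | None = None) -> str:
    """Introduce exactly n substitutions at random positions in [lo, hi)."""
    hi = hi if hi is not None else len(seq)
    chars = list(seq)
    positions = rng.choice(np.arange(lo, hi), size=n_subs, replace=False)
    for p in positions:
        options = [b for b in "ACGT" if b != chars[p]]
        chars[p] = options[int(rng.integers(0, 3))]
    return "".join(chars)


def brute_force_cluster(intervals):
    """O(n^2) single-linkage merge of overlapping-or-touching intervals."""
    items = [(s, e) for s, e in intervals]
    merged = True
    clusters = [[iv] for iv in items]
    while merged:
        merged = False
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                si = min(s for s, _ in clusters[i])
                ei = max(e for _, e in clusters[i])
                sj = min(s for s, _ in clusters[j])
                ej = max(e for _, e in clusters[j])
                if si <= ej and sj <= ei:
                    clusters[i].extend(clusters[j])
                    del clusters[j]
                    merged = True
                    break
            if merged:
                break
    out = []
    for c in clusters:
        out.append((min(s for s, _ in c), max(e for _, e in c), len(c)))
    return sorted(out)
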