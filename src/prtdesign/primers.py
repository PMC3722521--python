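"""Candidate primer-pair generation.

For each design window the generator enumerates admissible oligos (length,
melting temperature and GC within the current band, footprint free of
masked/N positions, no strong 3' self-dimer), keeps the best oligo per
anchor position (forward primers are anchored by their start, reverse
primers by their end), and pairs anchors whose product size is admissible.
Because the quota is far below the number of admissible pairs, emission
order matters: (fwd_start, rev_end) space is stratified into square cells
and pairs are emitted round-robin over cells — every cell's best pair (by
summed distance from the optimal parameters) first, then every cell's
second-best, and so on. This keeps the emitted set roughly uniform across
the window instead of piling the whole quota onto the few
thermodynamically optimal positions. If a round cannot satisfy the quota
the parameter bands are relaxed in fixed decrements (±1 °C on Tm, ∓5
points on GC, ±1 nt on length per round) and the scan repeats, emitting
only pairs not already produced.

Melting temperatures come from the unified nearest-neighbor model
(SantaLucia & Hicks 2004 parameters) at 50 mM monovalent salt and 50 nM
oligo, implemented here in vectorized form so tens of thousands of
candidates per window stay cheap.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from ._seq import encode, revcomp

log = logging.getLogger(__name__)

# Hard limits a relaxation round may never cross.
HARD_MIN_PRIMER_LEN = 15
HARD_MAX_PRIMER_LEN = 35

# 3' self-dimer screen: reject if the reverse complement of the 3'-terminal
# k-mer occurs anywhere in the primer (perfect self-annealing seed).
SELF_DIMER_3P_LEN = 8

# stratification cell width (bp) for round-robin pair emission
EMISSION_CELL = 16

# Unified NN parameters, SantaLucia & Hicks (2004): dH kcal/mol, dS cal/(mol K).
_NN = {
    "AA": (-7.6, -21.3), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}
_INIT_H, _INIT_S = 0.2, -5.7
_TERM_AT_H, _TERM_AT_S = 2.2, 6.9
_R = 1.987  # cal/(mol K)

# Duplex thermodynamics are strand-symmetric: fill the 16-entry table from
# the 10 unique stacks via reverse complement.
_DH = np.full(25, np.nan)
_DS = np.full(25, np.nan)
for _pair, (_h, _s) in _NN.items():
    for _p in (_pair, revcomp(_pair)):
        _idx = "ACGT".index(_p[0]) * 5 + "ACGT".index(_p[1])
        _DH[_idx] = _h
        _DS[_idx] = _s

DEFAULT_NA_MILLIMOLAR = 50.0
DEFAULT_OLIGO_NANOMOLAR = 50.0


def _tm_from_sums(dh: np.ndarray, ds: np.ndarray, length) -> np.ndarray:
    """Tm (°C) from summed stack enthalpies/entropies incl. initiation."""
    salt_corr = 0.368 * (np.asarray(length) - 1) * math.log(
        DEFAULT_NA_MILLIMOLAR / 1000.0
    )
    k = DEFAULT_OLIGO_NANOMOLAR * 1e-9
    return (1000.0 * dh) / (ds + salt_corr + _R * math.log(k)) - 273.15


def melting_temperature(oligo: str) -> float:
    """Nearest-neighbor melting temperature of ``oligo`` in °C.

    Fixed conditions: 50 mM Na+, 50 nM oligo; entropic salt correction
    0.368·(N−1)·ln[Na+]. Deterministic and symmetric under reverse
    complement.
    """
    if len(oligo) < 8:
        raise ValueError("oligo must be at least 8 nt")
    codes = encode(oligo)
    if (codes > 3).any():
        raise ValueError("oligo must contain only A/C/G/T")
    pair_idx = codes[:-1].astype(np.int64) * 5 + codes[1:]
    dh = _INIT_H + _DH[pair_idx].sum()
    ds = _INIT_S + _DS[pair_idx].sum()
    for term in (codes[0], codes[-1]):
        if term in (0, 3):  # A or T terminal
            dh += _TERM_AT_H
            ds += _TERM_AT_S
    return float(_tm_from_sums(dh, ds, len(oligo)))


def gc_percent(oligo: str) -> float:
    codes = encode(oligo)
    return 100.0 * float(((codes == 1) | (codes == 2)).sum()) / len(codes)


@dataclass(frozen=True)
class DesignParams:
    """Tunable primer-design parameters.

    ``ppn`` is the design density: primer pairs requested per nucleotide of
    target region (default 2, i.e. 2000 pairs per kb).
    """

    ppn: float = 2.0
    amplicon_size_range: tuple[int, int] = (100, 300)
    primer_len: tuple[int, int, int] = (18, 20, 27)
    tm: tuple[float, float, float] = (57.0, 60.0, 63.0)
    gc: tuple[float, float] = (20.0, 80.0)
    relaxation_rounds: int = 5

    def __post_init__(self) -> None:
        lo, opt, hi = self.primer_len
        if not lo <= opt <= hi:
            raise ValueError("primer_len must satisfy min <= opt <= max")
        tlo, topt, thi = self.tm
        if not tlo <= topt <= thi:
            raise ValueError("tm must satisfy min <= opt <= max")
        if not self.gc[0] <= self.gc[1]:
            raise ValueError("gc bounds out of order")
        if not self.amplicon_size_range[0] < self.amplicon_size_range[1]:
            raise ValueError("amplicon size range must satisfy min < max")
        if self.ppn <= 0:
            raise ValueError("ppn must be positive")
        if self.relaxation_rounds < 0:
            raise ValueError("relaxation_rounds must be >= 0")


@dataclass(frozen=True)
class PrimerPair:
    """A designed forward/reverse oligo pair.

    ``rev_seq`` is given 5'→3' on the opposite strand; ``fwd_start`` and
    ``rev_end`` are genomic (offset-adjusted) coordinates of the designed
    product, so ``designed_product_size == rev_end - fwd_start``.
    """

    id: str
    window: tuple[int, int]
    fwd_seq: str
    rev_seq: str
    fwd_start: int
    rev_end: int
    designed_product_size: int
    tm_f: float
    tm_r: float
    gc_f: float
    gc_r: float
    relaxation_round: int

    @property
    def total_primer_bases(self) -> int:
        return len(self.fwd_seq) + len(self.rev_seq)


def quota_for(window: tuple[int, int], ppn: float) -> int:
    """Number of primer pairs requested for a window at density ``ppn``."""
    length = window[1] - window[0]
    if length < 1:
        raise ValueError("window length must be >= 1")
    return math.ceil(length * ppn)


class _WindowScan:
    """Precomputed per-candidate admissibility arrays for one window."""

    def __init__(self, seq: str, masked: set[int]):
        self.seq = seq
        self.n = len(seq)
        codes = encode(seq)
        mask_arr = np.zeros(self.n, dtype=bool)
        if masked:
            idx = np.fromiter((p for p in masked if 0 <= p < self.n), dtype=np.int64)
            if idx.size:
                mask_arr[idx] = True
        cum_bad = np.zeros(self.n + 1, dtype=np.int64)
        cum_bad[1:] = np.cumsum(((codes > 3) | mask_arr).astype(np.int64))
        self.cum_bad = cum_bad

        pair_idx = codes[:-1].astype(np.int64) * 5 + codes[1:]
        dh = np.nan_to_num(_DH[pair_idx])
        ds = np.nan_to_num(_DS[pair_idx])
        self.cum_dh = np.concatenate(([0.0], np.cumsum(dh)))
        self.cum_ds = np.concatenate(([0.0], np.cumsum(ds)))
        self.is_at = (codes == 0) | (codes == 3)
        self.cum_gc = np.concatenate(
            ([0], np.cumsum(((codes == 1) | (codes == 2)).astype(np.int64)))
        )
        # per length: tm[s], gc[s], valid[s], dimer-ok (fwd / rev orientation)
        self._cache: dict[int, dict[str, np.ndarray]] = {}

    def arrays(self, L: int) -> dict[str, np.ndarray]:
        if L in self._cache:
            return self._cache[L]
        n_start = self.n - L + 1
        if n_start <= 0:
            out = {k: np.zeros(0) for k in ("tm", "gc", "valid", "dimer_f", "dimer_r")}
            self._cache[L] = out
            return out
        s = np.arange(n_start)
        valid = (self.cum_bad[s + L] - self.cum_bad[s]) == 0
        dh = _INIT_H + self.cum_dh[s + L - 1] - self.cum_dh[s]
        ds = _INIT_S + self.cum_ds[s + L - 1] - self.cum_ds[s]
        term = self.is_at[s].astype(np.int64) + self.is_at[s + L - 1]
        dh = dh + _TERM_AT_H * term
        ds = ds + _TERM_AT_S * term
        with np.errstate(invalid="ignore"):
            tm = _tm_from_sums(dh, ds, L)
        gc = 100.0 * (self.cum_gc[s + L] - self.cum_gc[s]) / L
        dimer_f = np.ones(n_start, dtype=bool)
        dimer_r = np.ones(n_start, dtype=bool)
        k = SELF_DIMER_3P_LEN
        for i in np.flatnonzero(valid):
            sub = self.seq[i : i + L]
            if revcomp(sub[-k:]) in sub:
                dimer_f[i] = False
            rprimer = revcomp(sub)
            if revcomp(rprimer[-k:]) in rprimer:
                dimer_r[i] = False
        out = {"tm": tm, "gc": gc, "valid": valid, "dimer_f": dimer_f, "dimer_r": dimer_r}
        self._cache[L] = out
        return out


def _round_bands(params: DesignParams, r: int):
    lmin = max(HARD_MIN_PRIMER_LEN, params.primer_len[0] - r)
    lmax = min(HARD_MAX_PRIMER_LEN, params.primer_len[2] + r)
    tm_lo, tm_hi = params.tm[0] - r, params.tm[2] + r
    gc_lo = max(0.0, params.gc[0] - 5 * r)
    gc_hi = min(100.0, params.gc[1] + 5 * r)
    return lmin, lmax, tm_lo, tm_hi, gc_lo, gc_hi


def _best_per_anchor(
    scan: _WindowScan,
    params: DesignParams,
    r: int,
    orientation: str,
) -> tuple[np.ndarray, np.ndarray]:
    """Best admissible oligo per anchor position for relaxation round ``r``.

    Returns (penalty, chosen_length) arrays indexed by anchor: forward
    primers are anchored at their start, reverse primers at their end
    (one past the footprint). Inadmissible anchors carry +inf.
    """
    lmin, lmax, tm_lo, tm_hi, gc_lo, gc_hi = _round_bands(params, r)
    n = scan.n
    pen = np.full(n + 1, np.inf)
    chosen = np.zeros(n + 1, dtype=np.int64)
    tm_opt, len_opt = params.tm[1], params.primer_len[1]
    for L in range(lmin, min(lmax, n) + 1):
        arr = scan.arrays(L)
        if arr["tm"].size == 0:
            continue
        dimer = arr["dimer_f"] if orientation == "fwd" else arr["dimer_r"]
        ok = (
            arr["valid"]
            & dimer
            & (arr["tm"] >= tm_lo)
            & (arr["tm"] <= tm_hi)
            & (arr["gc"] >= gc_lo)
            & (arr["gc"] <= gc_hi)
        )
        p = np.where(ok, np.abs(arr["tm"] - tm_opt) + 0.5 * abs(L - len_opt), np.inf)
        if orientation == "fwd":
            anchors = np.arange(p.size)
        else:
            anchors = np.arange(p.size) + L  # anchor = footprint end
        better = p < pen[anchors]
        upd = anchors[better]
        pen[upd] = p[better]
        chosen[upd] = L
    return pen, chosen


def design_window(
    genome_slice: str,
    masked: set[int],
    params: DesignParams,
    quota: int,
    offset: int = 0,
    window: tuple[int, int] | None = None,
    id_prefix: str = "P",
) -> list[PrimerPair]:
    """Design up to ``quota`` primer pairs within one window.

    ``masked`` holds slice-local positions no primer base may cover;
    ``offset`` shifts emitted coordinates to genomic space. Output order is
    deterministic: best-first within each relaxation round, ties broken by
    (fwd_start, rev_end).
    """
    if quota < 1:
        raise ValueError("quota must be >= 1")
    amp_min, amp_max = params.amplicon_size_range
    n = len(genome_slice)
    if n < amp_min:
        log.warning("window of %d nt shorter than minimum amplicon %d", n, amp_min)
        return []
    if window is None:
        window = (offset, offset + n)
    scan = _WindowScan(genome_slice, masked)

    emitted: list[PrimerPair] = []
    seen: set[tuple[int, int, int, int]] = set()
    for r in range(params.relaxation_rounds + 1):
        if len(emitted) >= quota:
            break
        pen_f, len_f = _best_per_anchor(scan, params, r, "fwd")
        pen_r, len_r = _best_per_anchor(scan, params, r, "rev")
        f_idx = np.flatnonzero(np.isfinite(pen_f))
        e_idx = np.flatnonzero(np.isfinite(pen_r))
        if f_idx.size == 0 or e_idx.size == 0:
            continue
        # all (fwd_start, rev_end) combos with admissible product size and
        # non-overlapping primer footprints
        prod = e_idx[None, :] - f_idx[:, None]
        sep = (e_idx[None, :] - len_r[e_idx][None, :]) - (
            f_idx[:, None] + len_f[f_idx][:, None]
        )
        okm = (prod >= amp_min) & (prod <= amp_max) & (sep >= 0)
        fi, ei = np.nonzero(okm)
        if fi.size == 0:
            continue
        f_pos = f_idx[fi]
        e_pos = e_idx[ei]
        pair_pen = pen_f[f_pos] + pen_r[e_pos]
        # stratified emission: rank each combo within its (fwd, rev) cell
        # by penalty; sorting by (rank, penalty) emits cell-best pairs
        # round-robin, spreading output uniformly over the window
        by_pen = np.lexsort((e_pos, f_pos, pair_pen))
        cell = (f_pos // EMISSION_CELL) * (1 + n // EMISSION_CELL + 1) + (
            e_pos // EMISSION_CELL
        )
        cell_in_pen_order = cell[by_pen]
        group = np.argsort(cell_in_pen_order, kind="stable")
        grouped = cell_in_pen_order[group]
        boundaries = np.flatnonzero(np.diff(grouped)) + 1
        starts = np.concatenate(([0], boundaries))
        lengths = np.diff(np.concatenate((starts, [grouped.size])))
        rank_in_cell = np.arange(grouped.size) - np.repeat(starts, lengths)
        cell_rank = np.empty(fi.size, dtype=np.int64)
        cell_rank[by_pen[group]] = rank_in_cell
        order = np.lexsort((e_pos, f_pos, pair_pen, cell_rank))
        for oi in order:
            f = int(f_pos[oi])
            e = int(e_pos[oi])
            lf = int(len_f[f])
            lr = int(len_r[e])
            key = (f, lf, e, lr)
            if key in seen:
                continue
            seen.add(key)
            fwd = genome_slice[f : f + lf]
            rev = revcomp(genome_slice[e - lr : e])
            emitted.append(
                PrimerPair(
                    id=f"{id_prefix}{len(emitted):06d}",
                    window=window,
                    fwd_seq=fwd,
                    rev_seq=rev,
                    fwd_start=offset + f,
                    rev_end=offset + e,
                    designed_product_size=e - f,
                    tm_f=melting_temperature(fwd),
                    tm_r=melting_temperature(rev),
                    gc_f=gc_percent(fwd),
                    gc_r=gc_percent(rev),
                    relaxation_round=r,
                )
            )
            if len(emitted) >= quota:
                break
    return emitted
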