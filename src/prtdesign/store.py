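"""Persistence of alignment results and final report/track writing.

The alignment stage can emit orders of magnitude more matches than fit
comfortably in memory, so matches stream into a single-file SQLite store.
Per pair the store keeps every match row (primary-keyed, so re-ingesting
the same stream is a no-op) and serves aggregated ``PairRecord`` views:
the first five exact genomic matches in genome order, the total exact
count, and the count of >900-score mispriming matches. Pairs matching
exactly twice — the PRT candidates — can then be extracted without a full
scan.

Report format: one header plus two tab-separated lines per assay (target
first, then reference) with columns ID, Chr, Start, End, Size, Misprime,
DGV, Forward, Reverse, SizeDiff, FSNP, RSNP; coordinates are 1-based
inclusive. The browser track is standard BED6 (0-based half-open).
"""

from __future__ import annotations

import logging
import sqlite3
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from .filters import PRTAssay
from .ispcr import AmpliconMatch, MISPRIME_SCORE_THRESHOLD, PrimingSite

log = logging.getLogger(__name__)

FIRST_EXACT_KEPT = 5

REPORT_COLUMNS = (
    "ID", "Chr", "Start", "End", "Size", "Misprime", "DGV",
    "Forward", "Reverse", "SizeDiff", "FSNP", "RSNP",
)

_SCHEMA = """
CREATE TABLE IF NOT EXISTS matches (
    pair_id TEXT NOT NULL,
    chrom   TEXT NOT NULL,
    start   INTEGER NOT NULL,
    end     INTEGER NOT NULL,
    product_size INTEGER NOT NULL,
    score   INTEGER NOT NULL,
    exact   INTEGER NOT NULL,
    fwd_strand TEXT, fwd_start INTEGER, fwd_end INTEGER, fwd_mism INTEGER,
    rev_strand TEXT, rev_start INTEGER, rev_end INTEGER, rev_mism INTEGER,
    PRIMARY KEY (pair_id, chrom, start, end)
);
CREATE INDEX IF NOT EXISTS idx_exact ON matches (exact, pair_id);
"""


@dataclass
class PairRecord:
    """Aggregated match statistics for one primer pair."""

    pair_id: str
    first_exact_matches: list[AmpliconMatch]
    n_exact: int
    n_score_gt900: int


def _match_row(a: AmpliconMatch) -> tuple:
    return (
        a.pair_id, a.chrom, a.start, a.end, a.product_size, a.score,
        1 if a.exact else 0,
        a.fwd_site.strand, a.fwd_site.start, a.fwd_site.end, a.fwd_site.mismatches,
        a.rev_site.strand, a.rev_site.start, a.rev_site.end, a.rev_site.mismatches,
    )


def _row_to_match(row: sqlite3.Row) -> AmpliconMatch:
    fwd = PrimingSite(row["chrom"], row["fwd_strand"], row["fwd_start"],
                      row["fwd_end"], row["fwd_mism"])
    rev = PrimingSite(row["chrom"], row["rev_strand"], row["rev_start"],
                      row["rev_end"], row["rev_mism"])
    return AmpliconMatch(
        pair_id=row["pair_id"], chrom=row["chrom"], start=row["start"],
        end=row["end"], product_size=row["product_size"],
        fwd_site=fwd, rev_site=rev, score=row["score"],
        exact=bool(row["exact"]),
    )


def _parse_bed_match(line: str) -> AmpliconMatch | None:
    """Parse a BED6 amplicon dump line back into a (site-less) match."""
    fields = line.split()
    if len(fields) < 6:
        return None
    chrom, start, end, name, score, _strand = fields[:6]
    try:
        s, e, sc = int(start), int(end), int(score)
    except ValueError:
        return None
    if not 0 <= s < e:
        return None
    site = PrimingSite(chrom, "+", s, s, 0 if sc == 1000 else 1)
    rsite = PrimingSite(chrom, "-", e, e, 0)
    return AmpliconMatch(
        pair_id=name, chrom=chrom, start=s, end=e, product_size=e - s,
        fwd_site=site, rev_site=rsite, score=sc, exact=sc == 1000,
    )


class ResultStore:
    """Embedded on-disk store of amplicon matches, keyed by pair.

    Ingestion is streamed (bounded memory independent of stream length)
    and idempotent: the primary key over (pair_id, chrom, start, end)
    makes re-ingesting an identical stream a no-op.
    """

    def __init__(self, path: str | Path = ":memory:"):
        self.path = str(path)
        self.conn = sqlite3.connect(self.path)
        self.conn.row_factory = sqlite3.Row
        self.conn.executescript(_SCHEMA)

    def close(self) -> None:
        self.conn.close()

    def __enter__(self) -> "ResultStore":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    def ingest(self, stream: Iterable[AmpliconMatch | str], batch: int = 1000) -> int:
        """Insert matches (objects or BED6 lines); returns rows ingested.

        Malformed text records are skipped with their line number logged.
        """
        rows = []
        n = 0
        for lineno, item in enumerate(stream, 1):
            if isinstance(item, str):
                if not item.strip() or item.startswith(("#", "track")):
                    continue
                match = _parse_bed_match(item)
                if match is None:
                    log.warning("skipping malformed match record at line %d", lineno)
                    continue
            else:
                match = item
            rows.append(_match_row(match))
            if len(rows) >= batch:
                self.conn.executemany(
                    "INSERT OR IGNORE INTO matches VALUES "
                    "(?,?,?,?,?,?,?,?,?,?,?,?,?,?,?)",
                    rows,
                )
                n += len(rows)
                rows.clear()
        if rows:
            self.conn.executemany(
                "INSERT OR IGNORE INTO matches VALUES (?,?,?,?,?,?,?,?,?,?,?,?,?,?,?)",
                rows,
            )
            n += len(rows)
        self.conn.commit()
        return n

    def record(self, pair_id: str) -> PairRecord:
        cur = self.conn.execute(
            "SELECT * FROM matches WHERE pair_id=? AND exact=1 "
            "ORDER BY chrom, start LIMIT ?",
            (pair_id, FIRST_EXACT_KEPT),
        )
        first = [_row_to_match(r) for r in cur.fetchall()]
        n_exact = self.conn.execute(
            "SELECT COUNT(*) FROM matches WHERE pair_id=? AND exact=1", (pair_id,)
        ).fetchone()[0]
        n_gt900 = self.conn.execute(
            "SELECT COUNT(*) FROM matches WHERE pair_id=? AND exact=0 AND score>?",
            (pair_id, MISPRIME_SCORE_THRESHOLD),
        ).fetchone()[0]
        return PairRecord(pair_id, first, n_exact, n_gt900)

    def matches_for(self, pair_id: str) -> list[AmpliconMatch]:
        cur = self.conn.execute(
            "SELECT * FROM matches WHERE pair_id=? ORDER BY chrom, start, end",
            (pair_id,),
        )
        return [_row_to_match(r) for r in cur.fetchall()]

    def pair_ids(self) -> list[str]:
        cur = self.conn.execute("SELECT DISTINCT pair_id FROM matches ORDER BY pair_id")
        return [r[0] for r in cur.fetchall()]

    def query_two_exact(self) -> Iterator[PairRecord]:
        """Pairs with exactly two exact genomic matches, in genome order
        of their first exact match."""
        cur = self.conn.execute(
            "SELECT pair_id FROM matches WHERE exact=1 "
            "GROUP BY pair_id HAVING COUNT(*)=2"
        )
        records = [self.record(row["pair_id"]) for row in cur.fetchall()]
        records.sort(
            key=lambda r: (
                r.first_exact_matches[0].chrom,
                r.first_exact_matches[0].start,
                r.pair_id,
            )
        )
        yield from records


def write_matches_bed(matches: Iterable[AmpliconMatch], path: str | Path) -> None:
    """Dump amplicon matches as BED6 (name = pair id, score = match score)."""
    with open(path, "w") as fh:
        for a in matches:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.pair_id}\t{a.score}\t+\n")


def _report_lines(assay: PRTAssay) -> list[str]:
    rows = []
    loci = [(assay.target, assay.dgv_target)]
    loci += [(t, assay.dgv_target) for t in assay.extra_targets]
    loci.append((assay.reference, assay.dgv_reference))
    for amp, dgv in loci:
        rows.append(
            "\t".join(
                str(x)
                for x in (
                    assay.id, amp.chrom, amp.start + 1, amp.end,
                    amp.product_size, assay.misprime, dgv,
                    assay.fwd_seq, assay.rev_seq, assay.size_diff,
                    assay.fsnp, assay.rsnp,
                )
            )
        )
    return rows


def sort_assays(assays: list[PRTAssay]) -> list[PRTAssay]:
    return sorted(
        assays, key=lambda a: (a.target.chrom, a.target.start, a.target.end, a.id)
    )


def write_report(assays: list[PRTAssay], path: str | Path) -> None:
    """Write the final PRT report: two lines per assay, target first.

    Coordinates are 1-based inclusive; ordering is deterministic (genomic
    order of the target amplicon).
    """
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for assay in sort_assays(assays):
            for line in _report_lines(assay):
                fh.write(line + "\n")


def write_track(assays: list[PRTAssay], path: str | Path) -> None:
    """Write a BED6 browser track: one feature per amplicon (/T, /R)."""
    with open(path, "w") as fh:
        for assay in sort_assays(assays):
            features = [(assay.target, "/T")]
            features += [(t, "/T") for t in assay.extra_targets]
            features.append((assay.reference, "/R"))
            for amp, suffix in features:
                fh.write(
                    f"{amp.chrom}\t{amp.start}\t{amp.end}\t"
                    f"{assay.id}{suffix}\t0\t+\n"
                )


def write_audit(rejections, path: str | Path) -> None:
    """Machine-readable rejection log: pair_id, stage, reason."""
    with open(path, "w") as fh:
        fh.write("pair_id\tstage\treason\n")
        for r in rejections:
            fh.write(f"{r.pair_id}\t{r.stage}\t{r.reason}\n")
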