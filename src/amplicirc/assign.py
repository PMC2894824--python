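"""Nearest-relative assignment from BLAST tabular output.

A 16S read aligned against a reference panel typically produces several
local alignments (HSPs) per read/reference pair, because the gene's
variable regions break the alignment into conserved-region fragments. The
pair's affinity is therefore measured by the *total* BLAST score — the sum
of the bit scores of all retained HSPs — rather than the best single HSP.
Two safeguards precede the sum: HSPs shorter than a minimum length are
discarded, and pairs whose HSPs are not colinear (subject-coordinate order
disagreeing with query-coordinate order, the signature of a false
alignment between unrelated regions) are excluded entirely. The reference
with the highest total score is the read's nearest relative, and the
alignment-length-weighted mean percent identity over its retained HSPs is
the read's average similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

logger = logging.getLogger(__name__)

#: bp of end-overlap between consecutive HSPs tolerated by the
#: consistency check (BLAST fragments often share a few terminal bases)
OVERLAP_TOLERANCE = 10


@dataclass(frozen=True)
class HSP:
    """One BLAST high-scoring pair (a row of 12-column tabular output).

    Coordinates are 1-based inclusive; ``s_start > s_end`` encodes a
    minus-strand match, per BLAST convention.
    """

    query_id: str
    subject_id: str
    pct_identity: float
    align_len: int
    score: float
    q_start: int
    q_end: int
    s_start: int
    s_end: int

    def __post_init__(self):
        if self.align_len < 1:
            raise ValueError("align_len must be >= 1")
        if not 0.0 <= self.pct_identity <= 100.0:
            raise ValueError("pct_identity must be in [0, 100]")
        if self.q_start > self.q_end:
            raise ValueError("q_start must be <= q_end")

    @property
    def strand(self) -> str:
        return "plus" if self.s_start <= self.s_end else "minus"

    @property
    def s_lo(self) -> int:
        return min(self.s_start, self.s_end)

    @property
    def s_hi(self) -> int:
        return max(self.s_start, self.s_end)


@dataclass
class PairGroup:
    """All retained HSPs for one (read, reference) pair."""

    query_id: str
    subject_id: str
    hsps: list[HSP]
    consistent: bool

    @property
    def total_score(self) -> float:
        return total_score(self)

    @property
    def avg_similarity(self) -> float:
        return average_similarity(self)


@dataclass(frozen=True)
class Assignment:
    query_id: str
    nearest_ref_id: str
    avg_similarity: float
    total_score: float


@dataclass(frozen=True)
class AssignConfig:
    min_hsp_len: int = 50
    similarity_floor_for_plot: float = 80.0

    def __post_init__(self):
        if self.min_hsp_len < 1:
            raise ValueError("min_hsp_len must be >= 1")


class BlastParseError(ValueError):
    pass


def parse_blast_tabular(path: str | Path) -> Iterator[HSP]:
    """Stream HSPs from 12-column BLAST tabular output (outfmt 6).

    Columns: qid sid pident length mismatch gapopen qstart qend sstart
    send evalue bitscore. Lines starting with '#' are skipped. Malformed
    rows raise :class:`BlastParseError` naming the line number.
    """
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 12:
                raise BlastParseError(
                    f"line {lineno}: expected 12 columns, got "
                    f"{len(fields)}")
            try:
                yield HSP(
                    query_id=fields[0],
                    subject_id=fields[1],
                    pct_identity=float(fields[2]),
                    align_len=int(fields[3]),
                    q_start=int(fields[6]),
                    q_end=int(fields[7]),
                    s_start=int(fields[8]),
                    s_end=int(fields[9]),
                    score=float(fields[11]),
                )
            except ValueError as exc:
                raise BlastParseError(f"line {lineno}: {exc}") from exc


def filter_hsps(hsps: Iterable[HSP],
                cfg: AssignConfig = AssignConfig()) -> list[HSP]:
    """Drop HSPs shorter than ``cfg.min_hsp_len`` (default 50 bp)."""
    return [h for h in hsps if h.align_len >= cfg.min_hsp_len]


def consistency_check(hsps: list[HSP],
                      overlap_tolerance: int = OVERLAP_TOLERANCE) -> bool:
    """True iff the HSPs of one pair are colinear.

    All HSPs must share a strand and, after sorting by query start, the
    subject intervals must advance strictly in the same direction
    (increasing on plus, decreasing on minus) with no overlap beyond
    ``overlap_tolerance`` bp on either axis. A pair that fails is a false
    alignment and is excluded from total-score comparison.
    """
    if not hsps:
        raise ValueError("empty HSP group")
    keys = {(h.query_id, h.subject_id) for h in hsps}
    if len(keys) > 1:
        raise ValueError(f"HSPs span multiple pairs: {sorted(keys)}")
    if len(hsps) == 1:
        return True
    if len({h.strand for h in hsps}) > 1:
        return False
    strand = hsps[0].strand
    ordered = sorted(hsps, key=lambda h: (h.q_start, h.q_end))
    for prev, cur in zip(ordered, ordered[1:]):
        if cur.q_start <= prev.q_start:
            return False
        if prev.q_end - cur.q_start + 1 > overlap_tolerance:
            return False
        if strand == "plus":
            if cur.s_lo <= prev.s_lo:
                return False
            if prev.s_hi - cur.s_lo + 1 > overlap_tolerance:
                return False
        else:
            if cur.s_hi >= prev.s_hi:
                return False
            if cur.s_hi - prev.s_lo + 1 > overlap_tolerance:
                return False
    return True


def total_score(group: PairGroup) -> float:
    """Sum of member HSP bit scores; defined only for consistent pairs."""
    if not group.consistent:
        raise ValueError(
            f"pair ({group.query_id}, {group.subject_id}) failed the "
            "consistency check; total score undefined")
    if not group.hsps:
        raise ValueError("no retained HSPs")
    return float(sum(h.score for h in group.hsps))


def average_similarity(group: PairGroup) -> float:
    """Alignment-length-weighted mean percent identity of the group."""
    if not group.consistent:
        raise ValueError(
            f"pair ({group.query_id}, {group.subject_id}) failed the "
            "consistency check; average similarity undefined")
    if not group.hsps:
        raise ValueError("no retained HSPs")
    wsum = sum(h.align_len * h.pct_identity for h in group.hsps)
    lsum = sum(h.align_len for h in group.hsps)
    return wsum / lsum


def group_hsps(hsps: Iterable[HSP],
               cfg: AssignConfig = AssignConfig()) -> dict[str, list[PairGroup]]:
    """Deduplicate, length-filter and group HSPs per (query, subject).

    Returns ``{query_id: [PairGroup, ...]}`` with each group's consistency
    verdict attached. Duplicate identical rows (e.g. from concatenated
    re-runs) are collapsed before grouping.
    """
    seen: set[HSP] = set()
    grouped: dict[tuple[str, str], list[HSP]] = {}
    queries: dict[str, None] = {}  # insertion-ordered set of query ids
    for h in hsps:
        queries.setdefault(h.query_id)
        if h in seen:
            continue
        seen.add(h)
        if h.align_len < cfg.min_hsp_len:
            continue
        grouped.setdefault((h.query_id, h.subject_id), []).append(h)
    out: dict[str, list[PairGroup]] = {q: [] for q in queries}
    for (qid, sid), members in grouped.items():
        # canonical member order: input row order must never matter,
        # down to float summation order
        members.sort(key=lambda h: (h.q_start, h.q_end, h.s_start,
                                    h.s_end, h.score))
        out[qid].append(PairGroup(
            query_id=qid, subject_id=sid, hsps=members,
            consistent=consistency_check(members)))
    return out


def nearest_relative(groups: list[PairGroup]) -> Assignment | None:
    """Pick the reference with the highest total score for one query.

    Inconsistent pairs are excluded before comparison. Ties break toward
    the lexicographically smallest subject id. Returns ``None`` when no
    consistent pair survives (the query is unassigned).
    """
    candidates = [g for g in groups if g.consistent and g.hsps]
    if not candidates:
        return None
    best = max(candidates,
               key=lambda g: (g.total_score, _neg_lex(g.subject_id)))
    return Assignment(query_id=best.query_id,
                      nearest_ref_id=best.subject_id,
                      avg_similarity=best.avg_similarity,
                      total_score=best.total_score)


class _neg_lex(str):
    """Inverts string comparison so max() prefers the smallest id."""

    def __lt__(self, other):
        return str.__gt__(self, other)

    def __gt__(self, other):
        return str.__lt__(self, other)


def assign_sample(blast_path: str | Path, panel=None,
                  cfg: AssignConfig = AssignConfig()
                  ) -> tuple[list[Assignment], list[str]]:
    """Assign every query in a BLAST tabular file to its nearest relative.

    Returns ``(assignments, unassigned_query_ids)``. If a panel is given,
    subject ids are validated against it. Exclusion statistics are logged.
    """
    n_raw = 0
    n_kept = 0

    def _stream():
        nonlocal n_raw, n_kept
        for h in parse_blast_tabular(blast_path):
            n_raw += 1
            if panel is not None and h.subject_id not in panel:
                raise ValueError(
                    f"subject id not in reference panel: {h.subject_id}")
            if h.align_len >= cfg.min_hsp_len:
                n_kept += 1
            yield h

    per_query = group_hsps(_stream(), cfg)
    assignments: list[Assignment] = []
    unassigned: list[str] = []
    n_inconsistent = 0
    for qid, groups in per_query.items():
        n_inconsistent += sum(1 for g in groups if not g.consistent)
        result = nearest_relative(groups)
        if result is None:
            unassigned.append(qid)
        else:
            assignments.append(result)
    logger.info(
        "assigned %d/%d queries (%d unassigned); %d/%d HSPs passed the "
        "length filter; %d pairs failed the consistency check",
        len(assignments), len(per_query), len(unassigned),
        n_kept, n_raw, n_inconsistent)
    return assignments, unassigned


def write_assignments(assignments: list[Assignment], unassigned: list[str],
                      out_tsv: str | Path) -> None:
    """Write assignments TSV plus a sibling ``.unassigned.txt`` list."""
    out_tsv = Path(out_tsv)
    with open(out_tsv, "w") as fh:
        fh.write("query_id\tref_id\tavg_similarity\ttotal_score\n")
        for a in assignments:
            fh.write(f"{a.query_id}\t{a.nearest_ref_id}\t"
                     f"{a.avg_similarity:.4f}\t{a.total_score:g}\n")
    side = out_tsv.with_suffix(out_tsv.suffix + ".unassigned.txt")
    with open(side, "w") as fh:
        for qid in unassigned:
            fh.write(qid + "\n")


def read_assignments(path: str | Path) -> list[Assignment]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"query_id": str,
                                            "ref_id": str})
    return [Assignment(query_id=r.query_id, nearest_ref_id=r.ref_id,
                       avg_similarity=float(r.avg_similarity),
                       total_score=float(r.total_score))
            for r in df.itertuples(index=False)]
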