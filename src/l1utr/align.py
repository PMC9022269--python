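"""Affine-gap local alignment of loci against the extended query.

One best local alignment per locus is all the downstream truncation census
needs: the query coordinate where the alignment starts gives the locus's 5'
start point, the coordinate where it ends tells whether the tether is intact.
Alignments can come from the built-in exact affine-gap local aligner (a
Gotoh-style dynamic program, run through Biopython's C pairwise engine) or be
imported from the standard 12-column tabular format written by external
tools, in which case selection uses the imported bit score.

Scoring follows nucleotide-BLAST-like defaults (+2 match, -3 mismatch, gap
open 5, gap extend 2); a length-L gap costs ``open + L * extend``.  No
identity threshold and no E-value model are applied.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Callable, Iterable, Sequence, TextIO

from Bio import Align

__all__ = [
    "ScoringScheme",
    "AlignmentHit",
    "AlignmentError",
    "TabularParseError",
    "DEFAULT_SCORING",
    "local_align",
    "import_hits_tabular",
    "write_hits_tabular",
    "best_hit_per_subject",
]

_QUERY_ALPHABET = frozenset("ACGT")
_SUBJECT_ALPHABET = frozenset("ACGTN")
# how many co-optimal alignments to examine when applying the tie-break
_TIE_SCAN = 32

TABULAR_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


class AlignmentError(ValueError):
    """Invalid input to an alignment operation."""


class TabularParseError(ValueError):
    """Malformed line in a 12-column tabular alignment file."""


@dataclass(frozen=True)
class ScoringScheme:
    """Integer affine-gap scoring; a length-L gap costs open + L*extend."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = 5
    gap_extend: int = 2

    def __post_init__(self) -> None:
        if self.match <= 0:
            raise AlignmentError("match reward must be > 0")
        if self.mismatch >= 0:
            raise AlignmentError("mismatch penalty must be < 0")
        if self.gap_open < 0 or self.gap_extend <= 0:
            raise AlignmentError("gap costs must be gap_open >= 0, gap_extend > 0")


DEFAULT_SCORING = ScoringScheme()


@dataclass(frozen=True)
class AlignmentHit:
    """One local alignment between a query and a subject sequence.

    Coordinates are 1-based inclusive.  ``minus_strand`` marks imported
    hits whose subject coordinates were reversed (sstart > send in the
    source file); such hits are excluded by the downstream orientation
    filter and keep their coordinates in plus-strand order here.
    """

    qseqid: str
    sseqid: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    score: float
    minus_strand: bool = False

    def __post_init__(self) -> None:
        if not (1 <= self.qstart <= self.qend):
            raise AlignmentError(
                f"invalid query coordinates {self.qstart}..{self.qend}"
            )
        if not (1 <= self.sstart <= self.send):
            raise AlignmentError(
                f"invalid subject coordinates {self.sstart}..{self.send}"
            )


@lru_cache(maxsize=8)
def _aligner(scoring: ScoringScheme) -> Align.PairwiseAligner:
    from Bio.Align import substitution_matrices

    alphabet = "ACGTN"
    matrix = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            # N never matches anything, including itself
            matrix[a, b] = (
                scoring.match if (a == b and a != "N") else scoring.mismatch
            )
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = matrix
    # Biopython charges open_gap_score for the first gap position and
    # extend_gap_score for each further one; our convention charges
    # open + extend for a length-1 gap.
    aligner.open_gap_score = -(scoring.gap_open + scoring.gap_extend)
    aligner.extend_gap_score = -scoring.gap_extend
    return aligner


def _check_sequence(seq: str, what: str, alphabet: frozenset[str]) -> None:
    if not seq:
        raise AlignmentError(f"{what} sequence is empty")
    bad = set(seq) - alphabet
    if bad:
        raise AlignmentError(
            f"{what} sequence contains invalid characters {sorted(bad)!r}"
        )


def _hit_from_alignment(
    alignment: Align.Alignment,
    query: str,
    subject: str,
    qseqid: str,
    sseqid: str,
) -> AlignmentHit:
    coords = alignment.coordinates
    qstart, qend = int(coords[0, 0]) + 1, int(coords[0, -1])
    sstart, send = int(coords[1, 0]) + 1, int(coords[1, -1])
    identities = columns = gapopen = diag_columns = 0
    for i in range(coords.shape[1] - 1):
        dq = int(coords[0, i + 1] - coords[0, i])
        ds = int(coords[1, i + 1] - coords[1, i])
        if dq and ds:  # diagonal segment
            columns += dq
            diag_columns += dq
            qs = query[int(coords[0, i]): int(coords[0, i + 1])]
            ss = subject[int(coords[1, i]): int(coords[1, i + 1])]
            identities += sum(
                1 for a, b in zip(qs, ss) if a == b and a != "N"
            )
        else:  # gap segment
            columns += max(dq, ds)
            gapopen += 1
    mismatches = diag_columns - identities
    return AlignmentHit(
        qseqid=qseqid,
        sseqid=sseqid,
        pident=100.0 * identities / columns,
        length=columns,
        mismatch=mismatches,
        gapopen=gapopen,
        qstart=qstart,
        qend=qend,
        sstart=sstart,
        send=send,
        score=float(alignment.score),
    )


def local_align(
    query: str,
    subject: str,
    scoring: ScoringScheme = DEFAULT_SCORING,
    qseqid: str = "query",
    sseqid: str = "subject",
) -> AlignmentHit | None:
    """Maximum-scoring affine-gap local alignment, or None if best <= 0.

    Ties between co-optimal alignments are broken by smallest subject
    start, then smallest query start, then longest alignment (scanned
    over a bounded prefix of the co-optimal enumeration).
    """
    _check_sequence(query, "query", _QUERY_ALPHABET)
    _check_sequence(subject, "subject", _SUBJECT_ALPHABET)
    aligner = _aligner(scoring)
    alignments = aligner.align(query, subject)
    if alignments.score <= 0:
        return None
    hits = [
        _hit_from_alignment(a, query, subject, qseqid, sseqid)
        for a in itertools.islice(alignments, _TIE_SCAN)
    ]
    return min(hits, key=lambda h: (h.sstart, h.qstart, -h.length))


def import_hits_tabular(source: str | Path | TextIO) -> list[AlignmentHit]:
    """Parse 12-column tabular alignment output (one hit per line).

    Minus-strand hits (``sstart > send`` in the file) are kept with their
    subject coordinates swapped into plus order and ``minus_strand=True``
    so the downstream orientation filter can reject them.  Any malformed
    line fails the whole parse, naming the line number.
    """
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            return import_hits_tabular(fh)
    hits: list[AlignmentHit] = []
    for lineno, raw in enumerate(source, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 12:
            raise TabularParseError(
                f"line {lineno}: expected >= 12 tab-separated fields, "
                f"got {len(fields)}"
            )
        try:
            pident = float(fields[2])
            length = int(fields[3])
            mismatch = int(fields[4])
            gapopen = int(fields[5])
            qstart, qend = int(fields[6]), int(fields[7])
            sstart, send = int(fields[8]), int(fields[9])
            bitscore = float(fields[11])
        except ValueError as exc:
            raise TabularParseError(f"line {lineno}: {exc}") from exc
        minus = sstart > send
        if minus:
            sstart, send = send, sstart
        try:
            hits.append(
                AlignmentHit(
                    qseqid=fields[0],
                    sseqid=fields[1],
                    pident=pident,
                    length=length,
                    mismatch=mismatch,
                    gapopen=gapopen,
                    qstart=qstart,
                    qend=qend,
                    sstart=sstart,
                    send=send,
                    score=bitscore,
                    minus_strand=minus,
                )
            )
        except AlignmentError as exc:
            raise TabularParseError(f"line {lineno}: {exc}") from exc
    return hits


def write_hits_tabular(
    hits: Iterable[AlignmentHit], path: str | Path
) -> None:
    """Write hits in the 12-column tabular layout (evalue written as 0)."""
    with open(path, "w") as fh:
        for h in hits:
            sstart, send = (
                (h.send, h.sstart) if h.minus_strand else (h.sstart, h.send)
            )
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        h.qseqid, h.sseqid, f"{h.pident:.3f}", h.length,
                        h.mismatch, h.gapopen, h.qstart, h.qend,
                        sstart, send, 0, f"{h.score:g}",
                    )
                )
                + "\n"
            )


def best_hit_per_subject(
    hits: Sequence[AlignmentHit],
    keep: Callable[[AlignmentHit], bool] | None = None,
) -> tuple[dict[str, AlignmentHit], list[str]]:
    """Select one maximal-score hit per subject among those passing ``keep``.

    Ties go to the smallest subject start, then the longest alignment.
    Returns the winning hit per subject id plus the subject ids that had
    hits but none surviving ``keep``.  All hits must share one query id.
    """
    query_ids = {h.qseqid for h in hits}
    if len(query_ids) > 1:
        raise AlignmentError(
            f"hits span multiple query ids: {sorted(query_ids)}"
        )
    best: dict[str, AlignmentHit] = {}
    seen: set[str] = set()
    for h in hits:
        seen.add(h.sseqid)
        if keep is not None and not keep(h):
            continue
        cur = best.get(h.sseqid)
        if cur is None or (-h.score, h.sstart, -h.length) < (
            -cur.score, cur.sstart, -cur.length
        ):
            best[h.sseqid] = h
    unaligned = sorted(seen - set(best))
    return best, unaligned
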