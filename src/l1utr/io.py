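"""Standard-format I/O: FASTA, BED intervals, strand-aware locus extraction,
and the TSV report writers used by the pipeline.

Coordinate conventions: BED input/output is 0-based half-open; everything
human-readable (domain offsets, alignment coordinates) is 1-based inclusive.
Minus-strand intervals are reverse-complemented on extraction so every locus
reads 5'->3' in element orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .census import RegressionResult, StartCall, SubfamilyCensus

__all__ = [
    "FastaError",
    "IntervalError",
    "GenomicInterval",
    "read_fasta",
    "write_fasta",
    "read_bed",
    "write_bed",
    "extract_loci",
    "write_calls_tsv",
    "write_census_tsv",
    "write_histograms_tsv",
    "write_regression_tsv",
    "write_truncation_bed",
]


class FastaError(ValueError):
    """Malformed FASTA input."""


class IntervalError(ValueError):
    """Invalid genomic interval."""


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "+"
    name: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise IntervalError(
                f"{self.name or self.chrom}: need 0 <= start < end, "
                f"got {self.start}..{self.end}"
            )
        if self.strand not in ("+", "-"):
            raise IntervalError(
                f"{self.name or self.chrom}: strand must be + or -, "
                f"got {self.strand!r}"
            )


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read FASTA records as (id, uppercase sequence) pairs.

    Duplicate ids and empty records are errors.
    """
    records: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise FastaError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper()
        if not seq:
            raise FastaError(f"{path}: record {rec.id!r} is empty")
        records.append((rec.id, seq))
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    return records


def write_fasta(
    records: Iterable[tuple[str, str]], path: str | Path, width: int = 70
) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED (>= 3 columns; name in col 4, strand in col 6, default +)."""
    intervals = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise IntervalError(
                    f"{path}, line {lineno}: need >= 3 BED columns"
                )
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise IntervalError(
                    f"{path}, line {lineno}: {exc}"
                ) from exc
            intervals.append(
                GenomicInterval(
                    chrom=fields[0],
                    start=start,
                    end=end,
                    name=fields[3] if len(fields) > 3 and fields[3] else "",
                    strand=fields[5] if len(fields) > 5 else "+",
                )
            )
    return intervals


def write_bed(
    intervals: Iterable[GenomicInterval], path: str | Path
) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name or '.'}"
                f"\t0\t{iv.strand}\n"
            )


def extract_loci(
    genome: Mapping[str, str] | str | Path,
    intervals: Sequence[GenomicInterval],
) -> list[tuple[str, str]]:
    """Extract interval sequences in element orientation.

    Minus-strand intervals are reverse-complemented so every locus reads
    5'->3' as the element does.  Names carry coordinates when the
    interval has no name of its own.
    """
    if not isinstance(genome, Mapping):
        genome = dict(read_fasta(genome))
    out = []
    for iv in intervals:
        if iv.chrom not in genome:
            raise IntervalError(
                f"interval {iv.name or iv.chrom}: unknown chromosome "
                f"{iv.chrom!r}"
            )
        chrom_seq = genome[iv.chrom]
        if iv.end > len(chrom_seq):
            raise IntervalError(
                f"interval {iv.name or iv.chrom} "
                f"({iv.chrom}:{iv.start}-{iv.end}) extends beyond "
                f"chromosome end {len(chrom_seq)}"
            )
        seq = chrom_seq[iv.start: iv.end]
        if iv.strand == "-":
            seq = str(Seq(seq).reverse_complement())
        name = iv.name or f"{iv.chrom}:{iv.start}-{iv.end}({iv.strand})"
        out.append((name, seq))
    return out


# --- TSV report writers -------------------------------------------------

def _call_frame(calls: Sequence[StartCall], status: Mapping[str, str]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "locus_id": c.locus_id,
                "pattern": c.pattern_id,
                "bin": c.bin,
                "offset": c.offset,
                "monomer_count": round(c.monomer_count, 4),
                "filter_status": status.get(c.locus_id, "pass"),
            }
        )
    return pd.DataFrame(rows)


def write_calls_tsv(
    calls: Sequence[StartCall],
    path: str | Path,
    failed: Mapping[str, str] | None = None,
) -> None:
    """Per-locus calls; ``failed`` maps locus id -> failure reason."""
    frame = _call_frame(calls, {})
    extra = pd.DataFrame(
        [
            {
                "locus_id": locus,
                "pattern": "",
                "bin": "",
                "offset": -1,
                "monomer_count": float("nan"),
                "filter_status": reason,
            }
            for locus, reason in sorted((failed or {}).items())
        ]
    )
    frame = pd.concat([frame, extra], ignore_index=True) if len(extra) else frame
    frame.to_csv(path, sep="\t", index=False)


def write_census_tsv(c: SubfamilyCensus, path: str | Path) -> None:
    rows = [
        {
            "subfamily": c.subfamily,
            "bin": lab,
            "count": n,
            "percent": c.percentages[lab],
        }
        for lab, n in c.bin_counts.items()
    ]
    frame = pd.DataFrame(rows)
    frame.to_csv(path, sep="\t", index=False)


def write_histograms_tsv(c: SubfamilyCensus, path: str | Path) -> None:
    rows = []
    for lab, hist in c.offset_histograms.items():
        for offset in sorted(hist):
            rows.append(
                {
                    "subfamily": c.subfamily,
                    "bin": lab,
                    "offset": offset,
                    "count": hist[offset],
                }
            )
    pd.DataFrame(
        rows, columns=["subfamily", "bin", "offset", "count"]
    ).to_csv(path, sep="\t", index=False)


def write_regression_tsv(r: RegressionResult, path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "slope": r.slope,
                "intercept": r.intercept,
                "r": r.r,
                "p": r.p,
                "n": r.n,
            }
        ]
    ).to_csv(path, sep="\t", index=False)


def write_truncation_bed(
    calls: Sequence[StartCall],
    path: str | Path,
) -> None:
    """BED-like per-locus truncation report.

    Each row marks the 5' breakpoint on the locus itself: 0-based
    half-open single-base interval at the locus start, with the bin and
    offset in the name field.  Loci are in element orientation, noted in
    the strand column.
    """
    with open(path, "w") as fh:
        fh.write("# element orientation; breakpoint at locus 5' end\n")
        for c in calls:
            fh.write(
                f"{c.locus_id}\t0\t1\t{c.bin}:{c.offset}"
                f"\t0\t+\n"
            )
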