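"""5'-truncation filtering, binning, and the per-subfamily monomer census.

A locus's alignment against the extended query is accepted only if it is
anchored at both ends of the element: the alignment must end within the last
``tether_tail_window`` (default 10) bases of the query's tether — otherwise
the locus carries a 3'-truncated tether — and must start within the first
``subject_head_window`` (default 10) bases of the locus itself — otherwise
the locus 5' end is something other than monomeric promoter sequence (e.g. a
chimeric 5'UTR).  The query position where a passing alignment starts places
the locus in one of 12 bins (tether T, monomers M1..M10, or M11+) and yields
a fractional monomer count: a locus starting at offset ``o`` inside the
``i``-th monomer (length ``L_i``) retains ``(i-1) + (L_i - o + 1)/L_i``
monomers.  Loci starting in T or M11+ are excluded from subfamily averages.

Subfamilies with several monomer-organisation patterns (the Gf patterns) are
aligned against one query per pattern; loci passing under more than one
pattern are kept once, under the highest-precedence pattern.

Reported percentages are rounded half away from zero to one decimal; the
relationship between subfamily age and average monomer count is summarised
by ordinary least squares with the two-sided slope t-test.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .align import AlignmentHit
from .promoter_model import ExtendedQuery

__all__ = [
    "FilterConfig",
    "FilterResult",
    "StartCall",
    "SubfamilyCensus",
    "RegressionResult",
    "CensusError",
    "filter_hit",
    "call_start",
    "dedup_patterns",
    "census",
    "pooled_census",
    "percent",
    "pairwise_identity",
    "age_regression",
    "correlation_pvalue",
    "bin_labels",
]

REASON_MINUS = "minus-orientation"
REASON_TETHER = "tether-3'-truncated"
REASON_ANCHOR = "not-5'-anchored"


class CensusError(ValueError):
    """Invalid input to a census operation."""


@dataclass(frozen=True)
class FilterConfig:
    """End-anchoring windows, in bp, both 1 or more."""

    tether_tail_window: int = 10
    subject_head_window: int = 10

    def __post_init__(self) -> None:
        if self.tether_tail_window < 1 or self.subject_head_window < 1:
            raise CensusError("filter windows must be >= 1")


@dataclass(frozen=True)
class FilterResult:
    passed: bool
    reason: str | None = None

    def __bool__(self) -> bool:
        return self.passed


@dataclass(frozen=True)
class StartCall:
    """Per-locus 5' start bin, within-domain offset and monomer count."""

    locus_id: str
    pattern_id: str
    bin: str
    offset: int
    monomer_count: float
    averaged: bool  # False for T and the open-ended top bin


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r: float
    p: float
    n: int


@dataclass
class SubfamilyCensus:
    """Aggregated bin table for one subfamily (or a pooled set)."""

    subfamily: str
    bin_counts: dict[str, int]
    total: int
    percentages: dict[str, float]
    cumulative: dict[int, tuple[int, float]]  # k -> (count >= k intact, %)
    average_monomer_count: float  # nan when no locus qualifies
    n_averaged: int
    n_excluded: int
    offset_histograms: dict[str, Counter] = field(default_factory=dict)


def bin_labels(total_monomers: int = 11) -> list[str]:
    """Bin labels 5'-proximal first: T, M1..M{total-1}, M{total}+."""
    return (
        ["T"]
        + [f"M{i}" for i in range(1, total_monomers)]
        + [f"M{total_monomers}+"]
    )


def filter_hit(
    hit: AlignmentHit,
    query: ExtendedQuery,
    cfg: FilterConfig = FilterConfig(),
    subject_length: int | None = None,
) -> FilterResult:
    """Accept a hit only if anchored at the tether tail and the subject head.

    Pass iff ``qend`` lies in the last ``tether_tail_window`` bases of the
    query and ``sstart`` in the first ``subject_head_window`` bases of the
    subject (and the hit is plus-orientation).
    """
    lq = len(query)
    if hit.qend > lq:
        raise CensusError(
            f"hit qend {hit.qend} beyond query length {lq}"
        )
    if subject_length is not None and hit.send > subject_length:
        raise CensusError(
            f"hit send {hit.send} beyond subject length {subject_length}"
        )
    if hit.minus_strand:
        return FilterResult(False, REASON_MINUS)
    if hit.qend < lq - cfg.tether_tail_window + 1:
        return FilterResult(False, REASON_TETHER)
    if hit.sstart > cfg.subject_head_window:
        return FilterResult(False, REASON_ANCHOR)
    return FilterResult(True)


def call_start(hit: AlignmentHit, query: ExtendedQuery) -> StartCall:
    """Bin a filtered hit by its query start and compute the monomer count.

    Starts in monomer ``i <= total-1`` give ``(i-1) + (L_i - offset + 1)/L_i``
    monomers; starts in the tether give 0; starts in the outermost monomer
    domain fall in the open-ended top bin (M11+ for an 11-monomer query),
    carry more than ``total-1`` monomers and are flagged not-averaged.
    """
    label, offset = query.map_position(hit.qstart)
    total = query.total_monomers
    if label == "T":
        return StartCall(
            locus_id=hit.sseqid,
            pattern_id=query.source_model.pattern_id,
            bin="T",
            offset=offset,
            monomer_count=0.0,
            averaged=False,
        )
    index = int(label[1:])
    length = query.domain_length(label)
    count = (index - 1) + (length - offset + 1) / length
    top = index == total
    return StartCall(
        locus_id=hit.sseqid,
        pattern_id=query.source_model.pattern_id,
        bin=f"M{total}+" if top else label,
        offset=offset,
        monomer_count=count,
        averaged=not top,
    )


def dedup_patterns(
    calls: Iterable[StartCall],
    precedence: Sequence[str] = ("II", "I", "IV"),
) -> list[StartCall]:
    """Keep each locus once, under its highest-precedence pattern.

    The default precedence II > I > IV matches the Gf monomer-organisation
    patterns (pattern II is the subfamily prototype; pattern III is
    excluded upstream).  Calls under unknown patterns are an error.
    """
    rank = {p: i for i, p in enumerate(precedence)}
    best: dict[str, StartCall] = {}
    order: list[str] = []
    for call in calls:
        if call.pattern_id not in rank:
            raise CensusError(
                f"pattern {call.pattern_id!r} not in precedence "
                f"{list(precedence)}"
            )
        cur = best.get(call.locus_id)
        if cur is None:
            best[call.locus_id] = call
            order.append(call.locus_id)
        elif rank[call.pattern_id] < rank[cur.pattern_id]:
            best[call.locus_id] = call
    return [best[locus] for locus in order]


def percent(numerator: float, denominator: float) -> float:
    """Reporting percentage: 100*n/d, half away from zero, one decimal."""
    if denominator == 0:
        raise CensusError("percentage undefined for zero denominator")
    value = 100.0 * numerator / denominator
    return float(
        Decimal(repr(value)).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP)
    )


def census(
    calls: Sequence[StartCall],
    subfamily: str,
    total_monomers: int = 11,
) -> SubfamilyCensus:
    """Aggregate deduplicated passing calls into a subfamily bin table.

    Cumulative categories count loci with at least ``k`` complete
    monomers, i.e. fractional monomer count >= k (a start in M(k+1) or
    beyond, or exactly at position 1 of Mk).  The average monomer count is
    taken over loci neither in T nor in the open-ended top bin.
    """
    labels = bin_labels(total_monomers)
    counts: dict[str, int] = {lab: 0 for lab in labels}
    histograms: dict[str, Counter] = {lab: Counter() for lab in labels}
    averaged: list[float] = []
    n_excluded = 0
    for call in calls:
        if call.bin not in counts:
            raise CensusError(f"unknown bin {call.bin!r}")
        counts[call.bin] += 1
        histograms[call.bin][call.offset] += 1
        if call.averaged:
            averaged.append(call.monomer_count)
        else:
            n_excluded += 1
    total = len(calls)
    percentages = {
        lab: (percent(c, total) if total else 0.0)
        for lab, c in counts.items()
    }
    cumulative: dict[int, tuple[int, float]] = {}
    for k in range(1, total_monomers):
        n_k = sum(1 for c in calls if c.monomer_count >= k)
        cumulative[k] = (n_k, percent(n_k, total) if total else 0.0)
    avg = float(sum(averaged) / len(averaged)) if averaged else math.nan
    return SubfamilyCensus(
        subfamily=subfamily,
        bin_counts=counts,
        total=total,
        percentages=percentages,
        cumulative=cumulative,
        average_monomer_count=avg,
        n_averaged=len(averaged),
        n_excluded=n_excluded,
        offset_histograms=histograms,
    )


def pooled_census(
    censuses: Sequence[SubfamilyCensus],
    name: str = "pooled",
) -> SubfamilyCensus:
    """Sum per-subfamily bin tables into one pooled table (no reweighting)."""
    if not censuses:
        raise CensusError("no censuses to pool")
    labels = list(censuses[0].bin_counts)
    counts = {lab: sum(c.bin_counts.get(lab, 0) for c in censuses)
              for lab in labels}
    total = sum(c.total for c in censuses)
    percentages = {
        lab: (percent(n, total) if total else 0.0)
        for lab, n in counts.items()
    }
    cumulative: dict[int, tuple[int, float]] = {}
    for k in censuses[0].cumulative:
        n_k = sum(c.cumulative[k][0] for c in censuses)
        cumulative[k] = (n_k, percent(n_k, total) if total else 0.0)
    n_averaged = sum(c.n_averaged for c in censuses)
    avg = (
        sum(c.average_monomer_count * c.n_averaged
            for c in censuses if c.n_averaged)
        / n_averaged
        if n_averaged
        else math.nan
    )
    histograms: dict[str, Counter] = {lab: Counter() for lab in labels}
    for c in censuses:
        for lab, hist in c.offset_histograms.items():
            histograms[lab].update(hist)
    return SubfamilyCensus(
        subfamily=name,
        bin_counts=counts,
        total=total,
        percentages=percentages,
        cumulative=cumulative,
        average_monomer_count=avg,
        n_averaged=n_averaged,
        n_excluded=sum(c.n_excluded for c in censuses),
        offset_histograms=histograms,
    )


def pairwise_identity(a: str, b: str) -> tuple[int, int, float]:
    """Column identity of two equal-length gapped sequences.

    Returns (identical columns, compared columns, percent).  A column
    containing a gap character '-' never counts as identical; all columns
    count toward the denominator.
    """
    if len(a) != len(b):
        raise CensusError(
            f"aligned sequences differ in length ({len(a)} vs {len(b)})"
        )
    if not a:
        raise CensusError("empty alignment")
    identical = sum(
        1 for x, y in zip(a, b) if x == y and x != "-"
    )
    return identical, len(a), percent(identical, len(a))


def correlation_pvalue(r: float, n: int) -> float:
    """Two-sided p-value for a Pearson correlation r on n points.

    Uses t = r*sqrt(n-2)/sqrt(1-r^2) on n-2 degrees of freedom, the same
    statistic as the simple-linear-regression slope test.
    """
    if n < 3:
        raise CensusError("need n >= 3 for a correlation test")
    if abs(r) >= 1.0:
        return 0.0
    t = r * math.sqrt((n - 2) / (1.0 - r * r))
    return float(2.0 * stats.t.sf(abs(t), n - 2))


def age_regression(
    points: Sequence[tuple[float, float]]
) -> RegressionResult:
    """OLS of average monomer count on subfamily age (Myr).

    ``r`` is the signed Pearson correlation; ``p`` the two-sided slope
    t-test p-value on n-2 degrees of freedom.
    """
    if len(points) < 3:
        raise CensusError("need at least 3 (age, count) points")
    x = [p[0] for p in points]
    y = [p[1] for p in points]
    if len(set(x)) < 2:
        raise CensusError("degenerate regression: ages have zero variance")
    if len(set(x)) != len(x):
        raise CensusError("ages must be distinct")
    fit = stats.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r=float(fit.rvalue),
        p=float(fit.pvalue),
        n=len(points),
    )
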