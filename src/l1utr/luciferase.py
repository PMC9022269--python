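"""Dual-luciferase reporter normalization and statistics.

Each well carries a firefly (Fluc) signal driven by the promoter under test
and a Renilla (Rluc) signal from an invariant cassette on the same plasmid;
their ratio cancels per-well transfection efficiency.  Normalization is
stepwise: (1) ratio = Fluc/Rluc per well; (2) average ratio of the
no-promoter control construct; (3) divide every well's ratio by that control
mean, so the control averages exactly 1 and a construct's normalized
activity reads as fold over assay background; (4) summarise per construct as
mean +/- SEM over replicate wells (SEM = SD/sqrt(n)).

Pairwise comparisons between constructs use two-sided t-tests with one
pooled standard deviation across all groups (residual df = N - k, the
convention of R's ``pairwise.t.test``) and Benjamini-Hochberg adjustment
across the pairs reported in one run.  Titration experiments are summarised
per dose, with deviations from an origin-through least-squares line flagging
signal saturation at high DNA dose.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .census import percent

__all__ = [
    "WellMeasurement",
    "ConstructSummary",
    "PairwiseTestResult",
    "TitrationSummary",
    "PlateError",
    "MissingControlError",
    "read_plate_table",
    "normalize_plate",
    "pairwise_tests",
    "activity_standard_error",
    "relative_activity",
    "summarize_titration",
    "summaries_to_frame",
]

WELL_COLUMNS = ["plate", "well", "construct", "fluc", "rluc"]


class PlateError(ValueError):
    """Invalid reporter-plate input."""


class MissingControlError(PlateError):
    """The no-promoter control construct is absent or under-replicated."""


@dataclass(frozen=True)
class WellMeasurement:
    plate: str
    well: str
    construct: str
    fluc: float
    rluc: float
    dose_ng: float | None = None

    def __post_init__(self) -> None:
        if self.fluc < 0:
            raise PlateError(f"well {self.well}: fluc must be >= 0")
        if self.rluc <= 0:
            raise PlateError(
                f"well {self.well}: rluc must be > 0 for the ratio"
            )


@dataclass(frozen=True)
class ConstructSummary:
    construct: str
    n_wells: int
    mean_normalized: float
    sem: float
    mean_ratio: float


@dataclass(frozen=True)
class PairwiseTestResult:
    construct_a: str
    construct_b: str
    raw_p: float
    adjusted_p: float
    significant: bool


@dataclass
class TitrationSummary:
    per_dose: pd.DataFrame  # dose, n, *_mean, *_sem for fluc/rluc/ratio
    slopes: dict[str, float]  # origin-through LS slope per signal
    deviations: pd.DataFrame  # dose, signal, relative deviation from fit
    fit_doses: tuple[float, ...]


def read_plate_table(path: str | Path) -> pd.DataFrame:
    """Read a TSV/CSV plate table (plate, well, construct, fluc, rluc[, dose_ng])."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep)
    missing = [c for c in WELL_COLUMNS if c not in df.columns]
    if missing:
        raise PlateError(f"{path}: missing columns {missing}")
    return df


def _validate_wells(wells: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in WELL_COLUMNS if c not in wells.columns]
    if missing:
        raise PlateError(f"plate table missing columns {missing}")
    bad = wells[~(wells["rluc"] > 0) | wells["rluc"].isna()]
    if len(bad):
        names = ", ".join(
            f"{r.plate}/{r.well}" for r in bad.head(5).itertuples()
        )
        raise PlateError(
            f"{len(bad)} well(s) with rluc <= 0 or missing (e.g. {names})"
        )
    if (wells["fluc"] < 0).any():
        raise PlateError("negative fluc values present")
    return wells


def normalize_plate(
    wells: pd.DataFrame,
    control: str,
) -> tuple[pd.DataFrame, list[ConstructSummary]]:
    """Per-well normalized activities plus per-construct summaries.

    Returns a copy of the well table with ``ratio`` (Fluc/Rluc) and
    ``normalized`` (ratio over the control-construct mean ratio) columns,
    and one :class:`ConstructSummary` per construct in first-appearance
    order.  The control construct must be present with >= 2 wells; its
    mean normalized activity is exactly 1 by construction.
    """
    wells = _validate_wells(wells).copy()
    control_wells = wells[wells["construct"] == control]
    if len(control_wells) == 0:
        raise MissingControlError(
            f"control construct {control!r} not found on the plate"
        )
    if len(control_wells) < 2:
        raise MissingControlError(
            f"control construct {control!r} needs >= 2 replicate wells"
        )
    wells["ratio"] = wells["fluc"] / wells["rluc"]
    control_mean = wells.loc[wells["construct"] == control, "ratio"].mean()
    wells["normalized"] = wells["ratio"] / control_mean
    summaries = []
    for construct in wells["construct"].drop_duplicates():
        sub = wells[wells["construct"] == construct]
        n = len(sub)
        sem = (
            float(sub["normalized"].std(ddof=1) / math.sqrt(n))
            if n > 1
            else math.nan
        )
        summaries.append(
            ConstructSummary(
                construct=str(construct),
                n_wells=n,
                mean_normalized=float(sub["normalized"].mean()),
                sem=sem,
                mean_ratio=float(sub["ratio"].mean()),
            )
        )
    return wells, summaries


def summaries_to_frame(
    summaries: Sequence[ConstructSummary],
) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "construct": [s.construct for s in summaries],
            "n_wells": [s.n_wells for s in summaries],
            "mean_normalized": [s.mean_normalized for s in summaries],
            "sem": [s.sem for s in summaries],
            "mean_ratio": [s.mean_ratio for s in summaries],
        }
    )


def pairwise_tests(
    groups: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
) -> list[PairwiseTestResult]:
    """All-pairs two-sided t-tests with one pooled SD, BH-adjusted.

    The pooled variance is the within-group residual variance across *all*
    groups (df = N - k); each pair's t statistic uses it with the pair's
    own group sizes.  When the pooled variance is zero, a pair with equal
    means gets p = 1 and a pair with different means p = 0.
    """
    if len(groups) < 2:
        raise PlateError("need at least two groups for pairwise tests")
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    for name, arr in arrays.items():
        if arr.size < 2:
            raise PlateError(
                f"group {name!r} has {arr.size} well(s); need >= 2"
            )
    n_total = sum(a.size for a in arrays.values())
    k = len(arrays)
    df = n_total - k
    ss_within = sum(
        float(((a - a.mean()) ** 2).sum()) for a in arrays.values()
    )
    pooled_var = ss_within / df
    pairs = list(itertools.combinations(arrays, 2))
    raw = []
    for a, b in pairs:
        xa, xb = arrays[a], arrays[b]
        diff = float(xa.mean() - xb.mean())
        if pooled_var == 0.0:
            raw.append(1.0 if diff == 0.0 else 0.0)
            continue
        se = math.sqrt(pooled_var * (1.0 / xa.size + 1.0 / xb.size))
        t = diff / se
        raw.append(float(2.0 * stats.t.sf(abs(t), df)))
    _, adjusted, _, _ = multipletests(raw, method="fdr_bh")
    return [
        PairwiseTestResult(
            construct_a=a,
            construct_b=b,
            raw_p=p,
            adjusted_p=float(q),
            significant=bool(q < alpha),
        )
        for (a, b), p, q in zip(pairs, raw, adjusted)
    ]


def activity_standard_error(
    summary: ConstructSummary, control: ConstructSummary
) -> float:
    """Delta-method standard error of a normalized activity estimate.

    The normalized activity is a ratio of two sample means (construct
    mean ratio over control mean ratio), so its standard error combines
    the construct-level SEM with the control mean's relative SEM:
    ``mean * sqrt((sem/mean)^2 + (sem_ctrl/mean_ctrl)^2)``.  The plain
    per-construct SEM reported alongside (SD/sqrt(n) of normalized
    values) omits the control term because every normalized value on a
    plate shares the same control denominator.
    """
    if summary.mean_normalized == 0 or control.mean_normalized == 0:
        raise PlateError("zero mean activity; standard error undefined")
    rel_a = summary.sem / summary.mean_normalized
    rel_c = control.sem / control.mean_normalized
    return abs(summary.mean_normalized) * math.sqrt(
        rel_a * rel_a + rel_c * rel_c
    )


def relative_activity(
    construct: ConstructSummary | float,
    reference: ConstructSummary | float,
) -> float:
    """Activity of one construct as a percentage of a reference (1 dp)."""
    a = (
        construct.mean_normalized
        if isinstance(construct, ConstructSummary)
        else float(construct)
    )
    ref = (
        reference.mean_normalized
        if isinstance(reference, ConstructSummary)
        else float(reference)
    )
    if ref <= 0:
        raise PlateError("reference activity must be positive")
    return percent(a, ref)


def summarize_titration(
    wells: pd.DataFrame,
    fit_doses: Sequence[float] | None = None,
) -> TitrationSummary:
    """Per-dose mean +/- SEM for Fluc, Rluc and their ratio, plus linearity.

    A least-squares line through the origin is fitted to the per-well
    signals on ``fit_doses`` (default: all doses); the relative deviation
    of each dose's mean signal from that line is reported, leaving the
    plateau judgement to the reader.
    """
    wells = _validate_wells(wells)
    if "dose_ng" not in wells.columns or wells["dose_ng"].isna().all():
        raise PlateError("titration requires a dose_ng column")
    wells = wells.copy()
    wells["ratio"] = wells["fluc"] / wells["rluc"]
    doses = sorted(wells["dose_ng"].unique())
    if len(doses) < 2:
        raise PlateError("need at least two doses for a titration summary")
    if fit_doses is None:
        fit_doses = doses
    fit_doses = tuple(float(d) for d in fit_doses)
    rows = []
    for d in doses:
        sub = wells[wells["dose_ng"] == d]
        row = {"dose_ng": float(d), "n": len(sub)}
        for col in ("fluc", "rluc", "ratio"):
            row[f"{col}_mean"] = float(sub[col].mean())
            row[f"{col}_sem"] = (
                float(sub[col].std(ddof=1) / math.sqrt(len(sub)))
                if len(sub) > 1
                else math.nan
            )
        rows.append(row)
    per_dose = pd.DataFrame(rows)
    fit_mask = wells["dose_ng"].isin(fit_doses)
    if not fit_mask.any():
        raise PlateError("fit_doses match no wells")
    slopes: dict[str, float] = {}
    dev_rows = []
    d_fit = wells.loc[fit_mask, "dose_ng"].to_numpy(float)
    for col in ("fluc", "rluc"):
        s_fit = wells.loc[fit_mask, col].to_numpy(float)
        slope = float((d_fit * s_fit).sum() / (d_fit * d_fit).sum())
        slopes[col] = slope
        for _, row in per_dose.iterrows():
            expected = slope * row["dose_ng"]
            dev_rows.append(
                {
                    "dose_ng": row["dose_ng"],
                    "signal": col,
                    "relative_deviation": (
                        (row[f"{col}_mean"] - expected) / expected
                        if expected
                        else math.nan
                    ),
                }
            )
    deviations = pd.DataFrame(dev_rows)
    return TitrationSummary(
        per_dose=per_dose,
        slopes=slopes,
        deviations=deviations,
        fit_doses=fit_doses,
    )
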