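"""End-to-end workflows: the genome-census run and the reporter-plate run.

``run_pipeline`` executes one of two workflows from a YAML/dict config:

* ``census`` — for each subfamily entry: build the extended query per
  monomer pattern, align each locus (or import tabular hits), apply the
  end-anchoring filters, call start bins, deduplicate across patterns,
  aggregate the census; then, if ages are given for >= 3 subfamilies,
  regress average monomer count on age.
* ``luciferase`` — normalize a reporter plate to its no-promoter control,
  summarise per construct, run BH-adjusted pooled-SD pairwise t-tests, and
  summarise a titration when a dose column is present.

All TSV outputs are written under ``output_dir`` together with a run log
carrying the config hash, so identical configs reproduce identical bytes.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import pandas as pd
import yaml

from . import __version__
from .align import (
    AlignmentHit,
    ScoringScheme,
    best_hit_per_subject,
    import_hits_tabular,
    local_align,
)
from .census import (
    FilterConfig,
    RegressionResult,
    StartCall,
    SubfamilyCensus,
    age_regression,
    call_start,
    census,
    dedup_patterns,
    filter_hit,
)
from .io import (
    read_fasta,
    write_calls_tsv,
    write_census_tsv,
    write_histograms_tsv,
    write_regression_tsv,
    write_truncation_bed,
)
from .luciferase import (
    normalize_plate,
    pairwise_tests,
    read_plate_table,
    summaries_to_frame,
    summarize_titration,
)
from .promoter_model import PromoterModel, build_extended_query, load_model

__all__ = ["PipelineError", "PipelineResult", "run_pipeline"]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


@dataclass
class PipelineResult:
    output_dir: Path
    censuses: dict[str, SubfamilyCensus] = field(default_factory=dict)
    calls: dict[str, list[StartCall]] = field(default_factory=dict)
    failed: dict[str, dict[str, str]] = field(default_factory=dict)
    regression: RegressionResult | None = None
    construct_summaries: pd.DataFrame | None = None
    pairwise: pd.DataFrame | None = None
    titration: pd.DataFrame | None = None


def _load_config(config: Mapping[str, Any] | str | Path) -> dict[str, Any]:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            doc = yaml.safe_load(fh)
        if not isinstance(doc, dict):
            raise PipelineError("config: file must be a YAML mapping")
        return doc
    return dict(config)


def _model_from_entry(entry: Mapping[str, Any], stage: str) -> PromoterModel:
    if "model" in entry and isinstance(entry["model"], Mapping):
        doc = entry["model"]
        try:
            return PromoterModel(
                subfamily=str(doc["subfamily"]),
                monomers=tuple(str(m).upper() for m in doc["monomers"]),
                tether=str(doc["tether"]).upper(),
                pattern_id=str(doc.get("pattern_id", "default")),
            )
        except Exception as exc:
            raise PipelineError(f"{stage}: invalid inline model: {exc}") from exc
    if "model" in entry:
        try:
            return load_model(entry["model"])
        except Exception as exc:
            raise PipelineError(f"{stage}: {exc}") from exc
    raise PipelineError(f"{stage}: pattern entry needs a 'model'")


def _census_workflow(
    cfg: Mapping[str, Any], outdir: Path, result: PipelineResult
) -> None:
    section = cfg.get("census")
    if not section:
        raise PipelineError("config: missing 'census' section")
    scoring = ScoringScheme(**section.get("scoring", {}))
    filt = FilterConfig(**section.get("filter", {}))
    total_monomers = int(section.get("total_monomers", 11))
    ages: list[tuple[float, float]] = []
    for entry in section.get("subfamilies", []):
        name = str(entry.get("name", "unnamed"))
        stage = f"census[{name}]"
        try:
            loci = read_fasta(entry["loci_fasta"])
        except KeyError as exc:
            raise PipelineError(f"{stage}: missing 'loci_fasta'") from exc
        except Exception as exc:
            raise PipelineError(f"{stage}: {exc}") from exc
        patterns = entry.get("patterns") or [
            {k: v for k, v in entry.items() if k in ("model", "hits")}
        ]
        all_calls: list[StartCall] = []
        failed: dict[str, str] = {}
        precedence: list[str] = []
        for pat in patterns:
            model = _model_from_entry(pat, stage)
            precedence.append(model.pattern_id)
            query = build_extended_query(model, total_monomers)
            if "hits" in pat:
                try:
                    hits = import_hits_tabular(pat["hits"])
                except Exception as exc:
                    raise PipelineError(f"{stage}: {exc}") from exc
            else:
                hits = []
                qname = f"{model.subfamily}|{model.pattern_id}"
                for locus_id, seq in loci:
                    hit = local_align(
                        query.sequence, seq, scoring,
                        qseqid=qname, sseqid=locus_id,
                    )
                    if hit is not None:
                        hits.append(hit)
            best, unaligned = best_hit_per_subject(hits)
            for locus_id in unaligned:
                failed.setdefault(locus_id, "unaligned")
            for locus_id, hit in sorted(best.items()):
                verdict = filter_hit(hit, query, filt)
                if verdict.passed:
                    all_calls.append(call_start(hit, query))
                else:
                    failed.setdefault(locus_id, verdict.reason or "filtered")
            for locus_id, _ in loci:
                if locus_id not in best and locus_id not in failed:
                    failed.setdefault(locus_id, "unaligned")
        configured = entry.get("pattern_precedence")
        if configured:
            precedence = [str(p) for p in configured]
        deduped = dedup_patterns(all_calls, precedence)
        passing_ids = {c.locus_id for c in deduped}
        failed = {k: v for k, v in failed.items() if k not in passing_ids}
        c = census(deduped, name, total_monomers)
        result.calls[name] = deduped
        result.failed[name] = failed
        result.censuses[name] = c
        write_calls_tsv(deduped, outdir / f"calls_{name}.tsv", failed)
        write_census_tsv(c, outdir / f"census_{name}.tsv")
        write_histograms_tsv(c, outdir / f"histograms_{name}.tsv")
        write_truncation_bed(deduped, outdir / f"truncation_{name}.bed")
        if "age_myr" in entry and c.n_averaged:
            ages.append((float(entry["age_myr"]), c.average_monomer_count))
    if len(ages) >= 3:
        result.regression = age_regression(ages)
        write_regression_tsv(result.regression, outdir / "regression.tsv")


def _luciferase_workflow(
    cfg: Mapping[str, Any], outdir: Path, result: PipelineResult
) -> None:
    section = cfg.get("luciferase")
    if not section:
        raise PipelineError("config: missing 'luciferase' section")
    try:
        plate = section["plate"]
        wells = (
            read_plate_table(plate)
            if isinstance(plate, (str, Path))
            else pd.DataFrame(plate)
        )
        control = str(section.get("control", "pLK037"))
        alpha = float(section.get("alpha", 0.05))
        wells, summaries = normalize_plate(wells, control)
        frame = summaries_to_frame(summaries)
        frame.to_csv(outdir / "construct_summaries.tsv", sep="\t", index=False)
        result.construct_summaries = frame
        groups = {
            str(k): g["normalized"].tolist()
            for k, g in wells.groupby("construct", sort=True)
        }
        if len(groups) >= 2 and min(len(v) for v in groups.values()) >= 2:
            tests = pairwise_tests(groups, alpha=alpha)
            tframe = pd.DataFrame(
                {
                    "construct_a": [t.construct_a for t in tests],
                    "construct_b": [t.construct_b for t in tests],
                    "raw_p": [t.raw_p for t in tests],
                    "adjusted_p": [t.adjusted_p for t in tests],
                    "significant": [t.significant for t in tests],
                }
            )
            tframe.to_csv(outdir / "pairwise_tests.tsv", sep="\t", index=False)
            result.pairwise = tframe
        if "dose_ng" in wells.columns and wells["dose_ng"].notna().any():
            tit = summarize_titration(
                wells, section.get("titration_fit_doses")
            )
            tit.per_dose.to_csv(outdir / "titration.tsv", sep="\t", index=False)
            tit.deviations.to_csv(
                outdir / "titration_deviations.tsv", sep="\t", index=False
            )
            result.titration = tit.per_dose
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError(f"luciferase: {exc}") from exc


def run_pipeline(
    config: Mapping[str, Any] | str | Path,
) -> PipelineResult:
    """Run one configured workflow and write its report bundle."""
    cfg = _load_config(config)
    workflow = cfg.get("workflow", "census")
    outdir = Path(cfg.get("output_dir", "l1utr_out"))
    outdir.mkdir(parents=True, exist_ok=True)
    result = PipelineResult(output_dir=outdir)
    if workflow == "census":
        _census_workflow(cfg, outdir, result)
    elif workflow == "luciferase":
        _luciferase_workflow(cfg, outdir, result)
    else:
        raise PipelineError(f"config: unknown workflow {workflow!r}")
    digest = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]
    with open(outdir / "run_log.txt", "w") as fh:
        fh.write(f"l1utr {__version__}\n")
        fh.write(f"python {sys.version.split()[0]}\n")
        fh.write(f"workflow {workflow}\n")
        fh.write(f"config_sha256 {digest}\n")
        fh.write(f"seed {cfg.get('seed', 1)}\n")
    return result
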