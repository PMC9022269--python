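"""Synthetic loci and reporter plates with known ground truth.

The locus generator emulates what the genome-wide census sees: each clean
locus is a 5'-truncated copy of an extended tandem-monomer promoter — the
truncation bin drawn from a categorical distribution over monomer slots, the
within-monomer breakpoint from a mixture of a uniform background and
single-nucleotide hotspots (defaults at offsets 83 and 86, the dominant
breakpoints observed for Tf and A monomers) — mutated with per-base
substitutions and small geometric-length indels.  A stated fraction of loci
lose >= 11 bp from the 3' end of the tether (guaranteed to fail the
tether-tail filter) and a further fraction are random-composition decoys.
Every locus comes with a truth record (class, bin, offset, fractional
monomer count) for recovery testing.

The plate generator encodes the reporter assay's design: a per-well
transfection efficiency multiplies Fluc and Rluc identically, so the
Fluc/Rluc ratio is the correct estimator of promoter strength; optional
dose series apply a shared Michaelis-style saturation factor to both
signals.  All outputs are byte-reproducible given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .promoter_model import ExtendedQuery, PromoterModel, build_extended_query

__all__ = [
    "LocusSimConfig",
    "PlateSimConfig",
    "SimulationError",
    "DEFAULT_BIN_PROBS",
    "DEFAULT_HOTSPOTS",
    "synthetic_promoter_model",
    "simulate_loci",
    "mutate_sequence",
    "simulate_plate",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


class SimulationError(ValueError):
    """Invalid simulation configuration."""


# Monomer-slot distribution loosely shaped like the young-subfamily census:
# a peak at the third monomer, a tail out to the open-ended top slot.
DEFAULT_BIN_PROBS: dict[int, float] = {
    1: 0.10, 2: 0.25, 3: 0.32, 4: 0.15, 5: 0.08, 6: 0.03,
    7: 0.03, 8: 0.015, 9: 0.01, 10: 0.005, 11: 0.01,
}

# (offset, weight) single-nucleotide truncation hotspots inside a monomer;
# the remainder of the mass is uniform over the monomer.  Offsets echo the
# dominant Tf (nt 83) and A (nt 86) breakpoints.
DEFAULT_HOTSPOTS: tuple[tuple[int, float], ...] = ((83, 0.17), (86, 0.10))


@dataclass(frozen=True)
class LocusSimConfig:
    """Configuration for the locus simulator."""

    model: PromoterModel
    n_loci: int = 500
    total_monomers: int = 11
    bin_probs: Mapping[int, float] = field(
        default_factory=lambda: dict(DEFAULT_BIN_PROBS)
    )
    hotspots: tuple[tuple[int, float], ...] = DEFAULT_HOTSPOTS
    substitution_rate: float = 0.01
    indel_rate: float = 0.0
    indel_length_p: float = 0.5
    fraction_tether_truncated: float = 0.0
    fraction_decoy: float = 0.0
    seed: int = 1

    def __post_init__(self) -> None:
        if self.n_loci < 1:
            raise SimulationError("n_loci must be >= 1")
        probs = dict(self.bin_probs)
        if any(p < 0 for p in probs.values()) or not math.isclose(
            sum(probs.values()), 1.0, abs_tol=1e-9
        ):
            raise SimulationError("bin_probs must be >= 0 and sum to 1")
        if any(not 1 <= b <= self.total_monomers for b in probs):
            raise SimulationError(
                f"bin_probs keys must lie in 1..{self.total_monomers}"
            )
        hot_w = sum(w for _, w in self.hotspots)
        if any(w < 0 for _, w in self.hotspots) or hot_w > 1.0 + 1e-9:
            raise SimulationError("hotspot weights must be >= 0, sum <= 1")
        for rate, name in (
            (self.substitution_rate, "substitution_rate"),
            (self.indel_rate, "indel_rate"),
        ):
            if not 0.0 <= rate < 1.0:
                raise SimulationError(f"{name} must be in [0, 1)")
        if not 0.0 < self.indel_length_p <= 1.0:
            raise SimulationError("indel_length_p must be in (0, 1]")
        for frac, name in (
            (self.fraction_tether_truncated, "fraction_tether_truncated"),
            (self.fraction_decoy, "fraction_decoy"),
        ):
            if not 0.0 <= frac <= 1.0:
                raise SimulationError(f"{name} must be in [0, 1]")
        if self.fraction_tether_truncated + self.fraction_decoy > 1.0:
            raise SimulationError("class fractions sum to more than 1")


@dataclass(frozen=True)
class PlateSimConfig:
    """Configuration for the reporter-plate simulator.

    ``strengths`` maps construct id to true promoter strength on the
    normalized scale, where the control's strength 1 is the assay
    background.  CVs are coefficients of variation of multiplicative
    log-normal factors.
    """

    strengths: Mapping[str, float]
    control: str = "pLK037"
    wells_per_construct: int = 4
    efficiency_cv: float = 0.15
    noise_cv: float = 0.10
    fluc_background: float = 135.0
    rluc_scale: float = 25000.0
    doses_ng: tuple[float, ...] | None = None
    saturation_K: float | None = None
    seed: int = 1

    def __post_init__(self) -> None:
        if self.control not in self.strengths:
            raise SimulationError(
                f"control construct {self.control!r} missing from strengths"
            )
        if any(s <= 0 for s in self.strengths.values()):
            raise SimulationError("strengths must be positive")
        if self.efficiency_cv < 0 or self.noise_cv < 0:
            raise SimulationError("CVs must be >= 0")
        if self.wells_per_construct < 1:
            raise SimulationError("wells_per_construct must be >= 1")
        if self.saturation_K is not None and self.saturation_K <= 0:
            raise SimulationError("saturation_K must be positive")


def synthetic_promoter_model(
    seed: int = 1,
    subfamily: str = "SimTf",
    n_monomers: int = 3,
    monomer_length: int = 212,
    tether_length: int = 205,
    divergence: float = 0.10,
    pattern_id: str = "default",
) -> PromoterModel:
    """A consensus-like promoter model with diverged tandem monomers.

    The 5'-most monomer is drawn uniformly over ACGT; each later monomer
    is a copy diverged by the stated per-base substitution fraction,
    mimicking the 77-97% pairwise identity of real monomer pairs.
    """
    rng = np.random.default_rng(seed)
    first = _random_dna(rng, monomer_length)
    monomers = [first]
    for _ in range(n_monomers - 1):
        monomers.append(_substitute(rng, monomers[-1], divergence))
    tether = _random_dna(rng, tether_length)
    return PromoterModel(
        subfamily=subfamily,
        monomers=tuple(monomers),
        tether=tether,
        pattern_id=pattern_id,
        notes=f"synthetic model, seed={seed}",
    )


def _random_dna(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode()


def _substitute(rng: np.random.Generator, seq: str, rate: float) -> str:
    """Substitute each base with probability ``rate``; always to a new base."""
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    mask = rng.random(arr.size) < rate
    idx = np.flatnonzero(mask)
    if idx.size:
        base_index = np.searchsorted(_BASES, arr[idx])
        shift = rng.integers(1, 4, size=idx.size)
        arr[idx] = _BASES[(base_index + shift) % 4]
    return arr.tobytes().decode()


def mutate_sequence(
    seq: str,
    substitution_rate: float,
    indel_rate: float = 0.0,
    indel_length_p: float = 0.5,
    rng: np.random.Generator | int | None = None,
) -> str:
    """Apply per-base substitutions and geometric-length indels.

    Substitutions always change the base.  With probability
    ``indel_rate/2`` per position a deletion of geometric length starts
    there; with the same probability an insertion of geometric length is
    placed before the position.  Reproducible given an integer seed or a
    seeded generator.
    """
    for rate, name in (
        (substitution_rate, "substitution_rate"),
        (indel_rate, "indel_rate"),
    ):
        if not 0.0 <= rate < 1.0:
            raise SimulationError(f"{name} must be in [0, 1)")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if indel_rate == 0.0:
        return _substitute(rng, seq, substitution_rate)
    out: list[str] = []
    i = 0
    n = len(seq)
    while i < n:
        u = rng.random()
        if u < indel_rate / 2.0:  # deletion
            i += int(rng.geometric(indel_length_p))
            continue
        if u < indel_rate:  # insertion before this base
            out.append(_random_dna(rng, int(rng.geometric(indel_length_p))))
        base = seq[i]
        if rng.random() < substitution_rate:
            k = int(np.searchsorted(_BASES, base.encode()))
            base = _BASES[(k + int(rng.integers(1, 4))) % 4].decode()
        out.append(base)
        i += 1
    return "".join(out)


def _draw_start(
    cfg: LocusSimConfig,
    query: ExtendedQuery,
    rng: np.random.Generator,
) -> tuple[str, int, float]:
    """Draw (bin label, offset, fractional count) for one clean locus."""
    bins = sorted(cfg.bin_probs)
    probs = np.array([cfg.bin_probs[b] for b in bins], dtype=float)
    probs /= probs.sum()
    index = int(rng.choice(bins, p=probs))
    label = f"M{index}"
    length = query.domain_length(label)
    hot = [(o, w) for o, w in cfg.hotspots if o <= length]
    u = rng.random()
    acc = 0.0
    offset = None
    for o, w in hot:
        acc += w
        if u < acc:
            offset = o
            break
    if offset is None:
        offset = int(rng.integers(1, length + 1))
    count = (index - 1) + (length - offset + 1) / length
    top = index == cfg.total_monomers
    return (
        f"M{cfg.total_monomers}+" if top else label,
        offset,
        count,
    )


def simulate_loci(
    cfg: LocusSimConfig,
) -> tuple[list[tuple[str, str]], pd.DataFrame]:
    """Generate locus sequences plus a ground-truth table.

    Returns ``(records, truth)`` where records are ``(id, sequence)``
    pairs and truth is a data frame with one row per locus: locus_id,
    true_class (clean / tether-truncated / decoy), true_bin, true_offset,
    true_monomer_count, length.  The decoy and tether-truncated counts
    are ``round(fraction * n_loci)``; remaining loci are clean.
    """
    rng = np.random.default_rng(cfg.seed)
    query = build_extended_query(cfg.model, cfg.total_monomers)
    n_decoy = int(round(cfg.fraction_decoy * cfg.n_loci))
    n_tt = int(round(cfg.fraction_tether_truncated * cfg.n_loci))
    n_tt = min(n_tt, cfg.n_loci - n_decoy)
    classes = (
        ["clean"] * (cfg.n_loci - n_decoy - n_tt)
        + ["tether-truncated"] * n_tt
        + ["decoy"] * n_decoy
    )
    width = len(str(cfg.n_loci))
    records: list[tuple[str, str]] = []
    rows = []
    for i, cls in enumerate(classes, start=1):
        locus_id = f"locus_{i:0{width}d}"
        label, offset, count = _draw_start(cfg, query, rng)
        # map through the real domain label even for the top bin
        domain = f"M{cfg.total_monomers}" if label.endswith("+") else label
        qstart = query.position_of(domain, offset)
        template = query.sequence[qstart - 1:]
        if cls == "decoy":
            seq = _random_dna(rng, len(template))
        else:
            if cls == "tether-truncated":
                chop = 11 + int(rng.integers(0, 20))
                template = template[:-chop]
            seq = mutate_sequence(
                template,
                cfg.substitution_rate,
                cfg.indel_rate,
                cfg.indel_length_p,
                rng,
            )
        records.append((locus_id, seq))
        rows.append(
            {
                "locus_id": locus_id,
                "true_class": cls,
                "true_bin": label if cls != "decoy" else "",
                "true_offset": offset if cls != "decoy" else -1,
                "true_monomer_count": count if cls != "decoy" else math.nan,
                "length": len(seq),
            }
        )
    return records, pd.DataFrame(rows)


def _lognormal_factor(
    rng: np.random.Generator, cv: float, size: int
) -> np.ndarray:
    """Mean-1 multiplicative log-normal noise with the given CV."""
    if cv == 0.0:
        return np.ones(size)
    sigma2 = math.log1p(cv * cv)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=math.sqrt(sigma2), size=size)


def simulate_plate(
    cfg: PlateSimConfig,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Simulate one reporter plate; returns (well table, truth strengths).

    Per well: ``rluc = E * rluc_scale * noise`` and
    ``fluc = E * fluc_background * strength * noise`` with independent
    noise factors, where E is the well's transfection efficiency.  With a
    dose series both signals are scaled by ``d`` (linear) or
    ``d*K/(K+d)`` (saturating), a common factor that cancels in the
    ratio.
    """
    rng = np.random.default_rng(cfg.seed)
    doses = list(cfg.doses_ng) if cfg.doses_ng else [None]
    rows = []
    counter = 0
    for construct, strength in cfg.strengths.items():
        for dose in doses:
            for _ in range(cfg.wells_per_construct):
                counter += 1
                eff = float(_lognormal_factor(rng, cfg.efficiency_cv, 1)[0])
                noise_f, noise_r = _lognormal_factor(rng, cfg.noise_cv, 2)
                if dose is None:
                    dose_factor = 1.0
                elif cfg.saturation_K is None:
                    dose_factor = float(dose)
                else:
                    dose_factor = float(
                        dose * cfg.saturation_K / (cfg.saturation_K + dose)
                    )
                row = {
                    "plate": "sim1",
                    "well": f"W{counter:03d}",
                    "construct": construct,
                    "fluc": cfg.fluc_background
                    * strength
                    * eff
                    * dose_factor
                    * float(noise_f),
                    "rluc": cfg.rluc_scale
                    * eff
                    * dose_factor
                    * float(noise_r),
                }
                if dose is not None:
                    row["dose_ng"] = float(dose)
                rows.append(row)
    return pd.DataFrame(rows), dict(cfg.strengths)
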