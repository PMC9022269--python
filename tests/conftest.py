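import numpy as np
import pytest

from l1utr.align import local_align
from l1utr.census import FilterConfig, call_start, filter_hit
from l1utr.promoter_model import PromoterModel, build_extended_query
from l1utr.simulate import synthetic_promoter_model

BASES = "ACGT"


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(BASES), size=length))


@pytest.fixture(scope="session")
def tf_like_model() -> PromoterModel:
    """A Tf-like model: 212 + 212 + 197 bp monomers, 205 bp tether."""
    rng = np.random.default_rng(2024)
    return PromoterModel(
        subfamily="Tf_sim",
        monomers=(
            random_dna(rng, 212),
            random_dna(rng, 212),
            random_dna(rng, 197),
        ),
        tether=random_dna(rng, 205),
    )


@pytest.fixture(scope="session")
def sim_model() -> PromoterModel:
    """Default synthetic consensus-like model used by the simulator."""
    return synthetic_promoter_model(seed=1)


def annotate_loci(records, model, total_monomers=11, cfg=FilterConfig()):
    """Mini-pipeline: align, filter, call; returns (calls, failures)."""
    query = build_extended_query(model, total_monomers)
    calls, failures = {}, {}
    for locus_id, seq in records:
        hit = local_align(query.sequence, seq, sseqid=locus_id)
        if hit is None:
            failures[locus_id] = "unaligned"
            continue
        verdict = filter_hit(hit, query, cfg)
        if not verdict.passed:
            failures[locus_id] = verdict.reason
            continue
        calls[locus_id] = call_start(hit, query)
    return calls, failures
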