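"""Promoter consensus models and extended tandem-monomer queries.

Mouse L1 5'UTRs are arrays of ~200-bp tandem repeats (monomers) joined to the
ORF1-proximal *tether* domain.  Genomic copies are 5'-truncated at variable
points inside the array, so the promoter of a locus is located by aligning it
against an *extended query*: the subfamily consensus whose 5'-most full
monomer has been duplicated until the array holds a fixed number of monomers
(11 by default), followed by the tether.  Monomer domains are labelled from
the 5' end as M11, M10, ..., M1, then T; M1 is adjacent to the tether.

A :class:`PromoterModel` stores the consensus *after* removal of any 5'
partial monomer, 5'-most full monomer first.  :func:`build_extended_query`
prepends copies of that monomer and records an exact position -> (domain,
offset) coordinate map, which downstream truncation calling relies on.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import yaml

__all__ = [
    "PromoterModel",
    "ExtendedQuery",
    "InvalidModelError",
    "build_extended_query",
    "map_query_position",
    "query_position_of",
    "load_model",
    "write_query_fasta",
]

_DNA = frozenset("ACGT")


class InvalidModelError(ValueError):
    """Raised for promoter models that violate their invariants."""


def _check_dna(seq: str, what: str) -> None:
    if not seq:
        raise InvalidModelError(f"{what} must be non-empty")
    bad = set(seq) - _DNA
    if bad:
        raise InvalidModelError(
            f"{what} contains non-ACGT characters: {sorted(bad)!r}"
        )


@dataclass(frozen=True)
class PromoterModel:
    """Consensus promoter structure for one subfamily / monomer pattern.

    Parameters
    ----------
    subfamily:
        Subfamily name, e.g. ``"Tf_I"``.
    monomers:
        Ordered monomer sequences, 5'-most full monomer first, the monomer
        adjacent to the tether last.  Lengths may differ (a 212-bp and a
        197-bp monomer can coexist in one model).
    tether:
        Non-monomeric sequence between the monomer array and ORF1.
    pattern_id:
        Monomer-organisation pattern for subfamilies with several (the Gf
        patterns I/II/IV); ``"default"`` otherwise.
    """

    subfamily: str
    monomers: tuple[str, ...]
    tether: str
    pattern_id: str = "default"
    notes: str = ""

    def __post_init__(self) -> None:
        if not self.subfamily:
            raise InvalidModelError("subfamily name must be non-empty")
        object.__setattr__(self, "monomers", tuple(self.monomers))
        if len(self.monomers) < 1:
            raise InvalidModelError("model needs at least one monomer")
        for i, m in enumerate(self.monomers):
            _check_dna(m, f"monomer {i + 1}")
        _check_dna(self.tether, "tether")

    @property
    def n_monomers(self) -> int:
        return len(self.monomers)


@dataclass(frozen=True)
class ExtendedQuery:
    """A tandem-monomer query sequence with its domain coordinate map.

    ``domains`` lists ``(label, length)`` pairs 5'->3': M{total}, ...,
    M1, T.  Every query position belongs to exactly one domain; offsets
    within a domain are 1-based and inclusive.
    """

    sequence: str
    domains: tuple[tuple[str, int], ...]
    total_monomers: int
    source_model: PromoterModel
    # cumulative end positions of each domain, for bisection
    _ends: tuple[int, ...] = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if sum(length for _, length in self.domains) != len(self.sequence):
            raise InvalidModelError("domain lengths do not sum to query length")
        ends, acc = [], 0
        for _, length in self.domains:
            acc += length
            ends.append(acc)
        object.__setattr__(self, "_ends", tuple(ends))

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def tether_length(self) -> int:
        return self.domains[-1][1]

    def domain_length(self, label: str) -> int:
        for lab, length in self.domains:
            if lab == label:
                return length
        raise KeyError(label)

    def map_position(self, pos: int) -> tuple[str, int]:
        """Return ``(domain label, 1-based offset)`` for a query position."""
        if not 1 <= pos <= len(self.sequence):
            raise IndexError(
                f"query position {pos} outside 1..{len(self.sequence)}"
            )
        i = bisect.bisect_left(self._ends, pos)
        start = 0 if i == 0 else self._ends[i - 1]
        return self.domains[i][0], pos - start

    def position_of(self, label: str, offset: int) -> int:
        """Inverse of :meth:`map_position`; round-trips exactly."""
        start = 0
        for (lab, length), end in zip(self.domains, self._ends):
            if lab == label:
                if not 1 <= offset <= length:
                    raise IndexError(
                        f"offset {offset} outside 1..{length} for domain {label}"
                    )
                return start + offset
            start = end
        raise KeyError(f"unknown domain label {label!r}")


def build_extended_query(
    model: PromoterModel, total_monomers: int = 11
) -> ExtendedQuery:
    """Duplicate the 5'-most full monomer to build the extended query.

    Copies of the model's 5'-most monomer are prepended until the array
    holds ``total_monomers`` monomers; the tether follows.  The supplied
    model must already have its 5' partial monomer removed.
    """
    k = model.n_monomers
    if total_monomers < k:
        raise ValueError(
            f"total_monomers={total_monomers} is fewer than the model's "
            f"{k} monomers"
        )
    n_extra = total_monomers - k
    monomers = (model.monomers[0],) * n_extra + model.monomers
    sequence = "".join(monomers) + model.tether
    labels = [f"M{total_monomers - i}" for i in range(total_monomers)]
    domains = tuple(
        [(lab, len(m)) for lab, m in zip(labels, monomers)]
        + [("T", len(model.tether))]
    )
    return ExtendedQuery(
        sequence=sequence,
        domains=domains,
        total_monomers=total_monomers,
        source_model=model,
    )


def map_query_position(query: ExtendedQuery, pos: int) -> tuple[str, int]:
    """Functional alias for :meth:`ExtendedQuery.map_position`."""
    return query.map_position(pos)


def query_position_of(query: ExtendedQuery, label: str, offset: int) -> int:
    """Functional alias for :meth:`ExtendedQuery.position_of`."""
    return query.position_of(label, offset)


def load_model(path: str | Path) -> PromoterModel:
    """Load a promoter model from a YAML file.

    Expected fields: ``subfamily``, optional ``pattern_id``, ``tether``,
    and either inline ``monomers`` (ordered list of sequences) or
    ``monomer_fasta`` (path, relative to the model file, whose records are
    taken in file order).
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, dict):
        raise InvalidModelError(f"{path}: model file must be a mapping")
    if "monomers" in doc:
        monomers = [str(m).upper() for m in doc["monomers"]]
    elif "monomer_fasta" in doc:
        from .io import read_fasta  # local import to avoid a cycle

        records = read_fasta(path.parent / doc["monomer_fasta"])
        monomers = [seq for _, seq in records]
    else:
        raise InvalidModelError(
            f"{path}: model file needs 'monomers' or 'monomer_fasta'"
        )
    try:
        return PromoterModel(
            subfamily=str(doc["subfamily"]),
            monomers=tuple(monomers),
            tether=str(doc["tether"]).upper(),
            pattern_id=str(doc.get("pattern_id", "default")),
            notes=str(doc.get("notes", "")),
        )
    except KeyError as exc:
        raise InvalidModelError(f"{path}: missing field {exc}") from exc


def write_query_fasta(query: ExtendedQuery, path: str | Path) -> None:
    """Export the extended query as FASTA for use with external aligners."""
    from .io import write_fasta

    name = f"{query.source_model.subfamily}|{query.source_model.pattern_id}" \
           f"|{query.total_monomers}mer"
    write_fasta([(name, query.sequence)], path)
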