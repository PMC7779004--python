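"""Core domain model: proteins, evidence channels, networks, gold standards.

Protein association evidence is organised in named *channels* (gene
neighborhood, gene fusion, phylogenetic co-occurrence, co-expression, lab
experiments, curated knowledge, text mining, plus a user-payload ``external``
channel). Every score is a probability in ``[0, 1]``; the 0-999 integer
encoding used by on-disk edge lists is purely an I/O dialect (see
:mod:`evinet.io`).

An edge connects two *distinct* canonical proteins and is unordered: the
record for ``(a, b)`` is the record for ``(b, a)``. Internally pairs are
canonicalised with the lexicographically smaller identifier first.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Set, Tuple

#: Closed enumeration of evidence channels.
CHANNELS: Tuple[str, ...] = (
    "neighborhood",
    "fusion",
    "cooccurrence",
    "coexpression",
    "experiments",
    "knowledge",
    "textmining",
    "external",
)

_CHANNEL_SET = frozenset(CHANNELS)

#: Assay-class flags on the experiments evidence of an edge.
ASSAY_CLASSES: Tuple[str, ...] = (
    "genetic_interference_only",
    "physical_capable",
    "unknown",
)


class DataError(ValueError):
    """Raised when user-supplied data violates a model invariant."""


def validate_protein_id(identifier: str) -> str:
    """Check that *identifier* is a non-empty token without whitespace."""
    if not isinstance(identifier, str) or not identifier:
        raise DataError(f"protein identifier must be a non-empty string, got {identifier!r}")
    if any(c.isspace() for c in identifier):
        raise DataError(f"protein identifier contains whitespace: {identifier!r}")
    return identifier


def validate_channel(channel: str) -> str:
    if channel not in _CHANNEL_SET:
        raise DataError(f"unknown evidence channel: {channel!r} (known: {', '.join(CHANNELS)})")
    return channel


def canonical_pair(a: str, b: str) -> Tuple[str, str]:
    """Return the unordered pair ``(a, b)`` in canonical (sorted) order.

    Raises :class:`DataError` for a self-pair: an association always
    connects two non-identical proteins.
    """
    validate_protein_id(a)
    validate_protein_id(b)
    if a == b:
        raise DataError(f"self-association not allowed: {a!r}")
    return (a, b) if a < b else (b, a)


def _validate_score(value: float, what: str) -> float:
    value = float(value)
    if not (0.0 <= value <= 1.0) or math.isnan(value):
        raise DataError(f"{what} must be a probability in [0, 1], got {value!r}")
    return value


@dataclass
class AssociationRecord:
    """One unordered protein pair with per-channel scores.

    Parameters
    ----------
    a, b
        Protein identifiers; stored in canonical order regardless of the
        order given.
    channel_scores
        Map from channel name to probability in ``[0, 1]``. Channels without
        evidence are simply absent.
    combined
        Integrated confidence, optional until computed.
    assay_class
        Provenance flag on the experiments evidence: whether the supporting
        assays can detect physical binding (``physical_capable``), are
        genetic-interference assays only (``genetic_interference_only``),
        or are of unknown class.
    """

    a: str
    b: str
    channel_scores: Dict[str, float] = field(default_factory=dict)
    combined: Optional[float] = None
    assay_class: str = "unknown"

    def __post_init__(self) -> None:
        self.a, self.b = canonical_pair(self.a, self.b)
        for channel, score in list(self.channel_scores.items()):
            validate_channel(channel)
            self.channel_scores[channel] = _validate_score(score, f"score for {channel}")
        if self.combined is not None:
            self.combined = _validate_score(self.combined, "combined score")
        if self.assay_class not in ASSAY_CLASSES:
            raise DataError(f"unknown assay class: {self.assay_class!r}")

    @property
    def pair(self) -> Tuple[str, str]:
        return (self.a, self.b)


class Network:
    """A simple undirected graph of association records.

    At most one record exists per unordered pair; endpoints are registered
    as proteins automatically. Isolated proteins may be added explicitly.
    """

    def __init__(self, edges: Iterable[AssociationRecord] = (), proteins: Iterable[str] = ()):
        self._edges: Dict[Tuple[str, str], AssociationRecord] = {}
        self.proteins: Set[str] = set()
        for p in proteins:
            self.proteins.add(validate_protein_id(p))
        for rec in edges:
            self.add_edge(rec)

    def add_edge(self, rec: AssociationRecord) -> None:
        if rec.pair in self._edges:
            raise DataError(f"duplicate edge for pair {rec.pair}")
        self._edges[rec.pair] = rec
        self.proteins.add(rec.a)
        self.proteins.add(rec.b)

    def edges(self) -> Iterator[AssociationRecord]:
        return iter(self._edges.values())

    def get(self, a: str, b: str) -> Optional[AssociationRecord]:
        return self._edges.get(canonical_pair(a, b))

    def n_edges(self) -> int:
        return len(self._edges)

    def __contains__(self, pair: Tuple[str, str]) -> bool:
        return canonical_pair(*pair) in self._edges

    def __len__(self) -> int:
        return len(self.proteins)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Network):
            return NotImplemented
        return self.proteins == other.proteins and self._edges == other._edges


class GoldStandard:
    """Curated protein complexes used to label pairs as true/false positives.

    A pair is *co-complexed* (a benchmark true positive) when some single
    complex contains both proteins — membership in two different complexes
    does not count. The *gold degree* of a protein is its degree in the
    co-complex graph: the number of distinct partners it shares at least
    one complex with.
    """

    def __init__(self, complexes: Mapping[str, Iterable[str]]):
        self.complexes: Dict[str, Set[str]] = {}
        for cid, members in complexes.items():
            member_set = {validate_protein_id(m) for m in members}
            if len(member_set) < 2:
                raise DataError(f"complex {cid!r} has fewer than 2 members")
            self.complexes[cid] = member_set
        # partner map on the co-complex graph (set union across complexes)
        self._partners: Dict[str, Set[str]] = {}
        for member_set in self.complexes.values():
            for p in member_set:
                self._partners.setdefault(p, set()).update(member_set - {p})

    @property
    def proteins(self) -> Set[str]:
        return set(self._partners)

    def __contains__(self, protein: str) -> bool:
        return protein in self._partners


def gold_degree(gold: GoldStandard, p: str) -> int:
    """Degree of *p* in the co-complex graph (0 if absent from the gold set).

    A partner appearing with *p* in several complexes is counted once.
    """
    return len(gold._partners.get(p, ()))


def co_complexed(gold: GoldStandard, a: str, b: str) -> bool:
    """True iff a single gold-standard complex contains both *a* and *b*."""
    if a == b:
        raise DataError(f"co_complexed is undefined for a self-pair: {a!r}")
    # the partner map is exactly the co-complex adjacency
    return b in gold._partners.get(a, ())


def edge_count_among(net: Network, subset: Set[str], min_combined: float = 0.0) -> int:
    """Count edges with both endpoints in *subset* and combined >= threshold.

    Every subset member must be a protein of the network; edges lacking a
    combined score are skipped.
    """
    missing = set(subset) - net.proteins
    if missing:
        raise DataError(f"subset proteins absent from the network: {sorted(missing)[:5]}")
    count = 0
    for rec in net.edges():
        if rec.a in subset and rec.b in subset:
            if rec.combined is not None and rec.combined >= min_combined:
                count += 1
    return count


@dataclass
class GeneSet:
    """A named set of proteins (a pathway, GO term, publication, cluster...)."""

    name: str
    description: str
    members: Set[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise DataError(f"gene set {self.name!r} is empty")
        self.members = {validate_protein_id(m) for m in self.members}


@dataclass
class AnnotationFramework:
    """A named collection of gene sets; set names are unique within it.

    Curated pathway collections and literature-derived publication sets are
    represented identically — framework size only matters for multiple
    testing.
    """

    name: str
    sets: List[GeneSet]

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        if len(names) != len(set(names)):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise DataError(f"duplicate set names in framework {self.name!r}: {dupes[:5]}")

    def __iter__(self) -> Iterator[GeneSet]:
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    @property
    def universe(self) -> Set[str]:
        out: Set[str] = set()
        for s in self.sets:
            out |= s.members
        return out


class RankedProfile:
    """Protein -> numeric value map (a study-specific measurement per protein)."""

    def __init__(self, entries: Mapping[str, float]):
        self.entries: Dict[str, float] = {}
        for p, v in entries.items():
            validate_protein_id(p)
            v = float(v)
            if not math.isfinite(v):
                raise DataError(f"non-finite value for protein {p!r}: {v!r}")
            self.entries[p] = v
        if len(self.entries) < 2:
            raise DataError("a ranked profile needs at least 2 proteins")

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, protein: str) -> bool:
        return protein in self.entries

    @property
    def proteins(self) -> Set[str]:
        return set(self.entries)


class CovariateTable:
    """Named per-protein covariates (abundance, length, publication count...)."""

    def __init__(self, covariates: Mapping[str, Mapping[str, float]]):
        self.covariates: Dict[str, Dict[str, float]] = {}
        for name, table in covariates.items():
            clean: Dict[str, float] = {}
            for p, v in table.items():
                validate_protein_id(p)
                v = float(v)
                if not math.isfinite(v):
                    raise DataError(f"non-finite covariate {name!r} for {p!r}")
                clean[p] = v
            self.covariates[name] = clean

    def names(self) -> List[str]:
        return list(self.covariates)

    def __getitem__(self, name: str) -> Dict[str, float]:
        return self.covariates[name]
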