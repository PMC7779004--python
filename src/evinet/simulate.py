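"""Seeded generators with known planted structure.

Every generator is a pure function of a :class:`SimulationSpec` (including
its seed): the same spec yields byte-identical outputs. Each generator also
returns a machine-readable manifest of the planted truth, so closed-loop
tests can assert recovery without re-deriving the ground truth.

What the defaults emulate
-------------------------
* ``simulate_network`` — a uniform simple graph G(n, m) (the null matching
  the closed-form expected edge count among uniform node subsets), with an
  optional planted clique and an optional preferential-attachment variant
  for degree-matched-null experiments.
* ``simulate_gold_and_scores`` — a gold standard of equally sized, disjoint
  complexes plus scored candidate pairs. Co-complex (true positive) pairs
  draw raw scores from Beta(2, 1) and cross-complex (false positive) pairs
  from Beta(1, 2); with equally many of each, the true precision at raw
  score ``s`` is exactly ``g(s) = s`` — the identity curve a calibration
  pipeline should recover.
* ``simulate_profile_and_sets`` — a genome-scale ranked profile with i.i.d.
  standard-normal background values; planted sets are shifted by the effect
  size in pooled-SD units (or split +/- for both-ends fixtures); decoy sets
  are uniform random draws.
* ``simulate_covariates`` — covariates with a requested Spearman correlation
  to the profile, generated through a Gaussian copula
  (``r = 2 sin(pi * rho / 6)`` converts the target rank correlation to the
  Pearson correlation of the underlying normals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Set, Tuple

import numpy as np

from .core import (
    AnnotationFramework,
    AssociationRecord,
    CovariateTable,
    DataError,
    GeneSet,
    GoldStandard,
    Network,
    RankedProfile,
)


def _default_covariate_biases() -> Dict[str, float]:
    # the five covariates conventionally screened for enrichment confounding;
    # gc_content is deliberately unbiased (the pure-noise control)
    return {
        "abundance": 0.5,
        "length": 0.3,
        "publications": 0.6,
        "disorder": 0.2,
        "gc_content": 0.0,
    }


@dataclass
class SimulationSpec:
    """All knobs of the generators; the seed drives every random draw."""

    seed: int = 0
    # network
    n_proteins: int = 200
    n_edges: int = 400
    planted_clique_size: int = 0
    preferential_attachment: bool = False
    # gold standard and scored candidate pairs
    n_complexes: int = 340
    complex_size: int = 6
    fp_ratio: float = 1.0  # false-positive candidate pairs per true-positive pair
    genetic_fraction: float = 0.0
    # ranked profile and gene sets
    profile_size: int = 2000
    planted_set_size: int = 20
    effect_size: float = 2.0
    n_decoy_sets: int = 50
    decoy_size_range: Tuple[int, int] = (10, 40)
    both_ends: bool = False
    # covariates: name -> target Spearman correlation with the profile
    covariate_biases: Dict[str, float] = field(default_factory=_default_covariate_biases)

    def __post_init__(self) -> None:
        if self.n_proteins < 2 or self.profile_size < 2:
            raise DataError("need at least 2 proteins")
        max_edges = self.n_proteins * (self.n_proteins - 1) // 2
        if self.n_edges > max_edges:
            raise DataError(f"{self.n_edges} edges exceed the {max_edges} possible pairs")
        if self.complex_size < 2:
            raise DataError("complexes need >= 2 members")
        if self.planted_set_size > self.profile_size:
            raise DataError("planted set larger than the profile")


def _protein_names(n: int, prefix: str = "P") -> List[str]:
    width = max(4, len(str(n - 1)))
    return [f"{prefix}{i:0{width}d}" for i in range(n)]


def _pair_from_index(idx: np.ndarray, n: int) -> Tuple[np.ndarray, np.ndarray]:
    """Map linear indices 0..n(n-1)/2-1 to (i, j) with i < j."""
    i = (np.floor((2 * n - 1 - np.sqrt((2 * n - 1) ** 2 - 8 * idx)) / 2)).astype(np.int64)
    j = (idx - i * (2 * n - 1 - i) // 2 + i + 1).astype(np.int64)
    return i, j


def simulate_network(spec: SimulationSpec) -> Tuple[Network, Dict]:
    """Uniform G(n, m) network with exactly ``n_edges`` edges.

    Combined scores are drawn uniformly in (0.4, 1.0), so every edge clears
    the conventional medium-confidence threshold. A planted clique (if
    requested) occupies the first ``planted_clique_size`` proteins; its
    edges count toward ``n_edges``. With ``preferential_attachment`` the
    random edges are grown with degree-proportional endpoint choice instead
    of uniformly. The manifest records the clique members.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_proteins
    names = _protein_names(n)
    edges: Set[Tuple[int, int]] = set()

    if spec.planted_clique_size:
        k = spec.planted_clique_size
        if k > n:
            raise DataError("clique larger than the network")
        clique = list(range(k))
        for x in range(k):
            for y in range(x + 1, k):
                edges.add((x, y))
        if len(edges) > spec.n_edges:
            raise DataError("planted clique alone exceeds the edge budget")
    else:
        clique = []

    if spec.preferential_attachment:
        degree = np.ones(n)
        while len(edges) < spec.n_edges:
            i, j = rng.choice(n, size=2, replace=False, p=degree / degree.sum())
            pair = (min(i, j), max(i, j))
            if pair not in edges:
                edges.add(pair)
                degree[i] += 1
                degree[j] += 1
    else:
        total = n * (n - 1) // 2
        # rejection loop: draw linear pair indices until the budget is met
        while len(edges) < spec.n_edges:
            need = spec.n_edges - len(edges)
            idx = rng.choice(total, size=min(total, 2 * need + 10), replace=False)
            ii, jj = _pair_from_index(idx.astype(np.float64), n)
            for x, y in zip(ii.tolist(), jj.tolist()):
                if len(edges) == spec.n_edges:
                    break
                edges.add((x, y))

    net = Network(proteins=names)
    for x, y in sorted(edges):
        combined = float(0.4 + 0.599 * rng.random())
        net.add_edge(AssociationRecord(names[x], names[y], combined=combined))
    manifest = {"clique_members": [names[i] for i in clique], "n_edges": len(edges)}
    return net, manifest


def simulate_gold_and_scores(
    spec: SimulationSpec,
) -> Tuple[GoldStandard, List[Tuple[Tuple[str, str], float]], Dict[Tuple[str, str], str], Dict]:
    """Gold-standard complexes plus scored candidate pairs with known precision.

    Returns ``(gold, [(pair, raw_score), ...], assay_flags, manifest)``.
    The manifest's ``true_precision`` callable gives the exact precision at
    any raw score (the identity under the default Beta mixture); a
    ``genetic_fraction`` of the candidate pairs is flagged
    ``genetic_interference_only``.
    """
    rng = np.random.default_rng(spec.seed + 1)
    n_members = spec.n_complexes * spec.complex_size
    if spec.n_complexes == 0:
        return GoldStandard({}), [], {}, {
            "n_tp_pairs": 0, "n_fp_pairs": 0,
            "true_precision": lambda s: float("nan"),
            "true_precision_name": "undefined",
        }
    names = _protein_names(n_members, prefix="G")
    complexes: Dict[str, List[str]] = {}
    membership = np.arange(n_members) // spec.complex_size
    for c in range(spec.n_complexes):
        complexes[f"C{c:04d}"] = [names[i] for i in np.flatnonzero(membership == c)]
    gold = GoldStandard(complexes)

    tp_pairs: List[Tuple[str, str]] = []
    for members in complexes.values():
        for x in range(len(members)):
            for y in range(x + 1, len(members)):
                a, b = members[x], members[y]
                tp_pairs.append((a, b) if a < b else (b, a))

    # cross-complex pairs exist only with >= 2 complexes
    n_fp = int(round(spec.fp_ratio * len(tp_pairs))) if spec.n_complexes >= 2 else 0
    fp_pairs: Set[Tuple[str, str]] = set()
    while len(fp_pairs) < n_fp:
        i, j = rng.integers(0, n_members, size=2)
        if i == j or membership[i] == membership[j]:
            continue
        a, b = names[i], names[j]
        fp_pairs.add((a, b) if a < b else (b, a))

    scored: List[Tuple[Tuple[str, str], float]] = []
    tp_scores = rng.beta(2.0, 1.0, size=len(tp_pairs))
    fp_scores = rng.beta(1.0, 2.0, size=len(fp_pairs))
    for pair, s in zip(tp_pairs, tp_scores):
        scored.append((pair, float(s)))
    for pair, s in zip(sorted(fp_pairs), fp_scores):
        scored.append((pair, float(s)))

    flags: Dict[Tuple[str, str], str] = {}
    genetic = rng.random(len(scored)) < spec.genetic_fraction
    for (pair, _), g in zip(scored, genetic):
        flags[pair] = "genetic_interference_only" if g else "physical_capable"

    fp_weight = spec.fp_ratio / (1.0 + spec.fp_ratio)

    def true_precision(s: float) -> float:
        # Beta(2,1) density 2s vs Beta(1,2) density 2(1-s), mixed by pair counts
        tp_mass = (1.0 - fp_weight) * 2.0 * s
        fp_mass = fp_weight * 2.0 * (1.0 - s)
        return tp_mass / (tp_mass + fp_mass)

    manifest = {
        "n_tp_pairs": len(tp_pairs),
        "n_fp_pairs": len(fp_pairs),
        "true_precision": true_precision,
        "true_precision_name": "identity" if spec.fp_ratio == 1.0 else "beta_mixture",
    }
    return gold, scored, flags, manifest


def simulate_profile_and_sets(
    spec: SimulationSpec,
) -> Tuple[AnnotationFramework, RankedProfile, Dict]:
    """Ranked profile with one planted gene set among uniform decoys.

    Background values are i.i.d. standard normal. The planted set is shifted
    by ``effect_size`` (in pooled SD units); with ``both_ends=True`` half
    the set is shifted up and half down instead, which a single-tail test
    should miss. The manifest names the planted set and its members.
    """
    rng = np.random.default_rng(spec.seed + 2)
    n = spec.profile_size
    names = _protein_names(n, prefix="Q")
    values = rng.standard_normal(n)

    planted_idx = rng.choice(n, size=spec.planted_set_size, replace=False)
    if spec.both_ends:
        half = spec.planted_set_size // 2
        values[planted_idx[:half]] += spec.effect_size
        values[planted_idx[half:]] -= spec.effect_size
    else:
        values[planted_idx] += spec.effect_size

    sets: List[GeneSet] = [
        GeneSet(
            name="planted_set",
            description=f"planted effect {spec.effect_size:+g}"
            + (" split both ends" if spec.both_ends else ""),
            members={names[i] for i in planted_idx},
        )
    ]
    lo, hi = spec.decoy_size_range
    for d in range(spec.n_decoy_sets):
        size = int(rng.integers(lo, hi + 1))
        members = {names[i] for i in rng.choice(n, size=size, replace=False)}
        sets.append(GeneSet(name=f"decoy_{d:03d}", description="uniform decoy", members=members))

    framework = AnnotationFramework(name="simulated", sets=sets)
    profile = RankedProfile(dict(zip(names, values.tolist())))
    manifest = {
        "planted_set": "planted_set",
        "planted_members": sorted(names[i] for i in planted_idx),
        "effect_size": spec.effect_size,
        "both_ends": spec.both_ends,
    }
    return framework, profile, manifest


def simulate_covariates(
    profile: RankedProfile, spec: SimulationSpec
) -> Tuple[CovariateTable, Dict]:
    """Covariates with requested Spearman correlation to the profile.

    For each ``(name, rho)`` in ``spec.covariate_biases`` a covariate is
    generated through a Gaussian copula on the profile's normal scores;
    ``rho = 1`` yields a monotone copy, ``rho = 0`` pure noise. A ``noise``
    control column is always appended.
    """
    rng = np.random.default_rng(spec.seed + 3)
    proteins = sorted(profile.entries)
    vals = np.array([profile.entries[p] for p in proteins])
    n = len(proteins)
    # normal scores of the profile ranks (ties broken deterministically)
    order = np.argsort(np.argsort(vals, kind="stable"), kind="stable")
    zscores = np.array(
        [float(x) for x in _normal_scores(n)]
    )[order]

    tables: Dict[str, Dict[str, float]] = {}
    for name, rho in spec.covariate_biases.items():
        rho = float(rho)
        if not (-1.0 <= rho <= 1.0):
            raise DataError(f"bias strength for {name!r} outside [-1, 1]")
        if abs(rho) == 1.0:
            cov = np.sign(rho) * zscores
        else:
            r = 2.0 * np.sin(np.pi * rho / 6.0)
            cov = r * zscores + np.sqrt(1.0 - r * r) * rng.standard_normal(n)
        tables[name] = dict(zip(proteins, cov.tolist()))
    tables["noise"] = dict(zip(proteins, rng.standard_normal(n).tolist()))
    manifest = {"target_rho": dict(spec.covariate_biases), "noise_column": "noise"}
    return CovariateTable(tables), manifest


def _normal_scores(n: int) -> np.ndarray:
    """Expected-normal-order-statistic approximation (Blom scores)."""
    from scipy import stats

    return stats.norm.ppf((np.arange(1, n + 1) - 0.375) / (n + 0.25))
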