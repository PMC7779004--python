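"""Over-representation analysis and whole-network interaction enrichment.

Gene-set over-representation uses the exact hypergeometric upper tail: with
a background of ``N`` proteins of which ``K`` carry the annotation, a query
of ``n`` background proteins containing ``k`` annotated ones scores

    p = P(X >= k),  X ~ Hypergeometric(N, K, n).

Every framework — curated pathways or millions of publication-derived sets —
is tested identically; framework size enters only through the
multiple-testing correction (Benjamini-Hochberg within each framework by
default, Bonferroni optionally).

The whole-network test asks whether a query set of proteins has more
interactions among themselves than random sets of the same size: the null
is uniform node subsets (optionally degree-weighted), and the p-value is a
permutation tail probability with add-one smoothing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from math import comb
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np
from statsmodels.stats.multitest import multipletests

from .core import AnnotationFramework, DataError, Network, edge_count_among

logger = logging.getLogger(__name__)


def hypergeom_upper(N: int, K: int, n: int, k: int) -> float:
    """Exact upper-tail hypergeometric probability P(X >= k).

    Computed as an integer-arithmetic tail sum (exact up to one float
    division), so tiny tails keep full precision.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise DataError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    if not (0 <= k <= min(K, n)):
        raise DataError(f"overlap k={k} outside [0, min(K={K}, n={n})]")
    if k == 0:
        return 1.0
    total = comb(N, n)
    tail = sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1))
    return tail / total


@dataclass
class OraResult:
    """One gene set's over-representation statistics."""

    framework: str
    set_name: str
    N: int  # background size
    K: int  # annotated proteins in background
    n: int  # query proteins in background
    k: int  # annotated query proteins
    p_value: float
    q_value: float = float("nan")


def _adjust(pvalues: Sequence[float], method: str) -> np.ndarray:
    if method == "bh":
        return multipletests(pvalues, method="fdr_bh")[1]
    if method == "bonferroni":
        return multipletests(pvalues, method="bonferroni")[1]
    raise DataError(f"unknown multiple-testing method: {method!r}")


def ora(
    framework: AnnotationFramework,
    query: Set[str],
    background: Optional[Set[str]] = None,
    method: str = "bh",
) -> List[OraResult]:
    """Test every set of a framework for over-representation in *query*.

    *background* defaults to all proteins annotated in the framework
    ("entire genome" semantics when the framework is genome-wide). Query
    proteins outside the background are dropped with a warning. Sets with
    zero overlap are reported with p = 1. Results are sorted by q then p,
    adjusted within this framework only.
    """
    if background is None:
        background = framework.universe
    dropped = query - background
    if dropped:
        logger.warning(
            "dropping %d query protein(s) absent from the background", len(dropped)
        )
    effective_query = query & background
    if not effective_query:
        raise DataError("query and background share no proteins")

    N = len(background)
    n = len(effective_query)
    results: List[OraResult] = []
    for gene_set in framework:
        members = gene_set.members & background
        K = len(members)
        k = len(members & effective_query)
        p = hypergeom_upper(N, K, n, k) if K > 0 else 1.0
        results.append(
            OraResult(
                framework=framework.name,
                set_name=gene_set.name,
                N=N,
                K=K,
                n=n,
                k=k,
                p_value=p,
            )
        )
    qvals = _adjust([r.p_value for r in results], method)
    for r, q in zip(results, qvals):
        r.q_value = float(q)
    results.sort(key=lambda r: (r.q_value, r.p_value, r.set_name))
    return results


@dataclass
class PpiEnrichmentResult:
    """Whole-network interaction-count enrichment for one query set."""

    observed: int
    expected: float  # mean edge count under the null
    p_value: float
    n_null: int
    seed: int
    null_counts: np.ndarray = field(repr=False, default=None)


def expected_edges_uniform(net: Network, subset_size: int, min_combined: float = 0.0) -> float:
    """Closed-form expected edge count among a uniform random node subset.

    Each of the ``m`` qualifying edges survives with probability
    ``k(k-1) / (n(n-1))``, giving ``m * k(k-1) / (n(n-1))``.
    """
    n = len(net.proteins)
    k = subset_size
    m = sum(
        1 for rec in net.edges() if rec.combined is not None and rec.combined >= min_combined
    )
    return m * k * (k - 1) / (n * (n - 1))


def ppi_enrichment(
    net: Network,
    query: Set[str],
    min_combined: float = 0.4,
    n_null: int = 1000,
    seed: int = 0,
    degree_matched: bool = False,
) -> PpiEnrichmentResult:
    """Test whether *query* contains more edges than same-size random subsets.

    The default null draws node subsets uniformly; ``degree_matched=True``
    draws nodes with probability proportional to degree instead (stricter
    for hub-rich queries). p is add-one smoothed: ``(1 + #{null >= obs}) /
    (n_null + 1)``.
    """
    if len(query) < 2:
        raise DataError("ppi enrichment needs a query of >= 2 proteins")
    observed = edge_count_among(net, query, min_combined)

    proteins = sorted(net.proteins)
    index = {p: i for i, p in enumerate(proteins)}
    n = len(proteins)
    k = len(query)
    qualifying = [
        rec for rec in net.edges() if rec.combined is not None and rec.combined >= min_combined
    ]
    u = np.array([index[rec.a] for rec in qualifying], dtype=np.intp)
    v = np.array([index[rec.b] for rec in qualifying], dtype=np.intp)

    rng = np.random.default_rng(seed)
    if degree_matched:
        degree = np.zeros(n)
        np.add.at(degree, u, 1.0)
        np.add.at(degree, v, 1.0)
        weights = degree + 1e-9  # keep isolated nodes drawable
        prob = weights / weights.sum()
    else:
        prob = None

    null_counts = np.empty(n_null, dtype=np.int64)
    mask = np.zeros(n, dtype=bool)
    for i in range(n_null):
        chosen = rng.choice(n, size=k, replace=False, p=prob)
        mask[:] = False
        mask[chosen] = True
        null_counts[i] = int(np.count_nonzero(mask[u] & mask[v]))
    p_value = (1 + int(np.count_nonzero(null_counts >= observed))) / (n_null + 1)
    return PpiEnrichmentResult(
        observed=observed,
        expected=float(null_counts.mean()),
        p_value=p_value,
        n_null=n_null,
        seed=seed,
        null_counts=null_counts,
    )
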