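"""Functional class scoring on ranked protein/value inputs.

These tests need no statistical background: the proteins of each gene set
are compared against the rest of the user's own ranked input. Three
statistics are provided:

* **Kolmogorov-Smirnov** — ``D`` is the supremum gap between the in-set and
  out-of-set empirical CDFs along the ranking (two-sided, or one-sided
  toward the top/bottom). Tied values are handled with mid-ranks: the ECDF
  gap is only evaluated where the sorted value actually changes, so a
  constant profile carries no ordering information and yields ``D = 0``.
* **Both-ends** — a set simultaneously enriched at the top *and* the bottom
  of the ranking (hence depleted in the middle). The in-set is split at its
  median value; each half is scored for outward skew against the rest of
  the profile with a normalized rank-sum statistic, and the both-ends
  statistic is the minimum of the two — large only when both halves skew
  outward. (A one-sided KS sup was rejected for this role: it saturates at
  ~0.5 for any half concentrated just above the median, so a compact
  middle set would masquerade as a both-ends signal.)
* **Aggregate fold change** — the mean of the in-set values, compared with
  size-matched random sets (exhaustive when the subset space is small,
  resampled otherwise).

All permutation p-values use the set-label null (random same-size subsets of
the input) with add-one smoothing, so they are never exactly zero. Because
this null depends only on the set size, null statistics are shared across
equally sized sets within one call.

The covariate bias report lives here because it shares the ranking
machinery: for each covariate (protein abundance, length, publication
count, predicted disorder, transcript GC content, ...) it reports the
Spearman correlation with the profile, a permutation p-value, and mean
covariate values within equal-size rank bins — a compact description of
systematic trends that can confound enrichment results.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from math import comb
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy import stats

from .core import AnnotationFramework, CovariateTable, DataError, GeneSet, RankedProfile
from .ora import _adjust

logger = logging.getLogger(__name__)

DIRECTIONS = ("high", "low", "both", "both_ends")


@dataclass
class FcsResult:
    """Rank-based enrichment statistics for one gene set."""

    set_name: str
    direction: str
    n_in: int
    ks_D: float
    p_ks: float
    afc_statistic: Optional[float] = None
    p_afc: Optional[float] = None
    q_value: float = float("nan")


class _RankedInput:
    """Profile sorted top (largest value) to bottom, with tie structure."""

    def __init__(self, profile: RankedProfile):
        items = sorted(profile.entries.items(), key=lambda kv: (-kv[1], kv[0]))
        self.proteins = [p for p, _ in items]
        self.values = np.array([v for _, v in items], dtype=float)
        self.position = {p: i for i, p in enumerate(self.proteins)}
        self.N = len(self.proteins)
        # evaluate ECDF gaps only at the last position of each tied block
        self.eval_mask = np.empty(self.N, dtype=bool)
        self.eval_mask[:-1] = self.values[:-1] != self.values[1:]
        self.eval_mask[-1] = True


def _ks_from_cumulative(
    cum_in: np.ndarray, m: int, N: int, eval_mask: np.ndarray, alternative: str
) -> np.ndarray:
    """KS statistic(s) from in-set cumulative counts along the ranking.

    ``cum_in`` has shape (..., N); returns shape (...,).
    """
    positions = np.arange(1, N + 1, dtype=float)
    diff = cum_in / m - (positions - cum_in) / (N - m)
    diff = diff[..., eval_mask]
    if alternative == "high":
        return diff.max(axis=-1)
    if alternative == "low":
        return (-diff).max(axis=-1)
    if alternative == "both":
        return np.abs(diff).max(axis=-1)
    raise DataError(f"unknown alternative: {alternative!r}")


def _membership_cumsum(position_sets: np.ndarray, N: int) -> np.ndarray:
    """Cumulative membership counts for rows of position indices.

    ``position_sets`` is (n_sets, m) of positions in 0..N-1; the result is
    (n_sets, N) with entry [s, t] = #(positions of set s <= t).
    """
    member = np.zeros((position_sets.shape[0], N), dtype=np.float64)
    rows = np.repeat(np.arange(position_sets.shape[0]), position_sets.shape[1])
    member[rows, position_sets.ravel()] = 1.0
    return np.cumsum(member, axis=1)


def ks_statistic(in_ranks: Set[int], N: int, alternative: str = "both") -> float:
    """KS statistic for an in-set given by distinct rank positions in 1..N.

    Rank 1 is the top of the list. ``alternative='both'`` is the classical
    two-sided ``sup |ECDF_in - ECDF_out|``; ``'high'``/``'low'`` are the
    one-sided versions toward either end.
    """
    ranks = sorted(in_ranks)
    m = len(ranks)
    if m == 0 or m >= N:
        raise DataError("in-set must be non-empty and a strict subset of 1..N")
    if ranks[0] < 1 or ranks[-1] > N or len(set(ranks)) != m:
        raise DataError("ranks must be distinct integers within 1..N")
    positions = np.array(ranks, dtype=np.intp) - 1
    cum_in = _membership_cumsum(positions[None, :], N)[0]
    eval_all = np.ones(N, dtype=bool)
    return float(_ks_from_cumulative(cum_in, m, N, eval_all, alternative))


def _random_position_sets(rng: np.random.Generator, n_sets: int, m: int, N: int) -> np.ndarray:
    """(n_sets, m) matrix of uniform random distinct positions in 0..N-1."""
    u = rng.random((n_sets, N))
    return np.argpartition(u, m - 1, axis=1)[:, :m]


class _NullCache:
    """Shared permutation nulls, keyed by statistic kind and set size."""

    def __init__(self, ranked: _RankedInput, n_perm: int, rng: np.random.Generator):
        self.ranked = ranked
        self.n_perm = n_perm
        self.rng = rng
        self._ks: Dict[Tuple[str, int], np.ndarray] = {}
        self._both_ends: Dict[int, np.ndarray] = {}
        self._afc: Dict[int, np.ndarray] = {}

    def ks(self, m: int, alternative: str) -> np.ndarray:
        key = (alternative, m)
        if key not in self._ks:
            pos = _random_position_sets(self.rng, self.n_perm, m, self.ranked.N)
            cum = _membership_cumsum(pos, self.ranked.N)
            self._ks[key] = _ks_from_cumulative(
                cum, m, self.ranked.N, self.ranked.eval_mask, alternative
            )
        return self._ks[key]

    def both_ends(self, m: int) -> np.ndarray:
        if m not in self._both_ends:
            pos = _random_position_sets(self.rng, self.n_perm, m, self.ranked.N)
            self._both_ends[m] = _both_ends_stat_rows(np.sort(pos, axis=1), self.ranked)
        return self._both_ends[m]

    def afc(self, m: int) -> np.ndarray:
        if m not in self._afc:
            pos = _random_position_sets(self.rng, self.n_perm, m, self.ranked.N)
            self._afc[m] = self.ranked.values[pos].mean(axis=1)
        return self._afc[m]


def _smoothed_p(null: np.ndarray, observed: float) -> float:
    return (1 + int(np.count_nonzero(null >= observed - 1e-12))) / (len(null) + 1)


def _both_ends_stat_rows(sorted_positions: np.ndarray, ranked: _RankedInput) -> np.ndarray:
    """Both-ends statistic for rows of sorted (ascending) position indices.

    Positions are ordered top to bottom, so the first half of each row holds
    the highest in-set values; the middle element of an odd-size set sits on
    the median and is dropped from both halves. Each half is scored for
    outward skew against the rest of the profile with the normalized
    rank-sum statistic ``A = U / (h * (N - h))`` (the probability that a
    half member outranks a random non-member, 1 = fully at its tail), and

        B = min(A_high_half_toward_top, A_low_half_toward_bottom).

    ``B`` is large only when *both* halves sit at their respective ends; a
    set concentrated in the middle ranks scores near 0.5, below the null.
    """
    m = sorted_positions.shape[1]
    half = m // 2
    if half < 2:
        raise DataError("both-ends testing needs an in-set of >= 4 proteins")
    N = ranked.N
    base = half * (N - 1 - half) + half * (half + 1) / 2.0
    denom = half * (N - half)
    u_high = base - sorted_positions[:, :half].sum(axis=1)
    # mirror the ranking for the low half: position p becomes N - 1 - p
    low = (N - 1) - sorted_positions[:, -half:]
    u_low = base - low.sum(axis=1)
    return np.minimum(u_high / denom, u_low / denom)


def _set_positions(members: Set[str], ranked: _RankedInput) -> np.ndarray:
    pos = sorted(ranked.position[p] for p in members if p in ranked.position)
    return np.array(pos, dtype=np.intp)


def both_ends_test(
    members: Set[str],
    profile: RankedProfile,
    n_perm: int = 999,
    seed: int = 0,
    set_name: str = "",
    _ranked: Optional[_RankedInput] = None,
    _cache: Optional[_NullCache] = None,
) -> FcsResult:
    """Test a set for simultaneous enrichment at both ends of the ranking."""
    ranked = _ranked if _ranked is not None else _RankedInput(profile)
    pos = _set_positions(members, ranked)
    m = len(pos)
    if m < 4:
        raise DataError(f"both-ends testing needs >= 4 profiled members, got {m}")
    if m >= ranked.N:
        raise DataError("in-set covers the whole profile")
    stat = float(_both_ends_stat_rows(pos[None, :], ranked)[0])
    cache = _cache if _cache is not None else _NullCache(ranked, n_perm, np.random.default_rng(seed))
    p = _smoothed_p(cache.both_ends(m), stat)
    return FcsResult(set_name=set_name, direction="both_ends", n_in=m, ks_D=stat, p_ks=p)


def aggregate_fold_change(
    members: Set[str],
    profile: RankedProfile,
    n_perm: int = 999,
    seed: int = 0,
    alternative: str = "greater",
    exhaustive_limit: int = 20000,
) -> Tuple[float, float]:
    """Mean in-set value against a size-matched random-set null.

    When the number of possible subsets is at most *exhaustive_limit* the
    null is enumerated completely and the p-value is the exact fraction of
    subsets with a mean at least as extreme (the observed set is one of
    them, so p is never 0 and no smoothing is applied); otherwise the null
    is resampled with add-one smoothing. ``alternative='two_sided'``
    doubles the smaller tail.
    """
    ranked = _RankedInput(profile)
    pos = _set_positions(members, ranked)
    m = len(pos)
    if m == 0:
        raise DataError("set has no profiled members")
    values = ranked.values
    observed = float(values[pos].mean())
    N = ranked.N

    if comb(N, m) <= exhaustive_limit:
        means = np.array([np.mean(values[list(c)]) for c in combinations(range(N), m)])
        p_up = float(np.count_nonzero(means >= observed - 1e-12)) / len(means)
        p_down = float(np.count_nonzero(means <= observed + 1e-12)) / len(means)
    else:
        rng = np.random.default_rng(seed)
        pos_null = _random_position_sets(rng, n_perm, m, N)
        means = values[pos_null].mean(axis=1)
        p_up = _smoothed_p(means, observed)
        p_down = (1 + int(np.count_nonzero(means <= observed + 1e-12))) / (n_perm + 1)

    if alternative == "greater":
        p = p_up
    elif alternative == "less":
        p = p_down
    elif alternative == "two_sided":
        p = min(1.0, 2.0 * min(p_up, p_down))
    else:
        raise DataError(f"unknown alternative: {alternative!r}")
    return observed, p


def fcs_test(
    framework: AnnotationFramework,
    profile: RankedProfile,
    direction: str = "both",
    n_perm: int = 999,
    seed: int = 0,
    min_set_size: int = 3,
    with_afc: bool = False,
    method: str = "permutation",
) -> List[FcsResult]:
    """Rank-based enrichment of every framework set within a ranked profile.

    Sets with fewer than *min_set_size* profiled members are skipped with a
    log entry (both-ends additionally needs 4). ``method='asymptotic'``
    replaces the permutation p with the classical two-sample KS
    approximation (not available for both-ends). q-values are
    Benjamini-Hochberg within this framework and direction.
    """
    if direction not in DIRECTIONS:
        raise DataError(f"direction must be one of {DIRECTIONS}")
    ranked = _RankedInput(profile)
    rng = np.random.default_rng(seed)
    cache = _NullCache(ranked, n_perm, rng)

    results: List[FcsResult] = []
    for gene_set in framework:
        pos = _set_positions(gene_set.members, ranked)
        m = len(pos)
        needed = max(min_set_size, 4 if direction == "both_ends" else min_set_size)
        if m < needed or m >= ranked.N:
            logger.info("skipping set %r: %d profiled member(s)", gene_set.name, m)
            continue
        if direction == "both_ends":
            res = both_ends_test(
                gene_set.members, profile, set_name=gene_set.name, _ranked=ranked, _cache=cache
            )
        else:
            cum = _membership_cumsum(pos[None, :], ranked.N)
            stat = float(_ks_from_cumulative(cum, m, ranked.N, ranked.eval_mask, direction)[0])
            if method == "asymptotic":
                # Smirnov asymptotics in the two-sample convention: finite-n
                # Kolmogorov distribution two-sided, Hodges' approximation
                # one-sided
                big, small = float(max(m, ranked.N - m)), float(min(m, ranked.N - m))
                en = big * small / (big + small)
                if direction == "both":
                    p = float(stats.kstwo.sf(stat, np.round(en)))
                else:
                    z = np.sqrt(en) * stat
                    expt = (-2 * z**2
                            - 2 * z * (big + 2 * small)
                            / np.sqrt(big * small * (big + small)) / 3.0)
                    p = float(np.exp(expt))
                p = min(1.0, max(np.finfo(float).tiny, p))
            else:
                p = _smoothed_p(cache.ks(m, direction), stat)
            res = FcsResult(
                set_name=gene_set.name, direction=direction, n_in=m, ks_D=stat, p_ks=p
            )
        if with_afc:
            afc_stat, p_afc = aggregate_fold_change(
                gene_set.members, profile, n_perm=n_perm, seed=seed, alternative="two_sided"
            )
            res.afc_statistic, res.p_afc = afc_stat, p_afc
        results.append(res)

    if results:
        qvals = _adjust([r.p_ks for r in results], "bh")
        for r, q in zip(results, qvals):
            r.q_value = float(q)
        results.sort(key=lambda r: (r.q_value, r.p_ks, r.set_name))
    return results


@dataclass
class BiasResult:
    """Trend of one covariate along the ranked input."""

    covariate: str
    n: int
    spearman_rho: float
    p_value: float
    degenerate: bool
    bin_value_means: List[float] = field(default_factory=list)
    bin_covariate_means: List[float] = field(default_factory=list)


def bias_report(
    profile: RankedProfile,
    covariates: CovariateTable,
    bins: int = 20,
    n_perm: int = 999,
    seed: int = 0,
) -> List[BiasResult]:
    """Per-covariate confounding diagnostics for a ranked input.

    For every covariate column: Spearman correlation with the profile over
    the shared proteins, a two-sided permutation p-value, and the mean
    profile value / covariate value within equal-size rank bins (top bin
    first). A constant covariate or profile slice is flagged degenerate and
    reported with rho = 0, p = 1.
    """
    rng = np.random.default_rng(seed)
    out: List[BiasResult] = []
    for name in covariates.names():
        table = covariates[name]
        shared = sorted(set(table) & profile.proteins)
        if len(shared) < 3:
            out.append(BiasResult(name, len(shared), 0.0, 1.0, True))
            continue
        prof_vals = np.array([profile.entries[p] for p in shared])
        cov_vals = np.array([table[p] for p in shared])
        order = np.argsort(-prof_vals, kind="stable")
        prof_sorted, cov_sorted = prof_vals[order], cov_vals[order]
        n_bins = min(bins, len(shared))
        bin_value_means = [float(chunk.mean()) for chunk in np.array_split(prof_sorted, n_bins)]
        bin_cov_means = [float(chunk.mean()) for chunk in np.array_split(cov_sorted, n_bins)]

        if np.ptp(prof_vals) == 0 or np.ptp(cov_vals) == 0:
            out.append(BiasResult(name, len(shared), 0.0, 1.0, True,
                                  bin_value_means, bin_cov_means))
            continue

        rho = float(stats.spearmanr(prof_vals, cov_vals).statistic)
        # permutation null on mid-ranks (Pearson on ranks == Spearman)
        r1 = stats.rankdata(prof_vals)
        r2 = stats.rankdata(cov_vals)
        z1 = (r1 - r1.mean()) / r1.std()
        z2 = (r2 - r2.mean()) / r2.std()
        n = len(shared)
        null = np.empty(n_perm)
        for i in range(n_perm):
            null[i] = z1 @ z2[rng.permutation(n)] / n
        p = (1 + int(np.count_nonzero(np.abs(null) >= abs(rho) - 1e-12))) / (n_perm + 1)
        out.append(BiasResult(name, n, rho, p, False, bin_value_means, bin_cov_means))
    return out


def plot_bias_report(results: Sequence[BiasResult], path: str) -> None:
    """Render the bias report as one panel per covariate (requires matplotlib)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    n = max(1, len(results))
    fig, axes = plt.subplots(1, n, figsize=(3.2 * n, 3.0), squeeze=False)
    for ax, res in zip(axes[0], results):
        ax.plot(range(1, len(res.bin_covariate_means) + 1), res.bin_covariate_means, "o-")
        ax.set_title(f"{res.covariate}\nrho={res.spearman_rho:.2f} p={res.p_value:.3g}")
        ax.set_xlabel("rank bin (top first)")
        ax.set_ylabel("mean covariate")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
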