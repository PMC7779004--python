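"""Hypergeometric ORA, BH behaviour, and network interaction enrichment."""

from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from evinet.core import AssociationRecord, DataError, GeneSet, Network
from evinet.ora import (
    expected_edges_uniform,
    hypergeom_upper,
    ora,
    ppi_enrichment,
)
from evinet.simulate import SimulationSpec, simulate_network

from conftest import make_framework


def enumeration_tail(N, K, n, k):
    """Brute-force P(X >= k) by enumerating every size-n draw."""
    annotated = set(range(K))
    hits = total = 0
    for draw in combinations(range(N), n):
        total += 1
        if len(annotated.intersection(draw)) >= k:
            hits += 1
    return hits / total


class TestHypergeomUpper:
    def test_spot_values_exact(self):
        assert hypergeom_upper(20, 5, 5, 5) == 1 / 15504
        assert hypergeom_upper(10, 4, 5, 3) == 66 / 252

    def test_zero_overlap_tail_is_one(self):
        assert hypergeom_upper(50, 10, 5, 0) == 1.0

    @pytest.mark.parametrize("N", [5, 8, 9])
    def test_matches_enumeration_small(self, N):
        for K in range(N + 1):
            for n in range(N + 1):
                for k in range(min(K, n) + 1):
                    expected = enumeration_tail(N, K, n, k)
                    assert hypergeom_upper(N, K, n, k) == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_scipy_survival_function(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            N = int(rng.integers(5, 200))
            K = int(rng.integers(0, N + 1))
            n = int(rng.integers(0, N + 1))
            k = int(rng.integers(0, min(K, n) + 1))
            ours = hypergeom_upper(N, K, n, k)
            ref = stats.hypergeom.sf(k - 1, N, K, n)
            assert ours == pytest.approx(ref, rel=1e-9, abs=1e-300)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(DataError):
            hypergeom_upper(10, 12, 5, 1)
        with pytest.raises(DataError):
            hypergeom_upper(10, 5, 5, 6)


class TestOra:
    def test_single_set_bh_is_identity(self):
        query = {f"Q{i}" for i in range(5)}
        background = query | {f"B{i}" for i in range(15)}
        fw = make_framework([("only", set(query))])
        (res,) = ora(fw, query, background=background)
        assert res.p_value == pytest.approx(1 / 15504)
        assert res.q_value == pytest.approx(res.p_value)
        assert (res.N, res.K, res.n, res.k) == (20, 5, 5, 5)

    def test_disjoint_query_all_p_one(self):
        fw = make_framework([("s1", {"A", "B"}), ("s2", {"C", "D"})])
        results = ora(fw, {"X", "Y"}, background={"A", "B", "C", "D", "X", "Y"})
        assert all(r.p_value == 1.0 for r in results)

    def test_duplicating_framework_weakly_increases_q(self):
        rng = np.random.default_rng(4)
        universe = [f"P{i}" for i in range(40)]
        sets = [
            (f"s{i}", set(rng.choice(universe, size=8, replace=False)))
            for i in range(6)
        ]
        query = set(rng.choice(universe, size=10, replace=False))
        single = ora(make_framework(sets), query, background=set(universe))
        doubled_sets = sets + [(f"{n}_copy", m) for n, m in sets]
        doubled = ora(make_framework(doubled_sets), query, background=set(universe))
        q_single = {r.set_name: r.q_value for r in single}
        q_doubled = {r.set_name: r.q_value for r in doubled}
        for name, q in q_single.items():
            assert q_doubled[name] >= q - 1e-12

    def test_query_outside_background_dropped(self, caplog):
        fw = make_framework([("s", {"A", "B"})])
        res = ora(fw, {"A", "ZZZ"}, background={"A", "B", "C"})
        assert res[0].n == 1

    def test_empty_effective_query_rejected(self):
        fw = make_framework([("s", {"A", "B"})])
        with pytest.raises(DataError):
            ora(fw, {"X"}, background={"A", "B"})

    def test_bonferroni_never_below_bh(self):
        rng = np.random.default_rng(5)
        universe = [f"P{i}" for i in range(30)]
        sets = [
            (f"s{i}", set(rng.choice(universe, size=6, replace=False))) for i in range(8)
        ]
        query = set(rng.choice(universe, size=8, replace=False))
        bh = ora(make_framework(sets), query, background=set(universe), method="bh")
        bonf = ora(make_framework(sets), query, background=set(universe), method="bonferroni")
        bh_q = {r.set_name: r.q_value for r in bh}
        for r in bonf:
            assert r.q_value >= bh_q[r.set_name] - 1e-12


class TestPpiEnrichment:
    def test_query_of_whole_network_p_one(self, triangle_network):
        res = ppi_enrichment(triangle_network, {"A", "B", "C"}, n_null=50, seed=1)
        assert res.p_value == 1.0
        assert res.observed == 3

    def test_small_query_rejected(self, triangle_network):
        with pytest.raises(DataError):
            ppi_enrichment(triangle_network, {"A"}, n_null=10, seed=1)

    def test_null_mean_matches_closed_form(self):
        """On G(10, 20) with size-5 subsets the expectation is 20*20/90."""
        spec = SimulationSpec(seed=3, n_proteins=10, n_edges=20)
        net, _ = simulate_network(spec)
        closed = expected_edges_uniform(net, 5, min_combined=0.0)
        assert closed == pytest.approx(20 * 20 / 90)
        query = set(sorted(net.proteins)[:5])
        res = ppi_enrichment(net, query, min_combined=0.0, n_null=4000, seed=9)
        mc_se = res.null_counts.std(ddof=1) / np.sqrt(len(res.null_counts))
        assert abs(res.expected - closed) <= 3 * mc_se

    def test_planted_clique_detected(self):
        spec = SimulationSpec(seed=5, n_proteins=200, n_edges=400, planted_clique_size=6)
        net, manifest = simulate_network(spec)
        clique = set(manifest["clique_members"])
        res = ppi_enrichment(net, clique, min_combined=0.4, n_null=1000, seed=11)
        assert res.observed == 15
        assert res.p_value <= 0.01

    def test_p_value_never_zero_and_smoothed(self, triangle_network):
        res = ppi_enrichment(triangle_network, {"A", "B"}, n_null=20, seed=2)
        assert res.p_value >= 1 / 21

    def test_degree_matched_null_is_stricter_for_hubs(self):
        spec = SimulationSpec(seed=8, n_proteins=100, n_edges=300, preferential_attachment=True)
        net, _ = simulate_network(spec)
        degree = {p: 0 for p in net.proteins}
        for rec in net.edges():
            degree[rec.a] += 1
            degree[rec.b] += 1
        hubs = set(sorted(degree, key=degree.get, reverse=True)[:10])
        uniform = ppi_enrichment(net, hubs, min_combined=0.0, n_null=500, seed=3)
        matched = ppi_enrichment(net, hubs, min_combined=0.0, n_null=500, seed=3,
                                 degree_matched=True)
        assert matched.expected > uniform.expected
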