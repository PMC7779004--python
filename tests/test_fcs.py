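"""Rank-based functional class scoring: KS, both-ends, AFC, bias report."""

import itertools

import numpy as np
import pytest

from evinet.core import CovariateTable, DataError, GeneSet, RankedProfile
from evinet.fcs import (
    aggregate_fold_change,
    bias_report,
    both_ends_test,
    fcs_test,
    ks_statistic,
)
from evinet.simulate import SimulationSpec, simulate_covariates, simulate_profile_and_sets

from conftest import make_framework


def brute_force_ks(in_ranks, N, alternative="both"):
    """Naive ECDF sup by recounting at every threshold."""
    m = len(in_ranks)
    best = -np.inf
    for t in range(1, N + 1):
        f_in = sum(1 for r in in_ranks if r <= t) / m
        f_out = (t - sum(1 for r in in_ranks if r <= t)) / (N - m)
        d = f_in - f_out
        if alternative == "both":
            d = abs(d)
        elif alternative == "low":
            d = -d
        best = max(best, d)
    return best


class TestKsStatistic:
    @pytest.mark.parametrize(
        "ranks,N,expected",
        [({1, 2}, 4, 1.0), ({1, 3}, 4, 0.5), ({2, 4}, 4, 0.5)],
    )
    def test_examples(self, ranks, N, expected):
        assert ks_statistic(ranks, N) == pytest.approx(expected)

    def test_interleaved_set_has_small_statistic(self):
        N = 1000
        ranks = set(range(1, N + 1, 2))
        assert ks_statistic(ranks, N) < 0.01

    def test_full_sweep_small_n_matches_brute_force(self):
        for N in range(2, 9):
            for m in range(1, N):
                for combo in itertools.combinations(range(1, N + 1), m):
                    got = ks_statistic(set(combo), N)
                    assert got == pytest.approx(brute_force_ks(set(combo), N), abs=1e-12)

    def test_randomized_matches_brute_force_up_to_50(self):
        rng = np.random.default_rng(11)
        for _ in range(150):
            N = int(rng.integers(5, 51))
            m = int(rng.integers(1, N))
            ranks = set(int(r) + 1 for r in rng.choice(N, size=m, replace=False))
            for alt in ("both", "high", "low"):
                assert ks_statistic(ranks, N, alt) == pytest.approx(
                    brute_force_ks(ranks, N, alt), abs=1e-12
                )

    def test_degenerate_sets_rejected(self):
        with pytest.raises(DataError):
            ks_statistic(set(), 5)
        with pytest.raises(DataError):
            ks_statistic({1, 2, 3}, 3)


class TestFcsTest:
    def test_planted_set_ranks_first(self):
        spec = SimulationSpec(seed=21)
        framework, profile, manifest = simulate_profile_and_sets(spec)
        # permutation resolution must support q < 0.05 after BH over 51 sets
        results = fcs_test(framework, profile, direction="high", n_perm=1999, seed=1)
        assert results[0].set_name == manifest["planted_set"]
        assert results[0].q_value < 0.05

    def test_constant_profile_carries_no_signal(self):
        names = [f"P{i}" for i in range(60)]
        profile = RankedProfile({p: 1.0 for p in names})
        fw = make_framework([("s", set(names[:10]))])
        (res,) = fcs_test(fw, profile, direction="both", n_perm=199, seed=2)
        assert res.ks_D == pytest.approx(0.0)
        assert res.p_ks == 1.0

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(13)
        names = [f"P{i}" for i in range(200)]
        vals = rng.standard_normal(200)
        fw = make_framework([("s", set(names[:15])), ("t", set(names[50:80]))])
        base = fcs_test(
            make_framework([("s", set(names[:15]))]),
            RankedProfile(dict(zip(names, vals))),
            direction="both", n_perm=199, seed=3,
        )
        transformed = fcs_test(
            make_framework([("s", set(names[:15]))]),
            RankedProfile(dict(zip(names, np.exp(vals) + 5))),
            direction="both", n_perm=199, seed=3,
        )
        assert base[0].ks_D == pytest.approx(transformed[0].ks_D, abs=1e-12)
        assert base[0].p_ks == transformed[0].p_ks

    def test_small_sets_skipped(self, null_profile):
        names = sorted(null_profile.proteins)
        fw = make_framework([("tiny", set(names[:2])), ("ok", set(names[:10]))])
        results = fcs_test(fw, null_profile, n_perm=99, seed=1)
        assert [r.set_name for r in results] == ["ok"]

    def test_permutation_p_never_zero(self, null_profile):
        names = sorted(null_profile.proteins)
        fw = make_framework([("top", set(names))])
        # a set at the extreme: take members from the top of the ranking
        ranked = sorted(null_profile.entries, key=null_profile.entries.get, reverse=True)
        fw = make_framework([("top", set(ranked[:20]))])
        (res,) = fcs_test(fw, null_profile, direction="high", n_perm=99, seed=1)
        assert res.p_ks >= 1 / 100

    def test_asymptotic_mode_matches_two_sample_ks(self, null_profile):
        """D and the asymptotic p agree with an independent two-sample KS."""
        from scipy import stats

        ranked = sorted(null_profile.entries, key=null_profile.entries.get, reverse=True)
        members = set(ranked[:10]) | set(ranked[500:525])
        fw = make_framework([("mix", members)])
        asym = fcs_test(fw, null_profile, direction="both", method="asymptotic")[0]
        in_vals = [null_profile.entries[p] for p in members]
        out_vals = [null_profile.entries[p] for p in null_profile.proteins - members]
        ref = stats.ks_2samp(in_vals, out_vals, method="asymp")
        assert asym.ks_D == pytest.approx(ref.statistic, abs=1e-12)
        assert asym.p_ks == pytest.approx(ref.pvalue, rel=1e-6)


class TestBothEnds:
    def test_extreme_both_ends_set_highly_significant(self, null_profile):
        ranked = sorted(null_profile.entries, key=null_profile.entries.get, reverse=True)
        members = set(ranked[:10]) | set(ranked[-10:])
        res = both_ends_test(members, null_profile, n_perm=999, seed=5)
        assert res.p_ks <= 0.001
        assert res.direction == "both_ends"

    def test_middle_set_not_significant(self, null_profile):
        ranked = sorted(null_profile.entries, key=null_profile.entries.get, reverse=True)
        mid = len(ranked) // 2
        members = set(ranked[mid - 10 : mid + 10])
        res = both_ends_test(members, null_profile, n_perm=499, seed=6)
        assert res.p_ks > 0.5

    def test_top_only_set_not_both_ends(self, null_profile):
        """A purely top-skewed set is caught by the high tail, not both-ends."""
        ranked = sorted(null_profile.entries, key=null_profile.entries.get, reverse=True)
        members = set(ranked[:20])
        be = both_ends_test(members, null_profile, n_perm=499, seed=7)
        fw = make_framework([("top", members)])
        high = fcs_test(fw, null_profile, direction="high", n_perm=499, seed=7)[0]
        assert high.p_ks <= 0.01
        assert be.p_ks > high.p_ks

    def test_too_small_set_rejected(self, null_profile):
        members = set(sorted(null_profile.proteins)[:3])
        with pytest.raises(DataError):
            both_ends_test(members, null_profile, n_perm=99, seed=1)


class TestAggregateFoldChange:
    def test_exhaustive_example(self):
        profile = RankedProfile({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        stat, p = aggregate_fold_change({"c", "d"}, profile, seed=1)
        assert stat == pytest.approx(3.5)
        assert p == pytest.approx(1 / 6)

    def test_whole_profile_p_one(self):
        profile = RankedProfile({"a": 1.0, "b": 2.0, "c": 3.0})
        stat, p = aggregate_fold_change({"a", "b", "c"}, profile, seed=1)
        assert stat == pytest.approx(2.0)
        assert p == 1.0

    def test_constant_profile_p_one(self):
        profile = RankedProfile({f"p{i}": 2.0 for i in range(6)})
        _, p = aggregate_fold_change({"p0", "p1"}, profile, seed=1)
        assert p == 1.0

    def test_monte_carlo_p_smoothed_never_zero(self, null_profile):
        ranked = sorted(null_profile.entries, key=null_profile.entries.get, reverse=True)
        _, p = aggregate_fold_change(set(ranked[:25]), null_profile, n_perm=99, seed=2)
        assert p >= 1 / 100

    def test_two_sided_doubles_smaller_tail(self):
        profile = RankedProfile({"a": 1.0, "b": 2.0, "c": 3.0, "d": 4.0})
        _, p = aggregate_fold_change({"c", "d"}, profile, alternative="two_sided", seed=1)
        assert p == pytest.approx(2 / 6)

    def test_empty_intersection_rejected(self, null_profile):
        with pytest.raises(DataError):
            aggregate_fold_change({"NOPE"}, null_profile, seed=1)


class TestBiasReport:
    def test_monotone_copy_has_rho_one(self):
        rng = np.random.default_rng(17)
        names = [f"P{i}" for i in range(300)]
        vals = rng.standard_normal(300)
        profile = RankedProfile(dict(zip(names, vals)))
        cov = CovariateTable({"copy": dict(zip(names, (2 * vals + 1).tolist()))})
        (res,) = bias_report(profile, cov, n_perm=199, seed=1)
        assert res.spearman_rho == pytest.approx(1.0)
        assert res.p_value <= 0.01
        assert not res.degenerate

    def test_constant_covariate_degenerate(self, null_profile):
        cov = CovariateTable({"const": {p: 5.0 for p in null_profile.proteins}})
        (res,) = bias_report(null_profile, cov, n_perm=99, seed=1)
        assert res.degenerate
        assert res.spearman_rho == 0.0
        assert res.p_value == 1.0

    def test_generated_bias_strength_recovered(self):
        spec = SimulationSpec(seed=23)
        _, profile, _ = simulate_profile_and_sets(spec)
        cov, manifest = simulate_covariates(profile, spec)
        results = {r.covariate: r for r in bias_report(profile, cov, n_perm=199, seed=2)}
        for name, rho in manifest["target_rho"].items():
            assert results[name].spearman_rho == pytest.approx(rho, abs=0.05)
        assert abs(results["noise"].spearman_rho) < 0.05

    def test_bin_means_trend_with_bias(self):
        spec = SimulationSpec(seed=29, covariate_biases={"strong": 0.9})
        _, profile, _ = simulate_profile_and_sets(spec)
        cov, _ = simulate_covariates(profile, spec)
        (res,) = [r for r in bias_report(profile, cov, bins=20, n_perm=99, seed=3)
                  if r.covariate == "strong"]
        assert len(res.bin_covariate_means) == 20
        # top bins (highest profile values) carry higher covariate means
        top = np.mean(res.bin_covariate_means[:5])
        bottom = np.mean(res.bin_covariate_means[-5:])
        assert top > bottom
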