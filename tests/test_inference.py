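import math
from itertools import combinations

import numpy as np
import pytest
from scipy import stats

from conftest import make_pairwise
from huttrial.inference import (
    InvalidSamplesError,
    compact_letter_display,
    conover_iman,
    kruskal_wallis,
    rank_sum_test,
)


def exact_rank_sum_oracle(a, b):
    """Brute-force two-sided rank-sum p over all label assignments."""
    pooled = list(a) + list(b)
    ranks = stats.rankdata(pooled)
    na, n = len(a), len(pooled)
    mu = na * (n + 1) / 2
    obs = abs(sum(ranks[:na]) - mu)
    hits = total = 0
    for combo in combinations(range(n), na):
        total += 1
        if abs(sum(ranks[i] for i in combo) - mu) >= obs - 1e-12:
            hits += 1
    return hits / total


def exact_kw_oracle(samples):
    """Brute-force permutation p of the tie-corrected H statistic."""
    labels = list(samples)
    sizes = [len(samples[g]) for g in labels]
    pooled = np.concatenate([np.asarray(samples[g], float) for g in labels])
    ranks = stats.rankdata(pooled)
    n = len(pooled)

    def h_of(groups):
        h = 12 / (n * (n + 1)) * sum(
            len(g) * (np.mean(g) - (n + 1) / 2) ** 2 for g in groups
        )
        _, t = np.unique(ranks, return_counts=True)
        c = 1 - (t**3 - t).sum() / (n**3 - n)
        return 0.0 if c <= 0 else h / c

    bounds = np.cumsum(sizes)[:-1]
    h_obs = h_of(np.split(ranks, bounds))

    def assignments(remaining, k):
        if k == len(sizes) - 1:
            yield (tuple(remaining),)
            return
        for combo in combinations(sorted(remaining), sizes[k]):
            for rest in assignments(sorted(set(remaining) - set(combo)), k + 1):
                yield (combo, *rest)

    hits = total = 0
    for part in assignments(list(range(n)), 0):
        total += 1
        if h_of([ranks[list(ix)] for ix in part]) >= h_obs - 1e-12:
            hits += 1
    return h_obs, hits / total


class TestKruskalWallis:
    def test_complete_ties_give_h_zero_p_one(self):
        res = kruskal_wallis({"a": [5, 5], "b": [5, 5], "c": [5]})
        assert res.statistic == 0.0 and res.p_value == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_scipy_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        samples = {
            g: rng.integers(0, 8, rng.integers(4, 12)).tolist()
            for g in "abcd"
        }
        res = kruskal_wallis(samples)
        ref = stats.kruskal(*samples.values())
        assert res.statistic == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-12)

    def test_exact_method_matches_permutation_oracle(self):
        samples = {"a": [1, 2, 3], "b": [4, 5, 6], "c": [7, 8, 9]}
        res = kruskal_wallis(samples, method="exact")
        h_ref, p_ref = exact_kw_oracle(samples)
        assert res.statistic == pytest.approx(h_ref, abs=1e-12)
        assert res.p_value == pytest.approx(p_ref, abs=1e-9)

    def test_two_groups_equal_squared_rank_sum_z(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=15).tolist()
        b = rng.normal(1.0, size=12).tolist()
        kw = kruskal_wallis({"a": a, "b": b})
        rs = rank_sum_test(a, b, exact_max_n=0)  # force normal approximation
        mu = len(a) * (len(a) + len(b) + 1) / 2
        pooled = stats.rankdata(a + b)
        var = len(a) * len(b) / 12 * (len(a) + len(b) + 1)
        z = (sum(pooled[: len(a)]) - mu) / math.sqrt(var)
        assert kw.statistic == pytest.approx(z * z, abs=1e-9)
        assert kw.p_value == pytest.approx(rs.p_value, abs=1e-9)

    def test_empty_group_rejected(self):
        with pytest.raises(InvalidSamplesError):
            kruskal_wallis({"a": [1, 2], "b": []})


class TestRankSum:
    def test_separated_triples_exact_p(self):
        # only 2 of the C(6,3)=20 rank splits are as extreme
        res = rank_sum_test([1, 2, 3], [4, 5, 6])
        assert res.p_value == pytest.approx(0.1, abs=1e-12)

    def test_identical_samples_give_p_one(self):
        assert rank_sum_test([2, 2, 3], [2, 2, 3]).p_value == 1.0

    def test_symmetric_in_sample_order(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 10, 20).tolist()
        b = rng.integers(2, 12, 25).tolist()
        assert rank_sum_test(a, b).p_value == pytest.approx(
            rank_sum_test(b, a).p_value, abs=1e-12
        )

    @pytest.mark.parametrize("transform", [
        lambda x: 2 * x + 1,
        lambda x: math.exp(x / 5),
        lambda x: x**3,
    ])
    def test_invariant_under_monotone_transforms(self, transform):
        rng = np.random.default_rng(2)
        a = rng.integers(-5, 6, 14).tolist()
        b = rng.integers(-3, 8, 17).tolist()
        base = rank_sum_test(a, b)
        mapped = rank_sum_test([transform(x) for x in a],
                               [transform(x) for x in b])
        assert mapped.p_value == pytest.approx(base.p_value, abs=1e-12)
        assert mapped.statistic == pytest.approx(base.statistic, abs=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(InvalidSamplesError):
            rank_sum_test([], [1])


class TestConoverIman:
    def test_identical_groups_nothing_significant(self):
        res = conover_iman({"a": [3, 3, 3], "b": [3, 3, 3], "c": [3, 3]})
        assert all(r.p_adjusted == 1.0 and not r.significant for r in res)

    def test_separation_pattern_matches_permutation_oracle(self):
        samples = {
            "low1": [1, 1, 2],
            "high": [10, 11, 12],
            "low2": [1, 2, 2],
        }
        res = {frozenset((r.group_a, r.group_b)): r
               for r in conover_iman(samples, alpha=0.05, bonferroni=False)}
        sig = {pair for pair, r in res.items() if r.significant}
        assert sig == {frozenset(("low1", "high")),
                       frozenset(("low2", "high"))}
        # with Bonferroni the slightly-less-extreme separated pair falls
        # just past alpha (hand arithmetic: t = 4/1.2472 = 3.207 on 6 df,
        # two-sided p = 0.01843, x3 = 0.0553)
        adj = {frozenset((r.group_a, r.group_b)): r
               for r in conover_iman(samples, alpha=0.05, bonferroni=True)}
        r = adj[frozenset(("low2", "high"))]
        assert r.p_adjusted == pytest.approx(0.05528, abs=1e-4)
        assert not r.significant
        assert adj[frozenset(("low1", "high"))].significant
        # permutation oracle: the pairs Conover-Iman flags are exactly
        # the completely separated ones (exact p at its 3v3 minimum of
        # 2/20), and the unflagged pair is thoroughly mixed
        for pair in res:
            g1, g2 = tuple(pair)
            p_exact = exact_rank_sum_oracle(samples[g1], samples[g2])
            if pair in sig:
                assert p_exact == pytest.approx(0.1, abs=1e-12)
            else:
                assert p_exact > 0.5

    def test_bonferroni_multiplies_by_pair_count(self):
        rng = np.random.default_rng(4)
        samples = {g: rng.normal(i, 1, 8).tolist()
                   for i, g in enumerate("abcde")}
        raw = conover_iman(samples, bonferroni=False)
        adj = conover_iman(samples, bonferroni=True)
        for r0, r1 in zip(raw, adj):
            assert r1.p_adjusted == pytest.approx(
                min(1.0, r0.p_value * 10), abs=1e-12
            )
            assert r0.p_adjusted == r0.p_value

    def test_statistic_follows_conover_iman_formula(self):
        # independent recomputation of one pairwise t from first principles
        samples = {"a": [1, 4, 2, 8], "b": [5, 7, 7, 3], "c": [9, 6, 10]}
        ranks = stats.rankdata(np.concatenate(
            [samples["a"], samples["b"], samples["c"]]))
        n, k = 11, 3
        h = stats.kruskal(*samples.values()).statistic
        s2 = (np.sum(ranks**2) - n * (n + 1) ** 2 / 4) / (n - 1)
        rbar_a, rbar_b = ranks[:4].mean(), ranks[4:8].mean()
        t_ref = (rbar_a - rbar_b) / math.sqrt(
            s2 * (n - 1 - h) / (n - k) * (1 / 4 + 1 / 4)
        )
        res = conover_iman(samples)
        r_ab = next(r for r in res if {r.group_a, r.group_b} == {"a", "b"})
        assert r_ab.statistic == pytest.approx(t_ref, abs=1e-9)
        assert r_ab.p_value == pytest.approx(
            2 * stats.t.sf(abs(t_ref), n - k), abs=1e-12
        )


def check_biconditional(pairwise, letters):
    for r in pairwise:
        shares = bool(set(letters[r.group_a]) & set(letters[r.group_b]))
        assert shares != r.significant, (
            f"{r.group_a}/{r.group_b}: significant={r.significant}, "
            f"letters {letters[r.group_a]}/{letters[r.group_b]}"
        )


class TestCompactLetterDisplay:
    def test_no_significance_single_letter(self):
        letters = compact_letter_display(make_pairwise(list("abcd"), []))
        assert set(letters.values()) == {"a"}

    def test_all_significant_distinct_letters(self):
        groups = list("abcd")
        pw = make_pairwise(groups, list(combinations(groups, 2)))
        letters = compact_letter_display(pw)
        assert sorted(letters.values()) == ["a", "b", "c", "d"]

    def test_five_arm_trial_pattern(self):
        # candidate and control each differ from everything; the three
        # reference nets are mutually indistinguishable
        groups = ["IG2", "Tsara", "PN2", "T-LLIN", "control"]
        sig = [("T-LLIN", g) for g in groups if g != "T-LLIN"]
        sig += [("control", g) for g in groups if g not in ("control", "T-LLIN")]
        pw = make_pairwise(groups, sig)
        letters = compact_letter_display(pw)
        assert letters == {
            "IG2": "a", "Tsara": "a", "PN2": "a", "T-LLIN": "b",
            "control": "c",
        }
        check_biconditional(pw, letters)

    def test_conflicting_duplicate_pair_rejected(self):
        pw = make_pairwise(["a", "b"], [("a", "b")])
        clone = pw[0].__class__(**{**pw[0].__dict__, "significant": False})
        with pytest.raises(ValueError, match="conflicting"):
            compact_letter_display(pw + [clone])

    def test_incomplete_pair_coverage_rejected(self):
        pw = make_pairwise(["a", "b", "c"], [])[:2]
        with pytest.raises(ValueError, match="incomplete"):
            compact_letter_display(pw)

    @pytest.mark.parametrize("seed", range(30))
    def test_biconditional_on_random_patterns(self, seed):
        rng = np.random.default_rng(seed)
        k = int(rng.integers(2, 9))
        groups = [f"g{i}" for i in range(k)]
        sig = [p for p in combinations(groups, 2) if rng.random() < 0.4]
        pw = make_pairwise(groups, sig)
        check_biconditional(pw, compact_letter_display(pw))
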