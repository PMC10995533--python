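"""Nonparametric inference for hut-trial count endpoints.

Nightly hut counts are overdispersed and far from normal, so arms are
compared with rank-based tests throughout: a Kruskal-Wallis test across
all arms, Conover-Iman rank comparisons between pairs of arms with
Bonferroni correction, and two-sample rank-sum (Wilcoxon/Mann-Whitney)
tests for head-to-head comparisons. Mid-ranks are used for ties and all
variance formulas carry the tie correction. Results are reported as a
compact letter display: two arms share a letter exactly when their
difference is not significant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy import stats


class InvalidSamplesError(ValueError):
    pass


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str


@dataclass(frozen=True)
class PairwiseResult:
    group_a: str
    group_b: str
    statistic: float
    p_value: float
    p_adjusted: float
    significant: bool


def _check_samples(samples: Mapping[str, Sequence[float]], min_groups: int = 2):
    if len(samples) < min_groups:
        raise InvalidSamplesError(f"need at least {min_groups} groups")
    for name, obs in samples.items():
        if len(obs) == 0:
            raise InvalidSamplesError(f"group {name!r} is empty")


def _pooled_ranks(samples: Mapping[str, Sequence[float]]):
    labels = list(samples)
    sizes = [len(samples[g]) for g in labels]
    pooled = np.concatenate([np.asarray(samples[g], float) for g in labels])
    ranks = stats.rankdata(pooled)  # mid-ranks
    split = np.split(ranks, np.cumsum(sizes)[:-1])
    return labels, sizes, pooled, ranks, split


def _h_statistic(ranks_by_group: list[np.ndarray], all_ranks: np.ndarray) -> float:
    """Tie-corrected Kruskal-Wallis H from pre-computed mid-ranks."""
    n = all_ranks.size
    h = 12.0 / (n * (n + 1)) * sum(
        r.size * (r.mean() - (n + 1) / 2.0) ** 2 for r in ranks_by_group
    )
    _, counts = np.unique(all_ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    denom = 1.0 - tie_term / (n**3 - n)
    if denom <= 0:  # every observation identical
        return 0.0
    return h / denom


def _group_index_partitions(sizes: Sequence[int]):
    """All ways to split indices 0..N-1 into ordered groups of given sizes."""
    n = sum(sizes)

    def rec(remaining: frozenset, k: int):
        if k == len(sizes) - 1:
            yield (tuple(sorted(remaining)),)
            return
        for combo in combinations(sorted(remaining), sizes[k]):
            for rest in rec(remaining - set(combo), k + 1):
                yield (combo, *rest)

    yield from rec(frozenset(range(n)), 0)


def kruskal_wallis(
    samples: Mapping[str, Sequence[float]], method: str = "chi2"
) -> TestResult:
    """Kruskal-Wallis H test across >= 2 groups.

    ``method="chi2"`` gives the usual chi-square approximation with k-1
    degrees of freedom; ``method="exact"`` enumerates every assignment
    of the pooled observations to groups of the observed sizes and
    returns the exact permutation p-value of H (feasible for small
    pooled n only).
    """
    _check_samples(samples)
    labels, sizes, _, ranks, split = _pooled_ranks(samples)
    n = int(ranks.size)
    if n < 3:
        raise InvalidSamplesError("need at least 3 observations in total")
    h = _h_statistic(split, ranks)
    if method == "chi2":
        if h == 0.0:
            return TestResult(0.0, 1.0, "kruskal-wallis chi2")
        p = float(stats.chi2.sf(h, len(labels) - 1))
        return TestResult(h, p, "kruskal-wallis chi2")
    if method == "exact":
        count = 0
        total = 0
        for part in _group_index_partitions(sizes):
            h_perm = _h_statistic([ranks[list(ix)] for ix in part], ranks)
            total += 1
            if h_perm >= h - 1e-12:
                count += 1
        return TestResult(h, count / total, "kruskal-wallis exact permutation")
    raise ValueError("method must be 'chi2' or 'exact'")


def conover_iman(
    samples: Mapping[str, Sequence[float]],
    alpha: float = 0.05,
    bonferroni: bool = True,
) -> list[PairwiseResult]:
    """Conover-Iman pairwise rank comparisons after Kruskal-Wallis.

    For groups i, j the statistic is

        t = (Rbar_i - Rbar_j) / sqrt(S^2 * (N-1-H)/(N-k) * (1/n_i + 1/n_j))

    where S^2 = (sum R^2 - N(N+1)^2/4) / (N-1) is the tie-corrected
    variance of the pooled mid-ranks and H the tie-corrected
    Kruskal-Wallis statistic; t is referred to Student's t with N-k
    degrees of freedom (two-sided). Bonferroni multiplies each p by the
    number of pairs, capped at 1.
    """
    _check_samples(samples)
    labels, sizes, _, ranks, split = _pooled_ranks(samples)
    n = int(ranks.size)
    k = len(labels)
    if n <= k:
        raise InvalidSamplesError("need more observations than groups")
    h = _h_statistic(split, ranks)
    s2 = (float(np.sum(ranks**2)) - n * (n + 1) ** 2 / 4.0) / (n - 1)
    scale = s2 * (n - 1.0 - h) / (n - k)
    df = n - k
    n_pairs = k * (k - 1) // 2
    means = {g: float(r.mean()) for g, r in zip(labels, split)}
    sizes_by = dict(zip(labels, sizes))

    results = []
    for a, b in combinations(labels, 2):
        diff = means[a] - means[b]
        se2 = scale * (1.0 / sizes_by[a] + 1.0 / sizes_by[b])
        if se2 <= 0:
            # degenerate: no residual rank variance (all ties, or H at its
            # maximum -> perfect separation of every group)
            t = 0.0 if diff == 0 else math.inf * np.sign(diff)
            p = 1.0 if diff == 0 else 0.0
        else:
            t = diff / math.sqrt(se2)
            p = 2.0 * float(stats.t.sf(abs(t), df))
        p_adj = min(1.0, p * n_pairs) if bonferroni else p
        results.append(
            PairwiseResult(
                group_a=a,
                group_b=b,
                statistic=float(t),
                p_value=min(p, 1.0),
                p_adjusted=p_adj,
                significant=p_adj < alpha,
            )
        )
    return results


def rank_sum_test(
    a: Sequence[float], b: Sequence[float], exact_max_n: int = 12
) -> TestResult:
    """Two-sided two-sample rank-sum (Wilcoxon/Mann-Whitney) test.

    Uses mid-ranks for ties. When the combined sample size is at most
    ``exact_max_n`` the exact conditional distribution of the rank sum
    given the observed (tied) ranks is enumerated; otherwise the normal
    approximation with tie-corrected variance is used (no continuity
    correction, so p-values are invariant under monotone transforms and
    under swapping the samples).
    """
    if len(a) == 0 or len(b) == 0:
        raise InvalidSamplesError("both samples must be non-empty")
    na, nb = len(a), len(b)
    n = na + nb
    pooled = np.concatenate([np.asarray(a, float), np.asarray(b, float)])
    ranks = stats.rankdata(pooled)
    w = float(ranks[:na].sum())
    mu = na * (n + 1) / 2.0
    if n <= exact_max_n:
        obs_dev = abs(w - mu)
        count = 0
        total = 0
        for combo in combinations(range(n), na):
            w_perm = float(ranks[list(combo)].sum())
            total += 1
            if abs(w_perm - mu) >= obs_dev - 1e-12:
                count += 1
        return TestResult(w, count / total, "rank-sum exact")
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts))
    var = na * nb / 12.0 * ((n + 1) - tie_term / (n * (n - 1.0)))
    if var <= 0:
        return TestResult(w, 1.0, "rank-sum normal")
    z = (w - mu) / math.sqrt(var)
    p = 2.0 * float(stats.norm.sf(abs(z)))
    return TestResult(w, min(p, 1.0), "rank-sum normal")


def compact_letter_display(
    pairwise: Sequence[PairwiseResult],
) -> dict[str, str]:
    """Assign significance letters by insert-and-absorb.

    Two groups share at least one letter if and only if their pairwise
    comparison is non-significant. Letters are a, b, c, ... in order of
    first use over groups taken in input order. Raises on incomplete or
    contradictory input (a pair listed twice with conflicting flags).
    """
    groups: list[str] = []
    for r in pairwise:
        for g in (r.group_a, r.group_b):
            if g not in groups:
                groups.append(g)
    sig: dict[frozenset, bool] = {}
    for r in pairwise:
        key = frozenset((r.group_a, r.group_b))
        if len(key) != 2:
            raise ValueError(f"self-comparison for group {r.group_a!r}")
        if key in sig and sig[key] != r.significant:
            raise ValueError(
                f"conflicting significance flags for pair {sorted(key)}"
            )
        sig[key] = r.significant
    expected = {frozenset(p) for p in combinations(groups, 2)}
    missing = expected - set(sig)
    if missing:
        raise ValueError(
            f"pairwise results incomplete: missing {sorted(map(sorted, missing))}"
        )

    # insert-and-absorb: start with one class holding everything; each
    # significant pair splits every class containing both members
    classes: list[set[str]] = [set(groups)]
    for pair, is_sig in sig.items():
        if not is_sig:
            continue
        x, y = tuple(pair)
        new_classes: list[set[str]] = []
        for cls in classes:
            if x in cls and y in cls:
                new_classes.append(cls - {x})
                new_classes.append(cls - {y})
            else:
                new_classes.append(cls)
        # absorb classes contained in another
        classes = [
            c
            for i, c in enumerate(new_classes)
            if c
            and not any(
                c < other or (c == other and i > j)
                for j, other in enumerate(new_classes)
            )
        ]

    order = {g: i for i, g in enumerate(groups)}
    classes.sort(key=lambda c: min(order[g] for g in c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {g: "" for g in groups}
    for i, cls in enumerate(classes):
        letter = alphabet[i % 26] * (i // 26 + 1)
        for g in groups:
            if g in cls:
                letters[g] += letter
    return letters
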