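"""Group-difference and environment-association tests.

ANOSIM (rank-based permutation test on a distance matrix), the Mantel test
(permutation correlation of two distance matrices), and one-way ANOVA with
Tukey's HSD and a compact letter display.

Permutation p-values use the (hits + 1)/(B + 1) convention for Monte-Carlo
runs and hits/N (identity included) for exact enumeration, so a reported p
is never 0. Small designs are enumerated exactly: ANOSIM whenever the number
of distinct label arrangements is at most 20 000 (3 groups of 3 gives
9!/(3!3!3!) = 1680), Mantel for n <= 7 samples (n! orderings).
"""

from __future__ import annotations

import dataclasses
import itertools
import warnings
from typing import Iterator, Mapping, Sequence

import numpy as np
from scipy import stats

from .datamodel import DistanceMatrix, TestResult, ValidationError

__all__ = ["anosim", "mantel", "anova_tukey", "TukeyTable", "assumption_checks"]

_EXACT_ANOSIM_LIMIT = 20_000


# ---------------------------------------------------------------------------
# combinatorics
# ---------------------------------------------------------------------------

def _n_arrangements(counts: Sequence[int]) -> int:
    """Distinct arrangements of a label multiset: n! / prod(n_g!)."""
    from math import factorial

    n = sum(counts)
    out = factorial(n)
    for c in counts:
        out //= factorial(c)
    return out


def _multiset_permutations(items: Sequence[int]) -> Iterator[tuple[int, ...]]:
    """All distinct permutations of a multiset, lexicographic order."""
    pool = sorted(items)

    def rec(remaining: list[int], prefix: list[int]) -> Iterator[tuple[int, ...]]:
        if not remaining:
            yield tuple(prefix)
            return
        prev = object()
        for k in range(len(remaining)):
            if remaining[k] == prev:
                continue
            prev = remaining[k]
            yield from rec(
                remaining[:k] + remaining[k + 1:], prefix + [remaining[k]]
            )

    return rec(pool, [])


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

def _anosim_r_batch(
    ranks: np.ndarray, labels: np.ndarray, iu: np.ndarray, ju: np.ndarray
) -> np.ndarray:
    """ANOSIM R for each row of ``labels`` (batch x n integer label matrix)."""
    within = labels[:, iu] == labels[:, ju]  # batch x M
    n_w = within.sum(axis=1)
    M = ranks.size
    sum_w = within @ ranks
    total = ranks.sum()
    mean_w = sum_w / n_w
    mean_b = (total - sum_w) / (M - n_w)
    return (mean_b - mean_w) / (M / 2.0)


def anosim(
    dm: DistanceMatrix,
    groups: Sequence[str],
    n_perm: int = 999,
    seed: int | None = None,
) -> TestResult:
    """Analysis of similarities across groups on a fixed distance matrix.

    R = (mean between-group rank - mean within-group rank) / (M/2) over the
    M = n(n-1)/2 pairwise distances, with average ranks for ties. The null
    permutes group labels over samples; arrangements are fully enumerated
    when feasible, otherwise ``n_perm`` Monte-Carlo draws are used.
    """
    groups = np.asarray([str(g) for g in groups])
    if groups.size != dm.n_samples:
        raise ValidationError("group labels do not match distance matrix samples")
    levels, codes = np.unique(groups, return_inverse=True)
    if levels.size < 2:
        raise ValidationError("anosim needs at least 2 groups")
    counts = np.bincount(codes)
    if counts.min() < 2:
        small = levels[int(np.argmin(counts))]
        raise ValidationError(f"group {small!r} has fewer than 2 samples")

    n = dm.n_samples
    iu, ju = np.triu_indices(n, k=1)
    cond = dm.d[iu, ju]
    if np.all(cond == cond[0]):
        warnings.warn("constant distance matrix: ANOSIM R is 0", stacklevel=2)
    ranks = stats.rankdata(cond)
    r_obs = float(_anosim_r_batch(ranks, codes[None, :], iu, ju)[0])

    n_arr = _n_arrangements(counts.tolist())
    if n_arr <= _EXACT_ANOSIM_LIMIT:
        perms = np.array(list(_multiset_permutations(codes.tolist())), dtype=int)
        r_perm = _anosim_r_batch(ranks, perms, iu, ju)
        p = float(np.count_nonzero(r_perm >= r_obs - 1e-12) / n_arr)
        return TestResult("anosim_r", r_obs, p, n_permutations=n_arr,
                          seed=seed, exact=True)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(codes) for _ in range(n_perm)])
    r_perm = _anosim_r_batch(ranks, perms, iu, ju)
    hits = int(np.count_nonzero(r_perm >= r_obs - 1e-12))
    p = (hits + 1) / (n_perm + 1)
    return TestResult("anosim_r", r_obs, p, n_permutations=n_perm,
                      seed=seed, exact=False)


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

def _condense_gather(d: np.ndarray, perms: np.ndarray,
                     iu: np.ndarray, ju: np.ndarray) -> np.ndarray:
    """Condensed distances of d after relabelling samples by each perm row."""
    return d[perms[:, iu], perms[:, ju]]


def mantel(
    dm_a: DistanceMatrix,
    dm_b: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
    method: str = "pearson",
    exact: bool | None = None,
) -> TestResult:
    """Mantel correlation between two distance matrices over the same samples.

    r is the correlation (Pearson by default, Spearman by flag) of the two
    condensed upper triangles; the one-sided "greater" p permutes the sample
    order of the first matrix. All n! orderings are enumerated when n <= 7
    (or ``exact=True``); otherwise ``n_perm`` Monte-Carlo permutations.
    """
    if dm_a.sample_ids != dm_b.sample_ids:
        raise ValidationError("mantel requires identical sample ids and order")
    n = dm_a.n_samples
    if n < 4:
        raise ValidationError("mantel needs at least 4 samples")
    iu, ju = np.triu_indices(n, k=1)
    a = dm_a.d
    b_cond = dm_b.d[iu, ju]
    if method == "spearman":
        # ranking the condensed vector commutes with sample relabelling,
        # so Spearman reduces to Pearson on a rank-transformed matrix
        a_rank = np.zeros_like(a)
        a_rank[iu, ju] = stats.rankdata(a[iu, ju])
        a = a_rank + a_rank.T
        b_cond = stats.rankdata(b_cond)
    elif method != "pearson":
        raise ValidationError(f"unknown correlation method {method!r}")
    a_cond = a[iu, ju]
    if np.std(a_cond) == 0 or np.std(b_cond) == 0:
        raise ValidationError("zero variance in a distance triangle: r undefined")

    bc = b_cond - b_cond.mean()
    bn = bc / np.linalg.norm(bc)

    def corr_batch(x: np.ndarray) -> np.ndarray:
        xc = x - x.mean(axis=1, keepdims=True)
        return (xc @ bn) / np.linalg.norm(xc, axis=1)

    r_obs = float(corr_batch(a_cond[None, :])[0])

    use_exact = exact if exact is not None else (n <= 7)
    if use_exact:
        perms = np.array(list(itertools.permutations(range(n))), dtype=int)
        r_perm = corr_batch(_condense_gather(a, perms, iu, ju))
        p = float(np.count_nonzero(r_perm >= r_obs - 1e-12) / len(perms))
        return TestResult("mantel_r", r_obs, p, n_permutations=len(perms),
                          seed=seed, exact=True)
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    r_perm = corr_batch(_condense_gather(a, perms, iu, ju))
    hits = int(np.count_nonzero(r_perm >= r_obs - 1e-12))
    p = (hits + 1) / (n_perm + 1)
    return TestResult("mantel_r", r_obs, p, n_permutations=n_perm,
                      seed=seed, exact=False)


# ---------------------------------------------------------------------------
# one-way ANOVA + Tukey HSD + compact letter display
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class TukeyTable:
    """One-way ANOVA with Tukey HSD pairwise comparisons and letters.

    Groups sharing a letter are not significantly different at ``alpha``.
    """

    groups: tuple[str, ...]
    means: np.ndarray
    letters: tuple[str, ...]
    pairwise_p: Mapping[tuple[str, str], float]
    alpha: float
    anova: TestResult

    def letter_of(self, group: str) -> str:
        return self.letters[self.groups.index(group)]


def _compact_letter_display(
    groups: Sequence[str],
    means: np.ndarray,
    pairwise_p: Mapping[tuple[str, str], float],
    alpha: float,
) -> tuple[str, ...]:
    """Insert-and-absorb letter assignment over the significance graph."""
    order = sorted(range(len(groups)), key=lambda i: -means[i])

    def sig(i: int, j: int) -> bool:
        key = (groups[i], groups[j]) if (groups[i], groups[j]) in pairwise_p \
            else (groups[j], groups[i])
        return pairwise_p[key] <= alpha

    sets: list[set[int]] = [set(order)]
    for ai in range(len(order)):
        for aj in range(ai + 1, len(order)):
            i, j = order[ai], order[aj]
            if not sig(i, j):
                continue
            for s in [s for s in sets if i in s and j in s]:
                sets.remove(s)
                s1, s2 = s - {i}, s - {j}
                for cand in (s1, s2):
                    if not any(cand <= other for other in sets):
                        sets.append(cand)
            sets = [s for s in sets if not any(
                s < other for other in sets)]
    # letter columns ordered by the best-ranked (highest-mean) member
    rank = {g: k for k, g in enumerate(order)}
    sets.sort(key=lambda s: min(rank[i] for i in s) if s else len(order))
    letters = ["" for _ in groups]
    for k, s in enumerate(sets):
        ch = chr(ord("a") + k)
        for i in s:
            letters[i] += ch
    return tuple("".join(sorted(l)) for l in letters)


def anova_tukey(
    values: Sequence[float],
    groups: Sequence[str],
    alpha: float = 0.05,
) -> TukeyTable:
    """One-way ANOVA with Tukey's HSD and compact letter display.

    Pairwise p-values come from the studentized range distribution with the
    Tukey-Kramer standard error, so unequal group sizes are handled.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray([str(x) for x in groups])
    if v.size != g.size:
        raise ValidationError("values and groups differ in length")
    if not np.all(np.isfinite(v)):
        raise ValidationError("non-finite value")
    levels = []
    for x in g:
        if x not in levels:
            levels.append(x)
    if len(levels) < 2:
        raise ValidationError("anova needs at least 2 groups")
    samples = [v[g == lev] for lev in levels]
    ns = np.array([len(s) for s in samples])
    if ns.min() < 2:
        raise ValidationError("every group needs at least 2 observations")
    means = np.array([s.mean() for s in samples])
    k = len(levels)
    N = int(ns.sum())
    df_w = N - k
    mse = sum(((s - s.mean()) ** 2).sum() for s in samples) / df_w

    eps = float(np.finfo(float).eps)
    if mse == 0.0:
        if np.allclose(means, means[0]):
            f_stat, p_f = 0.0, 1.0
        else:
            warnings.warn(
                "zero within-group variance with unequal means: "
                "p bounded at machine epsilon", stacklevel=2)
            f_stat, p_f = float("inf"), eps
        pairwise = {}
        for i in range(k):
            for j in range(i + 1, k):
                pairwise[(levels[i], levels[j])] = (
                    1.0 if means[i] == means[j] else eps
                )
    else:
        f_stat, p_f = stats.f_oneway(*samples)
        f_stat = float(f_stat)
        p_f = float(max(p_f, eps))
        if f_stat == 0.0:
            p_f = 1.0
        pairwise = {}
        for i in range(k):
            for j in range(i + 1, k):
                se = np.sqrt(mse / 2.0 * (1.0 / ns[i] + 1.0 / ns[j]))
                q = abs(means[i] - means[j]) / se
                p = float(stats.studentized_range.sf(q, k, df_w))
                pairwise[(levels[i], levels[j])] = min(max(p, eps), 1.0)

    letters = _compact_letter_display(levels, means, pairwise, alpha)
    return TukeyTable(
        groups=tuple(levels),
        means=means,
        letters=letters,
        pairwise_p=pairwise,
        alpha=alpha,
        anova=TestResult("anova_f", f_stat, p_f, n_permutations=0, exact=False),
    )


def assumption_checks(
    values: Sequence[float], groups: Sequence[str]
) -> dict[str, float]:
    """Advisory Shapiro-Wilk (on residuals) and Levene p-values.

    Purely informational; never gates the ANOVA.
    """
    v = np.asarray(values, dtype=float)
    g = np.asarray([str(x) for x in groups])
    levels = np.unique(g)
    samples = [v[g == lev] for lev in levels]
    resid = np.concatenate([s - s.mean() for s in samples])
    out: dict[str, float] = {}
    try:
        out["shapiro_p"] = float(stats.shapiro(resid).pvalue)
    except ValueError:
        out["shapiro_p"] = float("nan")
    try:
        out["levene_p"] = float(stats.levene(*samples).pvalue)
    except ValueError:
        out["levene_p"] = float("nan")
    return out
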