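"""Rank and permutation statistics with deterministic tie handling.

Every test used by the analysis is implemented here directly rather than
delegated, so the tie conventions and p-value routes are explicit and
stable:

* Mann-Whitney U: pairwise counting with 0.5 per cross-group tied pair,
  exact p by enumeration of the null U distribution when the data are
  tie-free and ``n1*n2`` is small, otherwise a normal approximation with
  tie and continuity corrections (the convention of R's ``wilcox.test``).
* Kruskal-Wallis H with midrank tie correction, chi-squared reference.
* Spearman rho as the Pearson correlation of midranks, reported together
  with the S statistic ``S = (1 - rho) * (n^3 - n) / 6`` so printed
  (S, rho) pairs can be checked against each other.
* A seeded chi-squared permutation test of independence for pairs of
  categorical labellings.

The SciPy equivalents serve as independent cross-checks in the test
suite; they are never called here.
"""

from __future__ import annotations

import logging
from functools import lru_cache
from itertools import combinations
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import distributions

from .core import TestResult, TraitTable

__all__ = [
    "midranks",
    "mann_whitney",
    "kruskal_wallis",
    "spearman",
    "rho_from_S",
    "chisq_permutation",
    "run_trait_contrasts",
]

log = logging.getLogger(__name__)

_EXACT_MAX_PRODUCT = 2500


def midranks(values: Sequence[float]) -> np.ndarray:
    """Ranks 1..n with tied values sharing their average (mid) rank."""
    a = np.asarray(values, dtype=float)
    order = np.argsort(a, kind="mergesort")
    ranks = np.empty(len(a), dtype=float)
    i = 0
    sorted_a = a[order]
    while i < len(a):
        j = i
        while j + 1 < len(a) and sorted_a[j + 1] == sorted_a[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


@lru_cache(maxsize=128)
def _u_null_counts(n1: int, n2: int) -> tuple[int, ...]:
    """Number of rank arrangements giving each U value, tie-free null.

    Built from the generating function prod_{j=1..n1} (1-q^(n2+j))/(1-q^j),
    whose coefficient of q^u counts arrangements with U = u.
    """
    max_u = n1 * n2
    poly = np.zeros(max_u + 1, dtype=object)
    poly[0] = 1
    for j in range(1, n1 + 1):
        # multiply by (1 - q^(n2+j))
        if n2 + j <= max_u:
            poly[n2 + j :] = poly[n2 + j :] - poly[: max_u + 1 - (n2 + j)]
        # divide by (1 - q^j): cumulative sum with stride j
        for u in range(j, max_u + 1):
            poly[u] = poly[u] + poly[u - j]
    return tuple(int(c) for c in poly)


def _exact_two_sided_p(u: float, n1: int, n2: int) -> float:
    counts = np.array(_u_null_counts(n1, n2), dtype=float)
    total = counts.sum()
    lo = counts[: int(u) + 1].sum() / total          # P(U <= u)
    hi = counts[int(u):].sum() / total               # P(U >= u)
    return float(min(1.0, 2.0 * min(lo, hi)))


def mann_whitney(
    x: Sequence[float], y: Sequence[float], alternative: str = "two_sided"
) -> TestResult:
    """Mann-Whitney U test of identical distributions for two samples.

    ``U_x`` counts pairs where x exceeds y, with each cross-group tie
    contributing 0.5; ``U_y = n1*n2 - U_x``.  All three of U_x, U_y and
    their minimum are reported, because published accounts quote either
    member of the pair.
    """
    if alternative not in ("two_sided", "less", "greater"):
        raise ValueError(f"unknown alternative {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both groups must be non-empty")

    pooled = np.concatenate([x, y])
    ranks = midranks(pooled)
    rank_sum_x = float(ranks[:n1].sum())
    u_x = rank_sum_x - n1 * (n1 + 1) / 2.0
    u_y = n1 * n2 - u_x

    _, tie_counts = np.unique(pooled, return_counts=True)
    has_ties = bool((tie_counts > 1).any())

    n = n1 + n2
    mean_u = n1 * n2 / 2.0
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term)

    if not has_ties and n1 * n2 <= _EXACT_MAX_PRODUCT:
        p_method = "exact"
        if alternative == "two_sided":
            p = _exact_two_sided_p(u_x, n1, n2)
        else:
            counts = np.array(_u_null_counts(n1, n2), dtype=float)
            total = counts.sum()
            if alternative == "greater":
                p = float(counts[int(u_x):].sum() / total)
            else:
                p = float(counts[: int(u_x) + 1].sum() / total)
    else:
        p_method = "normal_approx"
        if var_u <= 0:  # everything tied
            p = 1.0
        else:
            sd = np.sqrt(var_u)
            diff = u_x - mean_u
            # continuity correction toward the mean
            if alternative == "two_sided":
                z = (abs(diff) - 0.5) / sd
                p = float(min(1.0, 2.0 * distributions.norm.sf(max(z, 0.0))))
            elif alternative == "greater":
                z = (diff - 0.5) / sd
                p = float(distributions.norm.sf(z))
            else:
                z = (diff + 0.5) / sd
                p = float(distributions.norm.cdf(z))

    return TestResult(
        method="mann_whitney",
        statistics={"U_x": u_x, "U_y": u_y, "U_min": min(u_x, u_y)},
        n_per_group=(n1, n2),
        p_value=p,
        p_method=p_method,
        detail={"alternative": alternative, "ties": has_ties},
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Kruskal-Wallis rank test across two or more groups (tie-corrected)."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = midranks(pooled)

    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12.0 / (n * (n + 1)) * h - 3 * (n + 1)

    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - float((tie_counts**3 - tie_counts).sum()) / (n**3 - n)
    if correction == 0.0:  # all values identical
        h, p = 0.0, 1.0
    else:
        h /= correction
        p = float(distributions.chi2.sf(h, len(groups) - 1))

    return TestResult(
        method="kruskal_wallis",
        statistics={"H": h},
        n_per_group=tuple(len(g) for g in groups),
        p_value=p,
        p_method="chi2_approx",
    )


def rho_from_S(S: float, n: int) -> float:
    """Spearman rho from the S statistic: ``rho = 1 - 6 S / (n^3 - n)``."""
    if n < 2:
        raise ValueError("need n >= 2")
    return 1.0 - 6.0 * S / (n**3 - n)


def spearman(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Spearman rank correlation, reported as both rho and S.

    rho is the Pearson correlation of midranks.  S is reported through the
    tie-free identity ``S = (1 - rho)(n^3 - n)/6`` — the convention under
    which (S, rho) pairs are printed together — so the pair always
    satisfies :func:`rho_from_S` exactly.  p comes from the t
    approximation with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    n = len(x)
    if n < 3:
        raise ValueError("need n >= 3")
    rx, ry = midranks(x), midranks(y)
    sx, sy = rx.std(ddof=0), ry.std(ddof=0)
    if sx == 0.0 or sy == 0.0:
        raise ValueError("zero rank variance")
    rho = float(((rx - rx.mean()) * (ry - ry.mean())).mean() / (sx * sy))
    S = (1.0 - rho) * (n**3 - n) / 6.0

    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * np.sqrt((n - 2) / (1.0 - rho**2))
        p = float(2.0 * distributions.t.sf(abs(t), n - 2))

    return TestResult(
        method="spearman",
        statistics={"S": S, "rho": rho},
        n_per_group=(n,),
        p_value=p,
        p_method="t_approx",
    )


def _pearson_chi2(table: np.ndarray) -> float:
    """Pearson chi-squared on a contingency table, no continuity correction."""
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / table.sum()
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = (table - expected) ** 2 / expected
    return float(np.nansum(terms))


def chisq_permutation(
    labels_a: Sequence, labels_b: Sequence, reps: int = 9999, seed: int | None = None
) -> TestResult:
    """Permutation chi-squared test of independence of two labellings.

    The observed Pearson chi-squared on the cross-tabulation is compared
    with its distribution under ``reps`` seeded random shuffles of
    ``labels_b``; the p-value uses the add-one estimator
    ``(1 + #{chi2_perm >= chi2_obs}) / (reps + 1)``, which can never be 0.
    """
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    if len(a) != len(b):
        raise ValueError("label vectors must have equal length")
    ua, codes_a = np.unique(a, return_inverse=True)
    ub, codes_b = np.unique(b, return_inverse=True)
    ka, kb = len(ua), len(ub)
    if ka < 2 or kb < 2:
        raise ValueError("each labelling needs at least two levels (zero-variance margin)")

    n = len(a)
    observed = np.zeros((ka, kb))
    np.add.at(observed, (codes_a, codes_b), 1)
    chi2_obs = _pearson_chi2(observed)

    rng = np.random.default_rng(seed)
    permuted_b = rng.permuted(np.tile(codes_b, (reps, 1)), axis=1)
    joint = codes_a[None, :] * kb + permuted_b  # (reps, n) cell codes
    counts = np.zeros((reps, ka * kb))
    for cell in range(ka * kb):
        counts[:, cell] = (joint == cell).sum(axis=1)
    counts = counts.reshape(reps, ka, kb)

    rowm = counts.sum(axis=2, keepdims=True)
    colm = counts.sum(axis=1, keepdims=True)
    expected = rowm * colm / n
    with np.errstate(invalid="ignore", divide="ignore"):
        terms = (counts - expected) ** 2 / expected
    chi2_perm = np.nansum(terms, axis=(1, 2))

    exceed = int((chi2_perm >= chi2_obs - 1e-12).sum())
    p = (1 + exceed) / (reps + 1)

    return TestResult(
        method="chisq_permutation",
        statistics={"chi2": chi2_obs},
        n_per_group=(n,),
        p_value=p,
        p_method="permutation",
        seed=seed,
        detail={"reps": reps, "levels": (ka, kb)},
    )


def run_trait_contrasts(
    table: TraitTable,
    traits: Sequence[str],
    rate_column: str = "rate",
    reps: int = 9999,
    seed: int | None = None,
) -> dict:
    """Run the full battery of rate contrasts and independence tests.

    For every binary trait, a Mann-Whitney contrast of ``rate_column``
    between the trait's two levels; for every pair of traits, a seeded
    chi-squared permutation test of independence.  Traits with an empty
    level are skipped with a log message.
    """
    import pandas as pd

    df = table.df
    if rate_column not in df.columns:
        raise KeyError(f"no rate column {rate_column!r}")

    contrasts: dict[str, TestResult] = {}
    groups_used: dict[str, dict] = {}
    usable_traits = []
    for trait in traits:
        if trait not in df.columns:
            raise KeyError(f"no trait column {trait!r}")
        sub = df[[trait, rate_column, "gene"]].dropna()
        pos = sub[sub[trait].astype(bool)]
        neg = sub[~sub[trait].astype(bool)]
        if len(pos) == 0 or len(neg) == 0:
            log.warning("trait %r has an empty level; contrast skipped", trait)
            continue
        usable_traits.append(trait)
        res = mann_whitney(pos[rate_column].to_numpy(), neg[rate_column].to_numpy())
        contrasts[trait] = res
        groups_used[trait] = {
            "positive": list(pos["gene"]),
            "negative": list(neg["gene"]),
        }

    independence: dict[str, TestResult] = {}
    for i, (t1, t2) in enumerate(combinations(usable_traits, 2)):
        sub = df[[t1, t2]].dropna()
        pair_seed = None if seed is None else seed + i
        try:
            independence[f"{t1}~{t2}"] = chisq_permutation(
                sub[t1].astype(bool), sub[t2].astype(bool), reps=reps, seed=pair_seed
            )
        except ValueError as exc:
            log.warning("independence test %s~%s skipped: %s", t1, t2, exc)

    return {
        "contrasts": contrasts,
        "independence": independence,
        "groups": groups_used,
    }
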