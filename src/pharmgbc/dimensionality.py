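"""Participation-ratio effective dimensionality.

PR = (Σ_i λ̄_i²)⁻¹ with λ̄_i = λ_i / Σ_j λ_j, the λ_i being eigenvalues of
the feature-centered sample covariance of a set of per-subject maps.  PR is
the effective number of variance-carrying dimensions: N equal eigenvalues
give PR = N, a rank-1 spectrum gives PR = 1.

Because PR depends on sample size, group comparisons are run on equal-n
subsample distributions (full enumeration, leave-one-out jackknife, or
random subsets) followed by a one-way ANOVA with Bonferroni-corrected
pairwise Welch t-tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from math import comb
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError, InvalidArgumentError

SCHEMES = ("all_combinations", "jackknife", "random_k")


@dataclass
class DimensionalityDistribution:
    condition: str
    pr_values: np.ndarray
    scheme: str
    n_sub: int


def pr_from_eigenvalues(eigenvalues: Sequence[float]) -> float:
    """Participation ratio of a spectrum: (Σ λ̄_i²)⁻¹, λ̄_i = λ_i/Σλ."""
    lam = np.asarray(eigenvalues, float)
    lam = lam[lam > 0]
    if lam.size == 0:
        raise DegenerateInputError("no positive eigenvalues")
    lam_bar = lam / lam.sum()
    return float(1.0 / np.sum(lam_bar**2))


def participation_ratio(maps: np.ndarray) -> float:
    """PR of the feature-centered sample covariance of (n, P) maps.

    Eigenvalues below 1e-12 · λ_max are treated as zero.
    """
    maps = np.asarray(maps, float)
    if maps.ndim != 2 or maps.shape[0] < 3:
        raise InvalidArgumentError("need an (n >= 3) x P matrix")
    X = maps - maps.mean(axis=0)
    sv = np.linalg.svd(X, compute_uv=False)
    lam = sv**2 / (maps.shape[0] - 1)
    if lam.size == 0 or lam[0] <= 0:
        raise DegenerateInputError("all-zero data")
    lam[lam < 1e-12 * lam[0]] = 0.0
    return pr_from_eigenvalues(lam)


def pr_distribution(
    maps: np.ndarray,
    n_sub: int = 22,
    scheme: str = "all_combinations",
    n_draws: Optional[int] = None,
    seed: int = 0,
    condition: str = "",
) -> DimensionalityDistribution:
    """Distribution of PR values over equal-n subject subsamples.

    all_combinations enumerates every C(n, n_sub) subset; jackknife is the
    leave-one-out special case (requires n − n_sub = 1); random_k draws
    ``n_draws`` distinct subsets uniformly.
    """
    maps = np.asarray(maps, float)
    n = maps.shape[0]
    if n_sub > n:
        raise InvalidArgumentError(f"n_sub={n_sub} exceeds sample size {n}")
    if scheme not in SCHEMES:
        raise InvalidArgumentError(f"unknown scheme {scheme!r}")

    if scheme == "jackknife":
        if n - n_sub != 1:
            raise InvalidArgumentError("jackknife requires n - n_sub == 1")
        subsets = [tuple(j for j in range(n) if j != i) for i in range(n)]
        if n_draws is not None:
            subsets = subsets[:n_draws]
    elif scheme == "all_combinations":
        subsets = list(itertools.combinations(range(n), n_sub))
    else:  # random_k
        total = comb(n, n_sub)
        if n_draws is None:
            raise InvalidArgumentError("random_k requires n_draws")
        if n_draws > total:
            raise InvalidArgumentError(
                f"n_draws={n_draws} exceeds C({n},{n_sub})={total} distinct subsets"
            )
        rng = np.random.default_rng(seed)
        seen: set[tuple[int, ...]] = set()
        while len(seen) < n_draws:
            seen.add(tuple(sorted(rng.choice(n, size=n_sub, replace=False))))
        subsets = sorted(seen)

    pr = np.array([participation_ratio(maps[list(s)]) for s in subsets])
    return DimensionalityDistribution(
        condition=condition, pr_values=pr, scheme=scheme, n_sub=n_sub
    )


@dataclass
class ConditionComparison:
    anova_f: float
    anova_df: tuple[int, int]
    anova_p: float
    pairwise: pd.DataFrame


def compare_conditions(dists: Sequence[DimensionalityDistribution]) -> ConditionComparison:
    """One-way ANOVA across PR distributions plus pairwise Welch t-tests with
    Bonferroni-multiplied p-values."""
    if len(dists) < 2:
        raise InvalidArgumentError("need >= 2 conditions")
    groups = [np.asarray(d.pr_values, float) for d in dists]
    if any(len(g) < 3 for g in groups):
        raise InvalidArgumentError("each condition needs >= 3 PR values")
    f, p = stats.f_oneway(*groups)
    df1 = len(groups) - 1
    df2 = sum(len(g) for g in groups) - len(groups)

    pairs = list(itertools.combinations(range(len(groups)), 2))
    rows = []
    for i, j in pairs:
        t, pt = stats.ttest_ind(groups[i], groups[j], equal_var=False)
        rows.append(
            {
                "a": dists[i].condition or f"cond{i}",
                "b": dists[j].condition or f"cond{j}",
                "mean_a": groups[i].mean(),
                "mean_b": groups[j].mean(),
                "t": float(t),
                "p": float(pt),
                "p_bonferroni": min(1.0, float(pt) * len(pairs)),
            }
        )
    return ConditionComparison(
        anova_f=float(f), anova_df=(df1, df2), anova_p=float(p), pairwise=pd.DataFrame(rows)
    )
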