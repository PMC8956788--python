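"""Descriptive statistics around the priority index.

Covers the three analyses run alongside the index itself: pairwise
Pearson correlations among the index variables (richness, Cwt, RRw,
area), a rank-based two-group comparison of high- versus low-priority
units with an effect size, and the species accumulation curve used to
judge sampling completeness.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import AnalysisError
from .occurrence import LakeCountryUnit

__all__ = [
    "GroupComparison",
    "AccumulationCurve",
    "correlation_matrix",
    "compare_groups",
    "compare_by_class",
    "accumulation_curve",
]


def correlation_matrix(
    results: pd.DataFrame, variables: Sequence[str]
) -> pd.DataFrame:
    """All pairwise Pearson correlations among the named numeric columns.

    Returns one row per unordered pair (including each variable with
    itself) with columns ``var_a, var_b, r, df, p_value``; df = n - 2.
    Requires at least 3 rows.
    """
    n = len(results)
    if n < 3:
        raise AnalysisError(f"correlation needs at least 3 units, got {n}")
    rows = []
    for a, b in itertools.combinations_with_replacement(variables, 2):
        x = results[a].to_numpy(float)
        y = results[b].to_numpy(float)
        if a == b:
            r, p = 1.0, 0.0
        elif np.ptp(x) == 0 or np.ptp(y) == 0:
            r, p = np.nan, np.nan  # constant column: correlation undefined
        else:
            r, p = sps.pearsonr(x, y)
        rows.append({"var_a": a, "var_b": b, "r": r, "df": n - 2, "p_value": p})
    return pd.DataFrame(rows, columns=["var_a", "var_b", "r", "df", "p_value"])


@dataclass(frozen=True)
class GroupComparison:
    """Two-sample rank comparison result.

    ``statistic_w`` is the Mann–Whitney U statistic for the first group
    (0 ≤ W ≤ n1·n2); ``effect_size_r`` = |z| / sqrt(n1 + n2) where z is
    the tie-corrected standardized statistic (U - mean)/sigma, without
    continuity correction.
    """

    statistic_w: float
    p_value: float
    effect_size_r: float
    n1: int
    n2: int
    z: float
    method: str


def _rank_u_and_z(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """U statistic of x, raw z, and continuity-corrected z (tie-corrected).

    The raw standardized statistic (U - mean)/sigma feeds the effect
    size; the continuity-corrected z feeds the normal-approximation
    p-value.
    """
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    r1 = ranks[:n1].sum()
    u1 = r1 - n1 * (n1 + 1) / 2.0
    mu = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts**3 - tie_counts).sum()
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:  # all values identical
        return u1, 0.0, 0.0
    diff = u1 - mu
    sigma = math.sqrt(var)
    cc = 0.5 * np.sign(diff)  # continuity correction toward the mean
    z_cc = (diff - cc) / sigma if diff != 0 else 0.0
    return u1, diff / sigma, z_cc


def _exact_two_sided_p(x: np.ndarray, y: np.ndarray, u1: float) -> float:
    """Exact p by enumerating every assignment of the pooled values.

    Two-sided via distance of U from its null mean; midranks handle ties.
    """
    n1 = len(x)
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    mu = n1 * len(y) / 2.0
    offset = n1 * (n1 + 1) / 2.0
    observed = abs(u1 - mu)
    hits = 0
    total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        u = ranks[list(combo)].sum() - offset
        if abs(u - mu) >= observed - 1e-12:
            hits += 1
        total += 1
    return hits / total


def compare_groups(
    group1: Sequence[float],
    group2: Sequence[float],
    method: str = "auto",
) -> GroupComparison:
    """Unpaired two-sample rank-sum comparison with effect size.

    The test is the Mann–Whitney rank-sum test (the appropriate rank test
    for two independent groups of unequal size).  The p-value uses the
    tie-corrected normal approximation with continuity correction, except
    that small problems (n1 + n2 ≤ 12) are evaluated by exact enumeration
    when ``method="auto"``.  ``method`` may be ``"auto"``, ``"normal"`` or
    ``"exact"``.  The effect size r = |z| / sqrt(n1 + n2) always comes
    from the normal-approximation z.

    Raises :class:`AnalysisError` if either group is empty.
    """
    x = np.asarray(list(group1), float)
    y = np.asarray(list(group2), float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise AnalysisError("both groups must be non-empty for a rank comparison")
    u1, z_raw, z_cc = _rank_u_and_z(x, y)
    effect = abs(z_raw) / math.sqrt(n1 + n2)
    use_exact = method == "exact" or (method == "auto" and n1 + n2 <= 12)
    if use_exact:
        p = _exact_two_sided_p(x, y, u1)
        used = "exact"
    elif method in ("auto", "normal"):
        p = min(1.0, 2.0 * sps.norm.sf(abs(z_cc)))
        used = "normal"
    else:
        raise ValueError(f"unknown method {method!r}")
    return GroupComparison(
        statistic_w=float(u1),
        p_value=float(p),
        effect_size_r=float(effect),
        n1=n1,
        n2=n2,
        z=float(z_raw),
        method=used,
    )


def compare_by_class(
    results: pd.DataFrame,
    value_col: str,
    class_col: str = "priority_class",
    method: str = "auto",
) -> GroupComparison:
    """Rank-compare a numeric column between low- and high-priority units.

    The low-priority group enters first, so W is its U statistic.
    """
    low = results.loc[results[class_col] == "low", value_col]
    high = results.loc[results[class_col] == "high", value_col]
    return compare_groups(low, high, method=method)


@dataclass(frozen=True)
class AccumulationCurve:
    """Mean (± sd) cumulative distinct-species count over random site orders."""

    sites: np.ndarray
    mean_richness: np.ndarray
    sd: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"sites": self.sites, "mean_richness": self.mean_richness, "sd": self.sd}
        )


def accumulation_curve(
    units: Sequence[LakeCountryUnit],
    n_permutations: int = 100,
    seed: int | None = None,
) -> AccumulationCurve:
    """Species accumulation curve by random-order site addition.

    Sites (units) are added in ``n_permutations`` random orders; the curve
    reports the mean and sample sd of the cumulative distinct-species
    count at each number of sites.  The final point always equals the
    total distinct richness.  Reproducible given ``seed``.
    """
    if not units:
        raise AnalysisError("accumulation curve needs at least one unit")
    rng = np.random.default_rng(seed)
    species_sets = [set(u.species) for u in units]
    n_sites = len(species_sets)
    curves = np.empty((n_permutations, n_sites))
    for i in range(n_permutations):
        order = rng.permutation(n_sites)
        seen: set[str] = set()
        for j, idx in enumerate(order):
            seen |= species_sets[idx]
            curves[i, j] = len(seen)
    sd = curves.std(axis=0, ddof=1) if n_permutations > 1 else np.zeros(n_sites)
    return AccumulationCurve(
        sites=np.arange(1, n_sites + 1),
        mean_richness=curves.mean(axis=0),
        sd=sd,
    )
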