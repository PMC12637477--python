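"""Condition-level inference for two-timepoint spatial experiments.

Covers the comparisons made between harvest times: rank-sum (Mann-Whitney)
comparison of pooled nearest-partner distance distributions, per-section
cell-type composition with Wilson confidence intervals, the fraction of
cells expressing a gene set (e.g. effector cytokines in CD8 T cells),
per-cell gene-set scores, a section-level permutation test that avoids
treating cells as independent replicates, and the Spearman near-to-far
trend of a quantile-expression matrix.

The Mann-Whitney and Spearman statistics are implemented from their
definitions (exact rank-sum enumeration below a small-sample crossover,
tie-corrected normal approximation above it) rather than delegated, so
their behavior is fully specified and testable against independent
oracles.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb, erf, sqrt
from typing import Callable

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .annotate import lognorm
from .formats import ChronotimeError, SpatialSection
from .proximity import QuantileExpressionMatrix, nearest_partner_distances

DEFAULT_EFFECTOR_SET = ["Ifng", "Gzmb", "Prf1"]
DEFAULT_CHEMOKINE_SET = ["Cxcl9", "Cxcl10", "Cxcl16", "Ccl4", "Ccl5", "Xcl1"]

#: Combined sample size at or below which the rank-sum null is enumerated
#: exactly (tie-free data only); keeps enumeration desk-fast.
EXACT_RANKSUM_MAX_N = 16

#: Total label assignments at or below which the section permutation null
#: is enumerated exhaustively.
EXHAUSTIVE_PERM_MAX = 10_000


@dataclass
class CompositionTable:
    """Per-section, per-condition cell-type counts and proportions."""

    rows: pd.DataFrame  # section_id, condition, cell_type, count, proportion[, ci]

    def __post_init__(self) -> None:
        sums = self.rows.groupby("section_id")["proportion"].sum()
        if len(sums) and not np.allclose(sums, 1.0, atol=1e-12):
            raise ChronotimeError("proportions do not sum to 1 within a section")

    def condition_means(self) -> pd.DataFrame:
        return (
            self.rows.groupby(["condition", "cell_type"])["proportion"]
            .mean()
            .reset_index()
        )


@dataclass
class TestResult:
    """Outcome of one hypothesis test."""

    method: str
    statistic: float
    p_value: float
    n1: int
    n2: int
    alternative: str = "two-sided"
    exact: bool = False
    n_permutations: int | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.p_value <= 1.0):
            raise ChronotimeError(f"p-value {self.p_value} outside (0, 1]")


# ---------------------------------------------------------------------------
# Composition and expression summaries
# ---------------------------------------------------------------------------


def composition(
    sections: list[SpatialSection],
    types: list[str],
    ci: bool = False,
    ci_alpha: float = 0.05,
) -> CompositionTable:
    """Per-section counts and proportions of the requested cell types.

    Cells of any other type are collapsed into an ``"other"`` row so
    proportions always sum to one.  Wilson score intervals (not Wald) are
    attached when ``ci`` is set.
    """
    rows = []
    for section in sections:
        if section.n_cells == 0:
            raise ChronotimeError(f"section {section.section_id!r} is empty")
        labels = section.cells["cell_type"]
        collapsed = labels.where(labels.isin(types), other="other")
        total = len(collapsed)
        order = list(types)
        if "other" not in order and (collapsed == "other").any():
            order.append("other")
        for cell_type in order:
            count = int((collapsed == cell_type).sum())
            row = {
                "section_id": section.section_id,
                "condition": section.condition,
                "cell_type": cell_type,
                "count": count,
                "proportion": count / total,
            }
            if ci:
                lo, hi = proportion_confint(count, total, alpha=ci_alpha,
                                            method="wilson")
                row["ci_low"], row["ci_high"] = float(lo), float(hi)
            rows.append(row)
    return CompositionTable(pd.DataFrame(rows))


def expressing_fraction(
    section: SpatialSection,
    cell_type: str,
    gene_set: list[str],
    threshold: int = 1,
) -> float:
    """Fraction of ``cell_type`` cells with >= threshold raw counts in any
    gene of the set (detection calls use raw counts, not normalized values)."""
    if threshold < 1:
        raise ChronotimeError("threshold must be >= 1")
    mask = section.type_mask(cell_type)
    if not mask.any():
        raise ChronotimeError(f"no cells of type {cell_type!r}")
    rows = section.gene_index(gene_set)
    sub = section.counts[rows][:, mask]
    expressing = np.asarray((sub >= threshold).sum(axis=0)).ravel() > 0
    return float(expressing.mean())


def gene_set_score(
    section: SpatialSection,
    gene_set: list[str],
    cell_subset=None,
) -> pd.Series:
    """Per-cell mean log-normalized expression over a gene set.

    ``cell_subset`` may be a cell-type name, a boolean mask, or None for
    all cells; the result is indexed by cell_id.
    """
    rows = section.gene_index(gene_set)
    if cell_subset is None:
        mask = np.ones(section.n_cells, dtype=bool)
    elif isinstance(cell_subset, str):
        mask = section.type_mask(cell_subset)
    else:
        mask = np.asarray(cell_subset, dtype=bool)
        if mask.shape != (section.n_cells,):
            raise ChronotimeError("cell_subset mask has wrong length")
    ln = lognorm(section.counts)
    block = ln[rows][:, mask]
    score = np.asarray(block.mean(axis=0)).ravel()
    return pd.Series(score, index=section.cells.loc[mask, "cell_id"].to_numpy())


# ---------------------------------------------------------------------------
# Rank-sum (Mann-Whitney) test from the definition
# ---------------------------------------------------------------------------


def _midranks(values: np.ndarray) -> np.ndarray:
    """Average ranks (1-based) with midranks for ties."""
    order = np.argsort(values, kind="stable")
    ranks = np.empty(len(values))
    sorted_vals = values[order]
    i = 0
    while i < len(values):
        j = i
        while j + 1 < len(values) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2 + 1
        i = j + 1
    return ranks


def _norm_sf(z: float) -> float:
    return 0.5 * (1.0 - erf(z / sqrt(2.0)))


def rank_sum_test(x, y, alternative: str = "two-sided") -> TestResult:
    """Mann-Whitney rank-sum test of two independent samples.

    The statistic is U for the first sample (number of (x, y) pairs with
    x > y, counting ties as 1/2).  For combined n <= 16 with no ties the
    null distribution of U is enumerated exactly over all rank
    assignments; otherwise a normal approximation with tie-corrected
    variance and continuity correction is used.  ``alternative`` "less"
    means x tends to be smaller than y.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ChronotimeError("both samples must be non-empty")
    if alternative not in ("two-sided", "less", "greater"):
        raise ChronotimeError(f"unknown alternative {alternative!r}")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2  # U for x
    has_ties = len(np.unique(pooled)) < len(pooled)

    if n1 + n2 <= EXACT_RANKSUM_MAX_N and not has_ties:
        # exact null: every choice of which ranks belong to x is equally
        # likely; U = (sum of x ranks) - n1(n1+1)/2
        n = n1 + n2
        dist: dict[float, int] = {}
        for chosen in combinations(range(1, n + 1), n1):
            u_null = sum(chosen) - n1 * (n1 + 1) / 2
            dist[u_null] = dist.get(u_null, 0) + 1
        total = comb(n, n1)
        p_le = sum(c for v, c in dist.items() if v <= u) / total
        p_ge = sum(c for v, c in dist.items() if v >= u) / total
        if alternative == "less":
            p = p_le
        elif alternative == "greater":
            p = p_ge
        else:
            p = min(1.0, 2 * min(p_le, p_ge))
        return TestResult("mann-whitney-exact", float(u), float(p), n1, n2,
                          alternative, exact=True)

    n = n1 + n2
    mu = n1 * n2 / 2
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts ** 3 - tie_counts).sum() / (n * (n - 1))
                if n > 1 else 0.0)
    var = n1 * n2 / 12 * ((n + 1) - tie_term)
    if var <= 0:
        # all values identical in both samples: no evidence either way
        return TestResult("mann-whitney-normal", float(u), 1.0, n1, n2,
                          alternative, exact=False)
    sd = sqrt(var)
    if alternative == "less":
        z = (u - mu + 0.5) / sd
        p = _norm_sf(-z)  # Phi(z) = P(U <= u) under the null
    elif alternative == "greater":
        z = (u - mu - 0.5) / sd
        p = _norm_sf(z)
    else:
        shift = 0.5 if u > mu else (-0.5 if u < mu else 0.0)
        z = (u - mu - shift) / sd
        p = min(1.0, 2 * _norm_sf(abs(z)))
    p = min(1.0, max(p, np.nextafter(0, 1)))
    return TestResult("mann-whitney-normal", float(u), float(p), n1, n2,
                      alternative, exact=False)


# ---------------------------------------------------------------------------
# Section-level permutation test
# ---------------------------------------------------------------------------


def mean_nearest_distance_stat(source_type: str, target_type: str) -> Callable:
    """Per-section statistic: mean nearest-partner distance."""
    def stat(section: SpatialSection) -> float:
        return float(
            nearest_partner_distances(section, source_type, target_type)
            .distances.mean()
        )
    stat.__name__ = f"mean_{source_type}_to_{target_type}_distance"
    return stat


def expressing_fraction_stat(cell_type: str, gene_set: list[str],
                             threshold: int = 1) -> Callable:
    """Per-section statistic: expressing fraction of a gene set."""
    def stat(section: SpatialSection) -> float:
        return expressing_fraction(section, cell_type, gene_set, threshold)
    stat.__name__ = f"{cell_type}_expressing_fraction"
    return stat


def section_permutation_test(
    statistic: Callable[[SpatialSection], float],
    sections: list[SpatialSection],
    n_perm: int = 9999,
    seed: int | None = None,
) -> TestResult:
    """Two-condition permutation test on a per-section summary statistic.

    The observed absolute difference in condition means of the per-section
    statistic is compared to its distribution under random reassignment of
    condition labels to sections (group sizes fixed).  When the number of
    distinct assignments is small the null is enumerated exhaustively
    (deterministic, seed-free, p a multiple of 1/m with the identity
    assignment included); otherwise ``n_perm`` Monte-Carlo draws give
    p = (b + 1) / (n_perm + 1).

    Testing at section level sidesteps the pseudoreplication of cell-level
    tests, at the cost of power when sections are few.
    """
    conditions = sorted({s.condition for s in sections})
    if len(conditions) != 2:
        raise ChronotimeError(
            f"permutation test requires exactly 2 conditions, got {conditions}"
        )
    labels = np.array([s.condition for s in sections])
    for cond in conditions:
        if (labels == cond).sum() < 2:
            raise ChronotimeError("need >= 2 sections per condition")
    values = np.array([float(statistic(s)) for s in sections])
    group_a = labels == conditions[0]
    n_a = int(group_a.sum())

    def diff(mask: np.ndarray) -> float:
        return abs(values[mask].mean() - values[~mask].mean())

    observed = diff(group_a)
    n = len(sections)
    m_total = comb(n, n_a)
    if m_total <= EXHAUSTIVE_PERM_MAX:
        null = []
        for chosen in combinations(range(n), n_a):
            mask = np.zeros(n, dtype=bool)
            mask[list(chosen)] = True
            null.append(diff(mask))
        null = np.asarray(null)
        b = int((null >= observed - 1e-12).sum())
        p = b / m_total  # identity assignment counted, so p >= 1/m
        return TestResult(
            "section-permutation-exhaustive", observed, p,
            n_a, n - n_a, n_permutations=m_total, exact=True,
        )
    rng = np.random.default_rng(seed)
    b = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        mask = np.zeros(n, dtype=bool)
        mask[perm[:n_a]] = True
        if diff(mask) >= observed - 1e-12:
            b += 1
    p = (b + 1) / (n_perm + 1)
    return TestResult(
        "section-permutation-mc", observed, p, n_a, n - n_a,
        n_permutations=n_perm, seed=seed,
    )


# ---------------------------------------------------------------------------
# Quantile trend
# ---------------------------------------------------------------------------


def spearman_rho(x, y) -> float:
    """Spearman rank correlation with midranks, from the definition."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) != len(y) or len(x) < 2:
        raise ChronotimeError("need two equal-length samples of size >= 2")
    rx, ry = _midranks(x), _midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = sqrt((rx ** 2).sum() * (ry ** 2).sum())
    if denom == 0:
        return 0.0
    return float((rx * ry).sum() / denom)


def quantile_trend(qem: QuantileExpressionMatrix) -> pd.DataFrame:
    """Per-row Spearman correlation of expression with quantile index.

    Negative rho means expression falls with distance (near > far).
    Constant rows get rho = 0 with ``constant`` flagged True.
    """
    if qem.n_quantiles < 3:
        raise ChronotimeError("need >= 3 quantile columns for a trend")
    idx = np.arange(1, qem.n_quantiles + 1, dtype=float)
    rows = []
    for key, row in qem.values.iterrows():
        vals = row.to_numpy(float)
        constant = bool(np.all(vals == vals[0]))
        rho = 0.0 if constant else spearman_rho(idx, vals)
        rows.append(
            {"gene": key[0], "measured_in_type": key[1], "rho": rho,
             "constant": constant}
        )
    return pd.DataFrame(rows)
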