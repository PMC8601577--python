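"""Item analysis, reliability, validity correlations, group tests.

Conventions: two-sided p-values throughout; pairwise-complete
observations for correlation matrices, listwise deletion for Cronbach's
alpha and the ICC; Bonferroni control over the stated family sizes.

Cronbach's alpha confidence intervals use Feldt's F-distribution
method; ICC(A,1) — the two-way random-effects, absolute-agreement,
single-measure intraclass correlation — follows the McGraw & Wong
mean-squares definition with their F-based confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


class PsychometricsError(ValueError):
    pass


@dataclass(frozen=True)
class ReliabilityEstimate:
    statistic: str  # cronbach_alpha | icc_a1 | pearson | partial_pearson
    value: float
    ci_low: float
    ci_high: float
    n: int


@dataclass
class CorrelationMatrixResult:
    r: pd.DataFrame
    p: pd.DataFrame
    n: pd.DataFrame
    alpha_family: float
    significant: pd.DataFrame


@dataclass
class ItemAnalysisResult:
    passing_rate: pd.Series
    corrected_item_total: pd.Series
    flagged: pd.Series  # r < 0.2 ("poor discriminability")
    undefined: list[str]  # zero-variance items, excluded from summary


# ---------------------------------------------------------------- items

def item_passing_rates(
    matrix: pd.DataFrame, item_max: Sequence[float] | float = 1.0
) -> pd.Series:
    """Mean normalized score per item (a difficulty index in [0, 1]).

    ``matrix`` is participants x items (patient data); ``item_max``
    scales multi-point items to unit range.
    """
    m = matrix.astype(float)
    maxima = pd.Series(
        np.broadcast_to(np.asarray(item_max, dtype=float), (m.shape[1],)).copy(),
        index=m.columns,
    )
    if m.isna().all(axis=0).any():
        bad = list(m.columns[m.isna().all(axis=0)])
        raise PsychometricsError(f"items with no observations: {bad}")
    return m.mean(axis=0, skipna=True) / maxima


def corrected_item_total(matrix: pd.DataFrame, flag_below: float = 0.2) -> ItemAnalysisResult:
    """Correlation of each item with its subtest total minus that item.

    Items correlating below ``flag_below`` with the rest of the subtest
    are flagged as poorly discriminating; zero-variance items are
    reported as undefined (NaN) and excluded from the flag summary with
    a warning rather than failing the subtest.
    """
    m = matrix.astype(float)
    if m.shape[0] < 3:
        raise PsychometricsError("corrected item-total needs >= 3 participants")
    total = m.sum(axis=1)
    rs, undefined = {}, []
    for col in m.columns:
        rest = total - m[col]
        if m[col].std(ddof=1) == 0 or rest.std(ddof=1) == 0:
            rs[col] = np.nan
            undefined.append(col)
            continue
        rs[col] = float(stats.pearsonr(m[col], rest)[0])
    if undefined:
        warnings.warn(
            f"zero-variance items excluded from item-total summary: {undefined}",
            stacklevel=2,
        )
    r = pd.Series(rs)
    flagged = r < flag_below
    flagged[r.isna()] = False
    return ItemAnalysisResult(item_passing_rates(m), r, flagged, undefined)


# ---------------------------------------------------------- reliability

def cronbach_alpha(
    matrix: pd.DataFrame, ci: float = 0.95, ci_method: str = "feldt", n_boot: int = 2000,
    seed: int | None = None,
) -> ReliabilityEstimate:
    """Internal-consistency alpha over a subtest's items.

    alpha = k/(k-1) * (1 - sum var(item) / var(total)), on listwise-
    complete rows.  The default confidence interval is Feldt's exact
    F-based interval; ``ci_method='bootstrap'`` resamples participants
    instead.
    """
    m = matrix.dropna(axis=0, how="any").astype(float)
    n, k = m.shape
    if k < 2:
        raise PsychometricsError("alpha needs at least 2 items")
    if n < 3:
        raise PsychometricsError("alpha needs at least 3 complete rows")
    zero_var = [c for c in m.columns if m[c].var(ddof=1) == 0]
    if zero_var:
        warnings.warn(
            f"zero-variance items excluded from alpha: {zero_var}", stacklevel=2
        )
        m = m.drop(columns=zero_var)
        k = m.shape[1]
        if k < 2:
            raise PsychometricsError("fewer than 2 items with variance")
    total_var = m.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise PsychometricsError("zero total-score variance; alpha undefined")
    alpha = k / (k - 1) * (1 - m.var(ddof=1).sum() / total_var)
    a = 1 - ci
    if ci_method == "feldt":
        # (1 - alpha_hat)/(1 - alpha) ~ F(n-1, (n-1)(k-1))
        df1, df2 = n - 1, (n - 1) * (k - 1)
        lo = 1 - (1 - alpha) * stats.f.ppf(1 - a / 2, df1, df2)
        hi = 1 - (1 - alpha) * stats.f.ppf(a / 2, df1, df2)
    elif ci_method == "bootstrap":
        rng = np.random.default_rng(seed)
        vals = np.asarray(m)
        boots = []
        for _ in range(n_boot):
            idx = rng.integers(0, n, n)
            sample = vals[idx]
            tv = sample.sum(axis=1).var(ddof=1)
            if tv == 0:
                continue
            boots.append(k / (k - 1) * (1 - sample.var(axis=0, ddof=1).sum() / tv))
        lo, hi = np.quantile(boots, [a / 2, 1 - a / 2])
    else:
        raise PsychometricsError(f"unknown ci_method {ci_method!r}")
    return ReliabilityEstimate("cronbach_alpha", float(alpha), float(lo), float(hi), n)


def _twoway_mean_squares(x: np.ndarray) -> tuple[float, float, float]:
    """Row (subjects), column (raters), and residual mean squares of a
    complete two-way layout with one observation per cell."""
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((x - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(mse)


def icc_a1(ratings: pd.DataFrame | np.ndarray, ci: float = 0.95) -> ReliabilityEstimate:
    """ICC(A,1): two-way random effects, absolute agreement, single
    measure — the reliability of one rater's (or one session's) score.

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + k/n (MSC - MSE)), where MSR,
    MSC, MSE are the subject, rater and residual mean squares.  The CI
    uses the F-based interval with Satterthwaite degrees of freedom.
    """
    x = np.asarray(pd.DataFrame(ratings).dropna(axis=0, how="any"), dtype=float)
    n, k = x.shape
    if k < 2 or n < 3:
        raise PsychometricsError("ICC needs >= 2 columns and >= 3 complete rows")
    msr, msc, mse = _twoway_mean_squares(x)
    denom = msr + (k - 1) * mse + k / n * (msc - mse)
    if denom <= 0 or np.isclose(msr, 0) and np.isclose(denom, 0):
        raise PsychometricsError("zero between-subject variance; ICC undefined")
    icc = (msr - mse) / denom
    a = 1 - ci
    if np.isclose(icc, 1.0):
        lo = hi = 1.0
    else:
        # Satterthwaite df for the rater+error composite
        c_ = k * icc / (n * (1 - icc))
        d_ = 1 + k * icc * (n - 1) / (n * (1 - icc))
        v = (c_ * msc + d_ * mse) ** 2 / (
            (c_ * msc) ** 2 / (k - 1) + (d_ * mse) ** 2 / ((n - 1) * (k - 1))
        )
        f_lo = stats.f.ppf(1 - a / 2, n - 1, v)
        f_hi = stats.f.ppf(1 - a / 2, v, n - 1)
        lo = n * (msr - f_lo * mse) / (
            f_lo * (k * msc + (k * n - k - n) * mse) + n * msr
        )
        hi = n * (f_hi * msr - mse) / (
            k * msc + (k * n - k - n) * mse + n * f_hi * msr
        )
    return ReliabilityEstimate("icc_a1", float(icc), float(lo), float(hi), n)


# ------------------------------------------------------------- validity

def _pairwise_pearson(
    df: pd.DataFrame, min_n: int = 4
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    cols = list(df.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    n = pd.DataFrame(0, index=cols, columns=cols, dtype=int)
    for c in cols:
        n.loc[c, c] = int(df[c].notna().sum())
    for a, b in combinations(cols, 2):
        pair = df[[a, b]].dropna()
        n.loc[a, b] = n.loc[b, a] = len(pair)
        if len(pair) < min_n:
            r.loc[a, b] = r.loc[b, a] = np.nan
            p.loc[a, b] = p.loc[b, a] = np.nan
            continue
        res = stats.pearsonr(pair[a], pair[b])
        r.loc[a, b] = r.loc[b, a] = res.statistic
        p.loc[a, b] = p.loc[b, a] = res.pvalue
    return r, p, n


def pearson_matrix_bonferroni(
    subtest_accuracies: pd.DataFrame, family_alpha: float = 0.05
) -> CorrelationMatrixResult:
    """All pairwise Pearson correlations between subtest accuracies on
    pairwise-complete observations, with a Bonferroni family threshold
    (13 subtests -> 78 pairs -> .05/78 = .0006)."""
    r, p, n = _pairwise_pearson(subtest_accuracies)
    k = subtest_accuracies.shape[1]
    n_pairs = k * (k - 1) // 2
    threshold = family_alpha / n_pairs
    sig = (p < threshold) & ~np.eye(k, dtype=bool)
    return CorrelationMatrixResult(r, p, n, threshold, pd.DataFrame(
        sig, index=r.index, columns=r.columns))


def partial_pearson(
    x: np.ndarray, y: np.ndarray, z: np.ndarray
) -> tuple[float, float, int]:
    """First-order partial correlation of x and y given z, with the
    two-sided p from the t-distribution on n-3 degrees of freedom."""
    rxy = stats.pearsonr(x, y).statistic
    rxz = stats.pearsonr(x, z).statistic
    ryz = stats.pearsonr(y, z).statistic
    if np.isclose(abs(rxz), 1.0) or np.isclose(abs(ryz), 1.0):
        raise PsychometricsError("covariate collinear with a variable; partial r undefined")
    r = (rxy - rxz * ryz) / np.sqrt((1 - rxz**2) * (1 - ryz**2))
    n = len(x)
    df = n - 3
    r = float(np.clip(r, -1.0, 1.0))
    if df <= 0:
        return r, np.nan, n
    t = r * np.sqrt(df / max(1e-300, 1 - r**2))
    p = 2 * stats.t.sf(abs(t), df)
    return r, float(p), n


def partial_corr_matrix(
    subtest_accuracies: pd.DataFrame,
    severity_covariate: pd.Series,
    family_alpha: float = 0.05,
) -> CorrelationMatrixResult:
    """Pairwise partial correlations controlling for an external
    severity measure, on pairwise-complete rows, same Bonferroni family
    as the raw matrix."""
    cov = pd.Series(severity_covariate).reindex(subtest_accuracies.index)
    cols = list(subtest_accuracies.columns)
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    n = pd.DataFrame(0, index=cols, columns=cols, dtype=int)
    for a, b in combinations(cols, 2):
        block = pd.concat([subtest_accuracies[[a, b]], cov.rename("_z")], axis=1).dropna()
        n.loc[a, b] = n.loc[b, a] = len(block)
        if len(block) < 4:
            r.loc[a, b] = r.loc[b, a] = np.nan
            p.loc[a, b] = p.loc[b, a] = np.nan
            continue
        pr, pv, _ = partial_pearson(
            block[a].to_numpy(), block[b].to_numpy(), block["_z"].to_numpy()
        )
        r.loc[a, b] = r.loc[b, a] = pr
        p.loc[a, b] = p.loc[b, a] = pv
    n_pairs = k * (k - 1) // 2
    threshold = family_alpha / n_pairs
    sig = (p < threshold) & ~np.eye(k, dtype=bool)
    return CorrelationMatrixResult(r, p, n, threshold, pd.DataFrame(
        sig, index=r.index, columns=r.columns))


# ----------------------------------------------------------- group tests

def welch_t(
    group_a: Sequence[float], group_b: Sequence[float]
) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test (two-sided) with Satterthwaite
    degrees of freedom; returns (t, df, p)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise PsychometricsError("each group needs at least 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise PsychometricsError("both groups degenerate (zero variance)")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def bonferroni_threshold(family_size: int, alpha: float = 0.05) -> float:
    """Per-comparison significance threshold alpha/m (.05/13 = .0038,
    .05/26 = .0019, .05/78 = .0006 at the printed precision)."""
    if family_size < 1:
        raise PsychometricsError("family size must be positive")
    return alpha / family_size


def fisher_exact_cutoff(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 impaired/normal x subgroup
    table (e.g. hearing-deficit vs intact patients above/below cutoff)."""
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise PsychometricsError("need a 2x2 table of non-negative counts")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise PsychometricsError("empty row or column margin")
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


@dataclass
class PoolingResult:
    h: float
    p: float
    pairwise: pd.DataFrame  # columns: group_1, group_2, z, p, p_holm, significant
    merge_groups: list[list[str]]


def _dunn_z(ranks_mean_i, ranks_mean_j, n_i, n_j, n_total, tie_term) -> float:
    var = (n_total * (n_total + 1) / 12.0 - tie_term) * (1.0 / n_i + 1.0 / n_j)
    return (ranks_mean_i - ranks_mean_j) / np.sqrt(var)


def kruskal_dunn_pooling(
    groups: dict[str, Sequence[float]], alpha: float = 0.05
) -> PoolingResult:
    """Kruskal-Wallis omnibus test plus Dunn's pairwise post hoc with
    Holm adjustment, recommending which groups can be pooled.

    Groups with no significant pairwise difference land in the same
    recommended pool (connected components over non-significant pairs)
    — the age-stratification logic that merges adjacent age bands whose
    control distributions are indistinguishable.
    """
    names = list(groups)
    if len(names) < 2:
        raise PsychometricsError("need at least 2 groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if any(a.size < 2 for a in arrays):
        raise PsychometricsError("each group needs at least 2 values")
    h, p_omnibus = stats.kruskal(*arrays)

    pooled = np.concatenate(arrays)
    n_total = pooled.size
    ranks = stats.rankdata(pooled)
    # tie correction term sum(t^3 - t) / (12 (N - 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(counts**3 - counts)) / (12.0 * (n_total - 1))
    offsets = np.cumsum([0] + [a.size for a in arrays])
    mean_ranks = {
        g: ranks[offsets[i]:offsets[i + 1]].mean() for i, g in enumerate(names)
    }
    rows = []
    for a, b in combinations(names, 2):
        z = _dunn_z(
            mean_ranks[a], mean_ranks[b], len(groups[a]), len(groups[b]),
            n_total, tie_term,
        )
        rows.append({"group_1": a, "group_2": b, "z": z, "p": 2 * stats.norm.sf(abs(z))})
    pairwise = pd.DataFrame(rows)
    pairwise["p_holm"] = multipletests(pairwise["p"], method="holm")[1]
    pairwise["significant"] = pairwise["p_holm"] < alpha

    # union-find over non-significant pairs
    parent = {g: g for g in names}

    def find(g):
        while parent[g] != g:
            parent[g] = parent[parent[g]]
            g = parent[g]
        return g

    for row in pairwise.itertuples():
        if not row.significant:
            parent[find(row.group_1)] = find(row.group_2)
    pools: dict[str, list[str]] = {}
    for g in names:
        pools.setdefault(find(g), []).append(g)
    return PoolingResult(float(h), float(p_omnibus), pairwise, list(pools.values()))
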