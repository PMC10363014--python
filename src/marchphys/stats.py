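"""Fitness-group comparison statistics.

The battery mirrors common practice in field physiology: each outcome is
screened per group with the Shapiro-Wilk test; if every group looks normal
the omnibus test is a one-way ANOVA with Bonferroni-adjusted pairwise t
tests on the pooled within-group variance, otherwise a Kruskal-Wallis test
with Dunn-Bonferroni post-hoc comparisons.  Post-hoc tests run regardless of
the omnibus outcome (a borderline omnibus P can coexist with a significant
pairwise difference) and are flagged when the omnibus is non-significant.
Categorical outcomes (e.g. dropout by tertile) use an r x c Fisher exact
test: full enumeration of tables with the observed margins where feasible,
otherwise a seeded Monte-Carlo sample from the multivariate hypergeometric
null.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import gammaln

PARAMETRIC = "parametric"
NONPARAMETRIC = "nonparametric"


@dataclass
class PosthocResult:
    pair: tuple[str, str]
    raw_p: float
    adjusted_p: float      # Bonferroni: min(1, raw * n_pairs)
    significant: bool


@dataclass
class GroupComparison:
    variable: str
    test_used: str                     # "ANOVA" or "KruskalWallis"
    statistic: float                   # F or H
    p_value: float
    omnibus_significant: bool
    posthoc: list[PosthocResult]
    descriptives: dict[str, dict[str, float]]
    alpha: float
    notes: list[str] = field(default_factory=list)


@dataclass
class CategoricalAssociation:
    table: np.ndarray
    p_value: float
    method: str            # "enumeration" or "monte-carlo"
    n_tables: int          # tables enumerated or draws taken


def describe(values: np.ndarray) -> dict[str, float]:
    """Mean +/- SD [min, max] plus median; IQR, the dual Table-style summary."""
    v = np.asarray(values, dtype=float)
    q75, q25 = np.percentile(v, [75, 25])
    return {
        "n": int(v.size),
        "mean": float(v.mean()),
        "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
        "min": float(v.min()),
        "max": float(v.max()),
        "median": float(np.median(v)),
        "iqr": float(q75 - q25),
    }


def normality_gate(groups: list[np.ndarray], alpha: float = 0.05) -> str:
    """Choose the parametric track iff every group passes Shapiro-Wilk.

    Groups smaller than 3 or with zero variance cannot be tested and push
    the variable onto the nonparametric track with a warning.
    """
    for g in groups:
        g = np.asarray(g, dtype=float)
        if g.size < 3:
            warnings.warn("group with fewer than 3 observations; using nonparametric track")
            return NONPARAMETRIC
        if np.ptp(g) == 0:
            warnings.warn("constant group; Shapiro-Wilk undefined, using nonparametric track")
            return NONPARAMETRIC
        if sps.shapiro(g).pvalue < alpha:
            return NONPARAMETRIC
    return PARAMETRIC


def f_critical(alpha: float, k: int, n_total: int) -> float:
    """ANOVA rejection threshold F(1-alpha; k-1, n-k)."""
    return float(sps.f.ppf(1 - alpha, k - 1, n_total - k))


def h_critical(alpha: float, k: int) -> float:
    """Kruskal-Wallis large-sample rejection threshold chi2(1-alpha; k-1)."""
    return float(sps.chi2.ppf(1 - alpha, k - 1))


def _pooled_t_posthoc(groups: dict[str, np.ndarray], alpha: float) -> list[PosthocResult]:
    """Pairwise t tests on the ANOVA's pooled within-group MSE, Bonferroni-adjusted."""
    labels = list(groups)
    n_total = sum(g.size for g in groups.values())
    k = len(groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
    df = n_total - k
    mse = ss_within / df
    pairs = list(itertools.combinations(labels, 2))
    out = []
    for a, b in pairs:
        ga, gb = groups[a], groups[b]
        se = np.sqrt(mse * (1 / ga.size + 1 / gb.size))
        t = (ga.mean() - gb.mean()) / se if se > 0 else 0.0
        raw = float(2 * sps.t.sf(abs(t), df))
        adj = min(1.0, raw * len(pairs))
        out.append(PosthocResult((a, b), raw, adj, adj < alpha))
    return out


def dunn_bonferroni(groups: dict[str, np.ndarray], alpha: float = 0.05) -> list[PosthocResult]:
    """Dunn's pooled-rank z tests for all pairs, Bonferroni-adjusted.

    Ranks are mid-ranks over the pooled sample; the variance term carries the
    standard tie correction sum(t^3 - t) / (12 (N - 1)).
    """
    labels = list(groups)
    pooled = np.concatenate([groups[l] for l in labels])
    ranks = sps.rankdata(pooled)
    n_total = pooled.size
    mean_ranks, sizes = {}, {}
    start = 0
    for l in labels:
        n = groups[l].size
        mean_ranks[l] = ranks[start:start + n].mean()
        sizes[l] = n
        start += n
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts ** 3 - tie_counts).sum()) / (12 * (n_total - 1))) if n_total > 1 else 0.0
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    pairs = list(itertools.combinations(labels, 2))
    out = []
    for a, b in pairs:
        se = np.sqrt(var_base * (1 / sizes[a] + 1 / sizes[b]))
        z = (mean_ranks[a] - mean_ranks[b]) / se if se > 0 else 0.0
        raw = float(2 * sps.norm.sf(abs(z)))
        adj = min(1.0, raw * len(pairs))
        out.append(PosthocResult((a, b), raw, adj, adj < alpha))
    return out


def compare_three_groups(
    values: "np.ndarray | pd.Series",
    labels: "np.ndarray | pd.Series",
    variable: str = "",
    alpha: float = 0.05,
    force: str | None = None,
) -> GroupComparison:
    """Omnibus + post-hoc comparison of exactly three groups.

    The normality gate picks ANOVA or Kruskal-Wallis unless ``force``
    overrides it (e.g. ordinal questionnaire scores are always
    nonparametric).  Post-hoc pairwise tests always run; a note marks them
    exploratory when the omnibus is non-significant.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    group_names = list(pd.unique(labels))
    if len(group_names) != 3:
        raise ValueError(f"expected exactly 3 groups, got {len(group_names)}")
    groups = {g: values[labels == g] for g in group_names}
    for g, v in groups.items():
        if v.size == 0:
            raise ValueError(f"group {g!r} is empty")

    track = force or normality_gate(list(groups.values()), alpha)
    notes: list[str] = []
    if track == PARAMETRIC:
        stat, p = sps.f_oneway(*groups.values())
        posthoc = _pooled_t_posthoc(groups, alpha)
        test_used = "ANOVA"
    else:
        stat, p = sps.kruskal(*groups.values())
        posthoc = dunn_bonferroni(groups, alpha)
        test_used = "KruskalWallis"
    significant = p < alpha
    if not significant and any(r.significant for r in posthoc):
        notes.append("post-hoc significant despite non-significant omnibus; interpret cautiously")
    return GroupComparison(
        variable=variable,
        test_used=test_used,
        statistic=float(stat),
        p_value=float(p),
        omnibus_significant=bool(significant),
        posthoc=posthoc,
        descriptives={g: describe(v) for g, v in groups.items()},
        alpha=alpha,
        notes=notes,
    )


# --- r x c Fisher exact test -------------------------------------------------

def _log_table_prob(table: np.ndarray, log_margin: float) -> float:
    return log_margin - gammaln(table + 1).sum()


def _enumerate_tables(row_sums: np.ndarray, col_sums: np.ndarray, cap: int):
    """Yield all non-negative integer tables with the given margins.

    Rows are filled recursively; enumeration aborts by raising OverflowError
    once ``cap`` tables have been produced.
    """
    r, c = len(row_sums), len(col_sums)
    count = 0

    def fill_row(remaining_cols: np.ndarray, row_total: int, j: int, row: list[int]):
        if j == c - 1:
            if row_total <= remaining_cols[j]:
                yield row + [row_total]
            return
        hi = min(row_total, remaining_cols[j])
        for x in range(hi + 1):
            yield from fill_row(remaining_cols, row_total - x, j + 1, row + [x])

    def rec(i: int, remaining_cols: np.ndarray, rows: list[list[int]]):
        nonlocal count
        if i == r - 1:
            if all(x >= 0 for x in remaining_cols):
                count += 1
                if count > cap:
                    raise OverflowError
                yield np.array(rows + [list(remaining_cols)], dtype=np.int64)
            return
        for row in fill_row(remaining_cols, int(row_sums[i]), 0, []):
            yield from rec(i + 1, remaining_cols - np.array(row), rows + [row])

    yield from rec(0, col_sums.astype(np.int64).copy(), [])


def categorical_association(
    table: "np.ndarray | list[list[int]]",
    max_enumeration: int = 2_000_000,
    n_monte_carlo: int = 100_000,
    seed: int = 0,
) -> CategoricalAssociation:
    """Exact test of independence on an r x c count table.

    The p-value sums the conditional (multivariate hypergeometric)
    probabilities of every table with the observed margins whose probability
    does not exceed the observed table's.  Tables with more than
    ``max_enumeration`` candidates fall back to a seeded Monte-Carlo sample
    of the null, which estimates the same quantity.
    """
    t = np.asarray(table)
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("counts must be integers")
        t = np.round(t).astype(np.int64)
    if (t < 0).any():
        raise ValueError("counts must be non-negative")
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    n = int(t.sum())
    if n == 0:
        raise ValueError("table has no observations")
    # degenerate margins (an all-zero row/column) carry no information
    keep_r = row_sums > 0
    keep_c = col_sums > 0
    if keep_r.sum() < 2 or keep_c.sum() < 2:
        return CategoricalAssociation(t, 1.0, "enumeration", 1)
    t = t[np.ix_(keep_r, keep_c)]
    row_sums, col_sums = t.sum(axis=1), t.sum(axis=0)

    log_margin = gammaln(row_sums + 1).sum() + gammaln(col_sums + 1).sum() - gammaln(n + 1)
    log_p_obs = _log_table_prob(t, log_margin)
    eps = 1e-9 * abs(log_p_obs)

    try:
        total = 0.0
        count = 0
        for cand in _enumerate_tables(row_sums, col_sums, max_enumeration):
            count += 1
            lp = _log_table_prob(cand, log_margin)
            if lp <= log_p_obs + eps + 1e-12:
                total += np.exp(lp)
        return CategoricalAssociation(t, float(min(total, 1.0)), "enumeration", count)
    except OverflowError:
        pass

    rng = np.random.default_rng(seed)
    row_labels = np.repeat(np.arange(len(row_sums)), row_sums)
    col_labels = np.repeat(np.arange(len(col_sums)), col_sums)
    r, c = len(row_sums), len(col_sums)
    hits = 0
    for _ in range(n_monte_carlo):
        perm = rng.permutation(col_labels)
        flat = np.bincount(row_labels * c + perm, minlength=r * c)
        lp = _log_table_prob(flat.reshape(r, c), log_margin)
        if lp <= log_p_obs + eps + 1e-12:
            hits += 1
    return CategoricalAssociation(t, hits / n_monte_carlo, "monte-carlo", n_monte_carlo)
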