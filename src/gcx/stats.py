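"""Association statistics: contingency tests, enrichment scans across the
genomic-complexity groups, rank correlations and two-group comparisons.

Test choice follows a fixed rule rather than per-case judgement: a 2x2
table falls back to Fisher's exact test whenever any expected cell count
is below 5, otherwise (and for any r x c table) a chi-squared test without
continuity correction is used. Multiple testing within one scan is
controlled by Benjamini-Hochberg over the scan's own family of tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .errors import ContractViolation, UndefinedResultError, ValidationError


@dataclass
class ContingencyResult:
    feature: str
    grouping: str
    table: np.ndarray
    test_used: str
    p: float
    odds_ratio: float | None = None
    p_adj: float | None = None


@dataclass(frozen=True)
class CorrelationResult:
    variables: tuple[str, str]
    tau_b: float
    p: float
    n: int


@dataclass(frozen=True)
class RankSumResult:
    p: float
    statistic: float
    medians: tuple[float, float]
    n: tuple[int, int]


def odds_ratio_2x2(table: np.ndarray) -> float:
    """Cross-product odds ratio a*d / (b*c); divergent tables map to the
    +inf / 0 sentinels."""
    a, b = table[0]
    c, d = table[1]
    if b * c == 0:
        return float("inf") if a * d > 0 else (0.0 if a * d == 0 else float("inf"))
    return (a * d) / (b * c)


def contingency_test(
    table,
    feature: str = "",
    grouping: str = "",
    force: str | None = None,
) -> ContingencyResult:
    """Two-sided test of independence on an integer count table.

    Rule: Fisher's exact for a 2x2 with any expected cell < 5, chi-squared
    (no Yates correction) otherwise; ``force`` overrides with 'fisher' or
    'chi-squared'. The odds ratio is reported for 2x2 tables only.
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValidationError("need at least a 2x2 table")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValidationError("counts must be non-negative integers")
    t = np.round(t).astype(int)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise UndefinedResultError("a margin of the table is all zero")
    is_2x2 = t.shape == (2, 2)
    if force is not None:
        if force not in ("fisher", "chi-squared"):
            raise ValidationError(f"unknown test {force!r}")
        if force == "fisher" and not is_2x2:
            raise ValidationError("Fisher's exact test requires a 2x2 table")
        test = force
    else:
        expected = sps.contingency.expected_freq(t)
        test = "fisher" if (is_2x2 and (expected < 5).any()) else "chi-squared"
    if test == "fisher":
        _, p = sps.fisher_exact(t, alternative="two-sided")
    else:
        chi2, p, _, _ = sps.chi2_contingency(t, correction=False)
    return ContingencyResult(
        feature=feature,
        grouping=grouping,
        table=t,
        test_used=test,
        p=float(p),
        odds_ratio=odds_ratio_2x2(t) if is_2x2 else None,
    )


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, >= raw)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def enrichment_scan(
    cohort: pd.DataFrame,
    features: Sequence[str],
    grouping: str = "gc_class",
    groups: Sequence[str] | None = None,
) -> list[ContingencyResult]:
    """One-vs-rest enrichment of each feature in each level of ``grouping``.

    For every feature x group pair a 2x2 table (feature+/- vs in-group /
    out-of-group) is tested over complete cases; BH adjustment is applied
    across the whole scan (one family per call). Features with a single
    observed level are skipped. Results are sorted by adjusted p.
    """
    if grouping not in cohort.columns:
        raise ValidationError(f"no grouping column {grouping!r}")
    levels = list(groups) if groups is not None else sorted(
        cohort[grouping].dropna().unique()
    )
    results: list[ContingencyResult] = []
    for feat in features:
        if feat not in cohort.columns:
            raise ValidationError(f"no feature column {feat!r}")
        sub = cohort[[feat, grouping]].dropna()
        vals = sub[feat]
        if vals.nunique() < 2:
            continue
        x = vals.astype(bool) if vals.dtype == bool or vals.isin([0, 1, True, False]).all() else None
        if x is None:
            # categorical feature: test the full r x c table once per scan
            tab = pd.crosstab(sub[feat], sub[grouping]).to_numpy()
            results.append(contingency_test(tab, feature=feat, grouping=grouping))
            continue
        for level in levels:
            in_group = (sub[grouping] == level).to_numpy()
            fx = x.to_numpy()
            tab = np.array(
                [
                    [int((fx & in_group).sum()), int((fx & ~in_group).sum())],
                    [int((~fx & in_group).sum()), int((~fx & ~in_group).sum())],
                ]
            )
            try:
                res = contingency_test(tab, feature=feat, grouping=f"{grouping}={level}")
            except UndefinedResultError:
                continue
            results.append(res)
    adj = bh_adjust([r.p for r in results])
    for r, a in zip(results, adj):
        r.p_adj = float(a)
    results.sort(key=lambda r: (r.p_adj, r.p))
    return results


def kendall_tau(
    x, y, variables: tuple[str, str] = ("x", "y")
) -> CorrelationResult:
    """Kendall's tau-b (tie-corrected) with asymptotic two-sided p.

    Complete cases only; CNA counts are heavily tied, hence tau-b.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValidationError("need at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise UndefinedResultError("correlation undefined for a constant vector")
    res = sps.kendalltau(x, y, variant="b")
    return CorrelationResult(
        variables=variables, tau_b=float(res.statistic), p=float(res.pvalue), n=int(x.size)
    )


def group_compare_continuous(values, groups) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) comparison of a continuous
    variable between exactly two groups; reports the group medians."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    keep = ~np.isnan(values) & ~pd.isna(groups)
    values, groups = values[keep], groups[keep]
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ContractViolation(f"expected exactly 2 groups, got {len(levels)}")
    a = values[groups == levels[0]]
    b = values[groups == levels[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each group needs n >= 2")
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return RankSumResult(
        p=float(res.pvalue),
        statistic=float(res.statistic),
        medians=(float(np.median(a)), float(np.median(b))),
        n=(len(a), len(b)),
    )


def association_frame(results: Sequence[ContingencyResult]) -> pd.DataFrame:
    """Flatten scan results for TSV export."""
    rows = []
    for r in results:
        cells = ";".join(",".join(str(v) for v in row) for row in r.table)
        rows.append(
            {
                "feature": r.feature,
                "grouping": r.grouping,
                "table": cells,
                "odds_ratio": r.odds_ratio,
                "p": r.p,
                "p_adj": r.p_adj,
                "test_used": r.test_used,
            }
        )
    return pd.DataFrame(rows)
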