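"""Targeted group screen: detection-sufficiency filter, Mann-Whitney U,
fold change, ranking, and standardized multifactorial regression.

The screen retains metabolites with strictly more than ``min_values``
quantified values across both groups, tests each with a two-sided
Mann-Whitney U test (exact enumeration for small samples, tie-corrected
normal approximation otherwise), keeps rows significant at ``alpha`` and
ranks them by descending case-over-control fold change.
"""
from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import InvalidParameterError, RankDeficiencyError, UndefinedRatioError

__all__ = [
    "StatsConfig",
    "ComparisonRow",
    "lod_filter",
    "mann_whitney_u",
    "fold_change",
    "compare_groups",
    "comparison_to_frame",
    "standardized_regression",
]

_EXACT_MAX_N = 8  # both samples at or below this size -> exact enumeration


@dataclass(frozen=True)
class StatsConfig:
    min_values: int = 10  # strict ">" threshold on total quantified values
    alpha: float = 0.05
    bh_correction: bool = False  # off by default; no correction in the reference screen

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise InvalidParameterError("alpha must be in (0, 1)")
        if self.min_values < 0:
            raise InvalidParameterError("min_values must be >= 0")


@dataclass
class ComparisonRow:
    metabolite: str
    n_control: int
    n_case: int
    mean_control: float
    mean_case: float
    sd_control: float
    sd_case: float
    u_statistic: float
    p_value: float
    fold_change: float


def lod_filter(table: pd.DataFrame, config: StatsConfig = StatsConfig()) -> list[str]:
    """Metabolites with strictly more than ``min_values`` non-missing values in total."""
    if table.shape[1] == 0:
        raise InvalidParameterError("table has no metabolite columns")
    counts = table.notna().sum(axis=0)
    return [name for name, c in counts.items() if c > config.min_values]


def _exact_two_sided_p(x: np.ndarray, y: np.ndarray, u_obs: float) -> float:
    """Enumerate all group assignments of the pooled values (handles ties)."""
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    n1 = len(x)
    m = n1 * len(y)
    offset = n1 * (n1 + 1) / 2.0
    dev_obs = abs(u_obs - m / 2.0)
    hits = total = 0
    for combo in combinations(range(len(pooled)), n1):
        u = ranks[list(combo)].sum() - offset
        total += 1
        if abs(u - m / 2.0) >= dev_obs - 1e-9:
            hits += 1
    return hits / total


def mann_whitney_u(x, y) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Returns ``(U, p)`` with U counted for the first sample (pairs where x
    exceeds y, ties counting one half).  When both samples have at most 8
    values the p-value is computed by exact enumeration of all group
    assignments of the pooled (possibly tied) values; otherwise by the
    normal approximation with midranks, tie-corrected variance and
    continuity correction.  If every pooled value is identical, p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise InvalidParameterError("both samples must be nonempty")
    n1, n2 = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2.0)
    m = n1 * n2

    if n1 <= _EXACT_MAX_N and n2 <= _EXACT_MAX_N:
        return u, _exact_two_sided_p(x, y, u)

    _, tie_counts = np.unique(pooled, return_counts=True)
    n = n1 + n2
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (n * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return u, 1.0
    dev = u - m / 2.0
    cc = 0.5 * np.sign(dev)
    z = (dev - cc) / math.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(z))
    return u, float(min(p, 1.0))


def fold_change(mean_case: float, mean_control: float) -> float:
    """Case-over-control ratio of group means."""
    if mean_control <= 0:
        raise UndefinedRatioError(f"control mean must be > 0, got {mean_control}")
    return mean_case / mean_control


def compare_groups(
    table: pd.DataFrame,
    labels,
    config: StatsConfig = StatsConfig(),
    case_label: str = "PKU",
    control_label: str = "control",
) -> list[ComparisonRow]:
    """Per-metabolite group comparison, filtered at ``alpha`` and ranked.

    Applies the detection-sufficiency filter first, computes per-group
    n/mean/SD on non-missing values, the two-sided Mann-Whitney p and the
    fold change, keeps rows with p < alpha (optionally after
    Benjamini-Hochberg adjustment) and sorts by descending fold change.
    """
    labels = pd.Series(np.asarray(labels), index=table.index)
    present = set(labels.unique())
    if case_label not in present or control_label not in present:
        raise InvalidParameterError(
            f"labels must contain {case_label!r} and {control_label!r}; got {sorted(present)}"
        )
    case_rows = labels == case_label
    ctrl_rows = labels == control_label

    rows = []
    for name in lod_filter(table, config):
        xc = table.loc[case_rows, name].dropna().to_numpy()
        xh = table.loc[ctrl_rows, name].dropna().to_numpy()
        if xc.size == 0 or xh.size == 0:
            continue
        u, p = mann_whitney_u(xc, xh)
        mean_case, mean_ctrl = float(xc.mean()), float(xh.mean())
        rows.append(
            ComparisonRow(
                metabolite=name,
                n_control=int(xh.size),
                n_case=int(xc.size),
                mean_control=mean_ctrl,
                mean_case=mean_case,
                sd_control=float(xh.std(ddof=1)) if xh.size > 1 else float("nan"),
                sd_case=float(xc.std(ddof=1)) if xc.size > 1 else float("nan"),
                u_statistic=u,
                p_value=p,
                fold_change=fold_change(mean_case, mean_ctrl),
            )
        )
    if config.bh_correction and rows:
        order = np.argsort([r.p_value for r in rows])
        k = len(rows)
        adj = np.empty(k)
        prev = 1.0
        for rank_pos, idx in enumerate(reversed(order), start=0):
            i = k - rank_pos
            prev = min(prev, rows[idx].p_value * k / i)
            adj[idx] = prev
        for r, a in zip(rows, adj):
            r.p_value = float(a)
    kept = [r for r in rows if r.p_value < config.alpha]
    kept.sort(key=lambda r: r.fold_change, reverse=True)
    return kept


def comparison_to_frame(rows: list[ComparisonRow]) -> pd.DataFrame:
    """Comparison rows as a table mirroring the reference layout."""
    return pd.DataFrame(
        [
            {
                "metabolite": r.metabolite,
                "n_control": r.n_control,
                "mean_control": r.mean_control,
                "sd_control": r.sd_control,
                "n_case": r.n_case,
                "mean_case": r.mean_case,
                "sd_case": r.sd_case,
                "u_statistic": r.u_statistic,
                "p_value": r.p_value,
                "fold_change": r.fold_change,
            }
            for r in rows
        ]
    )


def standardized_regression(response, predictors: pd.DataFrame) -> pd.DataFrame:
    """OLS on z-scored response and predictors (standardized betas + p-values).

    Incomplete cases are dropped.  Collinear predictors raise a
    rank-deficiency error naming the offending columns.
    """
    predictors = pd.DataFrame(predictors)
    y = pd.Series(np.asarray(response, dtype=float), index=predictors.index, name="response")
    data = pd.concat([y, predictors.astype(float)], axis=1).dropna()
    k = predictors.shape[1]
    if data.shape[0] < k + 2:
        raise InvalidParameterError(
            f"need at least {k + 2} complete cases, got {data.shape[0]}"
        )
    z = (data - data.mean()) / data.std(ddof=1)
    if z.isna().any().any():
        flat = [c for c in z.columns if z[c].isna().any() and c != "response"]
        raise RankDeficiencyError(flat or ["response"])
    Xz = z[predictors.columns]
    rank = np.linalg.matrix_rank(Xz.to_numpy())
    if rank < k:
        _, r = np.linalg.qr(Xz.to_numpy())
        bad = [predictors.columns[j] for j in range(k) if abs(r[j, j]) < 1e-8 * abs(r).max()]
        raise RankDeficiencyError(bad or list(predictors.columns))
    fit = sm.OLS(z["response"], sm.add_constant(Xz)).fit()
    return pd.DataFrame(
        {"beta": fit.params.drop("const"), "p_value": fit.pvalues.drop("const")}
    )
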