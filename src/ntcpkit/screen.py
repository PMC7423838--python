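"""Univariate screening: Spearman correlation against ordinal toxicity
grades, Wilcoxon rank-sum between dichotomized groups, and the p < 0.1
candidate screen.

Spearman uses the full CTCAE 0-5 scale; the Wilcoxon test compares feature
values between the grade < 2 and grade >= 2 groups.  No multiple-testing
correction is applied at this stage (deliberately; screening only).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, ParameterError, UndefinedStatisticError

#: Covariates always carried into multivariate modeling regardless of p.
DEFAULT_ALWAYS_INCLUDE = ("treatment_days", "sbrt", "chemo")


@dataclass(frozen=True)
class UnivariateResult:
    feature: str
    endpoint: str
    rs: float
    p_spearman: float
    wilcoxon_p: float
    n: int
    passed: bool = False


def spearman(
    x: np.ndarray,
    grades: np.ndarray,
    method: str = "t",
    n_perm: int = 10_000,
    seed: int | None = None,
) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided p value.

    rs is the Pearson correlation of mid-ranks (average ranks on ties).
    ``method="t"`` (default) uses the t-approximation with n-2 degrees of
    freedom; ``method="permutation"`` runs a seeded permutation test.
    """
    x = np.asarray(x, dtype=float)
    g = np.asarray(grades, dtype=float)
    if x.shape != g.shape or x.ndim != 1:
        raise ParameterError("x and grades must be 1-D of equal length")
    n = x.size
    if n < 3:
        raise ParameterError("need at least 3 observations")
    if np.ptp(x) == 0 or np.ptp(g) == 0:
        raise UndefinedStatisticError("Spearman correlation undefined for constant input")

    rs = _rank_corr(x, g)
    if method == "t":
        p = _t_pvalue(rs, n)
    elif method == "permutation":
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            if abs(_rank_corr(x, rng.permutation(g))) >= abs(rs) - 1e-12:
                hits += 1
        p = (hits + 1) / (n_perm + 1)
    else:
        raise ParameterError(f"unknown method {method!r}")
    return float(rs), float(p)


def _rank_corr(x: np.ndarray, y: np.ndarray) -> float:
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx**2).sum() * (ry**2).sum())
    return float((rx * ry).sum() / denom)


def _t_pvalue(rs: float, n: int) -> float:
    if abs(rs) >= 1.0:
        return 0.0
    t = rs * np.sqrt((n - 2) / (1.0 - rs * rs))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


def wilcoxon_rank_sum(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns the rank-sum statistic of group ``a`` (mid-ranks) and a
    two-sided p value: exact by enumeration when the pooled sample has at
    most 12 tie-free observations, otherwise a normal approximation with
    tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ParameterError("both groups must be non-empty")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    method = "exact" if (pooled.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method, use_continuity=True)
    w = float(res.statistic) + a.size * (a.size + 1) / 2.0  # U -> rank sum
    return w, float(min(res.pvalue, 1.0))


def screen_features(
    features: pd.DataFrame,
    grades: pd.Series | np.ndarray,
    endpoint: str,
    alpha: float = 0.1,
    always_include: tuple[str, ...] = DEFAULT_ALWAYS_INCLUDE,
) -> pd.DataFrame:
    """Univariate screen of every feature column against one endpoint.

    A feature passes when its Spearman p is below ``alpha`` or when it is
    on the always-include list.  Output is sorted by \\|rs\\| descending and
    carries the Wilcoxon p between the grade < 2 and >= 2 groups.
    """
    if features.shape[1] == 0 or len(features) == 0:
        raise DataError("empty feature table")
    if not 0 <= alpha <= 1:
        raise ParameterError("alpha must lie in [0, 1]")
    g = np.asarray(grades, dtype=float)
    if g.shape[0] != len(features):
        raise ParameterError("grades length does not match feature table")
    lo = g < 2
    hi = ~lo

    rows = []
    for name in features.columns:
        x = features[name].to_numpy(dtype=float)
        constant = np.ptp(x) == 0
        if constant:
            rs, p = np.nan, np.nan
        else:
            rs, p = spearman(x, g)
        if lo.any() and hi.any() and not constant:
            _, wp = wilcoxon_rank_sum(x[hi], x[lo])
        else:
            wp = np.nan
        passed = (not constant and p < alpha) or name in always_include
        rows.append(
            UnivariateResult(
                feature=name,
                endpoint=endpoint,
                rs=rs,
                p_spearman=p,
                wilcoxon_p=wp,
                n=len(features),
                passed=bool(passed),
            )
        )
    df = pd.DataFrame([r.__dict__ for r in rows])
    df["abs_rs"] = df["rs"].abs()
    df = (
        df.sort_values(["abs_rs", "feature"], ascending=[False, True], na_position="last")
        .drop(columns="abs_rs")
        .reset_index(drop=True)
    )
    return df


def candidate_features(screen_df: pd.DataFrame) -> list[str]:
    """Features that passed the screen, in decreasing \\|rs\\| order."""
    return screen_df.loc[screen_df["passed"], "feature"].tolist()
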