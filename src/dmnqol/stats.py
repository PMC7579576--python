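"""Rank-based group comparison, variance tests, correlations, stepwise AIC.

The centerpiece is the reconstruction of a one-sided Mann–Whitney test from
*published summary statistics* (group sizes and mean ranks): those two
numbers per group determine the rank sum, hence U, hence the
normal-approximation z and its one-sided p.  The approximation deliberately
uses no continuity and no tie correction — that is the variant whose
truncated p-values match the printed significance column of the study this
package reimplements.  Exact enumeration, tie correction and continuity
correction are all available behind flags.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    CapacityError,
    ConsistencyError,
    DegenerateSignalError,
    ParameterError,
)

__all__ = [
    "CorrMatrixFlagged",
    "LeveneResult",
    "MWResult",
    "RankSummary",
    "StepwiseModel",
    "brown_forsythe_two_groups",
    "mann_whitney",
    "mann_whitney_from_ranks",
    "pearson_flagged_matrix",
    "rank_with_ties",
    "stepwise_aic",
]


@dataclass
class RankSummary:
    """Mid-rank summary of two groups pooled into one ranking."""

    n1: int
    n2: int
    mean_rank_1: float
    mean_rank_2: float
    rank_sum_1: float
    rank_sum_2: float
    ranks: np.ndarray = field(default=None, repr=False)  # type: ignore


def rank_with_ties(
    values: Sequence[float], groups: Sequence
) -> RankSummary:
    """Rank the pooled sample (ties share mid-ranks) and summarise by group.

    ``groups`` must contain exactly two distinct labels; the first label in
    order of appearance is group 1.
    """
    values = np.asarray(values, dtype=float)
    if not np.isfinite(values).all():
        raise ParameterError("all values must be finite")
    groups = np.asarray(groups)
    labels = list(dict.fromkeys(groups.tolist()))
    if len(labels) != 2:
        raise ParameterError(f"need exactly 2 groups, got {labels}")
    mask1 = groups == labels[0]
    n1, n2 = int(mask1.sum()), int((~mask1).sum())
    if n1 == 0 or n2 == 0:
        raise ParameterError("both groups must be nonempty")
    ranks = sps.rankdata(values, method="average")
    return RankSummary(
        n1=n1,
        n2=n2,
        mean_rank_1=float(ranks[mask1].mean()),
        mean_rank_2=float(ranks[~mask1].mean()),
        rank_sum_1=float(ranks[mask1].sum()),
        rank_sum_2=float(ranks[~mask1].sum()),
        ranks=ranks,
    )


@dataclass
class MWResult:
    """One-sided Mann–Whitney result.

    ``direction`` names the group (1 or 2) with the larger mean rank; the
    one-sided p is the upper-tail probability in that direction.
    """

    u: float
    z: float
    p_one_sided: float
    direction: int


def _mw_from_rank_sum(
    w_big: float, n_big: int, n_small: int, direction: int
) -> MWResult:
    u = w_big - n_big * (n_big + 1) / 2.0
    n1n2 = n_big * n_small
    u = min(max(u, 0.0), n1n2)
    sigma = math.sqrt(n1n2 * (n_big + n_small + 1) / 12.0)
    z = (u - n1n2 / 2.0) / sigma
    return MWResult(
        u=u, z=z, p_one_sided=float(sps.norm.sf(z)), direction=direction
    )


def mann_whitney_from_ranks(
    mean_rank_1: float, n1: int, mean_rank_2: float, n2: int
) -> MWResult:
    """Reconstruct the one-sided Mann–Whitney test from printed mean ranks.

    The rank sum of the larger-mean-rank group is ``mean_rank * n``,
    rounded to the nearest attainable half-integer (printed mean ranks are
    rounded); U follows as ``W - n(n+1)/2`` and z as the tie-free,
    continuity-free normal approximation
    ``(U - n1 n2 / 2) / sqrt(n1 n2 (n1 + n2 + 1) / 12)``.

    The mean ranks must be consistent with total-rank conservation
    (sum of rank sums = N(N+1)/2) up to printing precision.
    """
    if n1 <= 0 or n2 <= 0:
        raise ParameterError("group sizes must be positive")
    total = n1 + n2
    implied = mean_rank_1 * n1 + mean_rank_2 * n2
    expected = total * (total + 1) / 2.0
    if abs(implied - expected) > 0.005 * total + 0.01:
        raise ConsistencyError(
            f"mean ranks imply a rank total of {implied:.2f}, "
            f"expected {expected:.1f}"
        )
    if mean_rank_1 >= mean_rank_2:
        direction, mr, n_big, n_small = 1, mean_rank_1, n1, n2
    else:
        direction, mr, n_big, n_small = 2, mean_rank_2, n2, n1
    w_big = round(mr * n_big * 2.0) / 2.0
    return _mw_from_rank_sum(w_big, n_big, n_small, direction)


def mann_whitney(
    x: Sequence[float],
    y: Sequence[float],
    exact: bool = False,
    tie_correction: bool = False,
    continuity: bool = False,
) -> MWResult:
    """One-sided Mann–Whitney test on raw samples.

    The default approximate path matches :func:`mann_whitney_from_ranks`
    (no tie or continuity correction).  With ``exact=True`` the one-sided p
    is P(rank sum of the larger-mean-rank group >= observed) under all
    C(n1+n2, n1) equally likely group assignments of the pooled (possibly
    tied) values; enumeration is capped at n1 + n2 <= 12.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    summary = rank_with_ties(
        np.concatenate([x, y]), np.array([1] * n1 + [2] * n2)
    )
    direction = 1 if summary.mean_rank_1 >= summary.mean_rank_2 else 2
    if exact:
        if n1 + n2 > 12:
            raise CapacityError(
                "exact enumeration supported only for n1 + n2 <= 12"
            )
        ranks = summary.ranks
        n_big = n1 if direction == 1 else n2
        observed = summary.rank_sum_1 if direction == 1 else summary.rank_sum_2
        count = total = 0
        for combo in itertools.combinations(range(n1 + n2), n_big):
            total += 1
            if ranks[list(combo)].sum() >= observed - 1e-9:
                count += 1
        u_obs = observed - n_big * (n_big + 1) / 2.0
        return MWResult(
            u=float(u_obs),
            z=float("nan"),
            p_one_sided=count / total,
            direction=direction,
        )
    w_big = summary.rank_sum_1 if direction == 1 else summary.rank_sum_2
    n_big = n1 if direction == 1 else n2
    n_small = n2 if direction == 1 else n1
    result = _mw_from_rank_sum(w_big, n_big, n_small, direction)
    if tie_correction or continuity:
        n = n1 + n2
        _, counts = np.unique(summary.ranks, return_counts=True)
        tie_term = (
            (counts**3 - counts).sum() / (n * (n - 1)) if tie_correction
            else 0.0
        )
        sigma = math.sqrt(n1 * n2 / 12.0 * (n + 1 - tie_term))
        cc = 0.5 if continuity else 0.0
        if sigma == 0:
            raise DegenerateSignalError("all values tied; z undefined")
        z = (result.u - cc - n1 * n2 / 2.0) / sigma
        result = MWResult(
            u=result.u,
            z=z,
            p_one_sided=float(sps.norm.sf(z)),
            direction=direction,
        )
    return result


@dataclass
class LeveneResult:
    """Two-group variance-comparison result (median-centered by default)."""

    w: float
    df: tuple[int, int]
    p: float
    degenerate: bool = False


def brown_forsythe_two_groups(
    x: Sequence[float], y: Sequence[float], center: str = "median"
) -> LeveneResult:
    """Adapted Levene test for two groups (Brown–Forsythe variant).

    A one-way ANOVA on absolute deviations from the group medians (or
    means, with ``center="mean"``), df = (1, n1 + n2 - 2).  If every value
    equals its group center the statistic is undefined: the result carries
    ``W = inf`` and a degenerate flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ParameterError("each group needs at least 2 values")
    loc = np.median if center == "median" else np.mean
    dev_x = np.abs(x - loc(x))
    dev_y = np.abs(y - loc(y))
    pooled = np.concatenate([dev_x, dev_y])
    grand = pooled.mean()
    ssb = len(x) * (dev_x.mean() - grand) ** 2 + (
        len(y) * (dev_y.mean() - grand) ** 2
    )
    ssw = ((dev_x - dev_x.mean()) ** 2).sum() + (
        (dev_y - dev_y.mean()) ** 2
    ).sum()
    df = (1, len(x) + len(y) - 2)
    if ssw == 0.0:
        if ssb == 0.0:
            return LeveneResult(w=0.0, df=df, p=1.0)
        return LeveneResult(w=math.inf, df=df, p=0.0, degenerate=True)
    w = (ssb / df[0]) / (ssw / df[1])
    return LeveneResult(w=float(w), df=df, p=float(sps.f.sf(w, *df)))


@dataclass
class CorrMatrixFlagged:
    """Pearson correlation matrix with significance flags.

    Flags follow the reporting convention: ``*`` for p < 0.05, ``**`` for
    p < 0.001 (two-sided t-based p-values).
    """

    r: pd.DataFrame
    p: pd.DataFrame
    flags: pd.DataFrame


def pearson_flagged_matrix(table: pd.DataFrame) -> CorrMatrixFlagged:
    """Pairwise Pearson correlations over the columns of ``table``."""
    table = table.astype(float)
    n = len(table)
    if n < 3:
        raise ParameterError("need at least 3 rows to correlate")
    for col in table.columns:
        if table[col].std(ddof=0) == 0.0:
            raise DegenerateSignalError(f"zero-variance column {col!r}")
    r = table.corr(method="pearson")
    rv = r.to_numpy(copy=True)
    np.fill_diagonal(rv, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = rv * np.sqrt((n - 2) / np.clip(1.0 - rv**2, 1e-300, None))
    p = 2.0 * sps.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 0.0)
    flags = np.where(p < 0.001, "**", np.where(p < 0.05, "*", ""))
    np.fill_diagonal(flags, "")
    cols = r.columns
    return CorrMatrixFlagged(
        r=pd.DataFrame(rv, index=cols, columns=cols),
        p=pd.DataFrame(p, index=cols, columns=cols),
        flags=pd.DataFrame(flags, index=cols, columns=cols),
    )


@dataclass
class StepwiseModel:
    """Best linear model found by bidirectional AIC-stepwise search."""

    response: str
    coefficients: dict[str, float]  # includes "intercept"
    r_squared: float
    aic: float
    notes: list[str] = field(default_factory=list)

    @property
    def predictors(self) -> list[str]:
        return [k for k in self.coefficients if k != "intercept"]


def _ols_fit(y: np.ndarray, x: np.ndarray):
    import statsmodels.api as sm

    return sm.OLS(y, sm.add_constant(x, has_constant="add")).fit()


def _ols_aic(y: np.ndarray, design: np.ndarray) -> float:
    """Gaussian-likelihood AIC of an OLS fit (same convention as the
    final statsmodels fit: k counts every column of the design)."""
    n = len(y)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ beta
    ssr = float(resid @ resid)
    llf = -0.5 * n * (math.log(2.0 * math.pi) + math.log(ssr / n) + 1.0)
    return -2.0 * llf + 2.0 * design.shape[1]


def stepwise_aic(
    response: Sequence[float],
    predictors: pd.DataFrame,
    response_name: str = "response",
) -> StepwiseModel:
    """Bidirectional stepwise regression minimizing AIC.

    Starting from the intercept-only model, each step tries every single
    addition and every single deletion and applies the move with the
    lowest AIC, stopping when no move improves on the current model.  The
    intercept-only outcome is valid (the study's "rights" dimension selects
    no predictor).  Duplicated predictor columns are reduced to one copy;
    candidates that would make the design rank-deficient are skipped with a
    note.  R² is reported for the selected model but plays no role in the
    selection.
    """
    y = np.asarray(response, dtype=float)
    notes: list[str] = []
    cols: list[str] = []
    seen: dict[bytes, str] = {}
    for col in predictors.columns:
        key = np.ascontiguousarray(
            predictors[col].to_numpy(dtype=float)
        ).tobytes()
        if key in seen:
            notes.append(f"dropped duplicate column {col!r} (= {seen[key]!r})")
            continue
        seen[key] = col
        cols.append(col)
    x_all = predictors[cols].to_numpy(dtype=float)
    if len(y) != len(x_all):
        raise ParameterError("response and predictors differ in length")

    def candidate_aic(subset: list[str]) -> float | None:
        idx = [cols.index(c) for c in subset]
        design = np.column_stack([np.ones(len(y)), x_all[:, idx]])
        if np.linalg.matrix_rank(design) < design.shape[1]:
            return None
        return _ols_aic(y, design)

    current: list[str] = []
    current_aic = candidate_aic(current)
    assert current_aic is not None
    while True:
        best_move: tuple[float, list[str]] | None = None
        for col in cols:
            candidate = (
                [c for c in current if c != col]
                if col in current
                else current + [col]
            )
            if len(y) < len(candidate) + 2:
                continue
            aic = candidate_aic(candidate)
            if aic is None:
                notes.append(f"skipped rank-deficient candidate with {col!r}")
                continue
            if best_move is None or aic < best_move[0] - 1e-10:
                best_move = (aic, candidate)
        if best_move is None or best_move[0] >= current_aic - 1e-10:
            break
        current_aic, current = best_move
    current_fit = _ols_fit(
        y, x_all[:, [cols.index(c) for c in current]]
    )
    params = np.asarray(current_fit.params, dtype=float)
    coefficients = {"intercept": float(params[0])}
    coefficients.update(
        {c: float(b) for c, b in zip(current, params[1:])}
    )
    return StepwiseModel(
        response=response_name,
        coefficients=coefficients,
        r_squared=float(current_fit.rsquared) if current else 0.0,
        aic=float(current_fit.aic),
        notes=notes,
    )
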