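"""Hierarchical multiple-regression ledgers.

A ledger is an ordered sequence of nested ordinary-least-squares models for
one outcome: step k regresses the outcome on the union of predictor blocks
1..k. Each step is summarized by R^2, adjusted R^2

    adj R^2 = 1 - (1 - R^2) * (n - 1) / (n - p - 1),

the change in adjusted R^2 versus the previous step (the quantity used to
judge whether a block adds predictive power; adding predictors always raises
raw R^2, but adjusted R^2 can fall and even go negative), and the cumulative
model's overall F with (p, n - p - 1) degrees of freedom. A block-increment
partial F-test is available as an option.

Missing data are handled by listwise deletion per outcome, so different
outcomes can legitimately have different n.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .exceptions import CollinearityError, InsufficientDataError, ParameterError


@dataclass(frozen=True)
class PredictorBlock:
    """A named, ordered group of predictor variables added in one step."""

    name: str
    variables: tuple

    def __post_init__(self):
        object.__setattr__(self, "variables", tuple(self.variables))
        if not self.variables:
            raise ParameterError(f"block {self.name!r} has no variables")


@dataclass(frozen=True)
class OLSFit:
    coefficients: dict
    r2: float
    adj_r2: float
    f: float
    df1: int
    df2: int
    p: float
    n: int


@dataclass(frozen=True)
class LedgerStep:
    block: str
    cumulative_predictors: int
    r2: float
    adj_r2: float
    delta_adj_r2: float | None
    f: float
    df1: int
    df2: int
    p_value: float
    partial_f: float | None = None
    partial_p: float | None = None


@dataclass
class RegressionLedger:
    outcome: str
    n: int
    steps: list = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "outcome": self.outcome,
                "step": i + 1,
                "block": s.block,
                "n": self.n,
                "R2": s.r2,
                "adjR2": s.adj_r2,
                "deltaAdjR2": s.delta_adj_r2,
                "F": s.f,
                "df1": s.df1,
                "df2": s.df2,
                "p": s.p_value,
            }
            for i, s in enumerate(self.steps)
        ]
        return pd.DataFrame(rows)


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Closed-form adjusted R^2; may be negative for weak models."""
    if n <= p + 1:
        raise InsufficientDataError(f"n={n} must exceed p+1={p + 1}")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def _find_dependent_columns(X: np.ndarray, names) -> list[str]:
    """Columns that do not increase the rank when added left to right."""
    dependent = []
    rank = 0
    kept = np.empty((X.shape[0], 0))
    for j, name in enumerate(names):
        trial = np.column_stack([kept, X[:, j]])
        r = np.linalg.matrix_rank(trial)
        if r > rank:
            kept, rank = trial, r
        else:
            dependent.append(name)
    return dependent


def fit_ols(y, X, names=None, add_intercept: bool = True) -> OLSFit:
    """Ordinary least squares with overall-model F and adjusted R^2.

    ``X`` is an (n, p) matrix without the intercept column (added here unless
    ``add_intercept=False``). Rank-deficient designs raise
    :class:`CollinearityError` naming the dependent columns; ``n <= p + 1``
    raises :class:`InsufficientDataError`.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, p = X.shape
    if y.size != n:
        raise ParameterError("y and X must have matching length")
    names = list(names) if names is not None else [f"x{j + 1}" for j in range(p)]
    if len(names) != p:
        raise ParameterError("names must match the number of columns")
    if n <= p + 1:
        raise InsufficientDataError(
            f"n={n} observations cannot support p={p} predictors plus intercept"
        )
    design = sm.add_constant(X, has_constant="add") if add_intercept else X
    if np.linalg.matrix_rank(design) < design.shape[1]:
        intercept = np.ones((n, 1)) if add_intercept else np.empty((n, 0))
        dep = _find_dependent_columns(
            np.column_stack([intercept, X]),
            (["const"] if add_intercept else []) + names,
        )
        raise CollinearityError(dep or names)
    res = sm.OLS(y, design).fit()
    r2 = float(res.rsquared)
    df2 = n - p - 1
    # overall F recomputed from R^2 so degenerate fits (R^2 = 0) give F = 0
    f = (r2 / p) / ((1.0 - r2) / df2) if r2 < 1.0 else float("inf")
    p_value = float(sps.f.sf(f, p, df2)) if np.isfinite(f) else 0.0
    coef_names = (["const"] if add_intercept else []) + names
    return OLSFit(
        coefficients=dict(zip(coef_names, map(float, res.params))),
        r2=r2,
        adj_r2=adjusted_r2(r2, n, p),
        f=float(f),
        df1=p,
        df2=df2,
        p=p_value,
        n=n,
    )


def hierarchical_ledger(
    data: pd.DataFrame,
    outcome: str,
    blocks,
    partial_f: bool = False,
    small_sample_warning: int = 5,
) -> RegressionLedger:
    """Fit the nested model sequence and assemble the ledger.

    Parameters
    ----------
    data : DataFrame
        One row per animal, columns for the outcome and every predictor.
    outcome : str
        Outcome column name.
    blocks : sequence of PredictorBlock
        Ordered blocks; step k uses the union of blocks 1..k. A variable
        appearing in two blocks raises :class:`CollinearityError` at the
        later step.
    partial_f : bool
        Also compute the block-increment partial F-test per step (compares
        step k against step k-1 on the block's added degrees of freedom).
    small_sample_warning : int
        Warn when residual df (n - p - 1) falls at or below this value;
        ledgers with n of 9-13 and up to 6 predictors are permitted but
        fragile.
    """
    blocks = [b if isinstance(b, PredictorBlock) else PredictorBlock(*b) for b in blocks]
    seen: list[str] = []
    for k, b in enumerate(blocks):
        dup = [v for v in b.variables if v in seen]
        if dup:
            raise CollinearityError(
                dup, f"variable(s) {dup} repeated in block {k + 1} ({b.name!r})"
            )
        seen.extend(b.variables)
    cols = [outcome] + seen
    missing_cols = [c for c in cols if c not in data.columns]
    if missing_cols:
        raise ParameterError(f"missing column(s) in data: {missing_cols}")
    complete = data[cols].dropna()
    n = len(complete)
    ledger = RegressionLedger(outcome=outcome, n=n)
    y = complete[outcome].to_numpy(dtype=float)
    prev_adj = None
    prev_fit: OLSFit | None = None
    used: list[str] = []
    for b in blocks:
        used = used + list(b.variables)
        X = complete[used].to_numpy(dtype=float)
        fit = fit_ols(y, X, names=used)
        if fit.df2 <= small_sample_warning:
            warnings.warn(
                f"step {len(ledger.steps) + 1} ({b.name!r}) of outcome {outcome!r} "
                f"has only {fit.df2} residual df",
                stacklevel=2,
            )
        pf = pp = None
        if partial_f and prev_fit is not None:
            q = len(b.variables)
            num = (fit.r2 - prev_fit.r2) / q
            den = (1.0 - fit.r2) / fit.df2
            pf = num / den if den > 0 else float("inf")
            pp = float(sps.f.sf(pf, q, fit.df2)) if np.isfinite(pf) else 0.0
        ledger.steps.append(
            LedgerStep(
                block=b.name,
                cumulative_predictors=len(used),
                r2=fit.r2,
                adj_r2=fit.adj_r2,
                delta_adj_r2=None if prev_adj is None else fit.adj_r2 - prev_adj,
                f=fit.f,
                df1=fit.df1,
                df2=fit.df2,
                p_value=fit.p,
                partial_f=pf,
                partial_p=pp,
            )
        )
        prev_adj = fit.adj_r2
        prev_fit = fit
    return ledger
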