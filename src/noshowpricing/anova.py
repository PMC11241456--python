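"""Regression ANOVA of appointment covariates against the show-up outcome.

A linear probability model is fitted to the 0/1 outcome and each factor's
adjusted (Type-III / partial) sum of squares is the increase in residual SS
when that factor alone is dropped from the full model.  The partial F test
``F = (SS_drop/df) / (RSS_full/df_residual)`` with its F-distribution p-value
screens factors for statistical significance at the conventional p <= 0.05
rule (boundary inclusive).

Factor encodings:

* binary flags enter as single 0/1 columns (1 df);
* ``age`` enters centred (1 df);
* ``date`` enters as its annual sinusoid — the seasonal component of the
  appointment calendar (1 df);
* ``gender``, ``department`` and ``location_id`` enter as dummy blocks with
  the first level as reference (levels - 1 df).

The model is additive (no interactions), so partial SS coincides with the
classical Type-III adjusted SS regardless of contrast coding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f as f_dist

from noshowpricing.cohort import BINARY_COVARIATES, COVARIATES, DEPARTMENTS, _DAYS_PER_YEAR
from noshowpricing.io import outcome_to_binary

__all__ = ["AnovaRow", "AnovaTable", "regression_anova", "significance_screen", "AliasError"]

DEFAULT_FACTORS = tuple(c for c in COVARIATES)


class AliasError(ValueError):
    """The design matrix is rank deficient; carries the aliased factor names."""

    def __init__(self, aliased: list[str]):
        self.aliased = aliased
        super().__init__(f"aliased (rank-deficient) factor(s): {', '.join(aliased)}")


@dataclass(frozen=True)
class AnovaRow:
    """One source line: df, adjusted SS, adjusted MS, partial F and p-value."""

    source: str
    df: int
    adj_ss: float
    adj_ms: float
    f_value: float
    p_value: float

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValueError("df must be >= 1")
        if not (np.isnan(self.p_value) or 0.0 <= self.p_value <= 1.0):
            raise ValueError("p_value must lie in [0, 1]")


@dataclass(frozen=True)
class AnovaTable:
    """Factor rows plus the overall-regression and residual lines."""

    regression: AnovaRow
    rows: tuple[AnovaRow, ...]
    residual_df: int
    residual_ss: float

    @property
    def residual_ms(self) -> float:
        return self.residual_ss / self.residual_df

    def to_frame(self) -> pd.DataFrame:
        """The table in the conventional Source/DF/Adj SS/Adj MS/F/p layout."""
        records = [vars(self.regression)] + [vars(r) for r in self.rows]
        records.append(
            {
                "source": "Error",
                "df": self.residual_df,
                "adj_ss": self.residual_ss,
                "adj_ms": self.residual_ms,
                "f_value": np.nan,
                "p_value": np.nan,
            }
        )
        return pd.DataFrame.from_records(records)


def _dummies(values: pd.Series, levels: list) -> np.ndarray:
    codes = pd.Categorical(values, categories=levels).codes
    if (codes < 0).any():
        raise ValueError(f"unknown level in factor {values.name!r}")
    block = np.zeros((len(values), len(levels) - 1))
    for j in range(1, len(levels)):
        block[:, j - 1] = codes == j
    return block


def _factor_block(cohort: pd.DataFrame, factor: str) -> np.ndarray:
    if factor in BINARY_COVARIATES or factor == "weekend_flag":
        return cohort[factor].to_numpy(dtype=float)[:, None]
    if factor == "age":
        age = cohort["age"].to_numpy(dtype=float)
        return (age - age.mean())[:, None]
    if factor == "date":
        doy = pd.DatetimeIndex(cohort["date"]).dayofyear.to_numpy(dtype=float)
        return np.sin(2 * np.pi * doy / _DAYS_PER_YEAR)[:, None]
    if factor == "gender":
        return _dummies(cohort["gender"], ["female", "male"])
    if factor == "department":
        return _dummies(cohort["department"], list(DEPARTMENTS))
    if factor == "location_id":
        levels = sorted(cohort["location_id"].unique())
        return _dummies(cohort["location_id"], levels)
    raise ValueError(f"unknown factor {factor!r}")


def _rss(X: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Residual sum of squares and rank of the least-squares fit."""
    coef, res, rank, _ = np.linalg.lstsq(X, y, rcond=None)
    if res.size:
        return float(res[0]), int(rank)
    return float(((y - X @ coef) ** 2).sum()), int(rank)


def regression_anova(
    cohort: pd.DataFrame,
    outcome: str = "outcome",
    factors: tuple[str, ...] = DEFAULT_FACTORS,
) -> AnovaTable:
    """Partial-SS ANOVA of *factors* against the binary show-up outcome.

    Returns the overall regression line, one line per factor and the residual
    line.  Raises :class:`AliasError` when a factor block is linearly
    dependent on the rest of the design.
    """
    unknown = set(factors) - set(COVARIATES)
    if unknown:
        raise ValueError(f"factors not among the cohort covariates: {sorted(unknown)}")
    y = outcome_to_binary(cohort[outcome]).astype(float)
    n = len(y)

    blocks = {f: _factor_block(cohort, f) for f in factors}
    intercept = np.ones((n, 1))
    X_full = np.hstack([intercept] + [blocks[f] for f in factors])
    model_df_nominal = X_full.shape[1] - 1
    if n <= model_df_nominal + 1:
        raise ValueError(f"need n > model df + 1 ({model_df_nominal + 1}), got n = {n}")

    rss_full, rank_full = _rss(X_full, y)
    if rank_full < X_full.shape[1]:
        aliased = []
        for f in factors:
            X_red = np.hstack([intercept] + [blocks[g] for g in factors if g != f])
            if np.linalg.matrix_rank(X_red) == rank_full:
                aliased.append(f)
        raise AliasError(aliased or list(factors))

    df_res = n - rank_full
    ms_res = rss_full / df_res

    rows = []
    for f in factors:
        X_red = np.hstack([intercept] + [blocks[g] for g in factors if g != f])
        rss_red, _ = _rss(X_red, y)
        ss = max(rss_red - rss_full, 0.0)
        df = blocks[f].shape[1]
        ms = ss / df
        F = ms / ms_res
        rows.append(
            AnovaRow(
                source=f,
                df=df,
                adj_ss=ss,
                adj_ms=ms,
                f_value=F,
                p_value=float(f_dist.sf(F, df, df_res)),
            )
        )

    ss_total = float(((y - y.mean()) ** 2).sum())
    ss_model = max(ss_total - rss_full, 0.0)
    df_model = rank_full - 1
    F_model = (ss_model / df_model) / ms_res
    regression = AnovaRow(
        source="regression",
        df=df_model,
        adj_ss=ss_model,
        adj_ms=ss_model / df_model,
        f_value=F_model,
        p_value=float(f_dist.sf(F_model, df_model, df_res)),
    )
    return AnovaTable(
        regression=regression, rows=tuple(rows), residual_df=df_res, residual_ss=rss_full
    )


def significance_screen(
    table: AnovaTable | tuple[AnovaRow, ...], alpha: float = 0.05
) -> dict[str, list[str]]:
    """Partition factors into significant (p <= alpha) and non-significant sets."""
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    rows = table.rows if isinstance(table, AnovaTable) else tuple(table)
    if not rows:
        raise ValueError("no factor rows to screen")
    sig = [r.source for r in rows if r.p_value <= alpha]
    nonsig = [r.source for r in rows if r.p_value > alpha]
    return {"significant": sig, "non_significant": nonsig}
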