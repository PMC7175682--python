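"""Statistical comparisons for diet-breadth analyses.

Three analyses sit around the diet-quantification pipeline:

- Mann-Whitney rank-sum tests comparing diet breadth measured by direct
  flower-visit observation against pollen-load analysis (paired columns of
  per-species counts);
- an ordinary least squares (Gaussian) linear model of frequency of
  occurrence (farms occupied) on rarefied diet breadth, optionally with bee
  family and farm management type as fixed factors;
- Spearman's rank correlation as the non-parametric fallback when the
  response cannot be transformed to normality.

The W statistic follows the convention "number of (x, y) pairs with x > y,
ties counted 1/2", so identical samples of size n score n^2/2 and the null
mean is |x||y|/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "ModelFit",
    "rank_sum_test",
    "gaussian_linear_fit",
    "spearman_rank",
    "summarise_breadth",
]


@dataclass
class ModelFit:
    """A fitted test or model: statistic(s), p-value(s) and metadata."""

    method: str
    statistic: float | None = None
    pvalue: float | None = None
    coefficients: dict[str, float] = field(default_factory=dict)
    tvalues: dict[str, float] = field(default_factory=dict)
    pvalues: dict[str, float] = field(default_factory=dict)
    adj_r_squared: float | None = None
    df_resid: float | None = None
    formula: str = ""

    def to_dict(self) -> dict:
        out = {"method": self.method, "formula": self.formula}
        if self.statistic is not None:
            out["statistic"] = self.statistic
        if self.pvalue is not None:
            out["pvalue"] = self.pvalue
        if self.coefficients:
            out["coefficients"] = self.coefficients
            out["tvalues"] = self.tvalues
            out["pvalues"] = self.pvalues
        if self.adj_r_squared is not None:
            out["adj_r_squared"] = self.adj_r_squared
        if self.df_resid is not None:
            out["df_resid"] = self.df_resid
        return out


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], method: str = "asymptotic"
) -> ModelFit:
    """Mann-Whitney rank-sum test.

    W counts pairs where the first sample exceeds the second (ties 1/2).
    The p-value uses the normal approximation with midrank tie correction
    and continuity correction by default; ``method="exact"`` is available
    for tie-free data.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank_sum_test: both samples must be non-empty")
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return ModelFit(
        method="mann_whitney",
        statistic=float(res.statistic),
        pvalue=float(res.pvalue),
        formula="W = #(x > y) + 0.5 #(x = y)",
    )


def gaussian_linear_fit(
    data: pd.DataFrame,
    response: str = "n_farms",
    breadth: str = "rarefied_breadth",
    include_bee_family: bool = False,
    include_farm_type: bool = False,
) -> ModelFit:
    """OLS of occupied-farm count on rarefied diet breadth.

    Categorical factors (bee family, farm management type) enter with
    treatment coding, reference level = alphabetically first. Raises on a
    rank-deficient design.
    """
    import statsmodels.formula.api as smf

    if len(data) < 3:
        raise ValueError("gaussian_linear_fit: need at least 3 rows")
    terms = [breadth]
    if include_bee_family:
        terms.append("C(bee_family)")
    if include_farm_type:
        terms.append("C(farm_type)")
    formula = f"{response} ~ " + " + ".join(terms)
    model = smf.ols(formula, data=data)
    if np.linalg.matrix_rank(model.exog) < model.exog.shape[1]:
        raise ValueError(f"gaussian_linear_fit: degenerate design for {formula!r}")
    fit = model.fit()
    return ModelFit(
        method="ols",
        coefficients={k: float(v) for k, v in fit.params.items()},
        tvalues={k: float(v) for k, v in fit.tvalues.items()},
        pvalues={k: float(v) for k, v in fit.pvalues.items()},
        adj_r_squared=float(fit.rsquared_adj),
        df_resid=float(fit.df_resid),
        formula=formula,
    )


def spearman_rank(
    data: pd.DataFrame,
    breadth: str = "rarefied_breadth",
    response: str = "n_farms",
) -> ModelFit:
    """Spearman rank correlation between diet breadth and farm occupancy.

    Computed on midranks. A constant input has no defined rank correlation
    and raises ValueError.
    """
    if len(data) < 3:
        raise ValueError("spearman_rank: need at least 3 rows")
    x = np.asarray(data[breadth], dtype=float)
    y = np.asarray(data[response], dtype=float)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("spearman_rank: rho undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    return ModelFit(
        method="spearman",
        statistic=float(rho),
        pvalue=float(p),
        formula=f"rank({response}) ~ rank({breadth})",
    )


def summarise_breadth(table: pd.DataFrame, columns: Sequence[str] | None = None) -> pd.DataFrame:
    """Per-column mean and standard error (sd/sqrt(n)) of a breadth table.

    A single-row table yields SE = NaN (undefined), matching the usual
    sample-variance convention.
    """
    if table.empty:
        raise ValueError("summarise_breadth: empty table")
    cols = list(columns) if columns is not None else [
        c for c in table.columns if pd.api.types.is_numeric_dtype(table[c])
    ]
    rows = []
    for c in cols:
        vals = table[c].dropna().astype(float)
        n = len(vals)
        mean = vals.mean()
        se = vals.std(ddof=1) / np.sqrt(n) if n > 1 else float("nan")
        rows.append({"column": c, "n": n, "mean": mean, "se": se})
    return pd.DataFrame(rows).set_index("column")
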