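"""Benchmark predictors and model-comparison metrics for break-even panels.

Two baselines bracket the neural ODE:

* the **static linear CBA** predictor, which applies the break-even identity
  BE = c_tx_initial / (c_dialysis - c_post_tx) with first-year cost
  parameters frozen — it is exact in the first year by construction and
  errs in later years exactly as much as cost structures actually moved;
* a **two-way fixed-effects panel regression**
  BE_it = alpha_i + gamma_t + beta' X_it + eps_it with reference-level
  encoding (first country and first year dropped), fit by OLS via
  statsmodels.

Comparison metrics are RMSE, Gaussian concentrated-likelihood AIC/BIC
(AIC = K ln(RSS/K) + 2k, BIC = K ln(RSS/K) + k ln K), LOOCV R^2 and
pairwise proportional RMSE reductions / AIC differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .cba import NoPaybackError

__all__ = [
    "FixedEffectsResult",
    "ComparisonReport",
    "linear_cba_predict",
    "fit_fixed_effects",
    "rmse",
    "information_criteria",
    "comparison_report",
    "observed_break_even",
]


def observed_break_even(panel: pd.DataFrame) -> pd.Series:
    """Break-even per row from that row's own cost parameters."""
    saving = panel["c_dialysis"] - panel["c_post_tx"]
    if (saving <= 0).any():
        bad = panel.loc[saving <= 0, ["country_id", "year"]]
        raise NoPaybackError(f"non-positive savings for rows: {bad.to_dict('records')}")
    return panel["c_tx_initial"] / saving


def linear_cba_predict(panel: pd.DataFrame) -> pd.Series:
    """Static break-even prediction: first-year cost parameters held fixed.

    First-year rows therefore have zero residual; later years inherit the
    first-year break-even, so the residual isolates actual cost drift.
    """
    first_year = panel["year"].min()
    base = panel[panel["year"] == first_year].set_index("country_id")
    saving = base["c_dialysis"] - base["c_post_tx"]
    if (saving <= 0).any():
        raise NoPaybackError("non-positive first-year savings")
    be_base = base["c_tx_initial"] / saving
    return panel["country_id"].map(be_base).rename("be_pred_linear")


@dataclass
class FixedEffectsResult:
    """Two-way fixed-effects fit: coefficients, predictions, residual metrics."""

    params: pd.Series
    predictions: pd.Series
    residuals: pd.Series
    n_params: int
    rss: float
    model: object  # statsmodels results, for diagnostics

    @property
    def beta(self) -> pd.Series:
        """Covariate coefficients only (fixed effects excluded)."""
        keep = [
            name for name in self.params.index
            if not (name == "const" or name.startswith("country:") or name.startswith("year:"))
        ]
        return self.params[keep]


def fit_fixed_effects(
    panel: pd.DataFrame,
    covariates: list[str] | None = None,
    target: pd.Series | None = None,
) -> FixedEffectsResult:
    """OLS fit of BE_it = alpha_i + gamma_t + beta' X_it + eps_it.

    Identification by reference levels: the first country and first year are
    absorbed into the intercept.  Raises on rank-deficient designs, naming
    the collinear columns.
    """
    if panel["country_id"].nunique() < 2 or panel["year"].nunique() < 2:
        raise ValueError("fixed-effects fit needs >= 2 countries and 2 time points")
    y = observed_break_even(panel) if target is None else target
    covariates = covariates or []
    countries = sorted(panel["country_id"].unique())
    years = sorted(panel["year"].unique())
    blocks = {"const": np.ones(len(panel))}
    for c in countries[1:]:
        blocks[f"country:{c}"] = (panel["country_id"] == c).astype(float).to_numpy()
    for yr in years[1:]:
        blocks[f"year:{yr}"] = (panel["year"] == yr).astype(float).to_numpy()
    for col in covariates:
        blocks[col] = panel[col].to_numpy(dtype=float)
    X = pd.DataFrame(blocks, index=panel.index)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        # identify offending columns by incremental rank growth
        collinear = []
        cols: list[str] = []
        for name in X.columns:
            cand = X[cols + [name]].to_numpy()
            if np.linalg.matrix_rank(cand) == len(cols):
                collinear.append(name)
            else:
                cols.append(name)
        raise ValueError(f"rank-deficient design; collinear columns: {collinear}")
    res = sm.OLS(np.asarray(y, dtype=float), X).fit()
    predictions = pd.Series(res.fittedvalues, index=panel.index, name="be_pred_fe")
    residuals = y - predictions
    return FixedEffectsResult(
        params=pd.Series(res.params, index=X.columns),
        predictions=predictions,
        residuals=residuals,
        n_params=X.shape[1],
        rss=float(np.sum(residuals**2)),
        model=res,
    )


def rmse(observed, predicted) -> float:
    """Root mean squared error (the residual is squared before averaging)."""
    observed = np.asarray(observed, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if observed.shape != predicted.shape:
        raise ValueError(
            f"length mismatch: observed {observed.shape} vs predicted {predicted.shape}"
        )
    if observed.size == 0:
        raise ValueError("need at least one observation")
    return float(np.sqrt(np.mean((observed - predicted) ** 2)))


def information_criteria(rss: float, K: int, k_params: int) -> tuple[float, float]:
    """Gaussian concentrated-likelihood AIC and BIC (up to an additive constant).

    AIC = K ln(RSS/K) + 2k and BIC = K ln(RSS/K) + k ln K.  A zero RSS is a
    perfect fit and returns (-inf, -inf) rather than raising.
    """
    if K < 1 or k_params < 0:
        raise ValueError("K must be >= 1 and k_params >= 0")
    if rss < 0:
        raise ValueError("rss must be >= 0")
    if rss == 0:
        return float("-inf"), float("-inf")
    base = K * np.log(rss / K)
    return float(base + 2 * k_params), float(base + k_params * np.log(K))


@dataclass
class ComparisonReport:
    """Per-model metrics plus pairwise deltas, Table-2 style."""

    metrics: pd.DataFrame  # index: model, columns: rmse, aic, bic, loocv_r2
    rmse_reduction: pd.DataFrame  # (base, new) -> (rmse_base - rmse_new)/rmse_base
    delta_aic: pd.DataFrame  # (base, new) -> aic_base - aic_new

    def to_text(self) -> str:
        return self.metrics.to_string(float_format=lambda v: f"{v:.3f}")


def comparison_report(metrics: dict[str, dict[str, float]]) -> ComparisonReport:
    """Tabulate model metrics and pairwise improvements.

    ``metrics`` maps model name -> {"rmse": .., "aic": .., "bic": ..,
    "loocv_r2": ..}.  Proportional RMSE reduction of `new` over `base` is
    (rmse_base - rmse_new)/rmse_base (NaN when the base RMSE is zero);
    delta AIC is aic_base - aic_new (antisymmetric).
    """
    if len(metrics) < 2:
        raise ValueError("comparison needs at least two models")
    table = pd.DataFrame(metrics).T
    models = list(table.index)
    red = pd.DataFrame(np.nan, index=models, columns=models)
    daic = pd.DataFrame(np.nan, index=models, columns=models)
    for base in models:
        for new in models:
            rb = table.loc[base, "rmse"]
            red.loc[base, new] = np.nan if rb == 0 else (rb - table.loc[new, "rmse"]) / rb
            with np.errstate(invalid="ignore"):  # -inf - -inf for perfect fits
                daic.loc[base, new] = table.loc[base, "aic"] - table.loc[new, "aic"]
    return ComparisonReport(metrics=table, rmse_reduction=red, delta_aic=daic)
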