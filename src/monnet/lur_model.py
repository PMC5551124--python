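"""Land-use regression with constrained forward selection.

The model regresses annual-average concentrations at the monitoring sites
on geographic covariates, building the variable set greedily: at each step
the candidate giving the largest in-sample R² gain is added, provided its
coefficient is significant at ``entry_alpha``; after entry the variable is
checked against two multicollinearity guards (VIF of the new variable
within the selected set, and pairwise Pearson correlation with each
already-selected variable) and removed — and permanently barred — if either
fails.  Selection stops at ``max_vars`` (default five, reflecting the small
number of monitors) or when no remaining candidate qualifies.

Model skill is summarised by leave-one-out cross-validated R²,
``1 - MSE / var(y)``, which compares held-out predictions to observations
about the identity line and can be negative.  Reported effect sizes are
standardized as raw coefficient × (90th − 10th percentile) of the
covariate, i.e. the concentration change for an inter-decile shift.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["SelectionConfig", "LurModel", "forward_select", "loocv_r2",
           "predict", "standardize_coefficients"]


@dataclass(frozen=True)
class SelectionConfig:
    max_vars: int = 5
    vif_max: float = 10.0
    cor_max: float = 0.7
    entry_alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.max_vars < 1:
            raise ValueError("max_vars must be >= 1")
        if not 0 < self.entry_alpha < 1:
            raise ValueError("entry_alpha must lie in (0, 1)")


@dataclass
class LurModel:
    """Fitted land-use regression model.

    ``variables`` is in selection order; ``coefficients`` and ``pvalues``
    are keyed by variable name; ``standardized`` holds coefficient ×
    inter-decile range.
    """

    variables: list[str]
    intercept: float
    coefficients: dict[str, float]
    pvalues: dict[str, float] = field(default_factory=dict)
    loocv_r2: float | None = None
    standardized: dict[str, float] = field(default_factory=dict)
    percentile_method: str = "linear"

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({
                "variables": self.variables,
                "intercept": self.intercept,
                "coefficients": self.coefficients,
                "pvalues": self.pvalues,
                "loocv_r2": self.loocv_r2,
                "standardized": self.standardized,
                "percentile_method": self.percentile_method,
            }, fh, indent=2)

    @classmethod
    def from_json(cls, path) -> "LurModel":
        with open(path) as fh:
            return cls(**json.load(fh))


def _ols(X: pd.DataFrame, y: np.ndarray):
    return sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()


def _vif(X: pd.DataFrame, name: str) -> float:
    """VIF of ``name`` within the columns of ``X``: 1/(1−R²) of the
    regression of the variable on the other selected variables."""
    others = [c for c in X.columns if c != name]
    if not others:
        return 1.0
    r2 = _ols(X[others], X[name].to_numpy()).rsquared
    return np.inf if r2 >= 1.0 else 1.0 / (1.0 - r2)


def forward_select(X: pd.DataFrame, y: pd.Series | np.ndarray,
                   config: SelectionConfig = SelectionConfig()) -> LurModel:
    """Greedy forward selection with significance and collinearity guards.

    ``X`` holds recoded covariates at the monitoring sites (rows aligned
    with ``y``).  Raises on missing values or constant columns, which
    signal that recoding/exclusion was skipped.
    """
    y = np.asarray(y, dtype=float)
    if X.isna().any().any() or np.isnan(y).any():
        raise ValueError("missing values in X or y")
    const = X.columns[X.nunique() <= 1].tolist()
    if const:
        raise ValueError(f"constant column(s) {const}: run "
                         "exclude_low_variability first")
    if len(X) <= config.max_vars + 1:
        raise ValueError("need more monitors than max_vars + 1")

    selected: list[str] = []
    barred: set[str] = set()
    while len(selected) < config.max_vars:
        best_name, best_r2, best_p = None, -np.inf, None
        for name in X.columns:
            if name in selected or name in barred:
                continue
            fit = _ols(X[selected + [name]], y)
            pval = fit.pvalues[name]
            if pval < config.entry_alpha and fit.rsquared > best_r2:
                best_name, best_r2, best_p = name, fit.rsquared, pval
        if best_name is None:
            break
        trial = selected + [best_name]
        too_correlated = any(
            abs(np.corrcoef(X[best_name], X[s])[0, 1]) > config.cor_max
            for s in selected)
        if too_correlated or _vif(X[trial], best_name) > config.vif_max:
            barred.add(best_name)  # no re-entry: prevents cycling
            continue
        selected = trial

    if selected:
        fit = _ols(X[selected], y)
        intercept = float(fit.params["const"])
        coefs = {v: float(fit.params[v]) for v in selected}
        pvals = {v: float(fit.pvalues[v]) for v in selected}
    else:
        intercept, coefs, pvals = float(np.mean(y)), {}, {}
    model = LurModel(variables=selected, intercept=intercept,
                     coefficients=coefs, pvalues=pvals)
    model.loocv_r2 = loocv_r2(selected, X, y) if selected else None
    model.standardized = standardize_coefficients(model, X)
    return model


def loocv_r2(variables: list[str], X: pd.DataFrame,
             y: pd.Series | np.ndarray, var_ddof: int = 0) -> float:
    """Leave-one-out cross-validated R² for a fixed variable set.

    For each site the model is refit on the other n−1 sites and predicts
    the held-out site; the score is ``1 − MSE / var(y)`` with ``var`` using
    denominator n by default.  Can be negative when held-out predictions
    are worse than the mean.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if n < 3:
        raise ValueError("need at least 3 observations for LOOCV")
    var_y = np.var(y, ddof=var_ddof)
    if var_y == 0:
        raise ValueError("var(y) is zero")
    A = np.column_stack([np.ones(n), X[variables].to_numpy()])
    preds = np.empty(n)
    for i in range(n):
        mask = np.arange(n) != i
        beta, *_ = np.linalg.lstsq(A[mask], y[mask], rcond=None)
        preds[i] = A[i] @ beta
    mse = float(np.mean((y - preds) ** 2))
    return 1.0 - mse / var_y


def predict(model: LurModel, X_all: pd.DataFrame) -> pd.Series:
    """Linear prediction at arbitrary locations.

    ``X_all`` must contain every selected variable, recoded identically to
    the fitting matrix.
    """
    missing = [v for v in model.variables if v not in X_all.columns]
    if missing:
        raise KeyError(f"selected variable(s) missing from X_all: {missing}")
    out = np.full(len(X_all), model.intercept, dtype=float)
    for v in model.variables:
        out += model.coefficients[v] * X_all[v].to_numpy()
    return pd.Series(out, index=X_all.index, name="predicted")


def standardize_coefficients(model: LurModel, X: pd.DataFrame,
                             ) -> dict[str, float]:
    """Coefficient × (p90 − p10) of each selected covariate over ``X``.

    Percentiles use linear interpolation (recorded on the model for
    reproducibility).
    """
    out = {}
    for v in model.variables:
        p10, p90 = np.percentile(X[v].to_numpy(), [10, 90], method="linear")
        out[v] = float(model.coefficients[v] * (p90 - p10))
    return out
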