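"""Linear stage: feature-rating correlations and stepwise forward regression.

Pearson correlations relate each physiological feature to the mean
valence/arousal ratings across excerpts.  The regression stage mimics
classic stepwise forward entry: at each step the candidate with the
smallest partial-F p-value enters while that p-value is below
``alpha_enter``; after each entry, any member whose p-value has risen above
``alpha_keep`` is dropped.  With so few excerpts relative to predictors the
fits must be read cautiously; a warning is logged when n/predictors < 5.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .errors import ModelError
from .features import FEATURES

log = logging.getLogger(__name__)

DEFAULT_ALPHA_ENTER = 0.10
DEFAULT_ALPHA_KEEP = 0.15


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    df: int
    p: float


def pearson(x: np.ndarray, y: np.ndarray) -> CorrelationResult:
    """Pearson r with a t-based two-tailed p-value on df = n - 2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ModelError(f"length mismatch: {len(x)} vs {len(y)}")
    if len(x) < 3:
        raise ModelError("need n >= 3 for a correlation")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ModelError("undefined correlation: zero variance input")
    r, p = stats.pearsonr(x, y)
    return CorrelationResult(r=float(r), df=len(x) - 2, p=float(p))


def correlation_table(features: pd.DataFrame) -> pd.DataFrame:
    """r/df/p of every feature against mean valence and mean arousal."""
    rows = []
    for f in FEATURES:
        for target in ("mean_valence", "mean_arousal"):
            c = pearson(features[f].to_numpy(), features[target].to_numpy())
            rows.append([f, target.replace("mean_", ""), c.r, c.df, c.p])
    return pd.DataFrame(rows, columns=["feature", "target", "r", "df", "p"])


@dataclass
class RegressionModel:
    """A fitted (possibly empty) stepwise model for one rating dimension."""

    target: str
    selected: list[str] = field(default_factory=list)
    intercept: float = 0.0
    coefficients: dict[str, float] = field(default_factory=dict)
    p_values: dict[str, float] = field(default_factory=dict)
    r_squared: float = 0.0
    f_stat: float | None = None
    df_model: int = 0
    df_resid: int = 0
    train_mean: float = float("nan")

    def to_dict(self) -> dict:
        return {
            "target": self.target, "selected": self.selected,
            "intercept": self.intercept, "coefficients": self.coefficients,
            "p_values": self.p_values, "r_squared": self.r_squared,
            "f_stat": self.f_stat, "df_model": self.df_model,
            "df_resid": self.df_resid, "train_mean": self.train_mean,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RegressionModel":
        return cls(**d)


def _fit_ols(X: pd.DataFrame, y: np.ndarray, cols: list[str]):
    design = sm.add_constant(X[cols].to_numpy(), has_constant="add")
    if np.linalg.cond(design) > 1e10:
        raise ModelError(f"collinear predictor set {cols} (condition number > 1e10)")
    return sm.OLS(y, design).fit()


def stepwise_forward(X: pd.DataFrame, y: np.ndarray, target: str = "rating",
                     alpha_enter: float = DEFAULT_ALPHA_ENTER,
                     alpha_keep: float = DEFAULT_ALPHA_KEEP,
                     candidates: tuple[str, ...] = FEATURES) -> RegressionModel:
    """Stepwise forward entry with optional removal.

    Entry uses the partial-F p-value of each candidate given the current
    model (equivalently the two-tailed t-test of its coefficient).  Ties
    break by the fixed candidate order.  ``alpha_keep=1`` reproduces pure
    forward entry with no removal.
    """
    y = np.asarray(y, dtype=float)
    if len(X) < 3:
        raise ModelError("need n >= 3 rows for stepwise regression")
    if X[list(candidates)].isna().any().any() or np.isnan(y).any():
        raise ModelError("missing values in predictors or response")
    if len(X) / max(1, len(candidates)) < 5:
        log.warning("stepwise regression with n=%d rows over %d candidate predictors: "
                    "ratio below accepted norms, interpret with caution",
                    len(X), len(candidates))

    selected: list[str] = []
    while True:
        remaining = [c for c in candidates if c not in selected]
        if not remaining:
            break
        best_c, best_p = None, np.inf
        for c in remaining:
            res = _fit_ols(X, y, selected + [c])
            p = float(res.pvalues[-1])  # candidate coefficient: partial F == t^2
            if p < best_p:
                best_c, best_p = c, p
        if best_c is None or not best_p < alpha_enter:
            break
        selected.append(best_c)
        # backward removal sweep
        while selected:
            res = _fit_ols(X, y, selected)
            pvals = {c: float(res.pvalues[i + 1]) for i, c in enumerate(selected)}
            worst = max(selected, key=lambda c: pvals[c])
            if pvals[worst] > alpha_keep and worst != best_c:
                selected.remove(worst)
            else:
                break

    model = RegressionModel(target=target, train_mean=float(y.mean()))
    if not selected:
        return model
    res = _fit_ols(X, y, selected)
    model.selected = selected
    model.intercept = float(res.params[0])
    model.coefficients = {c: float(res.params[i + 1]) for i, c in enumerate(selected)}
    model.p_values = {c: float(res.pvalues[i + 1]) for i, c in enumerate(selected)}
    model.r_squared = float(res.rsquared)
    model.f_stat = float(res.fvalue)
    model.df_model = int(res.df_model)
    model.df_resid = int(res.df_resid)
    return model


def predict_linear(model: RegressionModel, X: pd.DataFrame) -> np.ndarray:
    """intercept + sum(coef x feature); an empty model predicts the training mean."""
    if not model.selected:
        return np.full(len(X), model.train_mean)
    missing = [c for c in model.selected if c not in X.columns]
    if missing:
        raise ModelError(f"missing predictor columns: {missing}")
    yhat = np.full(len(X), model.intercept)
    for c in model.selected:
        yhat = yhat + model.coefficients[c] * X[c].to_numpy(dtype=float)
    return yhat
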