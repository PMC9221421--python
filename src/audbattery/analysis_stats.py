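"""Descriptives, Pearson correlation screen, and backward-elimination OLS.

Reproduces the statistical stage of the battery analysis: per-variable
descriptive statistics, all pairwise Pearson correlations over the 11
reported variables with two-tailed p-values (optionally Bonferroni-
corrected), and backward linear regression predicting each speech measure
(CO, SEP, SRM) from {Age, PTA, TGap, DioFM, DichFM, TM, SM, STM}.

Backward elimination follows the stepwise-removal convention: fit the full
model, repeatedly drop the predictor with the largest partial t-test
p-value while that p exceeds the removal criterion (default p > 0.10; the
common alternative is 0.20), and report the final model's adjusted R^2,
overall F-test p, and residual standard error ("error", in the outcome's
dB units).  A final model with adjusted R^2 <= 0, or with every predictor
eliminated, is reported as "no model".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .virtual_listener import RESULT_COLUMNS

__all__ = [
    "PREDICTORS",
    "SPEECH_OUTCOMES",
    "RegressionModel",
    "AnalysisReport",
    "describe",
    "pearson",
    "correlation_screen",
    "fit_ols",
    "backward_eliminate",
    "analysis_report",
]


class UsageError(RuntimeError):
    pass


class UndefinedCorrelationError(ValueError):
    """Pearson r is undefined (zero variance in an input)."""


PREDICTORS = ("Age", "PTA", "TGap", "DioFM", "DichFM", "TM", "SM", "STM")
SPEECH_OUTCOMES = ("CO", "SEP", "SRM")


def describe(results: pd.DataFrame) -> pd.DataFrame:
    """Per-variable (min, max, mean, SD); SD uses the n-1 denominator."""
    cols = [c for c in RESULT_COLUMNS if c in results.columns]
    if not cols:
        cols = list(results.select_dtypes("number").columns)
    if len(results) < 2:
        raise UsageError("need at least 2 rows for descriptives")
    data = results[cols]
    return pd.DataFrame(
        {
            "Minimum": data.min(),
            "Maximum": data.max(),
            "Mean": data.mean(),
            "Std. Deviation": data.std(ddof=1),
        }
    )


def pearson(x, y) -> tuple[float, float]:
    """Pearson r and the two-tailed p from t = r sqrt((n-2)/(1-r^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise UsageError("need two equal-length samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise UsageError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise UndefinedCorrelationError("zero variance input")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


def correlation_screen(
    results: pd.DataFrame,
    alpha: float = 0.05,
    bonferroni: bool = False,
    n_comparisons: int | None = None,
) -> pd.DataFrame:
    """All unordered variable pairs with p below the criterion, sorted.

    With ``bonferroni`` the criterion becomes alpha / n_comparisons
    (defaulting to the number of pairs evaluated).  No correction is the
    default, matching the exploratory use of the screen.
    """
    cols = [c for c in RESULT_COLUMNS if c in results.columns]
    if len(results) < 3:
        raise UsageError("need at least 3 rows")
    pairs = list(itertools.combinations(cols, 2))
    criterion = alpha / (n_comparisons or len(pairs)) if bonferroni else alpha
    rows = []
    for a, b in pairs:
        try:
            r, p = pearson(results[a], results[b])
        except UndefinedCorrelationError:
            import warnings

            warnings.warn(f"skipping ({a}, {b}): zero variance", stacklevel=2)
            continue
        if p < criterion:
            rows.append({"Variable 1": a, "Variable 2": b, "Pearson Correlation": r,
                         "Sig. (2-Tailed)": p})
    out = pd.DataFrame(rows, columns=["Variable 1", "Variable 2",
                                      "Pearson Correlation", "Sig. (2-Tailed)"])
    return out.sort_values("Sig. (2-Tailed)", kind="stable").reset_index(drop=True)


@dataclass
class RegressionModel:
    """A fitted linear model (possibly the product of backward elimination)."""

    outcome: str
    predictors: tuple[str, ...]
    coefficients: pd.Series  # includes "const"
    p_values: pd.Series
    r2: float
    adjusted_r2: float
    model_p: float
    error_db: float  # residual standard error in the outcome's units
    elimination_trace: tuple[tuple[str, float], ...] = ()
    no_model: bool = False

    @property
    def retained(self) -> tuple[str, ...]:
        return self.predictors

    def summary_row(self) -> dict:
        if self.no_model:
            return {"Condition": self.outcome, "Predictors": "-", "Adjusted R^2": "-",
                    "p": "-", "Error (dB)": "-"}
        return {
            "Condition": self.outcome,
            "Predictors": ", ".join(self.predictors),
            "Adjusted R^2": round(self.adjusted_r2, 3),
            "p": round(self.model_p, 3),
            "Error (dB)": round(self.error_db, 2),
        }


def _fit(y: pd.Series, X: pd.DataFrame, outcome: str) -> RegressionModel:
    design = sm.add_constant(X, has_constant="add")
    if len(y) <= X.shape[1] + 1:
        raise UsageError("need n > number of predictors + 1")
    if np.linalg.matrix_rank(design.to_numpy()) < design.shape[1]:
        raise np.linalg.LinAlgError("singular design matrix")
    fit = sm.OLS(np.asarray(y, dtype=float), design).fit()
    resid_se = float(np.sqrt(fit.ssr / fit.df_resid))
    return RegressionModel(
        outcome=outcome,
        predictors=tuple(X.columns),
        coefficients=pd.Series(fit.params, index=design.columns),
        p_values=pd.Series(fit.pvalues, index=design.columns),
        r2=float(fit.rsquared),
        adjusted_r2=float(fit.rsquared_adj),
        model_p=float(fit.f_pvalue) if X.shape[1] else float("nan"),
        error_db=resid_se,
    )


def fit_ols(y, predictors: pd.DataFrame, outcome: str = "y") -> RegressionModel:
    """Single OLS fit (no elimination) with partial t-test p-values."""
    y = pd.Series(np.asarray(y, dtype=float))
    X = pd.DataFrame(predictors).reset_index(drop=True)
    return _fit(y.reset_index(drop=True), X, outcome)


def backward_eliminate(
    y,
    predictors: pd.DataFrame,
    p_remove: float = 0.10,
    outcome: str = "y",
) -> RegressionModel:
    """Backward stepwise removal on partial t-test p-values.

    Refit after each removal; stop when every retained predictor has
    p <= p_remove or none remain.  Ties in the maximal p are broken by
    removing the later predictor in column order.  The final model is
    flagged ``no_model`` when nothing is retained or its adjusted R^2 <= 0.
    """
    y = pd.Series(np.asarray(y, dtype=float))
    X = pd.DataFrame(predictors).reset_index(drop=True)
    trace: list[tuple[str, float]] = []
    current = list(X.columns)
    model = _fit(y, X[current], outcome)
    while current:
        p = model.p_values.drop("const")
        worst_p = p.max()
        if worst_p <= p_remove:
            break
        # later-column tie-break: take the last index attaining the max
        worst = p[p == worst_p].index[-1]
        trace.append((str(worst), float(worst_p)))
        current.remove(worst)
        if not current:
            model = RegressionModel(
                outcome=outcome, predictors=(), coefficients=pd.Series(dtype=float),
                p_values=pd.Series(dtype=float), r2=0.0, adjusted_r2=0.0,
                model_p=float("nan"), error_db=float(np.std(y, ddof=1)),
            )
            break
        model = _fit(y, X[current], outcome)
    model.elimination_trace = tuple(trace)
    if not model.predictors or model.adjusted_r2 <= 0.0:
        model.no_model = True
    return model


@dataclass
class AnalysisReport:
    """Descriptives, correlation screen, and the three final speech models."""

    descriptives: pd.DataFrame
    correlations: pd.DataFrame
    models: dict = field(default_factory=dict)  # outcome -> RegressionModel
    p_remove: float = 0.10

    def model_table(self) -> pd.DataFrame:
        return pd.DataFrame([self.models[o].summary_row() for o in SPEECH_OUTCOMES])

    def render_text(self) -> str:
        lines = ["Descriptive statistics", "======================",
                 self.descriptives.round(3).to_string(), ""]
        lines += ["Correlations with p < 0.05", "==========================",
                  self.correlations.round(3).to_string(index=False) or "(none)", ""]
        lines += [f"Final regression models (backward elimination, p_remove = {self.p_remove})",
                  "=================================================================",
                  self.model_table().to_string(index=False), ""]
        for outcome in SPEECH_OUTCOMES:
            m = self.models[outcome]
            if m.no_model:
                lines.append(f"{outcome}: no model (adjusted R^2 did not exceed 0)")
            else:
                coef = ", ".join(f"{k} = {v:.4g}" for k, v in m.coefficients.items())
                lines.append(f"{outcome}: {coef}")
            if m.elimination_trace:
                steps = " -> ".join(f"{name} (p={p:.3f})" for name, p in m.elimination_trace)
                lines.append(f"  eliminated: {steps}")
        return "\n".join(lines) + "\n"

    def to_csv(self, outdir) -> dict:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "descriptives": outdir / "table1_descriptives.csv",
            "correlations": outdir / "table2_correlations.csv",
            "models": outdir / "table3_regressions.csv",
            "report": outdir / "report.txt",
        }
        self.descriptives.to_csv(paths["descriptives"], index_label="Variable")
        self.correlations.to_csv(paths["correlations"], index=False)
        self.model_table().to_csv(paths["models"], index=False)
        paths["report"].write_text(self.render_text())
        return paths


def analysis_report(
    results: pd.DataFrame,
    p_remove: float = 0.10,
    alpha: float = 0.05,
    bonferroni: bool = False,
) -> AnalysisReport:
    """Full statistical stage on a results table.

    Runs descriptives, the correlation screen, and one backward-eliminated
    regression per speech outcome (CO, SEP, SRM) on the eight predictors.
    """
    missing = [c for c in (*SPEECH_OUTCOMES, *PREDICTORS) if c not in results.columns]
    if missing:
        raise UsageError(f"results table missing columns: {missing}")
    if results[list(RESULT_COLUMNS)].isna().any().any():
        raise UsageError("analysis input must have no missing cells")
    report = AnalysisReport(
        descriptives=describe(results),
        correlations=correlation_screen(results, alpha=alpha, bonferroni=bonferroni),
        p_remove=p_remove,
    )
    X = results[list(PREDICTORS)]
    for outcome in SPEECH_OUTCOMES:
        report.models[outcome] = backward_eliminate(
            results[outcome], X, p_remove=p_remove, outcome=outcome
        )
    return report
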