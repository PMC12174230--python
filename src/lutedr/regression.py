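"""Multivariable ordinary-least-squares engine with the reporting
quantities used in clinical regression tables: standardized coefficients,
95% confidence intervals, t and p values, variance inflation factors, and
adjusted R².

The fit itself is delegated to statsmodels OLS; the in-package additions
are the standardized-beta rescaling, the VIF computation from auxiliary
regressions, rank-deficiency diagnostics that name the collinear columns,
and a table-shaped report with the field's "< 0.0001" p-value convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

P_PRINT_FLOOR = 1e-4  # p values below this print as "< 0.0001"


@dataclass(frozen=True)
class OLSFit:
    """Result of a least-squares fit with an intercept.

    Coefficient-indexed arrays are ordered as ``predictors`` (the
    intercept is carried separately).  ``vif`` may contain ``inf`` for
    perfectly collinear predictors; callers should treat that as a flag.
    """

    predictors: tuple[str, ...]
    coefficients: np.ndarray
    intercept: float
    std_errors: np.ndarray
    intercept_se: float
    t_values: np.ndarray
    p_values: np.ndarray
    conf_int: np.ndarray  # shape (p, 2), 95% t-based
    standardized_beta: np.ndarray
    vif: np.ndarray
    r2: float
    adj_r2: float
    residual_sd: float
    n: int
    residuals: np.ndarray

    def __post_init__(self):
        p = len(self.predictors)
        for name in ("coefficients", "std_errors", "t_values", "p_values",
                     "standardized_beta", "vif"):
            if len(getattr(self, name)) != p:
                raise ValueError(f"{name} length != number of predictors")
        if self.conf_int.shape != (p, 2):
            raise ValueError("conf_int must be (p, 2)")

    def predict(self, X: pd.DataFrame | np.ndarray) -> np.ndarray:
        X = np.asarray(pd.DataFrame(X)[list(self.predictors)]
                       if isinstance(X, pd.DataFrame) else X, dtype=float)
        return X @ self.coefficients + self.intercept

    def report(self) -> pd.DataFrame:
        """Regression table: standardized beta with 95% CI, t, p, VIF."""
        return pd.DataFrame({
            "predictor": self.predictors,
            "coefficient": self.coefficients,
            "standardized_beta": self.standardized_beta,
            "ci_low": self.conf_int[:, 0],
            "ci_high": self.conf_int[:, 1],
            "t_value": self.t_values,
            "p_value": self.p_values,
            "p_printed": [format_p(p) for p in self.p_values],
            "vif": self.vif,
        })


def format_p(p: float) -> str:
    """Render a p value with the clinical-table convention."""
    if p < P_PRINT_FLOOR:
        return "< 0.0001"
    return f"{p:.4f}"


def _as_design(X) -> pd.DataFrame:
    X = pd.DataFrame(X)
    if X.shape[1] == 0:
        raise ValueError("design matrix has no columns")
    X.columns = [str(c) for c in X.columns]
    return X.astype(float)


def _check_rank(X: pd.DataFrame) -> None:
    """Raise, naming offending columns, if the design (with intercept)
    is rank deficient."""
    arr = np.column_stack([np.ones(len(X)), X.to_numpy()])
    if np.linalg.matrix_rank(arr) == arr.shape[1]:
        return
    # identify columns involved: a column is collinear if dropping it
    # does not reduce the rank
    full_rank = np.linalg.matrix_rank(arr)
    bad = []
    for j, name in enumerate(X.columns):
        sub = np.delete(arr, j + 1, axis=1)
        if np.linalg.matrix_rank(sub) == full_rank:
            bad.append(name)
    raise ValueError(
        "design matrix is rank deficient; collinear columns: "
        + (", ".join(bad) if bad else "<intercept-only degeneracy>")
    )


def fit_ols(X, y) -> OLSFit:
    """Least-squares fit of ``y`` on predictor columns ``X`` plus an
    intercept.

    Inference is t-based: two-sided p values and 95% confidence
    intervals on n - p - 1 degrees of freedom.  ``X`` must not already
    contain a constant column.  Raises on rank deficiency, naming the
    collinear columns.
    """
    X = _as_design(X)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y lengths differ")
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 observations (n={n}, p={p})")
    if any(np.ptp(X[c].to_numpy()) == 0 for c in X.columns):
        const = [c for c in X.columns if np.ptp(X[c].to_numpy()) == 0]
        raise ValueError(f"constant predictor column(s): {', '.join(const)}")
    _check_rank(X)

    design = sm.add_constant(X, prepend=True)
    res = sm.OLS(y, design).fit()

    coefs = res.params.iloc[1:].to_numpy()
    ci = res.conf_int(alpha=0.05).iloc[1:].to_numpy()
    sd_y = float(np.std(y, ddof=1))
    if sd_y == 0:
        beta = np.zeros(p)
    else:
        beta = coefs * X.std(ddof=1).to_numpy() / sd_y
    vifs = vif(X) if p >= 2 else np.ones(1)
    resid = y - res.fittedvalues.to_numpy()
    dof = n - p - 1
    return OLSFit(
        predictors=tuple(X.columns),
        coefficients=coefs,
        intercept=float(res.params.iloc[0]),
        std_errors=res.bse.iloc[1:].to_numpy(),
        intercept_se=float(res.bse.iloc[0]),
        t_values=res.tvalues.iloc[1:].to_numpy(),
        p_values=res.pvalues.iloc[1:].to_numpy(),
        conf_int=ci,
        standardized_beta=beta,
        vif=vifs,
        r2=float(res.rsquared),
        adj_r2=float(res.rsquared_adj),
        residual_sd=float(np.sqrt(resid @ resid / dof)) if dof > 0 else 0.0,
        n=n,
        residuals=resid,
    )


def standardized_coefficients(fit: OLSFit, X, y) -> np.ndarray:
    """Standardized betas: beta_j = coef_j * sd(x_j) / sd(y) (sample SD).

    Identical to the raw coefficients obtained by refitting on z-scored
    X and y.
    """
    X = _as_design(X)
    if tuple(X.columns) != fit.predictors:
        raise ValueError("X columns do not match the fit's predictors")
    y = np.asarray(y, dtype=float).ravel()
    sx = X.std(ddof=1).to_numpy()
    if np.any(sx == 0):
        zero = [c for c, s in zip(X.columns, sx) if s == 0]
        raise ValueError(f"zero-variance predictor(s): {', '.join(zero)}")
    sy = float(np.std(y, ddof=1))
    if sy == 0:
        raise ValueError("response has zero variance")
    return fit.coefficients * sx / sy


def vif(X) -> np.ndarray:
    """Variance inflation factors: VIF_j = 1 / (1 - R²_j), where R²_j is
    from regressing x_j on the remaining predictors (with intercept).

    Perfectly collinear predictors are reported as ``inf`` rather than
    raising, so the caller can flag them in a report.
    """
    X = _as_design(X)
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least two predictors")
    out = np.empty(p)
    arr = X.to_numpy()
    for j in range(p):
        xj = arr[:, j]
        others = sm.add_constant(np.delete(arr, j, axis=1), prepend=True)
        r2j = sm.OLS(xj, others).fit().rsquared
        out[j] = np.inf if r2j >= 1.0 - 1e-12 else 1.0 / (1.0 - r2j)
    return out


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Adjusted R² = 1 - (1 - R²)(n - 1)/(n - p - 1)."""
    if n <= p + 1:
        raise ValueError("need n > p + 1")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)
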