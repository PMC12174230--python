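"""Pretreatment prediction of the next-day external dose rate.

The chain has two fitted pieces and one algebraic composition:

* dose-rate model (two predictors):
    ``LateEDR = a1 * LUTtotal + a2 * dose_per_bw + c``
  fitted on post-therapy cycles with measured Late EDR-1 m;
* cross-tracer bridge:
    ``LUTtotal = b1 * OCTtotal + b0``
  fitted on paired Lu-177 / In-111 total-uptake indices;
* composed pretreatment predictor, at a fixed planned activity
  (default 7400 MBq):
    ``predict(oct, bw) = a1 * (b1 * oct + b0) + a2 * fixed_dose / bw + c``.

The numeric coefficients are always data — fitted from a site's own
cohort and serializable to JSON — never constants baked into the code.
Evaluation is by RMSE/MAE, Bland-Altman agreement, and classification
against the isolation-release limit (Japan: EDR-1 m <= 18 uSv/h,
inclusive).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import regression

RELEASE_LIMIT_USV_PER_H = 18.0
DEFAULT_FIXED_DOSE_MBQ = 7400.0


# ---------------------------------------------------------------------------
# fitted pieces
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EDRModelFit:
    """Dose-rate model coefficients (a1, a2, c) with the full OLS report."""

    a1: float  # uSv/h per SUV*mL of LUTtotal
    a2: float  # uSv/h per MBq/kg
    c: float   # uSv/h
    ols: regression.OLSFit


@dataclass(frozen=True)
class UptakeBridgeFit:
    """Cross-tracer bridge coefficients (b1, b0) with the OLS report."""

    b1: float
    b0: float
    ols: regression.OLSFit


def fit_edr_model(cohort: pd.DataFrame,
                  response: str = "measured_late_edr_uSv_per_h",
                  uptake_col: str = "luttotal",
                  dose_col: str = "dose_per_bw") -> EDRModelFit:
    """Fit ``LateEDR ~ LUTtotal + dose_per_bw`` by OLS.

    Needs at least 4 rows (two coefficients plus intercept plus one
    residual degree of freedom).  A constant dose-per-weight column is
    rejected by the regression engine.
    """
    for col in (response, uptake_col, dose_col):
        if col not in cohort.columns:
            raise ValueError(f"cohort is missing column {col!r}")
    sub = cohort[[uptake_col, dose_col, response]].dropna()
    if len(sub) < 4:
        raise ValueError(f"need >= 4 complete rows, got {len(sub)}")
    fit = regression.fit_ols(sub[[uptake_col, dose_col]], sub[response])
    return EDRModelFit(a1=float(fit.coefficients[0]),
                       a2=float(fit.coefficients[1]),
                       c=float(fit.intercept), ols=fit)


def fit_uptake_bridge(luttotal, octtotal) -> UptakeBridgeFit:
    """Fit ``LUTtotal ~ OCTtotal`` by simple OLS on paired scans."""
    lut = np.asarray(luttotal, dtype=float).ravel()
    oct_ = np.asarray(octtotal, dtype=float).ravel()
    if lut.shape != oct_.shape:
        raise ValueError("paired arrays must have equal length")
    if len(lut) < 3:
        raise ValueError(f"need >= 3 pairs, got {len(lut)}")
    fit = regression.fit_ols(pd.DataFrame({"octtotal": oct_}), lut)
    return UptakeBridgeFit(b1=float(fit.coefficients[0]),
                           b0=float(fit.intercept), ols=fit)


# ---------------------------------------------------------------------------
# composed predictor
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EDRPredictor:
    """Pretreatment Late EDR-1 m predictor at a fixed planned activity.

    ``predict(oct, bw) = a1*(b1*oct + b0) + a2*fixed_dose/bw + c``,
    algebraically identical to evaluating the bridge then the dose-rate
    model.
    """

    a1: float
    a2: float
    c: float
    b1: float
    b0: float
    fixed_dose_MBq: float = DEFAULT_FIXED_DOSE_MBQ

    def __post_init__(self):
        if self.fixed_dose_MBq <= 0:
            raise ValueError("fixed dose must be positive")

    def predict(self, octtotal, body_weight_kg) -> np.ndarray:
        oct_ = np.asarray(octtotal, dtype=float)
        bw = np.asarray(body_weight_kg, dtype=float)
        if np.any(bw <= 0):
            raise ValueError("body weight must be positive")
        return (self.a1 * (self.b1 * oct_ + self.b0)
                + self.a2 * self.fixed_dose_MBq / bw + self.c)

    def predict_from_luttotal(self, luttotal, dose_per_bw) -> np.ndarray:
        """Dose-rate model alone (no bridge), for measured LUTtotal."""
        return (self.a1 * np.asarray(luttotal, dtype=float)
                + self.a2 * np.asarray(dose_per_bw, dtype=float) + self.c)

    # -- serialization so a site can freeze its own fitted equation ----
    def to_json(self, path=None) -> str:
        payload = json.dumps(asdict(self), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    @classmethod
    def from_json(cls, source) -> "EDRPredictor":
        """Load from a JSON string or a path to a JSON file."""
        text = str(source)
        if not text.lstrip().startswith("{"):
            text = Path(source).read_text()
        return cls(**json.loads(text))


def compose(edr_model: EDRModelFit, bridge: UptakeBridgeFit,
            fixed_dose_MBq: float = DEFAULT_FIXED_DOSE_MBQ) -> EDRPredictor:
    """Substitute the bridge into the dose-rate model and fix the dose."""
    return EDRPredictor(a1=edr_model.a1, a2=edr_model.a2, c=edr_model.c,
                        b1=bridge.b1, b0=bridge.b0,
                        fixed_dose_MBq=fixed_dose_MBq)


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PredictionEval:
    n: int
    rmse: float  # uSv/h
    mae: float   # uSv/h
    residuals: np.ndarray  # measured - predicted

    def __post_init__(self):
        if self.rmse < 0 or self.mae < 0:
            raise ValueError("error metrics must be >= 0")


@dataclass(frozen=True)
class BlandAltmanResult:
    bias: float
    sd: float
    loa_low: float
    loa_high: float
    n: int

    def __post_init__(self):
        if not self.loa_low <= self.bias <= self.loa_high:
            raise ValueError("limits of agreement must bracket the bias")


def evaluate(measured, predicted) -> PredictionEval:
    """Root-mean-square and mean absolute error of predictions, uSv/h."""
    m = np.asarray(measured, dtype=float).ravel()
    p = np.asarray(predicted, dtype=float).ravel()
    if m.shape != p.shape:
        raise ValueError(f"length mismatch: {m.shape} vs {p.shape}")
    if len(m) < 1:
        raise ValueError("need at least one pair")
    resid = m - p
    return PredictionEval(
        n=len(m),
        rmse=float(np.sqrt(np.mean(resid ** 2))),
        mae=float(np.mean(np.abs(resid))),
        residuals=resid,
    )


def bland_altman(a, b) -> BlandAltmanResult:
    """Agreement between two measurement series: bias = mean(a - b),
    limits of agreement = bias +/- 1.96 * sample SD of the differences."""
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("paired arrays must have equal length")
    if len(a) < 2:
        raise ValueError("need at least two pairs")
    diff = a - b
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanResult(bias=bias, sd=sd,
                             loa_low=bias - 1.96 * sd,
                             loa_high=bias + 1.96 * sd, n=len(a))


def classify_release(edr_uSv_per_h: float,
                     limit: float = RELEASE_LIMIT_USV_PER_H) -> bool:
    """True iff the dose rate meets the isolation-release criterion
    (inclusive: exactly at the limit is releasable)."""
    edr = float(edr_uSv_per_h)
    if edr < 0:
        raise ValueError("dose rate must be >= 0")
    if limit <= 0:
        raise ValueError("limit must be positive")
    return edr <= limit


# ---------------------------------------------------------------------------
# packaged seven-case validation table
# ---------------------------------------------------------------------------

def load_test_table() -> pd.DataFrame:
    """The packaged seven-case external validation table: per-case body
    weight, pretreatment OCTtotal, dose per body weight, and measured vs
    predicted Late EDR-1 m (uSv/h), transcribed at the printed one-decimal
    precision."""
    with resources.files("lutedr").joinpath("data/validation_test_cases.csv").open() as fh:
        return pd.read_csv(fh)
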