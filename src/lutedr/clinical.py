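"""Clinical covariates for the dose-rate model.

Cockcroft-Gault creatinine clearance (drug excretion), the
albumin-bilirubin (ALBI) score (liver function), and dose per body
weight.  Units are fixed: creatinine mg/dL, albumin g/L, bilirubin
umol/L, weight kg, dose MBq; converters are provided for the common
alternates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd


@dataclass(frozen=True)
class AdministrationRecord:
    """One treatment cycle: covariates plus (optionally) the measured
    next-day external dose rate at 1 m and the uptake indices."""

    subject: str
    cycle: int
    age_y: float
    sex: str  # "male" | "female"
    body_weight_kg: float
    administered_dose_MBq: float
    serum_creatinine_mg_per_dL: float
    albumin_g_per_L: float
    bilirubin_umol_per_L: float
    measured_late_edr_uSv_per_h: float | None = None
    elapsed_h: float | None = None
    luttotal: float | None = None
    octtotal: float | None = None

    def __post_init__(self):
        if self.body_weight_kg <= 0:
            raise ValueError("body weight must be positive")
        if self.administered_dose_MBq <= 0:
            raise ValueError("dose must be positive")
        if self.age_y <= 0:
            raise ValueError("age must be positive")
        if self.sex not in ("male", "female"):
            raise ValueError(f"sex must be 'male' or 'female', got {self.sex!r}")
        edr = self.measured_late_edr_uSv_per_h
        if edr is not None and edr < 0:
            raise ValueError("measured dose rate must be >= 0")


def cockcroft_gault(age_y: float, weight_kg: float, scr_mg_per_dL: float,
                    sex: str) -> float:
    """Creatinine clearance, mL/min, by the Cockcroft-Gault formula.

    CCr = (140 - age) * weight / (72 * Scr), multiplied by 0.85 for
    women.  Actual body weight is used; the estimate is not capped.
    """
    if scr_mg_per_dL <= 0:
        raise ValueError("serum creatinine must be positive")
    if not 0 < age_y <= 140:
        raise ValueError("age must be in (0, 140] years")
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    if sex not in ("male", "female"):
        raise ValueError(f"sex must be 'male' or 'female', got {sex!r}")
    ccr = (140.0 - age_y) * weight_kg / (72.0 * scr_mg_per_dL)
    if sex == "female":
        ccr *= 0.85
    return ccr


def albi_score(albumin_g_per_L: float, bilirubin_umol_per_L: float) -> float:
    """Albumin-bilirubin score: log10(bilirubin umol/L) * 0.66
    + albumin g/L * (-0.085).  More negative = better liver function."""
    if albumin_g_per_L <= 0:
        raise ValueError("albumin must be positive")
    if bilirubin_umol_per_L <= 0:
        raise ValueError("bilirubin must be positive")
    return math.log10(bilirubin_umol_per_L) * 0.66 + albumin_g_per_L * (-0.085)


def dose_per_body_weight(dose_MBq: float, weight_kg: float) -> float:
    """Administered activity per body weight, MBq/kg."""
    if weight_kg <= 0:
        raise ValueError("weight must be positive")
    if dose_MBq < 0:
        raise ValueError("dose must be >= 0")
    return dose_MBq / weight_kg


# unit converters for the common alternate lab units
def albumin_g_dl_to_g_l(albumin_g_per_dL: float) -> float:
    return albumin_g_per_dL * 10.0


def bilirubin_mg_dl_to_umol_l(bilirubin_mg_per_dL: float) -> float:
    # molar mass of bilirubin 584.66 g/mol -> 1 mg/dL = 17.1 umol/L
    return bilirubin_mg_per_dL * 17.1


def creatinine_umol_l_to_mg_dl(scr_umol_per_L: float) -> float:
    # molar mass of creatinine 113.12 g/mol -> 1 mg/dL = 88.4 umol/L
    return scr_umol_per_L / 88.4


def add_derived_columns(cohort: pd.DataFrame) -> pd.DataFrame:
    """Append ccr_ml_min, albi and dose_per_bw columns to a cohort table.

    Expects columns: age_y, sex, body_weight_kg, administered_dose_MBq,
    serum_creatinine_mg_per_dL, albumin_g_per_L, bilirubin_umol_per_L.
    Returns a copy; the input is not modified.
    """
    out = cohort.copy()
    out["ccr_ml_min"] = [
        cockcroft_gault(a, w, s, sx)
        for a, w, s, sx in zip(out["age_y"], out["body_weight_kg"],
                               out["serum_creatinine_mg_per_dL"], out["sex"])
    ]
    out["albi"] = [
        albi_score(alb, bil)
        for alb, bil in zip(out["albumin_g_per_L"], out["bilirubin_umol_per_L"])
    ]
    out["dose_per_bw"] = [
        dose_per_body_weight(d, w)
        for d, w in zip(out["administered_dose_MBq"], out["body_weight_kg"])
    ]
    return out
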