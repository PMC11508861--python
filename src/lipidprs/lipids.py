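"""Lipid arithmetic: LDL estimation, unit conversion, log-scale effect
interpretation, and guideline threshold categorisation.

All lipid values are mmol/L internally.  LDL is estimated with the
Friedewald equation (TC − HDL − TG/2.2) when TG < 3.9 mmol/L and otherwise
from apolipoprotein B with a pluggable linear (Planella-style) estimator.
Conversion constants 38.67 mg/dL per mmol/L (cholesterol species) and
88.57 (triglycerides) reproduce the usual printed mmol↔mg pairings within
rounding.  Log-scale regression coefficients are natural logs throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

CHOL_MGDL_PER_MMOL = 38.67
TG_MGDL_PER_MMOL = 88.57

#: TG above this (mmol/L) invalidates Friedewald; switch to the apoB route.
FRIEDEWALD_TG_LIMIT = 3.9


class FriedewaldInvalid(ValueError):
    """Raised when the Friedewald equation is requested at TG ≥ 3.9 mmol/L."""


def friedewald_ldl(tc: float, hdl: float, tg: float) -> float:
    """Friedewald LDL estimate, mmol/L form: TC − HDL − TG/2.2.

    Valid only below 3.9 mmol/L TG; above that the VLDL ≈ TG/2.2
    approximation breaks down and ``FriedewaldInvalid`` is raised to signal
    the switch to the apoB-based estimator.
    """
    if tc < 0 or hdl < 0 or tg < 0:
        raise ValueError("lipid inputs must be non-negative")
    if tg >= FRIEDEWALD_TG_LIMIT:
        raise FriedewaldInvalid(
            f"TG {tg} >= {FRIEDEWALD_TG_LIMIT} mmol/L: use the apoB estimator")
    return tc - hdl - tg / 2.2


@dataclass(frozen=True)
class PlanellaConstants:
    """Slope/intercept of the linear apoB → LDL (mmol/L) estimator.

    The defaults are a synthetic calibration (documented in the methods
    note) mapping physiologic apoB of 0.6–1.8 g/L into roughly 1.3–4.5
    mmol/L LDL; substitute constants fitted to a local apoB assay where
    available.
    """

    slope: float = 2.70  # mmol/L LDL per g/L apoB
    intercept: float = -0.30


def planella_ldl(apob: Optional[float],
                 constants: PlanellaConstants = PlanellaConstants()) -> float:
    """apoB-based linear LDL estimate for the high-TG branch (mmol/L).

    Returns NaN when apoB is unavailable; the caller logs such subjects.
    """
    if apob is None or (isinstance(apob, float) and math.isnan(apob)):
        return float("nan")
    if apob <= 0:
        raise ValueError("apoB must be positive")
    return constants.slope * apob + constants.intercept


def derive_ldl_frame(pheno: pd.DataFrame,
                     constants: PlanellaConstants = PlanellaConstants()
                     ) -> tuple[pd.Series, pd.Series]:
    """Fill LDL for a phenotype table, preferring measured values.

    Returns ``(ldl, ldl_method)`` where method is one of measured /
    friedewald / planella / missing.  Friedewald applies below the 3.9
    mmol/L TG limit; above it the apoB estimator is used when apoB is
    present, else LDL stays missing.
    """
    ldl = pheno["ldl"].astype(float).copy() if "ldl" in pheno else \
        pd.Series(np.nan, index=pheno.index)
    method = pd.Series(np.where(ldl.notna(), "measured", "missing"),
                       index=pheno.index)
    tc, hdl, tg = (pheno.get(c, pd.Series(np.nan, index=pheno.index))
                   for c in ("tc", "hdl", "tg"))
    apob = pheno.get("apob", pd.Series(np.nan, index=pheno.index))

    fried = ldl.isna() & tc.notna() & hdl.notna() & tg.notna() & \
        (tg < FRIEDEWALD_TG_LIMIT)
    ldl[fried] = tc[fried] - hdl[fried] - tg[fried] / 2.2
    method[fried] = "friedewald"

    high_tg = ldl.isna() & tg.notna() & (tg >= FRIEDEWALD_TG_LIMIT)
    plan = high_tg & apob.notna()
    ldl[plan] = constants.slope * apob[plan] + constants.intercept
    method[plan] = "planella"
    return ldl, method


def mmol_to_mgdl(x: float, analyte: str) -> float:
    """Convert mmol/L to mg/dL; ``analyte`` is cholesterol or triglyceride
    (TC, LDL and HDL all use the cholesterol constant)."""
    factors = {"cholesterol": CHOL_MGDL_PER_MMOL, "triglyceride": TG_MGDL_PER_MMOL}
    if analyte not in factors:
        raise ValueError(f"unknown analyte {analyte!r}")
    return x * factors[analyte]


def mgdl_to_mmol(x: float, analyte: str) -> float:
    factors = {"cholesterol": CHOL_MGDL_PER_MMOL, "triglyceride": TG_MGDL_PER_MMOL}
    if analyte not in factors:
        raise ValueError(f"unknown analyte {analyte!r}")
    return x / factors[analyte]


def percent_change_per_allele(beta_log: float) -> float:
    """Percent change in the geometric-mean level per extra risk allele
    implied by a natural-log-scale coefficient: 100·(e^β − 1)."""
    return 100.0 * (math.exp(beta_log) - 1.0)


def absolute_change_at_mean(beta_log: float, mean_level: float) -> float:
    """Absolute change (mmol/L) at a given mean level implied by a
    natural-log-scale coefficient: mean·(e^β − 1)."""
    if mean_level <= 0:
        raise ValueError("mean_level must be positive")
    return mean_level * (math.exp(beta_log) - 1.0)


#: Guideline thresholds (mmol/L): name → (lipid column, operator, cut).
THRESHOLDS = {
    "ldl_gt_2_6": ("ldl", ">", 2.6),
    "ldl_gt_3_0": ("ldl", ">", 3.0),
    "hdl_lt_1_03": ("hdl", "<", 1.03),
    "hdl_gt_1_55": ("hdl", ">", 1.55),
    "tg_gt_1_69": ("tg", ">", 1.69),
    "tg_gt_2_26": ("tg", ">", 2.26),
}


def categorize(ldl: Optional[float] = None, hdl: Optional[float] = None,
               tg: Optional[float] = None) -> dict[str, Optional[bool]]:
    """Strict-inequality guideline flags; None where the lipid is missing."""
    values = {"ldl": ldl, "hdl": hdl, "tg": tg}
    out: dict[str, Optional[bool]] = {}
    for name, (lipid, op, cut) in THRESHOLDS.items():
        v = values[lipid]
        if v is None or (isinstance(v, float) and math.isnan(v)):
            out[name] = None
        else:
            out[name] = v > cut if op == ">" else v < cut
    return out


def categorize_frame(pheno: pd.DataFrame) -> pd.DataFrame:
    """Vectorised threshold flags over a cohort table (nullable boolean)."""
    out = {}
    for name, (lipid, op, cut) in THRESHOLDS.items():
        v = pheno.get(lipid, pd.Series(np.nan, index=pheno.index)).astype(float)
        flag = (v > cut) if op == ">" else (v < cut)
        flag = flag.astype("boolean")
        flag[v.isna()] = pd.NA
        out[name] = flag
    return pd.DataFrame(out)
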