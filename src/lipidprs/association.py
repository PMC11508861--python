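"""Regression models linking the allele-count scores to lipid outcomes.

Linear models regress (log-)lipid levels on a score treated as a continuous
allele count; HDL and TG are natural-log-transformed first, and subjects on
lipid-lowering medication and/or with coronary disease are excluded from
lipid-level models.  Logistic models give per-allele odds ratios for the
guideline threshold categories and for coronary disease, and bin contrasts
compare the top score tertile/quartile against the bottom one.  Inference
is Wald-based in both families (symmetric CIs on the log-odds scale,
exponentiated for ORs).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .scoring import BinAssignment

#: Fully-adjusted covariate sets per trait (lipid-level models).
DEFAULT_COVARIATES = {
    "LDL": ("male", "age", "bmi", "diabetes", "smoking"),
    "HDL": ("male", "age", "bmi", "diabetes", "alcohol"),
    "TG": ("male", "age", "bmi", "diabetes", "alcohol", "hypertension"),
    "CAD": ("age", "male", "hypertension", "diabetes", "smoking"),
}


@dataclass(frozen=True)
class ModelSpec:
    """One regression: outcome, exposure, covariates and population filter."""

    outcome: str
    exposure: str
    covariates: tuple[str, ...] = ()
    log_outcome: bool = False
    exclude_cad_and_lipid_lowering: bool = False
    family: str = "linear"  # linear | logistic


@dataclass(frozen=True)
class AssociationResult:
    spec: ModelSpec
    estimate: float          # beta (linear) or OR (logistic) per allele/contrast
    ci95: tuple[float, float]
    p_value: float
    n_used: int
    r_squared: Optional[float] = None       # exposure-only model (linear)
    r_squared_full: Optional[float] = None  # full covariate model (linear)
    separation: bool = False

    def __post_init__(self) -> None:
        lo, hi = self.ci95
        if not (np.isnan(lo) or lo <= self.estimate <= hi):
            raise ValueError("CI must contain the point estimate")


def _population_filter(cohort: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    df = cohort
    if spec.exclude_cad_and_lipid_lowering:
        cad = df.get("cad", pd.Series(False, index=df.index)).fillna(False).astype(bool)
        llt = df.get("on_lipid_lowering",
                     pd.Series(False, index=df.index)).fillna(False).astype(bool)
        df = df[~(cad | llt)]
    return df


def _design(cohort: pd.DataFrame, spec: ModelSpec,
            extra: Sequence[str] = ()) -> tuple[pd.Series, pd.DataFrame, int]:
    """Complete-case outcome/design matrices; returns (y, X, n_dropped)."""
    cols = [spec.outcome, spec.exposure, *spec.covariates, *extra]
    missing = [c for c in cols if c not in cohort.columns]
    if missing:
        raise KeyError(f"cohort lacks column(s): {missing}")
    df = cohort[cols].apply(pd.to_numeric, errors="coerce").astype(float)
    n0 = len(df)
    df = df.dropna()
    y = df[spec.outcome]
    if spec.log_outcome:
        if (y <= 0).any():
            raise ValueError("log transform requires strictly positive outcome")
        y = np.log(y)
    X = sm.add_constant(df[[spec.exposure, *spec.covariates, *extra]], has_constant="add")
    return y, X, n0 - len(df)


def fit_linear(cohort: pd.DataFrame, spec: ModelSpec) -> AssociationResult:
    """OLS of a (log-)lipid level on the score, with Wald inference.

    Reports the per-allele beta with 95% CI and p, the r² of the
    exposure-only model, and the r² of the full covariate model — the two
    "explained variability" figures of an unadjusted/adjusted pair.
    """
    df = _population_filter(cohort, spec)
    y, X, _ = _design(df, spec)
    if len(y) < len(X.columns) + 1:
        raise ValueError(f"too few complete cases ({len(y)}) for the design")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design matrix")
    if np.ptp(y.to_numpy()) == 0:
        return AssociationResult(spec, 0.0, (0.0, 0.0), 1.0, len(y), 0.0, 0.0)
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int().loc[spec.exposure]
    r2_exposure = sm.OLS(y, X[["const", spec.exposure]]).fit().rsquared
    return AssociationResult(
        spec, float(fit.params[spec.exposure]), (float(ci[0]), float(ci[1])),
        float(fit.pvalues[spec.exposure]), int(fit.nobs),
        r_squared=float(r2_exposure), r_squared_full=float(fit.rsquared))


def fit_logistic(cohort: pd.DataFrame, spec: ModelSpec) -> AssociationResult:
    """ML logistic fit; returns the per-allele OR with a Wald 95% CI."""
    df = _population_filter(cohort, spec)
    y, X, _ = _design(df, spec)
    classes = np.unique(y)
    if len(classes) < 2:
        raise ValueError("outcome has a single class after filtering")
    if not set(classes) <= {0.0, 1.0}:
        raise ValueError("logistic outcome must be binary 0/1")
    try:
        import warnings
        with warnings.catch_warnings():
            warnings.filterwarnings(
                "ignore", message=".*[Ss]eparation.*", category=Warning)
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    except Exception as err:
        # perfect separation surfaces either as an explicit separation
        # error or as a singular Hessian during Newton steps
        if ("separation" in f"{type(err).__name__} {err}".lower()
                or isinstance(err, np.linalg.LinAlgError)):
            return AssociationResult(spec, np.nan, (np.nan, np.nan), np.nan,
                                     len(y), separation=True)
        raise
    beta = float(fit.params[spec.exposure])
    se = float(fit.bse[spec.exposure])
    if not np.isfinite(se) or se > 50:
        return AssociationResult(spec, np.nan, (np.nan, np.nan), np.nan,
                                 len(y), separation=True)
    lo, hi = beta - 1.959963984540054 * se, beta + 1.959963984540054 * se
    return AssociationResult(
        spec, float(np.exp(beta)), (float(np.exp(lo)), float(np.exp(hi))),
        float(fit.pvalues[spec.exposure]), int(fit.nobs))


def bin_contrast(cohort: pd.DataFrame, bins: BinAssignment, outcome: str,
                 covariates: Sequence[str] = (),
                 contrast: str = "upper_vs_lower",
                 exclude_cad_and_lipid_lowering: bool = False
                 ) -> list[AssociationResult]:
    """Logistic OR(s) for score bins against the lowest bin.

    ``upper_vs_lower`` restricts to the extreme bins and returns a single
    OR (the tertile comparison); ``each_vs_first`` keeps all bins and
    returns one OR per non-reference bin (the quartile layout, k−1 ORs).
    """
    df = cohort.copy()
    df["_bin"] = bins.bin_index.reindex(df.index)
    df = df[df["_bin"].notna()]
    if contrast == "upper_vs_lower":
        df = df[df["_bin"].isin([1, bins.k])]
        indicators = {f"bin_{bins.k}_vs_1": (df["_bin"] == bins.k).astype(float)}
    elif contrast == "each_vs_first":
        indicators = {f"bin_{j}_vs_1": (df["_bin"] == j).astype(float)
                      for j in range(2, bins.k + 1)}
    else:
        raise ValueError(f"unknown contrast {contrast!r}")
    for name, col in indicators.items():
        df[name] = col
    names = list(indicators)
    results = []
    for name in names:
        # one joint model holds all bin indicators; each OR is read from it
        others = tuple(n for n in names if n != name)
        spec = ModelSpec(outcome=outcome, exposure=name,
                         covariates=tuple([*others, *covariates]),
                         family="logistic",
                         exclude_cad_and_lipid_lowering=exclude_cad_and_lipid_lowering)
        results.append(fit_logistic(df, spec))
    return results


def linear_table(results: dict[str, tuple[AssociationResult, AssociationResult]]
                 ) -> pd.DataFrame:
    """Per-trait linear summary: unadjusted and adjusted beta/CI/p/r²."""
    rows = []
    for trait, (unadj, adj) in results.items():
        rows.append({
            "score": f"{trait}-PRS",
            "outcome": adj.spec.outcome + (" (log)" if adj.spec.log_outcome else ""),
            "beta_unadj": unadj.estimate,
            "ci_unadj_lo": unadj.ci95[0], "ci_unadj_hi": unadj.ci95[1],
            "p_unadj": unadj.p_value,
            "explained_pct_unadj": 100 * (unadj.r_squared or 0),
            "beta_adj": adj.estimate,
            "ci_adj_lo": adj.ci95[0], "ci_adj_hi": adj.ci95[1],
            "p_adj": adj.p_value,
            "explained_pct_adj": 100 * (adj.r_squared_full or 0),
            "n_used": adj.n_used,
        })
    return pd.DataFrame(rows)


def logistic_table(rows: list[dict]) -> pd.DataFrame:
    """Threshold-by-model logistic summary (one row per lipid threshold)."""
    return pd.DataFrame(rows)


def result_row(label: str, r: AssociationResult) -> dict:
    return {f"{label}_or": r.estimate, f"{label}_ci_lo": r.ci95[0],
            f"{label}_ci_hi": r.ci95[1], f"{label}_p": r.p_value}
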