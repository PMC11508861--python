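"""ROC discrimination: AUC with DeLong variance and the paired DeLong test.

The AUC is the Mann–Whitney probability that a random case outscores a
random control, counting ties half.  Confidence intervals use DeLong's
structural-component variance; nested coronary-disease risk models (with
and without the LDL score) are compared on the same subjects with the
paired DeLong normal test on the AUC difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .association import ModelSpec, fit_logistic, DEFAULT_COVARIATES

_Z975 = 1.959963984540054


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def _structural_components(scores: np.ndarray, labels: np.ndarray
                           ) -> tuple[float, np.ndarray, np.ndarray]:
    """DeLong decomposition: (AUC, per-case V10, per-control V01)."""
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    m, n = len(cases), len(controls)
    all_ranks = _midranks(np.concatenate([cases, controls]))
    case_ranks = _midranks(cases)
    control_ranks = _midranks(controls)
    auc = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    v10 = (all_ranks[:m] - case_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - control_ranks) / m
    return float(auc), v10, v01


@dataclass(frozen=True)
class AucResult:
    auc: float
    ci95: tuple[float, float]
    se: float
    n_cases: int
    n_controls: int


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> AucResult:
    """AUC with a DeLong-variance 95% CI (CI clipped to [0, 1])."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must align")
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes")
    auc, v10, v01 = _structural_components(scores, labels)
    m, n = len(v10), len(v01)
    var = (np.var(v10, ddof=1) / m if m > 1 else 0.0) + \
          (np.var(v01, ddof=1) / n if n > 1 else 0.0)
    se = float(np.sqrt(var))
    ci = (max(0.0, auc - _Z975 * se), min(1.0, auc + _Z975 * se))
    return AucResult(auc, ci, se, m, n)


def auc_pair_counting(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Brute-force AUC over all case–control pairs (ties count half).

    Quadratic in sample size; intended for small inputs and cross-checks.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    wins = sum((c > d) + 0.5 * (c == d) for c in cases for d in controls)
    return float(wins / (len(cases) * len(controls)))


@dataclass(frozen=True)
class RocComparison:
    auc_base: AucResult
    auc_augmented: AucResult
    auc_difference: float
    delong_p: float
    degenerate: bool = False


def delong_paired_test(pred_base: Sequence[float], pred_augmented: Sequence[float],
                       labels: Sequence[int]) -> RocComparison:
    """Paired DeLong test for two correlated ROC curves on the same subjects.

    Two-sided normal test on the AUC difference using the DeLong covariance
    of the paired structural components.  A degenerate variance (e.g. the
    model compared with itself) is reported as p = 1 with a flag.
    """
    pb = np.asarray(pred_base, dtype=float)
    pa = np.asarray(pred_augmented, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not (pb.shape == pa.shape == labels.shape):
        raise ValueError("prediction vectors and labels must align")
    r_base = roc_auc(pb, labels)
    r_aug = roc_auc(pa, labels)
    auc_b, v10_b, v01_b = _structural_components(pb, labels)
    auc_a, v10_a, v01_a = _structural_components(pa, labels)
    m, n = len(v10_b), len(v01_b)
    s10 = np.cov(np.vstack([v10_b, v10_a]), ddof=1)
    s01 = np.cov(np.vstack([v01_b, v01_a]), ddof=1)
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    diff = auc_a - auc_b
    if var_diff <= 1e-16:
        return RocComparison(r_base, r_aug, float(diff), 1.0, degenerate=True)
    z = diff / np.sqrt(var_diff)
    p = float(2 * stats.norm.sf(abs(z)))
    return RocComparison(r_base, r_aug, float(diff), max(p, np.finfo(float).tiny))


def _predicted_probabilities(cohort: pd.DataFrame, spec: ModelSpec
                             ) -> tuple[np.ndarray, np.ndarray, pd.Index]:
    import statsmodels.api as sm

    cols = [spec.outcome, spec.exposure, *spec.covariates]
    df = cohort[cols].apply(pd.to_numeric, errors="coerce").dropna()
    y = df[spec.outcome]
    X = sm.add_constant(df[[spec.exposure, *spec.covariates]], has_constant="add")
    fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
    return fit.predict(X).to_numpy(), y.to_numpy().astype(int), df.index


@dataclass(frozen=True)
class CadModelComparison:
    auc_prs: AucResult        # age + sex + LDL score
    auc_crf: AucResult        # traditional risk factors
    auc_crf_prs: AucResult    # risk factors + LDL score
    comparison: RocComparison  # crf vs crf + score (nested pair)


def fit_and_compare_cad_models(cohort: pd.DataFrame, prs_column: str = "ldl_prs",
                               outcome: str = "cad") -> CadModelComparison:
    """Fit the three coronary-disease models and compare the nested pair.

    Models: (1) age + sex + score, (2) traditional risk factors (age, sex,
    diabetes, hypertension, smoking), (3) risk factors + score.  In-sample
    predicted probabilities feed the ROC; the paired DeLong test contrasts
    (2) against (3) on the common complete-case subjects.
    """
    crf = ("age", "male", "diabetes", "hypertension", "smoking")
    needed = [outcome, prs_column, *crf]
    df = cohort[needed].apply(pd.to_numeric, errors="coerce").dropna()

    spec_prs = ModelSpec(outcome, prs_column, ("age", "male"), family="logistic")
    spec_crf = ModelSpec(outcome, crf[0], tuple(crf[1:]), family="logistic")
    spec_both = ModelSpec(outcome, prs_column, crf, family="logistic")

    p_prs, y, _ = _predicted_probabilities(df, spec_prs)
    p_crf, y2, _ = _predicted_probabilities(df, spec_crf)
    p_both, _, _ = _predicted_probabilities(df, spec_both)
    assert np.array_equal(y, y2)

    comparison = delong_paired_test(p_crf, p_both, y)
    return CadModelComparison(roc_auc(p_prs, y), comparison.auc_base,
                              comparison.auc_augmented, comparison)


def roc_coordinates(scores: Sequence[float], labels: Sequence[int]) -> pd.DataFrame:
    """FPR/TPR coordinates for plotting (sklearn's ROC curve)."""
    from sklearn.metrics import roc_curve

    fpr, tpr, thresh = roc_curve(labels, scores)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thresh})
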