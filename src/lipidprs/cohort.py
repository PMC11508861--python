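"""Subject records, clinical flag derivation, and the genotype container."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd


@dataclass
class GenotypeMatrix:
    """Subjects × variants risk-allele dosages.

    ``dosage`` is a float DataFrame indexed by subject id with one column per
    rsid; values are 0/1/2 counts of the variant's risk allele, NaN for a
    missing call.
    """

    dosage: pd.DataFrame

    def __post_init__(self) -> None:
        d = self.dosage
        if d.index.has_duplicates:
            raise ValueError("duplicate subject ids in genotype matrix")
        vals = d.to_numpy(dtype=float)
        ok = np.isnan(vals) | np.isin(vals, (0.0, 1.0, 2.0))
        if not ok.all():
            raise ValueError("dosages must be 0, 1, 2 or missing")

    @property
    def subject_ids(self) -> pd.Index:
        return self.dosage.index

    @property
    def rsids(self) -> list[str]:
        return list(self.dosage.columns)

    def __len__(self) -> int:
        return len(self.dosage)


@dataclass
class SubjectRecord:
    """One subject's phenotypes and covariates (lipids in mmol/L)."""

    id: str
    age: float
    sex: str  # "male" | "female"
    bmi: float
    tc: Optional[float] = None
    hdl: Optional[float] = None
    tg: Optional[float] = None
    ldl: Optional[float] = None
    apob: Optional[float] = None
    sbp: Optional[float] = None
    dbp: Optional[float] = None
    on_antihypertensive: Optional[bool] = None
    on_lipid_lowering: Optional[bool] = None
    diabetes_history: Optional[bool] = None
    on_hypoglycaemic_agents: Optional[bool] = None
    smoker_current: Optional[bool] = None
    alcohol_regular: Optional[bool] = None
    alcohol_days_per_week: Optional[float] = None
    hypercholesterolemia_history: Optional[bool] = None
    cad: Optional[bool] = None

    def __post_init__(self) -> None:
        if self.age is not None and not self.age > 0:
            raise ValueError(f"{self.id}: age must be positive")
        if self.bmi is not None and not self.bmi > 0:
            raise ValueError(f"{self.id}: BMI must be positive")
        sex = str(self.sex).lower()
        if sex not in ("male", "female"):
            raise ValueError(f"{self.id}: sex must be male or female")
        self.sex = sex
        for name in ("tc", "hdl", "tg", "ldl", "apob"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValueError(f"{self.id}: {name} must be non-negative")


@dataclass(frozen=True)
class ClinicalFlags:
    """Guideline-style clinical factor flags; None = undeterminable."""

    obesity: Optional[bool]
    hypertension: Optional[bool]
    diabetes: Optional[bool]
    smoking: Optional[bool]
    alcohol: Optional[bool]
    hypercholesterolemia: Optional[bool]


def derive_clinical_flags(s: SubjectRecord) -> ClinicalFlags:
    """Derive clinical flags from a subject record.

    Definitions: obesity = BMI ≥ 30 kg/m²; hypertension = SBP ≥ 140 mmHg or
    DBP ≥ 90 mmHg or current antihypertensive use; diabetes = history or
    hypoglycaemic agents (incl. insulin); smoking = current regular smoker;
    alcohol = drinking on more than 3 days/week; hypercholesterolemia =
    history or lipid-lowering therapy.  Missing inputs propagate to a
    missing flag unless another input already decides it (e.g. medication
    use with absent blood pressure still means hypertensive).
    """
    obesity = None if s.bmi is None else s.bmi >= 30.0

    bp_high = None
    if s.sbp is not None or s.dbp is not None:
        bp_high = (s.sbp is not None and s.sbp >= 140.0) or (
            s.dbp is not None and s.dbp >= 90.0)
    hypertension = _or3(bp_high, s.on_antihypertensive)

    diabetes = _or3(s.diabetes_history, s.on_hypoglycaemic_agents)
    smoking = s.smoker_current
    if s.alcohol_regular is not None:
        alcohol = s.alcohol_regular
    elif s.alcohol_days_per_week is not None:
        alcohol = s.alcohol_days_per_week > 3
    else:
        alcohol = None
    chol = _or3(s.hypercholesterolemia_history, s.on_lipid_lowering)
    return ClinicalFlags(obesity, hypertension, diabetes, smoking, alcohol, chol)


def _or3(*args: Optional[bool]) -> Optional[bool]:
    """Three-valued OR: True dominates, all-missing stays missing."""
    if any(a is True for a in args):
        return True
    if all(a is None for a in args):
        return None
    return False


def derive_flags_frame(pheno: pd.DataFrame) -> pd.DataFrame:
    """Vectorised flag derivation over a phenotype table.

    Returns a nullable-boolean DataFrame with columns obesity, hypertension,
    diabetes, smoking, alcohol, hypercholesterolemia, indexed like ``pheno``.
    """
    def col(name):
        if name in pheno:
            return pheno[name]
        return pd.Series(pd.NA, index=pheno.index)

    obesity = (col("bmi") >= 30.0).astype("boolean")
    obesity[col("bmi").isna()] = pd.NA

    sbp, dbp = col("sbp"), col("dbp")
    bp_high = ((sbp >= 140.0) | (dbp >= 90.0)).astype("boolean")
    bp_high[sbp.isna() & dbp.isna()] = pd.NA
    hypertension = _or_series(bp_high, _as_bool(col("on_antihypertensive")))

    diabetes = _or_series(_as_bool(col("diabetes_history")),
                          _as_bool(col("on_hypoglycaemic_agents")))
    smoking = _as_bool(col("smoker_current"))
    alc_days = col("alcohol_days_per_week")
    from_days = (alc_days > 3).astype("boolean")
    from_days[alc_days.isna()] = pd.NA
    alcohol = _as_bool(col("alcohol_regular"))
    alcohol = alcohol.where(~alcohol.isna(), from_days)
    chol = _or_series(_as_bool(col("hypercholesterolemia_history")),
                      _as_bool(col("on_lipid_lowering")))
    out = pd.DataFrame({
        "obesity": obesity, "hypertension": hypertension, "diabetes": diabetes,
        "smoking": smoking, "alcohol": alcohol, "hypercholesterolemia": chol,
    })
    return out.astype("boolean")


def _as_bool(s: pd.Series) -> pd.Series:
    return s.map(lambda v: pd.NA if pd.isna(v) else bool(v))


def _or_series(a: pd.Series, b: pd.Series) -> pd.Series:
    out = pd.Series(pd.NA, index=a.index, dtype="object")
    out[(a == True) | (b == True)] = True  # noqa: E712 — nullable comparison
    both_missing = a.isna() & b.isna()
    out[~both_missing & out.isna()] = False
    return out


def records_to_frame(records: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Tabulate subject records (index = subject id)."""
    rows = [vars(r).copy() for r in records]
    df = pd.DataFrame(rows).set_index("id")
    return df
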