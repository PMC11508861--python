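"""Unweighted polygenic risk scores and their tertile/quartile binning.

Each score is a plain sum of risk-allele dosages over its member SNPs
(plus the ε2 haplotype dosage for the TG score): 0/1/2 per component, so
the LDL, HDL and TG scores range over 0–10, 0–8 and 0–12.  The HDL score
counts HDL-LOWERING alleles, so a higher HDL score predicts a lower HDL.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .apoe import epsilon2_dosage_series
from .cohort import GenotypeMatrix
from .panel import ScoreDefinition

MISSING_POLICIES = ("complete_case", "mean_impute")


@dataclass(frozen=True)
class PRSResult:
    subject_id: str
    trait: str
    score: float  # integer-valued unless imputation filled a missing call
    n_markers_used: int
    complete: bool


def compute_prs(g: GenotypeMatrix, definition: ScoreDefinition,
                apoe_e2: Optional[pd.Series] = None,
                missing_policy: str = "mean_impute") -> pd.DataFrame:
    """Compute one score for every subject.

    Returns a DataFrame indexed by subject id with columns ``score``,
    ``n_markers_used`` and ``complete``.  Under ``complete_case`` a subject
    missing any component gets a NaN score; under ``mean_impute`` a missing
    dosage is replaced by twice the cohort allele frequency at that marker
    (estimated from the observed calls) and the subject is marked
    incomplete.
    """
    if missing_policy not in MISSING_POLICIES:
        raise ValueError(f"missing_policy must be one of {MISSING_POLICIES}")
    absent = [r for r in definition.snp_members if r not in g.dosage.columns]
    if absent:
        raise KeyError(f"{definition.trait} score references absent rsid(s): {absent}")

    comp = g.dosage[list(definition.snp_members)].copy()
    if definition.include_apoe_e2_dosage:
        e2 = apoe_e2 if apoe_e2 is not None else epsilon2_dosage_series(g)
        comp["apoe_e2"] = e2.reindex(comp.index).astype(float)

    observed = comp.notna()
    n_used = observed.sum(axis=1).astype(int)
    complete = n_used == comp.shape[1]
    if missing_policy == "mean_impute":
        filled = comp.fillna(comp.mean())
        score = filled.sum(axis=1)
        n_used = pd.Series(comp.shape[1], index=comp.index)
    else:
        score = comp.sum(axis=1).where(complete, np.nan)
    return pd.DataFrame({
        "score": score.astype(float),
        "n_markers_used": n_used,
        "complete": complete,
    })


def prs_results(scores: pd.DataFrame, trait: str) -> list[PRSResult]:
    """Unpack a score frame into per-subject records."""
    return [PRSResult(str(i), trait, float(r.score), int(r.n_markers_used),
                      bool(r.complete))
            for i, r in scores.iterrows()]


@dataclass(frozen=True)
class BinAssignment:
    k: int
    cutpoints: tuple[float, ...]
    bin_index: pd.Series  # 1..k per scored subject

    def share(self, j: int) -> float:
        """Fraction of scored subjects in bin ``j``."""
        return float((self.bin_index == j).mean())


def bin_score(scores: pd.Series, k: int) -> BinAssignment:
    """Assign scored subjects to ``k`` quantile bins (tertiles/quartiles).

    Cutpoints are the empirical j/k quantiles of the score distribution.
    Because the scores are discrete, all subjects sharing a score value tied
    with a cutpoint are assigned to the lower bin, so bin shares can be far
    from 1/k (a top quartile can hold well under 25% of subjects).
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    s = scores.dropna()
    if s.nunique() < k:
        raise ValueError(f"need >= {k} distinct score values, got {s.nunique()}")
    cuts = tuple(float(np.quantile(s, j / k)) for j in range(1, k))
    idx = pd.Series(1, index=s.index)
    for c in cuts:
        idx = idx + (s > c).astype(int)
    return BinAssignment(k, cuts, idx)


def score_table(ldl: pd.DataFrame, hdl: pd.DataFrame, tg: pd.DataFrame) -> pd.DataFrame:
    """Combine the three per-trait score frames into one export table."""
    out = pd.DataFrame(index=ldl.index)
    for trait, frame in (("ldl", ldl), ("hdl", hdl), ("tg", tg)):
        out[f"{trait}_prs"] = frame["score"]
        out[f"{trait}_prs_complete"] = frame["complete"]
    return out


def plink_score_file(definition: ScoreDefinition,
                     panel: Sequence) -> pd.DataFrame:
    """PLINK-style score layout: rsid, risk allele, unit weight."""
    by_rsid = {v.rsid: v for v in panel}
    rows = [{"rsid": r, "allele": by_rsid[r].risk_allele, "weight": 1}
            for r in definition.snp_members if r in by_rsid]
    return pd.DataFrame(rows)
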