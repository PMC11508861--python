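"""Per-variant genotype quality control.

Call rate, risk-allele frequency (by default on the CAD-free subset, since
published panel frequencies refer to subjects without coronary disease),
and an exact conditional Hardy–Weinberg equilibrium test.  The family-wise
HWE threshold defaults to a Bonferroni 0.05 / 13 ≈ 3.85 × 10⁻³.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import GenotypeMatrix
from .panel import DEFAULT_PANEL, VariantDef


@dataclass(frozen=True)
class QCConfig:
    min_call_rate: float = 0.95
    hwe_alpha_family: float = 0.05
    n_tests: int = 13

    def __post_init__(self) -> None:
        if not 0 < self.min_call_rate <= 1:
            raise ValueError("min_call_rate must be in (0, 1]")
        if self.n_tests < 1:
            raise ValueError("n_tests must be >= 1")

    @property
    def hwe_threshold(self) -> float:
        return self.hwe_alpha_family / self.n_tests


@dataclass(frozen=True)
class VariantQCReport:
    rsid: str
    call_rate: float
    raf: float
    genotype_counts: tuple[int, int, int]  # (hom risk, het, hom other)
    hwe_p: float
    passed: bool


def call_rate(g: GenotypeMatrix, rsid: str) -> float:
    """Fraction of subjects with a non-missing call at ``rsid``."""
    if rsid not in g.dosage.columns:
        raise KeyError(f"unknown rsid {rsid!r}")
    col = g.dosage[rsid]
    return float(col.notna().sum() / len(col)) if len(col) else 0.0


def risk_allele_frequency(g: GenotypeMatrix, rsid: str,
                          subset: Optional[np.ndarray] = None) -> float:
    """Risk-allele frequency among non-missing calls.

    ``subset`` is an optional boolean mask (aligned with subjects) selecting
    the subjects to count — e.g. those free of coronary disease.
    """
    if rsid not in g.dosage.columns:
        raise KeyError(f"unknown rsid {rsid!r}")
    col = g.dosage[rsid]
    if subset is not None:
        col = col[np.asarray(subset, dtype=bool)]
    col = col.dropna()
    if col.empty:
        raise ValueError(f"{rsid}: no non-missing genotypes in subset")
    return float(col.sum() / (2 * len(col)))


def genotype_counts(g: GenotypeMatrix, rsid: str,
                    subset: Optional[np.ndarray] = None) -> tuple[int, int, int]:
    col = g.dosage[rsid]
    if subset is not None:
        col = col[np.asarray(subset, dtype=bool)]
    col = col.dropna()
    return (int((col == 2).sum()), int((col == 1).sum()), int((col == 0).sum()))


def hwe_exact_test(n_hom_risk: int, n_het: int, n_hom_other: int) -> float:
    """Exact conditional Hardy–Weinberg test.

    Conditions on the total genotype count n and the minor-allele count, and
    sums the probabilities of all heterozygote counts whose conditional
    probability does not exceed that of the observed count (the
    probability-ordering two-sided rule).  Returns a p-value in (0, 1].
    """
    counts = (n_hom_risk, n_het, n_hom_other)
    if any(c < 0 for c in counts):
        raise ValueError("genotype counts must be non-negative")
    n = sum(counts)
    if n < 1:
        raise ValueError("at least one genotype required")
    n_rare = min(2 * n_hom_risk + n_het, 2 * n_hom_other + n_het)
    if n_rare == 0:
        return 1.0  # monomorphic: a single possible outcome
    hets = range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    logps = np.array([_log_prob_het(h, n, n_rare) for h in hets])
    probs = np.exp(logps - logps.max())
    probs /= probs.sum()
    p_obs = probs[list(hets).index(n_het)]
    # 1e-12 relative slack guards against ties lost to rounding
    p = probs[probs <= p_obs * (1 + 1e-12)].sum()
    return float(min(p, 1.0))


def _log_prob_het(n_het: int, n: int, n_rare: int) -> float:
    """Unnormalised log-probability of ``n_het`` heterozygotes."""
    n_hom_rare = (n_rare - n_het) // 2
    n_hom_common = n - n_het - n_hom_rare
    lg = math.lgamma
    return (n_het * math.log(2.0)
            - lg(n_hom_rare + 1) - lg(n_het + 1) - lg(n_hom_common + 1))


def hwe_chisq_test(n_hom_risk: int, n_het: int, n_hom_other: int) -> float:
    """One-df chi-square HWE test (approximation; offered as an option)."""
    n = n_hom_risk + n_het + n_hom_other
    if n < 1:
        raise ValueError("at least one genotype required")
    p = (2 * n_hom_risk + n_het) / (2 * n)
    q = 1 - p
    if p == 0 or q == 0:
        return 1.0
    expected = np.array([n * p * p, 2 * n * p * q, n * q * q])
    observed = np.array([n_hom_risk, n_het, n_hom_other])
    chi2 = ((observed - expected) ** 2 / expected).sum()
    return float(stats.chi2.sf(chi2, df=1))


def qc_panel(g: GenotypeMatrix, cfg: QCConfig = QCConfig(),
             subset: Optional[np.ndarray] = None,
             method: str = "exact") -> list[VariantQCReport]:
    """QC every variant: call rate, RAF, genotype counts, HWE p, pass flag.

    ``subset`` restricts RAF/HWE counting (commonly the CAD-free subjects);
    the call rate is always computed on all subjects.
    """
    test = {"exact": hwe_exact_test, "chisq": hwe_chisq_test}[method]
    reports = []
    for rsid in g.rsids:
        cr = call_rate(g, rsid)
        counts = genotype_counts(g, rsid, subset)
        n = sum(counts)
        raf = (2 * counts[0] + counts[1]) / (2 * n) if n else float("nan")
        p = test(*counts) if n else float("nan")
        passed = bool(cr >= cfg.min_call_rate and n and p > cfg.hwe_threshold)
        reports.append(VariantQCReport(rsid, cr, raf, counts, p, passed))
    return reports


def qc_report_frame(reports: Sequence[VariantQCReport],
                    panel: Sequence[VariantDef] = DEFAULT_PANEL) -> pd.DataFrame:
    """Tabulate QC reports with panel annotations (gene, alleles, RAFs)."""
    by_rsid = {v.rsid: v for v in panel}
    rows = []
    for r in reports:
        v = by_rsid.get(r.rsid)
        rows.append({
            "rsid": r.rsid,
            "gene": v.gene_label if v else "",
            "risk_allele": v.risk_allele if v else "",
            "other_allele": v.other_allele if v else "",
            "raf": r.raf,
            "raf_published_ac": v.raf_ac if v else float("nan"),
            "call_rate": r.call_rate,
            "n_hom_risk": r.genotype_counts[0],
            "n_het": r.genotype_counts[1],
            "n_hom_other": r.genotype_counts[2],
            "hwe_p": r.hwe_p,
            "pass": r.passed,
        })
    return pd.DataFrame(rows)


def write_qc_tsv(reports: Sequence[VariantQCReport], path: str | Path,
                 panel: Sequence[VariantDef] = DEFAULT_PANEL) -> None:
    qc_report_frame(reports, panel).to_csv(path, sep="\t", index=False)
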