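"""End-to-end orchestration: harmonize a cohort and render report tables.

``assemble_cohort_table`` merges genotypes and phenotypes into one table
with derived clinical flags, estimated LDL, guideline threshold flags,
APOE ε calls and the three allele-count scores.  ``run_all`` chains QC →
APOE → scoring → lipid derivation → association models → ROC comparison
and writes flat TSV outputs shaped like the study's summary tables.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import association as assoc
from .apoe import apoe_label, call_apoe_series, epsilon2_dosage
from .cohort import GenotypeMatrix, derive_flags_frame
from .discrimination import fit_and_compare_cad_models, roc_coordinates
from .lipids import categorize_frame, derive_ldl_frame
from .panel import default_score_definitions
from .qc import QCConfig, qc_panel, write_qc_tsv
from .scoring import bin_score, compute_prs
from .simulate import SyntheticCohort

log = logging.getLogger("lipidprs")

THRESHOLD_TRAIT = {
    "ldl_gt_2_6": "LDL", "ldl_gt_3_0": "LDL",
    "hdl_lt_1_03": "HDL", "hdl_gt_1_55": "HDL",
    "tg_gt_1_69": "TG", "tg_gt_2_26": "TG",
}


def assemble_cohort_table(source: Union[SyntheticCohort, tuple[GenotypeMatrix, pd.DataFrame]],
                          missing_policy: str = "mean_impute") -> pd.DataFrame:
    """Build the harmonized per-subject analysis table.

    Columns: phenotypes, derived flags (0/1 floats, NaN undeterminable),
    ``male`` indicator, estimated LDL with method provenance, threshold
    flags, APOE ε label and ε2 dosage, and the three scores.
    """
    if isinstance(source, SyntheticCohort):
        g, pheno = source.genotypes, source.phenotypes
    else:
        g, pheno = source
    pheno = pheno.copy()
    common = pheno.index.intersection(g.subject_ids)
    if len(common) < len(pheno) or len(common) < len(g):
        log.info("subject overlap: %d of %d phenotyped / %d genotyped",
                 len(common), len(pheno), len(g))
    pheno = pheno.loc[common]
    g = GenotypeMatrix(g.dosage.loc[common])

    flags = derive_flags_frame(pheno)
    n_ht_missing = int(flags["hypertension"].isna().sum())
    if n_ht_missing:
        log.info("hypertension undeterminable for %d subject(s); they drop "
                 "from models requiring it", n_ht_missing)

    ldl, method = derive_ldl_frame(pheno)
    pheno["ldl"] = ldl
    pheno["ldl_method"] = method
    n_ldl_missing = int(ldl.isna().sum())
    if n_ldl_missing:
        log.info("LDL underivable for %d subject(s) (high TG without apoB)",
                 n_ldl_missing)

    out = pheno.copy()
    out["male"] = (pheno["sex"] == "male").astype(float)
    for col in flags:
        out[col] = flags[col].astype("float")
    thr = categorize_frame(pheno)
    for col in thr:
        out[col] = thr[col].astype("float")

    calls = call_apoe_series(g)
    out["apoe"] = calls.map(apoe_label)
    e2 = calls.map(epsilon2_dosage).astype(float)
    out["apoe_e2_dosage"] = e2

    for d in default_score_definitions():
        scores = compute_prs(g, d, apoe_e2=e2, missing_policy=missing_policy)
        out[f"{d.trait.lower()}_prs"] = scores["score"]
        out[f"{d.trait.lower()}_prs_complete"] = scores["complete"]
    if "cad" in out:
        out["cad"] = out["cad"].astype("float")
    if "on_lipid_lowering" in out:
        out["on_lipid_lowering"] = out["on_lipid_lowering"].astype("float")
    return out


def linear_models(cohort: pd.DataFrame) -> dict:
    """Unadjusted and fully adjusted lipid-level models for each score."""
    layout = {"LDL": ("ldl", "ldl_prs", False),
              "HDL": ("hdl", "hdl_prs", True),
              "TG": ("tg", "tg_prs", True)}
    results = {}
    for trait, (outcome, exposure, logged) in layout.items():
        unadj = assoc.fit_linear(cohort, assoc.ModelSpec(
            outcome, exposure, (), log_outcome=logged,
            exclude_cad_and_lipid_lowering=True))
        adj = assoc.fit_linear(cohort, assoc.ModelSpec(
            outcome, exposure, assoc.DEFAULT_COVARIATES[trait],
            log_outcome=logged, exclude_cad_and_lipid_lowering=True))
        log.info("%s-PRS linear model: n=%d (filtered from %d)",
                 trait, adj.n_used, len(cohort))
        results[trait] = (unadj, adj)
    return results


def threshold_models(cohort: pd.DataFrame) -> pd.DataFrame:
    """Per-allele and tertile-contrast ORs for the six lipid thresholds."""
    rows = []
    for threshold, trait in THRESHOLD_TRAIT.items():
        exposure = f"{trait.lower()}_prs"
        row = {"threshold": threshold, "score": f"{trait}-PRS"}
        for label, covs in (("age_sex", ("age", "male")),
                            ("full", assoc.DEFAULT_COVARIATES[trait])):
            r = assoc.fit_logistic(cohort, assoc.ModelSpec(
                threshold, exposure, covs, family="logistic",
                exclude_cad_and_lipid_lowering=True))
            row.update({f"{label}_{k}": v
                        for k, v in assoc.result_row("prs", r).items()})
            row[f"{label}_n"] = r.n_used
        filt = cohort[~(cohort.get("cad", 0).fillna(0).astype(bool) |
                        cohort.get("on_lipid_lowering", 0).fillna(0).astype(bool))]
        bins = bin_score(filt[exposure], 3)
        for label, covs in (("tertile_age_sex", ("age", "male")),
                            ("tertile_full", assoc.DEFAULT_COVARIATES[trait])):
            r = assoc.bin_contrast(filt, bins, threshold, covs)[0]
            row.update({f"{label}_{k}": v
                        for k, v in assoc.result_row("or", r).items()})
        rows.append(row)
    return pd.DataFrame(rows)


def cad_models(cohort: pd.DataFrame) -> pd.DataFrame:
    """Adjusted per-allele CAD odds ratios for the three scores."""
    rows = []
    for trait in ("LDL", "HDL", "TG"):
        r = assoc.fit_logistic(cohort, assoc.ModelSpec(
            "cad", f"{trait.lower()}_prs", assoc.DEFAULT_COVARIATES["CAD"],
            family="logistic"))
        rows.append({"score": f"{trait}-PRS", "or": r.estimate,
                     "ci_lo": r.ci95[0], "ci_hi": r.ci95[1],
                     "p": r.p_value, "n_used": r.n_used})
    return pd.DataFrame(rows)


def cad_quartile_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Quartile-of-LDL-score CAD odds ratios against the lowest quartile."""
    bins = bin_score(cohort["ldl_prs"], 4)
    results = assoc.bin_contrast(cohort, bins, "cad",
                                 assoc.DEFAULT_COVARIATES["CAD"],
                                 contrast="each_vs_first")
    rows = []
    for j, r in enumerate(results, start=2):
        rows.append({"quartile": f"Q{j}", "share": bins.share(j),
                     "or": r.estimate, "ci_lo": r.ci95[0], "ci_hi": r.ci95[1],
                     "p": r.p_value})
    rows.insert(0, {"quartile": "Q1", "share": bins.share(1), "or": 1.0,
                    "ci_lo": np.nan, "ci_hi": np.nan, "p": np.nan})
    return pd.DataFrame(rows)


def run_all(g: GenotypeMatrix, pheno: pd.DataFrame, outdir: str | Path,
            qc_config: Optional[QCConfig] = None) -> dict:
    """Run the full pipeline and write the report bundle as TSVs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    try:
        return _run_all(g, pheno, outdir, qc_config or QCConfig())
    finally:
        log.removeHandler(handler)
        handler.close()


def _run_all(g, pheno, outdir, qc_config):
    stage = "qc"
    try:
        cad_free = None
        if "cad" in pheno:
            cad_mask = ~pheno["cad"].fillna(False).astype(bool)
            cad_free = cad_mask.reindex(g.subject_ids).fillna(False).to_numpy()
        reports = qc_panel(g, qc_config, subset=cad_free)
        write_qc_tsv(reports, outdir / "qc_table.tsv")
        log.info("QC: %d/%d variants pass", sum(r.passed for r in reports),
                 len(reports))

        stage = "cohort"
        cohort = assemble_cohort_table((g, pheno))
        cohort.to_csv(outdir / "cohort.tsv", sep="\t")

        stage = "association"
        lin = linear_models(cohort)
        assoc.linear_table(lin).to_csv(outdir / "linear_table.tsv",
                                       sep="\t", index=False)
        thr = threshold_models(cohort)
        thr.to_csv(outdir / "logistic_table.tsv", sep="\t", index=False)
        cad_tab = cad_models(cohort)
        cad_tab.to_csv(outdir / "cad_table.tsv", sep="\t", index=False)
        quart = cad_quartile_table(cohort)
        quart.to_csv(outdir / "cad_quartiles.tsv", sep="\t", index=False)

        stage = "discrimination"
        comp = fit_and_compare_cad_models(cohort)
        pd.DataFrame([{
            "model": "age+sex+LDL-PRS", "auc": comp.auc_prs.auc,
            "ci_lo": comp.auc_prs.ci95[0], "ci_hi": comp.auc_prs.ci95[1],
        }, {
            "model": "CRF", "auc": comp.auc_crf.auc,
            "ci_lo": comp.auc_crf.ci95[0], "ci_hi": comp.auc_crf.ci95[1],
        }, {
            "model": "CRF+LDL-PRS", "auc": comp.auc_crf_prs.auc,
            "ci_lo": comp.auc_crf_prs.ci95[0],
            "ci_hi": comp.auc_crf_prs.ci95[1],
        }]).assign(delong_p_nested=comp.comparison.delong_p).to_csv(
            outdir / "roc_comparison.tsv", sep="\t", index=False)
        cc = cohort[["ldl_prs", "cad"]].dropna()
        roc_coordinates(cc["ldl_prs"], cc["cad"].astype(int)).to_csv(
            outdir / "roc_ldl_prs.tsv", sep="\t", index=False)
        return {"qc": reports, "cohort": cohort, "linear": lin,
                "thresholds": thr, "cad": cad_tab, "quartiles": quart,
                "roc": comp}
    except Exception as err:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {err}") from err
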