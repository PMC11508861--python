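"""Synthetic cohort generator.

Generates cohorts with the statistical structure the analysis pipeline
assumes: panel genotypes in Hardy–Weinberg proportions at the study
population's risk-allele frequencies, APOE drawn at the haplotype level
(which induces the natural dependence between rs429358 and rs7412 and the
right LDL-score variance), lipid levels with configured per-allele effects
and marginal moments, covariates at the study prevalences, a logistic
liability model for coronary disease calibrated to a target prevalence,
and per-variant missingness matching the observed call rates.

The generating parameters are kept in the returned truth record so that
parameter-recovery checks can be rerun against them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional

import numpy as np
import pandas as pd
from scipy import optimize, special

from .apoe import epsilon2_dosage_series
from .association import DEFAULT_COVARIATES, ModelSpec, fit_linear, fit_logistic
from .cohort import GenotypeMatrix
from .panel import (DEFAULT_APOE_FREQS, DEFAULT_PANEL, ScoreDefinition,
                    default_score_definitions)
from .scoring import compute_prs

APOE_RSIDS = ("rs429358", "rs7412")


@dataclass
class SimulationConfig:
    """Generating parameters; defaults emulate the study sample."""

    n_subjects: int = 705
    seed: int = 0

    #: rsid → generating risk-allele frequency (APOE handled via haplotypes)
    rafs: dict = field(default_factory=lambda: {
        v.rsid: v.raf_ac for v in DEFAULT_PANEL if v.rsid not in APOE_RSIDS})
    apoe_haplotype_freqs: tuple[float, float, float] = DEFAULT_APOE_FREQS
    cetp_haplotype_r: float = 0.0  # optional LD between the two CETP SNPs
    missingness_rate: float = 0.03  # per variant, echoing 96–98% call rates

    # per-allele generating effects (LDL raw scale; HDL/TG natural-log scale)
    beta_ldl: float = 0.144
    beta_loghdl: float = -0.021
    beta_logtg: float = 0.018

    # marginal lipid and age moments
    mean_ldl: float = 3.08
    sd_ldl: float = 0.89
    mean_hdl: float = 1.36
    sd_hdl: float = 0.48
    mean_tg: float = 1.11
    sd_tg: float = 0.73
    mean_age: float = 53.71
    sd_age: float = 14.02
    mean_bmi: float = 27.06
    sd_bmi: float = 5.46

    # covariate prevalences
    p_male: float = 0.494
    p_hypertension: float = 0.406
    p_diabetes: float = 0.173
    p_smoking: float = 0.197
    p_alcohol: float = 0.185

    # modest covariate effects on lipids (see methods note); orthogonal to
    # the genotype, so they leave the per-allele effects untouched
    ldl_age_per_year: float = 0.008
    ldl_bmi_per_unit: float = 0.015
    ldl_male: float = -0.06
    loghdl_male: float = -0.045
    loghdl_bmi_per_unit: float = -0.008
    logtg_male: float = 0.11
    logtg_bmi_per_unit: float = 0.010
    tc_noise_sd: float = 0.05

    # coronary disease liability model
    cad_prevalence_target: float = 0.272
    cad_or_per_ldl_allele: float = 1.27
    cad_age_per_year: float = 0.05
    cad_male: float = 0.7
    cad_hypertension: float = 0.6
    cad_diabetes: float = 0.5
    cad_smoking: float = 0.5

    # treatment / ancillary structure
    p_lipid_lowering_given_cad: float = 0.75
    p_lipid_lowering_no_cad: float = 0.078
    cap_tg_below_friedewald_limit: bool = True
    generate_apob: bool = True

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        f = self.apoe_haplotype_freqs
        if len(f) != 3 or abs(sum(f) - 1.0) > 1e-9 or min(f) < 0:
            raise ValueError("APOE haplotype frequencies must be a simplex triple")
        for rsid, p in self.rafs.items():
            if not 0 <= p <= 1:
                raise ValueError(f"{rsid}: frequency {p} outside [0, 1]")
        if not 0 <= self.missingness_rate < 1:
            raise ValueError("missingness_rate must be in [0, 1)")
        for name in ("sd_ldl", "sd_hdl", "sd_tg", "sd_age", "sd_bmi"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class SyntheticCohort:
    genotypes: GenotypeMatrix      # observed (post-missingness) dosages
    true_dosages: pd.DataFrame     # pre-missingness dosages
    phenotypes: pd.DataFrame       # indexed by subject id
    truth: dict                    # generating parameters + derived moments


# ---------------------------------------------------------------------------
# analytic score moments under the generating model

def prs_moments(cfg: SimulationConfig,
                definition: ScoreDefinition) -> tuple[float, float]:
    """Expectation and variance of a score under the generating model.

    Non-APOE members contribute 2p and 2p(1−p).  The pair of APOE SNPs in
    the LDL score contributes the sum over two haplotypes of a {0, 1, 2}
    component (ε2 → 0, ε3 → 1, ε4 → 2), whose covariance structure the
    haplotype-level simulation induces.  The ε2 dosage term is
    Binomial(2, f_ε2).  Optional CETP haplotype correlation adds
    4·r·√(p₁q₁p₂q₂) to the HDL score variance.
    """
    f2, f3, f4 = cfg.apoe_haplotype_freqs
    mean = var = 0.0
    members = set(definition.snp_members)
    apoe_in = members & set(APOE_RSIDS)
    for rsid in members - set(APOE_RSIDS):
        p = cfg.rafs[rsid]
        mean += 2 * p
        var += 2 * p * (1 - p)
    if apoe_in:
        if apoe_in != set(APOE_RSIDS):
            raise ValueError("scores must use both APOE SNPs or neither")
        ex = f3 + 2 * f4           # per-haplotype E[X], X ∈ {0,1,2}
        ex2 = f3 + 4 * f4
        mean += 2 * ex
        var += 2 * (ex2 - ex ** 2)
    if definition.include_apoe_e2_dosage:
        mean += 2 * f2
        var += 2 * f2 * (1 - f2)
    cetp = {"rs17231506", "rs708272"} & members
    if len(cetp) == 2 and cfg.cetp_haplotype_r:
        p1, p2 = cfg.rafs["rs17231506"], cfg.rafs["rs708272"]
        var += 4 * cfg.cetp_haplotype_r * np.sqrt(
            p1 * (1 - p1) * p2 * (1 - p2))
    return mean, var


# ---------------------------------------------------------------------------
# genotypes

def simulate_genotypes(cfg: SimulationConfig,
                       rng: Optional[np.random.Generator] = None
                       ) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Draw panel genotypes; returns (observed matrix, true dosages).

    Observed dosages equal the true ones with independent per-call
    missingness at ``cfg.missingness_rate``.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    n = cfg.n_subjects
    ids = pd.Index([f"S{i + 1:05d}" for i in range(n)], name="subject_id")
    cols: dict[str, np.ndarray] = {}

    f2, f3, f4 = cfg.apoe_haplotype_freqs
    # two APOE haplotypes per subject: 0 = ε2, 1 = ε3, 2 = ε4
    haps = rng.choice(3, size=(n, 2), p=[f2, f3, f4])
    cols["rs429358"] = (haps == 2).sum(axis=1).astype(float)   # C dosage = #ε4
    cols["rs7412"] = (haps != 0).sum(axis=1).astype(float)     # C dosage = 2 − #ε2

    cetp = ("rs17231506", "rs708272")
    ld_pair = cfg.cetp_haplotype_r and all(r in cfg.rafs for r in cetp)
    for rsid, p in cfg.rafs.items():
        if ld_pair and rsid in cetp:
            continue
        cols[rsid] = rng.binomial(2, p, size=n).astype(float)
    if ld_pair:
        p1, p2 = cfg.rafs[cetp[0]], cfg.rafs[cetp[1]]
        cov = cfg.cetp_haplotype_r * np.sqrt(p1 * (1 - p1) * p2 * (1 - p2))
        p11 = p1 * p2 + cov
        probs = np.array([p11, p1 - p11, p2 - p11, 1 - p1 - p2 + p11])
        if probs.min() < 0:
            raise ValueError("cetp_haplotype_r incompatible with the CETP RAFs")
        draws = rng.choice(4, size=(n, 2), p=probs)  # per-haplotype joint state
        cols[cetp[0]] = (draws <= 1).sum(axis=1).astype(float)
        cols[cetp[1]] = np.isin(draws, (0, 2)).sum(axis=1).astype(float)

    order = [v.rsid for v in DEFAULT_PANEL if v.rsid in cols]
    true = pd.DataFrame({r: cols[r] for r in order}, index=ids)
    observed = true.copy()
    if cfg.missingness_rate > 0:
        mask = rng.random(true.shape) < cfg.missingness_rate
        observed = observed.mask(mask)
    return GenotypeMatrix(observed), true


# ---------------------------------------------------------------------------
# phenotypes

def simulate_lipids(true_dosages: pd.DataFrame, cfg: SimulationConfig,
                    rng: np.random.Generator) -> pd.DataFrame:
    """Draw covariates and lipid levels given the true genotypes.

    Lipids follow the generating regressions on the allele-count scores
    (raw scale for LDL; natural-log scale for HDL and TG), with residual
    variances solved so the marginal moments match the configured targets.
    TC is composed as LDL + HDL + TG/2.2 plus small noise so the Friedewald
    estimate round-trips approximately.
    """
    n = len(true_dosages)
    ids = true_dosages.index
    g_true = GenotypeMatrix(true_dosages)
    defs = {d.trait: d for d in default_score_definitions()}
    prs = {t: compute_prs(g_true, d)["score"] for t, d in defs.items()}

    age = np.clip(rng.normal(cfg.mean_age, cfg.sd_age, n), 19, 95)
    male = rng.random(n) < cfg.p_male
    bmi = np.clip(rng.normal(cfg.mean_bmi, cfg.sd_bmi, n), 15, 60)
    hypertension = rng.random(n) < cfg.p_hypertension
    diabetes = rng.random(n) < cfg.p_diabetes
    smoking = rng.random(n) < cfg.p_smoking
    alcohol = rng.random(n) < cfg.p_alcohol

    def centered(x, mean):
        return np.asarray(x, dtype=float) - mean

    # LDL on the raw scale
    mu_prs, var_prs = prs_moments(cfg, defs["LDL"])
    ldl_signal = (cfg.beta_ldl * centered(prs["LDL"], mu_prs)
                  + cfg.ldl_age_per_year * centered(age, cfg.mean_age)
                  + cfg.ldl_bmi_per_unit * centered(bmi, cfg.mean_bmi)
                  + cfg.ldl_male * centered(male, cfg.p_male))
    var_sig = (cfg.beta_ldl ** 2 * var_prs
               + cfg.ldl_age_per_year ** 2 * cfg.sd_age ** 2
               + cfg.ldl_bmi_per_unit ** 2 * cfg.sd_bmi ** 2
               + cfg.ldl_male ** 2 * cfg.p_male * (1 - cfg.p_male))
    res_var = cfg.sd_ldl ** 2 - var_sig
    if res_var <= 0:
        raise ValueError("LDL effects too large for the target marginal SD")
    ldl = np.maximum(cfg.mean_ldl + ldl_signal + rng.normal(0, np.sqrt(res_var), n),
                     0.1)

    # HDL and TG on the natural-log scale (lognormal marginal moments)
    hdl = _lognormal_outcome(
        prs["HDL"], cfg, defs["HDL"], cfg.mean_hdl, cfg.sd_hdl, cfg.beta_loghdl,
        {"male": (centered(male, cfg.p_male), cfg.loghdl_male,
                  cfg.p_male * (1 - cfg.p_male)),
         "bmi": (centered(bmi, cfg.mean_bmi), cfg.loghdl_bmi_per_unit,
                 cfg.sd_bmi ** 2)}, rng)
    tg = _lognormal_outcome(
        prs["TG"], cfg, defs["TG"], cfg.mean_tg, cfg.sd_tg, cfg.beta_logtg,
        {"male": (centered(male, cfg.p_male), cfg.logtg_male,
                  cfg.p_male * (1 - cfg.p_male)),
         "bmi": (centered(bmi, cfg.mean_bmi), cfg.logtg_bmi_per_unit,
                 cfg.sd_bmi ** 2)}, rng)
    if cfg.cap_tg_below_friedewald_limit:
        tg = np.minimum(tg, 3.89)

    tc = ldl + hdl + tg / 2.2 + rng.normal(0, cfg.tc_noise_sd, n)

    # blood pressure / medication drawn consistently with the drawn flag
    on_antihyp = hypertension & (rng.random(n) < 0.6)
    untreated_high = hypertension & ~on_antihyp
    sbp = np.where(untreated_high, 140 + rng.exponential(10, n),
                   np.where(on_antihyp, rng.normal(135, 10, n),
                            np.minimum(rng.normal(125, 8, n), 139)))
    dbp = np.where(untreated_high, np.minimum(rng.normal(88, 8, n), 110),
                   np.where(on_antihyp, np.minimum(rng.normal(82, 8, n), 115),
                            np.minimum(rng.normal(78, 7, n), 89)))

    pheno = pd.DataFrame({
        "age": age, "sex": np.where(male, "male", "female"), "bmi": bmi,
        "sbp": sbp, "dbp": dbp,
        "tc": tc, "hdl": hdl, "tg": tg, "ldl": ldl,
        "on_antihypertensive": on_antihyp,
        "diabetes_history": diabetes,
        "on_hypoglycaemic_agents": diabetes & (rng.random(n) < 0.8),
        "smoker_current": smoking,
        "alcohol_regular": alcohol,
    }, index=ids)
    pheno.index.name = "id"
    if cfg.generate_apob:
        pheno["apob"] = np.maximum((ldl + 0.30) / 2.70 + rng.normal(0, 0.05, n),
                                   0.2)
    return pheno


def _lognormal_outcome(prs: pd.Series, cfg: SimulationConfig,
                       definition: ScoreDefinition, mean: float, sd: float,
                       beta: float, covs: dict, rng: np.random.Generator
                       ) -> np.ndarray:
    """Lognormal lipid with a log-scale score effect and target marginal
    mean/SD (moment-matched via the lognormal relation)."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2
    mu_prs, var_prs = prs_moments(cfg, definition)
    signal = beta * (np.asarray(prs, dtype=float) - mu_prs)
    var_sig = beta ** 2 * var_prs
    for vals, coef, var in covs.values():
        signal += coef * vals
        var_sig += coef ** 2 * var
    res_var = sigma2 - var_sig
    if res_var <= 0:
        raise ValueError("log-scale effects too large for the target SD")
    return np.exp(mu + signal + rng.normal(0, np.sqrt(res_var), len(prs)))


# ---------------------------------------------------------------------------
# coronary disease

def simulate_cad(pheno: pd.DataFrame, true_dosages: pd.DataFrame,
                 cfg: SimulationConfig, rng: np.random.Generator
                 ) -> tuple[pd.Series, float]:
    """Draw CAD labels from the logistic liability model.

    The intercept is solved so the cohort-average probability equals the
    target prevalence (to well within 0.002).  Returns (labels, intercept).
    """
    g_true = GenotypeMatrix(true_dosages)
    ldl_def = default_score_definitions()[0]
    prs = compute_prs(g_true, ldl_def)["score"].to_numpy()
    eta = (np.log(cfg.cad_or_per_ldl_allele) * prs
           + cfg.cad_age_per_year * (pheno["age"].to_numpy() - cfg.mean_age)
           + cfg.cad_male * (pheno["sex"] == "male").to_numpy()
           + cfg.cad_hypertension * _flag(pheno, "on_antihypertensive", "sbp")
           + cfg.cad_diabetes * pheno["diabetes_history"].to_numpy(dtype=float)
           + cfg.cad_smoking * pheno["smoker_current"].to_numpy(dtype=float))

    def mean_prob(alpha):
        return special.expit(alpha + eta).mean() - cfg.cad_prevalence_target

    lo, hi = -30.0, 30.0
    if mean_prob(lo) > 0 or mean_prob(hi) < 0:
        raise ValueError("target prevalence unreachable given coefficients")
    alpha = float(optimize.brentq(mean_prob, lo, hi, xtol=1e-10))
    labels = rng.random(len(eta)) < special.expit(alpha + eta)
    return pd.Series(labels, index=pheno.index, name="cad"), alpha


def _flag(pheno: pd.DataFrame, med_col: str, sbp_col: str) -> np.ndarray:
    meds = pheno[med_col].to_numpy(dtype=bool)
    high = (pheno[sbp_col].to_numpy() >= 140) | (pheno["dbp"].to_numpy() >= 90)
    return (meds | high).astype(float)


# ---------------------------------------------------------------------------
# full cohort

def simulate_cohort(cfg: SimulationConfig) -> SyntheticCohort:
    """Generate a complete synthetic cohort (genotypes, phenotypes, truth)."""
    rng = np.random.default_rng(cfg.seed)
    observed, true = simulate_genotypes(cfg, rng)
    pheno = simulate_lipids(true, cfg, rng)
    cad, alpha = simulate_cad(pheno, true, cfg, rng)
    pheno["cad"] = cad
    llt_p = np.where(cad, cfg.p_lipid_lowering_given_cad,
                     cfg.p_lipid_lowering_no_cad)
    pheno["on_lipid_lowering"] = rng.random(len(pheno)) < llt_p
    pheno["hypercholesterolemia_history"] = False

    truth = asdict(cfg)
    truth["cad_intercept"] = alpha
    for d in default_score_definitions():
        mu, var = prs_moments(cfg, d)
        truth[f"prs_{d.trait.lower()}_mean"] = mu
        truth[f"prs_{d.trait.lower()}_var"] = var
    return SyntheticCohort(observed, true, pheno, truth)


def write_truth_json(truth: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth, fh, indent=2, default=float)


def replicate_unadjusted_ldl_r2(cfg: SimulationConfig, n_replicates: int,
                                seed: int) -> np.ndarray:
    """Per-replicate unadjusted r² of LDL regressed on the LDL score.

    Each replicate regenerates genotypes and LDL levels under ``cfg`` (with
    a fresh child seed), scores the cohort, and fits the exposure-only
    linear model; the replicate's r² is returned.  This is the variance
    the 5-SNP allele-count score explains under the generating per-allele
    effect and marginal SD.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ldl_def = default_score_definitions()[0]
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2 ** 31)
    r2 = np.empty(n_replicates)
    for i, s in enumerate(seeds):
        rng = np.random.default_rng(int(s))
        observed, true = simulate_genotypes(cfg, rng)
        pheno = simulate_lipids(true, cfg, rng)
        frame = pd.DataFrame({
            "ldl": pheno["ldl"],
            "ldl_prs": compute_prs(observed, ldl_def)["score"],
        })
        res = fit_linear(frame, ModelSpec("ldl", "ldl_prs"))
        r2[i] = res.r_squared
    return r2


# ---------------------------------------------------------------------------
# parameter-recovery harness

def recovery_report(cfg: SimulationConfig, n_replicates: int,
                    seed: int) -> pd.DataFrame:
    """Replicate the generate→analyse loop and summarise recovery.

    For each generating parameter (per-allele LDL/log-HDL/log-TG effect and
    the adjusted per-allele CAD odds ratio) reports the mean estimate, the
    bias against the generating truth, and the empirical coverage of the
    per-replicate 95% CIs.  Deterministic given the seed.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    from .pipeline import assemble_cohort_table  # local import: avoid cycle

    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2 ** 31)
    truths = {"beta_ldl": cfg.beta_ldl, "beta_loghdl": cfg.beta_loghdl,
              "beta_logtg": cfg.beta_logtg,
              "cad_or_per_ldl_allele": cfg.cad_or_per_ldl_allele}
    estimates = {k: [] for k in truths}
    covered = {k: [] for k in truths}
    outcomes = {"beta_ldl": ("ldl", "ldl_prs", False, "LDL"),
                "beta_loghdl": ("hdl", "hdl_prs", True, "HDL"),
                "beta_logtg": ("tg", "tg_prs", True, "TG")}
    for s in seeds:
        rep_cfg = SimulationConfig(**{**asdict(cfg), "seed": int(s)})
        cohort = assemble_cohort_table(simulate_cohort(rep_cfg))
        for key, (outcome, exposure, log, trait) in outcomes.items():
            spec = ModelSpec(outcome, exposure, DEFAULT_COVARIATES[trait],
                             log_outcome=log, exclude_cad_and_lipid_lowering=True)
            res = fit_linear(cohort, spec)
            estimates[key].append(res.estimate)
            covered[key].append(res.ci95[0] <= truths[key] <= res.ci95[1])
        spec = ModelSpec("cad", "ldl_prs", DEFAULT_COVARIATES["CAD"],
                         family="logistic")
        res = fit_logistic(cohort, spec)
        estimates["cad_or_per_ldl_allele"].append(res.estimate)
        covered["cad_or_per_ldl_allele"].append(
            res.ci95[0] <= truths["cad_or_per_ldl_allele"] <= res.ci95[1])
    rows = []
    for key in truths:
        est = np.asarray(estimates[key])
        rows.append({
            "parameter": key, "truth": truths[key],
            "mean_estimate": est.mean(), "bias": est.mean() - truths[key],
            "sd_estimate": est.std(ddof=1) if len(est) > 1 else 0.0,
            "ci95_coverage": float(np.mean(covered[key])),
            "n_replicates": n_replicates,
        })
    return pd.DataFrame(rows)
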