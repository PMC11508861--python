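import numpy as np
import pandas as pd
import pytest

from lipidprs.association import ModelSpec, fit_linear
from lipidprs.panel import default_score_definitions
from lipidprs.pipeline import assemble_cohort_table
from lipidprs.qc import hwe_exact_test
from lipidprs.simulate import (SimulationConfig, SyntheticCohort, prs_moments,
                               recovery_report, simulate_cohort,
                               simulate_genotypes)


@pytest.fixture(scope="module")
def big_genotypes():
    cfg = SimulationConfig(n_subjects=100_000, seed=123, missingness_rate=0.0)
    observed, true = simulate_genotypes(cfg)
    return cfg, true


def test_empirical_rafs_within_three_binomial_se(big_genotypes):
    cfg, true = big_genotypes
    n = len(true)
    for rsid, p in cfg.rafs.items():
        emp = true[rsid].mean() / 2
        se = np.sqrt(p * (1 - p) / (2 * n))
        assert abs(emp - p) < 3 * se, rsid


def test_apoe_haplotype_construction_reproduces_snp_frequencies(big_genotypes):
    cfg, true = big_genotypes
    # rs7412 C frequency = 1 - eps2 = 0.91; rs429358 C frequency = eps4 = 0.24
    assert true["rs7412"].mean() / 2 == pytest.approx(0.91, abs=0.005)
    assert true["rs429358"].mean() / 2 == pytest.approx(0.24, abs=0.005)


def test_simulated_genotypes_in_hwe(big_genotypes):
    _, true = big_genotypes
    sub = true.iloc[:5000]
    for rsid in ("rs12916", "rs328", "rs3916027"):
        col = sub[rsid]
        p = hwe_exact_test(int((col == 2).sum()), int((col == 1).sum()),
                           int((col == 0).sum()))
        assert p > 0.05 / 13


def test_missingness_and_determinism():
    cfg = SimulationConfig(n_subjects=500, seed=9, missingness_rate=0.0)
    observed, _ = simulate_genotypes(cfg)
    assert observed.dosage.notna().all().all()

    a = simulate_cohort(SimulationConfig(n_subjects=400, seed=21))
    b = simulate_cohort(SimulationConfig(n_subjects=400, seed=21))
    pd.testing.assert_frame_equal(a.genotypes.dosage, b.genotypes.dosage)
    pd.testing.assert_frame_equal(a.phenotypes, b.phenotypes)
    c = simulate_cohort(SimulationConfig(n_subjects=400, seed=22))
    assert not a.phenotypes["ldl"].equals(c.phenotypes["ldl"])


def test_observed_call_rate_near_configured(big_genotypes):
    cfg = SimulationConfig(n_subjects=20_000, seed=5, missingness_rate=0.03)
    observed, _ = simulate_genotypes(cfg)
    rates = observed.dosage.notna().mean()
    assert ((rates > 0.955) & (rates < 0.985)).all()


def test_lipid_marginal_moments_match_targets():
    cfg = SimulationConfig(n_subjects=100_000, seed=31, missingness_rate=0.0)
    cohort = simulate_cohort(cfg)
    ph = cohort.phenotypes
    assert ph["ldl"].mean() == pytest.approx(3.08, abs=0.02)
    assert ph["ldl"].std() == pytest.approx(0.89, rel=0.02)
    assert ph["hdl"].mean() == pytest.approx(1.36, abs=0.02)
    assert ph["hdl"].std() == pytest.approx(0.48, rel=0.03)
    assert ph["tg"].mean() == pytest.approx(1.11, abs=0.02)
    # TG is capped below the Friedewald limit, which trims the upper tail a bit
    assert ph["tg"].std() == pytest.approx(0.73, rel=0.06)
    assert (ph["tg"] < 3.9).all()


def test_cad_prevalence_calibrated():
    cohort = simulate_cohort(SimulationConfig(n_subjects=100_000, seed=41))
    assert cohort.phenotypes["cad"].mean() == pytest.approx(0.272, abs=0.01)


def test_null_effects_leave_lipids_independent_of_score():
    cfg = SimulationConfig(n_subjects=2000, seed=51, beta_ldl=0.0,
                           beta_loghdl=0.0, beta_logtg=0.0,
                           cad_or_per_ldl_allele=1.0, missingness_rate=0.0)
    cohort = assemble_cohort_table(simulate_cohort(cfg))
    res = fit_linear(cohort, ModelSpec("ldl", "ldl_prs"))
    assert res.ci95[0] <= 0.0 <= res.ci95[1]


def test_analytic_prs_variance_matches_empirical_r2():
    """Closed-form r2 = beta^2 Var(PRS) / sd^2, with Var(PRS) summing
    2p(1-p) over the three independent SNPs plus the APOE haplotype
    component, matches the empirical unadjusted r2 at large n."""
    cfg = SimulationConfig(n_subjects=100_000, seed=61, missingness_rate=0.0)
    ldl_def = default_score_definitions()[0]
    _, var_prs = prs_moments(cfg, ldl_def)
    expected_r2 = cfg.beta_ldl ** 2 * var_prs / cfg.sd_ldl ** 2
    cohort = assemble_cohort_table(simulate_cohort(cfg))
    res = fit_linear(cohort, ModelSpec("ldl", "ldl_prs"))
    assert res.r_squared == pytest.approx(expected_r2, rel=0.05)


def test_effects_too_large_for_target_sd_rejected():
    cfg = SimulationConfig(n_subjects=100, seed=1, beta_ldl=2.0)
    with pytest.raises(ValueError, match="too large"):
        simulate_cohort(cfg)


def test_config_validation():
    with pytest.raises(ValueError):
        SimulationConfig(n_subjects=0)
    with pytest.raises(ValueError):
        SimulationConfig(apoe_haplotype_freqs=(0.5, 0.5, 0.5))
    with pytest.raises(ValueError):
        SimulationConfig(missingness_rate=1.0)


def test_recovery_report_contract():
    cfg = SimulationConfig(n_subjects=300)
    with pytest.raises(ValueError):
        recovery_report(cfg, 0, seed=1)
    a = recovery_report(cfg, 3, seed=2)
    b = recovery_report(cfg, 3, seed=2)
    pd.testing.assert_frame_equal(a, b)
    assert set(a["parameter"]) == {"beta_ldl", "beta_loghdl", "beta_logtg",
                                   "cad_or_per_ldl_allele"}


def test_truth_record_carries_generating_parameters(default_cohort):
    assert isinstance(default_cohort, SyntheticCohort)
    t = default_cohort.truth
    assert t["beta_ldl"] == 0.144
    assert "cad_intercept" in t and "prs_ldl_var" in t
    assert t["prs_ldl_var"] == pytest.approx(1.7458, abs=1e-4)
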