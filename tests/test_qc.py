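import numpy as np
import pandas as pd
import pytest

from lipidprs.cohort import GenotypeMatrix
from lipidprs.qc import (QCConfig, call_rate, genotype_counts, hwe_chisq_test,
                         hwe_exact_test, qc_panel, risk_allele_frequency)

from .oracles import hwe_enumeration_p


def test_call_rate_counts_nonmissing_fraction(tiny_genotypes):
    assert call_rate(tiny_genotypes, "rs1529729") == 1.0
    assert call_rate(tiny_genotypes, "rs12916") == 0.75
    all_missing = GenotypeMatrix(pd.DataFrame(
        {"rs12916": [np.nan, np.nan]}, index=pd.Index(["A", "B"])))
    assert call_rate(all_missing, "rs12916") == 0.0
    with pytest.raises(KeyError):
        call_rate(tiny_genotypes, "rs999")


def test_risk_allele_frequency_excludes_missing(tiny_genotypes):
    # rs12916 dosages 0,1,2,missing -> 3 risk alleles over 6
    assert risk_allele_frequency(tiny_genotypes, "rs12916") == pytest.approx(0.5)
    g = GenotypeMatrix(pd.DataFrame({"rs12916": [1.0, np.nan, 0.0]},
                                    index=pd.Index(list("ABC"))))
    assert risk_allele_frequency(g, "rs12916") == pytest.approx(0.25)
    g2 = GenotypeMatrix(pd.DataFrame({"rs12916": [2.0, 2.0, 2.0]},
                                     index=pd.Index(list("ABC"))))
    assert risk_allele_frequency(g2, "rs12916") == 1.0


def test_raf_subset_filter(tiny_genotypes):
    subset = np.array([True, True, False, False])
    # subjects A, B at rs599839: dosages 2, 0 -> RAF 0.5
    assert risk_allele_frequency(tiny_genotypes, "rs599839", subset) == 0.5
    with pytest.raises(ValueError, match="no non-missing"):
        risk_allele_frequency(tiny_genotypes, "rs12916",
                              np.array([False, False, False, True]))


@pytest.mark.parametrize("counts,expected", [
    ((0, 2, 0), 1.0),        # observed het count is the modal outcome
    ((1, 0, 1), 1 / 3),      # only het=0 is as improbable as observed
    ((5, 0, 0), 1.0),        # monomorphic: single possible outcome
    ((0, 0, 7), 1.0),
])
def test_hwe_exact_reference_values(counts, expected):
    assert hwe_exact_test(*counts) == pytest.approx(expected)


def test_hwe_exact_rejects_invalid_counts():
    with pytest.raises(ValueError):
        hwe_exact_test(-1, 2, 3)
    with pytest.raises(ValueError):
        hwe_exact_test(0, 0, 0)


def test_hwe_exact_matches_enumeration_oracle_moderate_n():
    """Spot-check the exact test against rational-arithmetic enumeration
    (the exhaustive n<=30 sweep runs with the acceptance checks)."""
    rng = np.random.default_rng(42)
    for _ in range(200):
        n = int(rng.integers(1, 60))
        a = int(rng.integers(0, n + 1))
        b = int(rng.integers(0, n - a + 1))
        c = n - a - b
        assert hwe_exact_test(a, b, c) == pytest.approx(
            hwe_enumeration_p(a, b, c), rel=1e-9)


def test_hwe_chisq_close_to_exact_at_large_balanced_counts():
    # large expected counts: the approximation should agree loosely
    p_exact = hwe_exact_test(250, 500, 250)
    p_chi = hwe_chisq_test(250, 500, 250)
    assert p_exact > 0.5 and p_chi > 0.5


def test_hwe_type_i_error_controlled_under_null():
    """Fraction of HWE-simulated variants rejected at alpha stays ~<= alpha."""
    rng = np.random.default_rng(3)
    alpha, n_variants, n = 0.05, 1000, 200
    rejections = 0
    for _ in range(n_variants):
        p = rng.uniform(0.1, 0.9)
        dosages = rng.binomial(2, p, size=n)
        counts = ((dosages == 2).sum(), (dosages == 1).sum(), (dosages == 0).sum())
        if hwe_exact_test(*counts) <= alpha:
            rejections += 1
    # exact conditional test is conservative; allow binomial noise above alpha
    assert rejections / n_variants <= alpha + 3 * np.sqrt(alpha * (1 - alpha) / n_variants)


def test_qc_panel_pass_logic_and_threshold():
    cfg = QCConfig()
    assert cfg.hwe_threshold == pytest.approx(0.05 / 13)
    rng = np.random.default_rng(11)
    cols = {"rs12916": rng.binomial(2, 0.24, 400).astype(float)}
    # rs1529729 with a 10% missing rate fails the 95% call-rate floor
    bad = rng.binomial(2, 0.29, 400).astype(float)
    bad[:40] = np.nan
    cols["rs1529729"] = bad
    g = GenotypeMatrix(pd.DataFrame(cols, index=pd.Index(
        [f"S{i}" for i in range(400)])))
    reports = {r.rsid: r for r in qc_panel(g, cfg)}
    assert reports["rs12916"].passed
    assert not reports["rs1529729"].passed
    assert reports["rs1529729"].call_rate == pytest.approx(0.90)
    counts = genotype_counts(g, "rs12916")
    assert sum(counts) == 400
    assert reports["rs12916"].raf == pytest.approx(
        (2 * counts[0] + counts[1]) / 800)
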