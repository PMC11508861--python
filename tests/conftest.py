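import numpy as np
import pandas as pd
import pytest

from lipidprs.cohort import GenotypeMatrix
from lipidprs.pipeline import assemble_cohort_table
from lipidprs.simulate import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One full-size synthetic cohort shared across read-only tests."""
    return simulate_cohort(SimulationConfig(n_subjects=705, seed=7))


@pytest.fixture(scope="session")
def cohort_table(default_cohort):
    return assemble_cohort_table(default_cohort)


@pytest.fixture()
def tiny_genotypes():
    """Hand-written 4-subject genotype matrix over three LDL-panel SNPs."""
    dosage = pd.DataFrame(
        {
            "rs12916": [0.0, 1.0, 2.0, np.nan],
            "rs1529729": [1.0, 1.0, 0.0, 2.0],
            "rs599839": [2.0, 0.0, 1.0, 0.0],
        },
        index=pd.Index(["A", "B", "C", "D"], name="subject_id"),
    )
    return GenotypeMatrix(dosage)
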