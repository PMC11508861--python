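"""APOE ε genotype inference from unphased rs429358/rs7412 genotypes.

The three common APOE haplotypes are defined jointly by the two coding
SNPs: ε4 = (rs429358-C, rs7412-C), ε3 = (T, C), ε2 = (T, T).  The rare ε1
haplotype (C, T) is assumed absent, which makes every unphased genotype
pair resolvable except the double heterozygote — that one is called ε2/ε4
(the only resolution without ε1) and flagged ambiguous.  Under no-ε1 the
ε2 haplotype count equals the T-allele dosage at rs7412.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .cohort import GenotypeMatrix


@dataclass(frozen=True)
class ApoeGenotype:
    """Unordered ε haplotype pair, e.g. ("e2", "e4")."""

    epsilon_pair: tuple[str, str]
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if any(e not in ("e2", "e3", "e4") for e in self.epsilon_pair):
            raise ValueError(f"invalid epsilon haplotype in {self.epsilon_pair}")


def call_apoe(d429358_c, d7412_c) -> Optional[ApoeGenotype]:
    """Call the ε genotype from C-allele dosages at rs429358 and rs7412.

    Returns None when either dosage is missing.  The (1, 1) double
    heterozygote is called ε2/ε4 with ``ambiguous=True``.  Dosage pairs that
    would require an ε1 haplotype — reachable only through genotyping error —
    are resolved by trusting the rs7412-derived ε2 count (capping the ε4
    count) and are also flagged ambiguous, so the call stays total.
    """
    if d429358_c is None or d7412_c is None or \
            (isinstance(d429358_c, float) and np.isnan(d429358_c)) or \
            (isinstance(d7412_c, float) and np.isnan(d7412_c)):
        return None
    a, b = int(d429358_c), int(d7412_c)
    if a not in (0, 1, 2) or b not in (0, 1, 2):
        raise ValueError(f"dosages must be 0/1/2, got ({d429358_c}, {d7412_c})")
    # haplotype counts under no-ε1: #ε4 = rs429358-C, #ε2 = rs7412-T
    n_e2 = 2 - b
    n_e4 = min(a, 2 - n_e2)
    n_e3 = 2 - n_e4 - n_e2
    pair = tuple(sorted(["e2"] * n_e2 + ["e3"] * n_e3 + ["e4"] * n_e4))
    return ApoeGenotype(pair, ambiguous=(a == 1 and b == 1) or n_e4 < a)


def epsilon2_dosage(genotype: Optional[ApoeGenotype]):
    """Count of ε2 haplotypes in a called genotype (NaN when missing)."""
    if genotype is None:
        return float("nan")
    return sum(e == "e2" for e in genotype.epsilon_pair)


def epsilon2_dosage_series(g: GenotypeMatrix) -> pd.Series:
    """Per-subject ε2 dosage from the genotype matrix (NaN when either
    APOE SNP call is missing).  Equals 2 − (rs7412 C dosage) when callable."""
    calls = call_apoe_series(g)
    return calls.map(epsilon2_dosage).astype(float)


def call_apoe_series(g: GenotypeMatrix) -> pd.Series:
    """Vector of ApoeGenotype (or None) for every subject."""
    for rsid in ("rs429358", "rs7412"):
        if rsid not in g.dosage.columns:
            raise KeyError(f"genotype matrix lacks {rsid}")
    return pd.Series(
        [call_apoe(a, b) for a, b in zip(g.dosage["rs429358"], g.dosage["rs7412"])],
        index=g.subject_ids, dtype=object)


def apoe_label(genotype: Optional[ApoeGenotype]) -> str:
    """Human-readable label like ``e3/e4`` (``./.`` when missing)."""
    if genotype is None:
        return "./."
    return "/".join(genotype.epsilon_pair)
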