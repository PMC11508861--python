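"""Independent brute-force oracles used only by the test suite."""

from fractions import Fraction
from math import factorial

import numpy as np


def hwe_enumeration_p(n_hom_risk: int, n_het: int, n_hom_other: int) -> float:
    """Exact conditional HWE p-value by full enumeration in rational
    arithmetic: probabilities of all heterozygote counts compatible with
    (n, minor allele count), summed over those no more probable than the
    observed count."""
    n = n_hom_risk + n_het + n_hom_other
    n_rare = min(2 * n_hom_risk + n_het, 2 * n_hom_other + n_het)
    if n_rare == 0:
        return 1.0

    def weight(het: int) -> Fraction:
        hom_rare = (n_rare - het) // 2
        hom_common = n - het - hom_rare
        return Fraction(2 ** het,
                        factorial(hom_rare) * factorial(het) * factorial(hom_common))

    hets = list(range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2))
    weights = {h: weight(h) for h in hets}
    total = sum(weights.values())
    p_obs = weights[n_het]
    return float(sum(w for w in weights.values() if w <= p_obs) / total)


def auc_pairs(scores, labels) -> float:
    """AUC by exhaustive case-control pair counting, ties worth half."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    total = 0.0
    for c in cases:
        for d in controls:
            total += 1.0 if c > d else 0.5 if c == d else 0.0
    return total / (len(cases) * len(controls))
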