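"""Descriptive cohort summaries in the usual mean (SD) / n (%) layout."""

from __future__ import annotations

import numpy as np
import pandas as pd

CONTINUOUS = ("age", "bmi", "tc", "ldl", "hdl", "tg")
CATEGORICAL = ("obesity", "hypertension", "diabetes", "smoking", "alcohol",
               "cad", "on_lipid_lowering", "male")


def format_percent(count: int, total: int, ndigits: int = 1) -> str:
    """Percentage of ``count`` out of ``total`` as printed, e.g. '8.7'."""
    if total <= 0:
        raise ValueError("total must be positive")
    return f"{round(100 * count / total, ndigits):.{ndigits}f}"


def mean_sd(values: pd.Series, ndigits: int = 2) -> str:
    v = pd.to_numeric(values, errors="coerce").dropna()
    return f"{v.mean():.{ndigits}f} ({v.std(ddof=1):.{ndigits}f})"


def count_percent(flags: pd.Series, ndigits: int = 1) -> str:
    f = flags.dropna().astype(bool)
    if f.empty:
        return "0 (0.0)"
    return f"{int(f.sum())} ({format_percent(int(f.sum()), len(f), ndigits)})"


def descriptive_table(cohort: pd.DataFrame) -> pd.DataFrame:
    """Mean (SD) and n (%) summaries, overall and by sex.

    Lipid rows are restricted to subjects free of coronary disease and not
    on lipid-lowering therapy, matching how such samples are described.
    Denominators vary by row with the available (non-missing) data.
    """
    male = cohort.get("male", pd.Series(np.nan, index=cohort.index)) == 1
    cad = cohort.get("cad", pd.Series(0.0, index=cohort.index)).fillna(0) == 1
    llt = cohort.get("on_lipid_lowering",
                     pd.Series(0.0, index=cohort.index)).fillna(0) == 1
    lipid_sub = ~(cad | llt)
    groups = {"all": pd.Series(True, index=cohort.index),
              "males": male, "females": ~male}
    rows = []
    for var in CATEGORICAL:
        if var not in cohort:
            continue
        rows.append({"variable": var, **{
            gname: count_percent(cohort.loc[gmask, var])
            for gname, gmask in groups.items()}})
    for var in CONTINUOUS:
        if var not in cohort:
            continue
        mask = lipid_sub if var in ("tc", "ldl", "hdl", "tg") else \
            pd.Series(True, index=cohort.index)
        rows.append({"variable": var, **{
            gname: mean_sd(cohort.loc[gmask & mask, var])
            for gname, gmask in groups.items()}})
    return pd.DataFrame(rows).set_index("variable")
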