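"""File ingestion and export: genotype TSV/VCF, phenotype CSV, cohort TSV.

Genotype TSV dialect: a ``subject_id`` column plus one column per rsid; each
cell is either an allele-pair string (``CT``, order irrelevant) or an integer
risk-allele dosage 0/1/2 — auto-detected per column.  Missing calls are
``.`` or empty.  VCF input is matched to the panel by the ID field only.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cohort import GenotypeMatrix
from .panel import DEFAULT_PANEL, VariantDef

_MISSING_TOKENS = {".", "", "na", "nan"}

PHENOTYPE_COLUMNS = (
    "age", "sex", "bmi", "sbp", "dbp", "tc", "hdl", "tg", "ldl", "apob",
    "on_antihypertensive", "on_lipid_lowering", "diabetes_history",
    "on_hypoglycaemic_agents", "smoker_current", "alcohol_regular",
    "alcohol_days_per_week", "hypercholesterolemia_history", "cad",
)

_BOOL_COLUMNS = (
    "on_antihypertensive", "on_lipid_lowering", "diabetes_history",
    "on_hypoglycaemic_agents", "smoker_current", "alcohol_regular",
    "hypercholesterolemia_history", "cad",
)


def _dosage_from_pair(cell: str, variant: VariantDef) -> float:
    alleles = cell.strip().upper()
    if len(alleles) != 2:
        raise ValueError(f"{variant.rsid}: malformed genotype {cell!r}")
    valid = {variant.risk_allele, variant.other_allele}
    bad = set(alleles) - valid
    if bad:
        raise ValueError(
            f"{variant.rsid}: allele(s) {sorted(bad)} not in {sorted(valid)}")
    return float(sum(a == variant.risk_allele for a in alleles))


def read_genotypes_tsv(path: str | Path,
                       panel: Sequence[VariantDef] = DEFAULT_PANEL) -> GenotypeMatrix:
    """Read a genotype TSV, orienting every column to its risk allele."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if "subject_id" not in df.columns:
        raise ValueError("genotype TSV must have a subject_id column")
    if df["subject_id"].duplicated().any():
        dups = df.loc[df["subject_id"].duplicated(), "subject_id"].tolist()
        raise ValueError(f"duplicate subject id(s): {dups}")
    by_rsid = {v.rsid: v for v in panel}
    out = {}
    for col in df.columns:
        if col == "subject_id":
            continue
        if col not in by_rsid:
            raise ValueError(f"unknown rsid column {col!r}")
        variant = by_rsid[col]
        cells = df[col].str.strip()
        dosages = np.full(len(cells), np.nan)
        present = ~cells.str.lower().isin(_MISSING_TOKENS)
        # per-column dialect: all-numeric cells are dosages, else allele pairs
        nonmissing = cells[present]
        if len(nonmissing) and nonmissing.str.fullmatch(r"[012]").all():
            dosages[present.to_numpy()] = nonmissing.astype(float).to_numpy()
        else:
            dosages[present.to_numpy()] = [
                _dosage_from_pair(c, variant) for c in nonmissing]
        out[col] = dosages
    dosage = pd.DataFrame(out, index=pd.Index(df["subject_id"], name="subject_id"))
    return GenotypeMatrix(dosage)


def read_genotypes_vcf(path: str | Path,
                       panel: Sequence[VariantDef] = DEFAULT_PANEL) -> GenotypeMatrix:
    """Read panel variants from a VCF, matching records by rsid in ID."""
    from cyvcf2 import VCF

    by_rsid = {v.rsid: v for v in panel}
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cols: dict[str, np.ndarray] = {}
    for rec in vcf:
        variant = by_rsid.get(rec.ID)
        if variant is None:
            continue
        if len(rec.ALT) != 1:
            raise ValueError(f"{rec.ID}: expected a biallelic record")
        ref, alt = rec.REF.upper(), rec.ALT[0].upper()
        if {ref, alt} != {variant.risk_allele, variant.other_allele}:
            raise ValueError(
                f"{rec.ID}: alleles {ref}/{alt} do not match panel "
                f"{variant.risk_allele}/{variant.other_allele}")
        alt_dosage = np.array([
            np.nan if -1 in g[:2] else float(g[0] + g[1])
            for g in rec.genotypes])
        cols[rec.ID] = alt_dosage if alt == variant.risk_allele else 2.0 - alt_dosage
    vcf.close()
    dosage = pd.DataFrame(cols, index=pd.Index(samples, name="subject_id"))
    return GenotypeMatrix(dosage)


def read_genotypes(path: str | Path,
                   panel: Sequence[VariantDef] = DEFAULT_PANEL) -> GenotypeMatrix:
    """Dispatch on extension: ``.vcf`` → VCF reader, anything else → TSV."""
    if str(path).endswith((".vcf", ".vcf.gz")):
        return read_genotypes_vcf(path, panel)
    return read_genotypes_tsv(path, panel)


def write_genotypes_tsv(g: GenotypeMatrix, path: str | Path) -> None:
    """Write dosages as TSV (missing as ``.``); round-trips exactly."""
    df = g.dosage.map(lambda v: "." if np.isnan(v) else str(int(v)))
    df.index.name = "subject_id"
    df.to_csv(path, sep="\t")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    """Read the phenotype CSV into a table indexed by subject id.

    Expected header: ``id`` plus any of the documented phenotype columns;
    sex coded male/female (case-insensitive), booleans as 0/1 or true/false,
    lipids in mmol/L, missing values empty.
    """
    df = pd.read_csv(path)
    if "id" not in df.columns:
        raise ValueError("phenotype CSV must have an id column")
    if df["id"].duplicated().any():
        raise ValueError("duplicate subject ids in phenotype CSV")
    df = df.set_index("id")
    unknown = set(df.columns) - set(PHENOTYPE_COLUMNS)
    if unknown:
        raise ValueError(f"unknown phenotype column(s): {sorted(unknown)}")
    if "sex" in df:
        sex = df["sex"].astype(str).str.lower()
        bad = ~sex.isin(["male", "female"]) & df["sex"].notna()
        if bad.any():
            raise ValueError(f"invalid sex value(s): {df.loc[bad, 'sex'].unique()}")
        df["sex"] = sex
    for col in _BOOL_COLUMNS:
        if col in df:
            df[col] = df[col].map(_parse_bool).astype("boolean")
    return df


def _parse_bool(v):
    if pd.isna(v):
        return pd.NA
    if isinstance(v, str):
        s = v.strip().lower()
        if s in ("1", "true", "yes"):
            return True
        if s in ("0", "false", "no"):
            return False
        raise ValueError(f"invalid boolean value {v!r}")
    return bool(v)


def write_cohort_tsv(cohort: pd.DataFrame, path: str | Path) -> None:
    """Write the harmonized cohort table (phenotypes + derived columns)."""
    cohort.to_csv(path, sep="\t", index=True)
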