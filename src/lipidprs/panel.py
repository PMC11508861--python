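"""Variant panel and score definitions.

The package ships a fixed 13-SNP panel of lipid-associated variants
(LDL-raising, HDL-lowering and TG-raising) together with the three score
definitions built from it.  Risk-allele frequencies are given both for the
Afro-Caribbean study population the simulator emulates (``raf_ac``) and for
people of European ancestry (``raf_pea``); per-allele published effects are
in mmol/L on the raw (LDL) or natural-log (HDL, TG) scale.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml

TRAITS = ("LDL", "HDL", "TG")

_BASES = frozenset("ACGT")


@dataclass(frozen=True)
class VariantDef:
    """One scored SNP: alleles, trait membership and published statistics."""

    rsid: str
    gene_label: str
    chromosome: str
    risk_allele: str
    other_allele: str
    traits: frozenset[str]
    raf_ac: float
    raf_pea: float
    published_beta: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.risk_allele not in _BASES or self.other_allele not in _BASES:
            raise ValueError(f"{self.rsid}: alleles must be single bases")
        if self.risk_allele == self.other_allele:
            raise ValueError(f"{self.rsid}: risk and other allele identical")
        if not self.traits or not set(self.traits) <= set(TRAITS):
            raise ValueError(f"{self.rsid}: traits must be a nonempty subset of {TRAITS}")
        for raf in (self.raf_ac, self.raf_pea):
            if not 0.0 <= raf <= 1.0:
                raise ValueError(f"{self.rsid}: allele frequency {raf} outside [0, 1]")


def _v(rsid, gene, chrom, risk, other, traits, raf_ac, raf_pea, betas):
    return VariantDef(rsid, gene, chrom, risk, other, frozenset(traits), raf_ac, raf_pea, betas)


#: The 13-SNP default panel (risk/reference alleles and study-sample RAFs).
DEFAULT_PANEL: tuple[VariantDef, ...] = (
    _v("rs12916", "HMGCR", "5", "C", "T", {"LDL"}, 0.24, 0.38, {"LDL": 0.02}),
    _v("rs1529729", "SMARCA4", "19", "C", "T", {"LDL"}, 0.29, 0.45, {"LDL": 0.09}),
    _v("rs599839", "SORT1", "1", "A", "G", {"LDL"}, 0.23, 0.77, {"LDL": 0.14}),
    _v("rs429358", "APOE112", "19", "C", "T", {"LDL"}, 0.24, 0.19, {"LDL": 0.24}),
    _v("rs7412", "APOE158", "19", "C", "T", {"LDL"}, 0.91, 0.96, {"LDL": 0.49}),
    _v("rs301", "LPL", "8", "C", "T", {"HDL"}, 0.29, 0.75, {"HDL": -0.04}),
    _v("rs3916027", "SLC18A1/LPL", "8", "G", "A", {"HDL", "TG"}, 0.59, 0.73,
       {"HDL": -0.04, "TG": 0.08}),
    _v("rs17231506", "CETP", "16", "C", "T", {"HDL"}, 0.73, 0.68, {"HDL": -0.07}),
    _v("rs708272", "CETP", "16", "C", "T", {"HDL"}, 0.76, 0.57, {"HDL": -0.06}),
    _v("rs1260326", "GCKR", "2", "T", "C", {"TG"}, 0.16, 0.41, {"TG": 0.10}),
    _v("rs17145713", "BAZ1B", "7", "C", "T", {"TG"}, 0.69, 0.80, {"TG": 0.09}),
    _v("rs328", "LPL", "8", "C", "G", {"TG"}, 0.94, 0.89, {"TG": 0.11}),
    _v("rs17108993", "RBP4", "10", "G", "T", {"TG"}, 0.16, 0.03, {"TG": 0.14}),
)

PANEL_BY_RSID: dict[str, VariantDef] = {v.rsid: v for v in DEFAULT_PANEL}

#: Study-sample APOE haplotype frequencies (ε2, ε3, ε4) implied by the
#: printed rs429358-C (0.24) and rs7412-C (0.91) frequencies under no-ε1.
DEFAULT_APOE_FREQS: tuple[float, float, float] = (0.09, 0.67, 0.24)


@dataclass(frozen=True)
class ScoreDefinition:
    """Membership of one unweighted allele-count score.

    ``include_apoe_e2_dosage`` adds the ε2 haplotype count (0/1/2, inferred
    from rs429358/rs7412) as one extra additive component; it is on by
    default for the TG score only.
    """

    trait: str
    snp_members: tuple[str, ...]
    include_apoe_e2_dosage: bool = False

    def __post_init__(self) -> None:
        if self.trait not in TRAITS:
            raise ValueError(f"unknown trait {self.trait!r}")
        if not self.snp_members:
            raise ValueError(f"{self.trait} score has no members")
        if len(set(self.snp_members)) != len(self.snp_members):
            raise ValueError(f"{self.trait} score lists duplicate rsids")

    @property
    def n_components(self) -> int:
        return len(self.snp_members) + int(self.include_apoe_e2_dosage)

    @property
    def max_score(self) -> int:
        return 2 * self.n_components


def default_score_definitions() -> tuple[ScoreDefinition, ...]:
    """The three default scores: 5-SNP LDL, 4-SNP HDL, 5-SNP + ε2 TG."""
    return (
        ScoreDefinition("LDL", ("rs12916", "rs1529729", "rs599839", "rs429358", "rs7412")),
        ScoreDefinition("HDL", ("rs301", "rs3916027", "rs17231506", "rs708272")),
        ScoreDefinition("TG", ("rs1260326", "rs17145713", "rs3916027", "rs328", "rs17108993"),
                        include_apoe_e2_dosage=True),
    )


def load_score_config(path: str | Path,
                      panel: Iterable[VariantDef] = DEFAULT_PANEL) -> tuple[ScoreDefinition, ...]:
    """Load score definitions from a YAML or JSON config.

    The config maps trait names to a block with ``snps`` (list of rsids) and,
    optionally, ``include_apoe_e2_dosage``.  When the flag is absent it
    defaults to true for TG and false otherwise.  Every rsid must exist in
    the panel.
    """
    path = Path(path)
    text = path.read_text()
    data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("score config must map trait names to blocks")
    known = {v.rsid for v in panel}
    defs = []
    for trait, block in data.items():
        if trait not in TRAITS:
            raise ValueError(f"unknown trait {trait!r} in score config")
        if isinstance(block, list):
            block = {"snps": block}
        snps = tuple(block.get("snps", ()))
        missing = [s for s in snps if s not in known]
        if missing:
            raise ValueError(f"{trait} score references rsids absent from panel: {missing}")
        apoe = block.get("include_apoe_e2_dosage", trait == "TG")
        defs.append(ScoreDefinition(trait, snps, bool(apoe)))
    return tuple(defs)
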