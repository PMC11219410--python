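"""Packaged per-gene summary rows for the published drug-target MR analyses.

The packaged TSVs hold, for each (outcome, gene) pair, the top cis-eQTL and the
printed eQTL/GWAS/MR/HEIDI columns: the overall breast-cancer table (23 genes)
and the subtype table (ER status and five molecular subtypes).  They serve as a
worked-example input: from the (b, se) pairs the Wald ratio, SMR p and odds
ratios can be recomputed and compared against the printed MR columns.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Optional

import pandas as pd

from .sumstats import AssocRecord, VariantKey

__all__ = ["TableRow", "fixture_from_tables", "OUTCOME_LABELS"]

# outcome identifiers used in the packaged tables
OUTCOME_LABELS = (
    "overall",
    "er_positive",
    "er_negative",
    "luminal_a",
    "luminal_b",
    "luminal_b_her2_neg",
    "her2_enriched",
    "triple_negative",
)

# published p-values of 0.00E+00 underflow double precision; records need p > 0
_P_FLOOR = 1e-300


@dataclass(frozen=True)
class TableRow:
    """One printed per-gene row: top-SNP eQTL and GWAS associations plus MR columns."""

    outcome: str
    gene: str
    probe: str
    probe_chr: str
    probe_bp: int
    top_snp: str
    top_snp_chr: str
    top_snp_bp: int
    effect_allele: str
    other_allele: str
    freq: float
    b_eqtl: float
    se_eqtl: float
    p_eqtl: float
    b_gwas: float
    se_gwas: float
    p_gwas: float
    b_smr: float
    se_smr: float
    p_smr: float
    p_smr_multi: float
    p_heidi: float
    nsnp_heidi: int

    def eqtl_record(self) -> AssocRecord:
        return AssocRecord(
            variant=VariantKey(self.top_snp, self.top_snp_chr, self.top_snp_bp),
            effect_allele=self.effect_allele,
            other_allele=self.other_allele,
            eaf=self.freq,
            beta=self.b_eqtl,
            se=self.se_eqtl,
            p=max(self.p_eqtl, _P_FLOOR),
        )

    def gwas_record(self) -> AssocRecord:
        return AssocRecord(
            variant=VariantKey(self.top_snp, self.top_snp_chr, self.top_snp_bp),
            effect_allele=self.effect_allele,
            other_allele=self.other_allele,
            eaf=self.freq,
            beta=self.b_gwas,
            se=self.se_gwas,
            p=max(self.p_gwas, _P_FLOOR),
        )


def _load(name: str) -> list[TableRow]:
    with resources.files("drugtarget_mr.data").joinpath(name).open() as fh:
        df = pd.read_csv(fh, sep="\t")
    rows = []
    for _, r in df.iterrows():
        rows.append(
            TableRow(
                outcome=str(r["outcome"]),
                gene=str(r["gene"]),
                probe=str(r["probe"]),
                probe_chr=str(r["probe_chr"]),
                probe_bp=int(r["probe_bp"]),
                top_snp=str(r["topSNP"]),
                top_snp_chr=str(r["topSNP_chr"]),
                top_snp_bp=int(r["topSNP_bp"]),
                effect_allele=str(r["effect_allele"]),
                other_allele=str(r["other_allele"]),
                freq=float(r["freq"]),
                b_eqtl=float(r["b_eqtl"]),
                se_eqtl=float(r["se_eqtl"]),
                p_eqtl=float(r["p_eqtl"]),
                b_gwas=float(r["b_gwas"]),
                se_gwas=float(r["se_gwas"]),
                p_gwas=float(r["p_gwas"]),
                b_smr=float(r["b_smr"]),
                se_smr=float(r["se_smr"]),
                p_smr=float(r["p_smr"]),
                p_smr_multi=float(r["p_smr_multi"]),
                p_heidi=float(r["p_heidi"]),
                nsnp_heidi=int(r["nsnp_heidi"]),
            )
        )
    return rows


def fixture_from_tables(outcome: Optional[str] = None) -> list[TableRow]:
    """All packaged per-gene rows, optionally filtered to one outcome label.

    ``overall`` yields the 23 overall-risk rows; the subtype labels yield the
    corresponding subtype rows.
    """
    rows = _load("table1.tsv") + _load("table2.tsv")
    if outcome is None:
        return rows
    if outcome not in OUTCOME_LABELS:
        raise ValueError(f"unknown outcome {outcome!r}; expected one of {OUTCOME_LABELS}")
    return [r for r in rows if r.outcome == outcome]
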