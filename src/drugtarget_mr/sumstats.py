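"""Data model and I/O for GWAS/eQTL summary statistics, LD matrices and annotations.

Every downstream estimator (Wald ratio, SMR, HEIDI, colocalization, GSMR) consumes
per-variant association records: effect allele, other allele, effect-allele
frequency, beta, SE, p and sample size.  Two dialects are supported for flat
files: the GCTA-COJO ``.ma`` layout (``SNP A1 A2 freq b se p N``) and a flat
eQTL layout that adds gene and position columns.  Alleles of a second trait are
harmonized to the effect allele of a reference record before any ratio of betas
is formed.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "VariantKey",
    "AssocRecord",
    "SumstatsSet",
    "GeneModel",
    "LDMatrix",
    "TargetMap",
    "TraitType",
    "HarmonizeVerdict",
    "SumstatsFormatError",
    "read_sumstats",
    "write_sumstats",
    "harmonize",
    "cis_window",
    "f_statistic",
    "write_results_table",
    "read_gene_annotation",
    "read_ld_matrix",
    "write_ld_matrix",
    "read_target_map",
    "RESULT_COLUMNS",
]

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# scientific notation in published tables sometimes prints an en-dash minus
_DASHES = re.compile("[‐‑‒–—−]")


def _parse_float(text: str) -> float:
    """Parse a float accepting en-dash/minus-sign variants (e.g. ``3.2E–86``)."""
    return float(_DASHES.sub("-", str(text).strip()))


class SumstatsFormatError(ValueError):
    """A summary-statistics file does not match its declared dialect."""


class TraitType(str, Enum):
    QUANTITATIVE = "quantitative"
    CASE_CONTROL = "case_control"


@dataclass(frozen=True)
class VariantKey:
    rsid: str
    chrom: str = ""
    pos: int = 0

    def __post_init__(self) -> None:
        if not self.rsid:
            raise ValueError("rsid must be non-empty")
        if self.pos < 0:
            raise ValueError("pos must be >= 1 (0 = unknown)")


@dataclass(frozen=True)
class AssocRecord:
    """One variant's association with one trait.

    ``beta`` is in trait units per copy of ``effect_allele``; for a case-control
    trait it is the log odds per coded allele.
    """

    variant: VariantKey
    effect_allele: str
    other_allele: str
    eaf: float
    beta: float
    se: float
    p: float
    n: Optional[int] = None

    def __post_init__(self) -> None:
        if self.effect_allele == self.other_allele:
            raise ValueError(f"{self.variant.rsid}: effect and other allele identical")
        if not self.se > 0:
            raise ValueError(f"{self.variant.rsid}: se must be > 0, got {self.se}")
        if not (0.0 <= self.eaf <= 1.0):
            raise ValueError(f"{self.variant.rsid}: eaf outside [0, 1]: {self.eaf}")
        if not (0.0 < self.p <= 1.0):
            raise ValueError(f"{self.variant.rsid}: p outside (0, 1]: {self.p}")

    @property
    def rsid(self) -> str:
        return self.variant.rsid

    @property
    def z(self) -> float:
        return self.beta / self.se

    @property
    def maf(self) -> float:
        return min(self.eaf, 1.0 - self.eaf)

    def check_p_consistency(self, rtol: float = 0.10) -> bool:
        """True when the stored p agrees with the two-sided normal p of beta/se."""
        p_wald = 2.0 * stats.norm.sf(abs(self.z))
        if p_wald == 0.0:
            return self.p <= 1e-300
        return abs(self.p - p_wald) <= rtol * p_wald

    def is_palindromic(self) -> bool:
        return _COMPLEMENT.get(self.effect_allele) == self.other_allele


@dataclass
class SumstatsSet:
    """A trait's summary statistics keyed by rsid."""

    trait_id: str
    trait_type: TraitType = TraitType.QUANTITATIVE
    sdY: Optional[float] = None
    records: dict[str, AssocRecord] = field(default_factory=dict)

    def add(self, rec: AssocRecord) -> None:
        if rec.rsid in self.records:
            raise ValueError(f"duplicate rsid {rec.rsid} in {self.trait_id}")
        self.records[rec.rsid] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self.records

    def get(self, rsid: str) -> Optional[AssocRecord]:
        return self.records.get(rsid)

    def subset(self, rsids: Iterable[str]) -> "SumstatsSet":
        keep = {r: self.records[r] for r in rsids if r in self.records}
        return SumstatsSet(self.trait_id, self.trait_type, self.sdY, keep)

    def in_window(self, chrom: str, start: int, end: int) -> "SumstatsSet":
        keep = {
            r: rec
            for r, rec in self.records.items()
            if rec.variant.chrom == str(chrom) and start <= rec.variant.pos <= end
        }
        return SumstatsSet(self.trait_id, self.trait_type, self.sdY, keep)


@dataclass(frozen=True)
class GeneModel:
    gene_id: str
    chrom: str
    probe_pos: int
    start: int
    end: int

    def __post_init__(self) -> None:
        if not (self.start <= self.probe_pos <= self.end):
            raise ValueError(
                f"{self.gene_id}: probe_pos {self.probe_pos} outside [{self.start}, {self.end}]"
            )


class LDMatrix:
    """Ordered variant list with a symmetric pairwise-correlation matrix."""

    def __init__(self, variants: Sequence[str], r: np.ndarray):
        r = np.asarray(r, dtype=float)
        if r.ndim != 2 or r.shape[0] != r.shape[1]:
            raise ValueError("r must be a square matrix")
        if len(variants) != r.shape[0]:
            raise ValueError("variant list length must match matrix order")
        if not np.allclose(np.diag(r), 1.0, atol=1e-9):
            raise ValueError("LD matrix diagonal must be exactly 1")
        if not np.allclose(r, r.T, atol=1e-12):
            raise ValueError("LD matrix must be symmetric")
        if np.any(np.abs(r) > 1.0 + 1e-9):
            raise ValueError("|r_ij| must be <= 1")
        self.variants = list(variants)
        self.r = r
        self._index = {v: i for i, v in enumerate(self.variants)}
        if len(self._index) != len(self.variants):
            raise ValueError("duplicate rsids in LD matrix")

    def __len__(self) -> int:
        return len(self.variants)

    def __contains__(self, rsid: str) -> bool:
        return rsid in self._index

    def corr(self, a: str, b: str) -> float:
        return float(self.r[self._index[a], self._index[b]])

    def submatrix(self, rsids: Sequence[str]) -> "LDMatrix":
        idx = [self._index[r] for r in rsids]
        return LDMatrix(list(rsids), self.r[np.ix_(idx, idx)])


@dataclass(frozen=True)
class TargetEntry:
    drug: str
    drug_class: str
    gene_id: str


DRUG_CLASSES = ("ACEi", "ARB", "BB", "CCB", "diuretic", "AH_other")


class TargetMap:
    """Many-to-many drug -> class -> target-gene mapping."""

    def __init__(self, entries: Iterable[TargetEntry]):
        self.entries: list[TargetEntry] = []
        seen = set()
        for e in entries:
            if e.drug_class not in DRUG_CLASSES:
                raise ValueError(f"unknown drug class {e.drug_class!r}")
            key = (e.drug, e.gene_id)
            if key in seen:
                raise ValueError(f"duplicate (drug, gene) pair {key}")
            seen.add(key)
            self.entries.append(e)

    @property
    def genes(self) -> list[str]:
        out: list[str] = []
        for e in self.entries:
            if e.gene_id not in out:
                out.append(e.gene_id)
        return out

    def genes_for_class(self, drug_class: str) -> list[str]:
        return sorted({e.gene_id for e in self.entries if e.drug_class == drug_class})


# ---------------------------------------------------------------------------
# harmonization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HarmonizeVerdict:
    """Outcome of aligning a record to a reference effect allele."""

    record: Optional[AssocRecord]
    action: str  # kept | flipped | strand_flipped | strand_flipped_sign | dropped
    reason: str = ""

    @property
    def kept(self) -> bool:
        return self.record is not None


# EAF band inside which a palindromic variant cannot be oriented by frequency
PALINDROMIC_EAF_BAND = (0.42, 0.58)


def _in_band(eaf: float, band: tuple[float, float] = PALINDROMIC_EAF_BAND) -> bool:
    return band[0] <= eaf <= band[1]


def harmonize(reference: AssocRecord, other: AssocRecord) -> HarmonizeVerdict:
    """Align ``other`` so its beta refers to the reference's effect allele.

    Allele pairs may match directly, match after swapping effect/other (beta sign
    flips, eaf -> 1 - eaf), or match after strand complementation.  Palindromic
    variants (A/T, C/G) are un-orientable by strand, so they are resolved by EAF
    concordance and dropped when either trait's EAF falls in the ambiguity band
    around 0.5.
    """
    if reference.rsid != other.rsid:
        raise ValueError(
            f"harmonize called on different variants: {reference.rsid} vs {other.rsid}"
        )

    ref_pair = (reference.effect_allele, reference.other_allele)
    oth_pair = (other.effect_allele, other.other_allele)

    if reference.is_palindromic():
        if oth_pair == ref_pair:
            aligned, action = other, "kept"
        elif oth_pair == ref_pair[::-1]:
            aligned, action = _flip(other), "flipped"
        else:
            return HarmonizeVerdict(None, "dropped", "allele_mismatch")
        if _in_band(reference.eaf) or _in_band(aligned.eaf):
            return HarmonizeVerdict(None, "dropped", "palindromic_ambiguous")
        # strand cannot be read off the alleles; orient by frequency concordance
        if (reference.eaf < 0.5) == (aligned.eaf < 0.5):
            return HarmonizeVerdict(aligned, action)
        corrected = replace(aligned, beta=-aligned.beta, eaf=1.0 - aligned.eaf)
        return HarmonizeVerdict(corrected, "strand_flipped_sign")

    if oth_pair == ref_pair:
        return HarmonizeVerdict(other, "kept")
    if oth_pair == ref_pair[::-1]:
        return HarmonizeVerdict(_flip(other), "flipped")

    comp = tuple(_COMPLEMENT.get(a, "?") for a in oth_pair)
    if comp == ref_pair:
        rec = replace(other, effect_allele=ref_pair[0], other_allele=ref_pair[1])
        return HarmonizeVerdict(rec, "strand_flipped")
    if comp == ref_pair[::-1]:
        rec = _flip(replace(other, effect_allele=comp[0], other_allele=comp[1]))
        return HarmonizeVerdict(rec, "strand_flipped")

    return HarmonizeVerdict(None, "dropped", "allele_mismatch")


def _flip(rec: AssocRecord) -> AssocRecord:
    """Swap effect/other allele: beta changes sign, eaf reflects."""
    return replace(
        rec,
        effect_allele=rec.other_allele,
        other_allele=rec.effect_allele,
        beta=-rec.beta,
        eaf=1.0 - rec.eaf,
    )


# ---------------------------------------------------------------------------
# small per-record operations
# ---------------------------------------------------------------------------

def cis_window(gene: GeneModel, flank: int = 1_000_000) -> tuple[str, int, int]:
    """Closed cis interval around a gene: [max(1, start - flank), end + flank]."""
    if flank < 0:
        raise ValueError("flank must be >= 0")
    return gene.chrom, max(1, gene.start - flank), gene.end + flank


def f_statistic(rec: AssocRecord) -> float:
    """Single-SNP instrument-strength F, the squared Wald z of the association."""
    if rec.se <= 0:
        raise ValueError("se must be > 0")
    return (rec.beta / rec.se) ** 2


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

_MA_COLUMNS = ["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]
_EQTL_COLUMNS = [
    "gene", "chr", "probe_bp", "SNP", "snp_chr", "snp_bp",
    "A1", "A2", "freq", "b", "se", "p", "N",
]


def read_sumstats(
    path,
    dialect: str = "cojo_ma",
    trait_id: Optional[str] = None,
    trait_type: TraitType = TraitType.QUANTITATIVE,
    sdY: Optional[float] = None,
) -> SumstatsSet | dict[str, SumstatsSet]:
    """Read a summary-statistics table.

    ``cojo_ma`` returns a single :class:`SumstatsSet`; ``eqtl_flat`` (which adds
    gene and position columns) returns a mapping gene_id -> SumstatsSet.
    Records with non-positive SE or unparsable fields are rejected with a
    warning rather than aborting the read.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=None, engine="python", dtype=str)
    if dialect == "cojo_ma":
        required = _MA_COLUMNS[:-1]  # N optional
    elif dialect == "eqtl_flat":
        required = _EQTL_COLUMNS[:-1]
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    for col in required:
        if col not in df.columns:
            raise SumstatsFormatError(f"{path.name}: missing mandatory column {col!r}")

    n_rejected = 0

    def _make_record(row) -> Optional[AssocRecord]:
        nonlocal n_rejected
        try:
            n_val = None
            if "N" in df.columns and not pd.isna(row.get("N")):
                n_val = int(round(_parse_float(row["N"])))
            if dialect == "eqtl_flat":
                key = VariantKey(str(row["SNP"]), str(row["snp_chr"]),
                                 int(_parse_float(row["snp_bp"])))
            else:
                key = VariantKey(str(row["SNP"]))
            return AssocRecord(
                variant=key,
                effect_allele=str(row["A1"]).upper(),
                other_allele=str(row["A2"]).upper(),
                eaf=_parse_float(row["freq"]),
                beta=_parse_float(row["b"]),
                se=_parse_float(row["se"]),
                p=_parse_float(row["p"]),
                n=n_val,
            )
        except (ValueError, TypeError) as exc:
            n_rejected += 1
            logger.warning("%s: rejected record (%s)", path.name, exc)
            return None

    if dialect == "cojo_ma":
        out = SumstatsSet(trait_id or path.stem, trait_type, sdY)
        for _, row in df.iterrows():
            rec = _make_record(row)
            if rec is not None:
                out.add(rec)
        if n_rejected:
            logger.warning("%s: %d record(s) rejected", path.name, n_rejected)
        return out

    by_gene: dict[str, SumstatsSet] = {}
    for _, row in df.iterrows():
        rec = _make_record(row)
        if rec is None:
            continue
        gene = str(row["gene"])
        ss = by_gene.setdefault(gene, SumstatsSet(gene, trait_type, sdY))
        ss.add(rec)
    if n_rejected:
        logger.warning("%s: %d record(s) rejected", path.name, n_rejected)
    return by_gene


def write_sumstats(sumstats: SumstatsSet, path) -> None:
    """Write a SumstatsSet in the GCTA-COJO ``.ma`` layout."""
    rows = []
    for rec in sumstats.records.values():
        rows.append({
            "SNP": rec.rsid,
            "A1": rec.effect_allele,
            "A2": rec.other_allele,
            "freq": f"{rec.eaf:.6g}",
            "b": f"{rec.beta:.6g}",
            "se": f"{rec.se:.6g}",
            "p": f"{rec.p:.6g}",
            "N": "" if rec.n is None else str(rec.n),
        })
    pd.DataFrame(rows, columns=_MA_COLUMNS).to_csv(path, sep="\t", index=False)


def read_gene_annotation(path) -> dict[str, GeneModel]:
    """BED-like TSV with columns chrom, start, end, gene_id, probe_bp."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("chrom", "start", "end", "gene_id", "probe_bp"):
        if col not in df.columns:
            raise SumstatsFormatError(f"gene annotation missing column {col!r}")
    genes = {}
    for _, row in df.iterrows():
        g = GeneModel(
            gene_id=str(row["gene_id"]),
            chrom=str(row["chrom"]),
            probe_pos=int(_parse_float(row["probe_bp"])),
            start=int(_parse_float(row["start"])),
            end=int(_parse_float(row["end"])),
        )
        genes[g.gene_id] = g
    return genes


def read_ld_matrix(path) -> LDMatrix:
    """TSV whose first row and first column are rsids; body is r values."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise SumstatsFormatError("LD matrix row and column rsids differ")
    return LDMatrix([str(v) for v in df.index], df.to_numpy(dtype=float))


def write_ld_matrix(ld: LDMatrix, path) -> None:
    pd.DataFrame(ld.r, index=ld.variants, columns=ld.variants).to_csv(
        path, sep="\t", float_format="%.10g"
    )


def read_target_map(path) -> TargetMap:
    """TSV with columns drug, class, gene."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("drug", "class", "gene"):
        if col not in df.columns:
            raise SumstatsFormatError(f"target map missing column {col!r}")
    return TargetMap(
        TargetEntry(str(r["drug"]), str(r["class"]), str(r["gene"]))
        for _, r in df.iterrows()
    )


# ---------------------------------------------------------------------------
# results table (per-gene row layout used throughout the analysis)
# ---------------------------------------------------------------------------

RESULT_COLUMNS = [
    "Gene", "Probe", "Chr", "Probe_bp", "topSNP", "topSNP_chr", "topSNP_bp",
    "Effect_allele", "Other_allele", "Freq",
    "b_eQTL", "se_eQTL", "p_eQTL", "b_GWAS", "se_GWAS", "p_GWAS",
    "b_SMR", "se_SMR", "p_SMR", "p_SMR_multi", "p_HEIDI", "nSNP_HEIDI",
]


def write_results_table(rows: Iterable[Mapping], path) -> None:
    """Write per-gene result rows in a fixed column order (missing -> NA).

    Keys beyond the standard layout (e.g. per-family significance flags) are
    appended after the fixed columns in sorted order.
    """
    rows = list(rows)
    extra = sorted({k for row in rows for k in row} - set(RESULT_COLUMNS))
    columns = RESULT_COLUMNS + extra
    table = [{c: row.get(c, "NA") for c in columns} for row in rows]
    df = pd.DataFrame(table, columns=columns)

    def _fmt(v):
        if isinstance(v, float):
            if math.isnan(v):
                return "NA"
            return f"{v:.6g}"
        return v

    df = df.map(_fmt)
    df.to_csv(path, sep="\t", index=False)
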