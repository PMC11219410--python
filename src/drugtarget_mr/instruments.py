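"""Selection and ranking of cis-eQTL instruments for a target gene.

A variant qualifies as an instrument for a gene's expression when it lies in the
cis window (1 Mb on either side of the gene by default), is common
(MAF > 1%), reaches the genome-wide eQTL significance threshold (p < 5e-8) and
is a strong instrument (F > 10, with the single-SNP summary-data F taken as the
squared Wald z).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

from .sumstats import AssocRecord, GeneModel, SumstatsSet, cis_window, f_statistic

__all__ = ["Instrument", "NoInstrumentError", "select_instruments", "top_snp"]


class NoInstrumentError(ValueError):
    """No instrument is available where at least one is required."""


@dataclass(frozen=True)
class Instrument:
    gene_id: str
    record: AssocRecord
    f_stat: float
    is_top: bool = False

    @property
    def rsid(self) -> str:
        return self.record.rsid


def select_instruments(
    eqtl: SumstatsSet,
    gene: GeneModel,
    p_max: float = 5e-8,
    maf_min: float = 0.01,
    f_min: float = 10.0,
    flank: int = 1_000_000,
) -> list[Instrument]:
    """All cis-eQTL records passing the MAF, p and F filters, ordered by ascending p.

    Records without positional information never match the cis window and are
    excluded.  An empty list is a valid result (gene has no usable instrument).
    """
    chrom, lo, hi = cis_window(gene, flank)
    out = []
    for rec in eqtl.records.values():
        if rec.variant.chrom != chrom or not (lo <= rec.variant.pos <= hi):
            continue
        if rec.maf <= maf_min:
            continue
        if rec.p >= p_max:
            continue
        f = f_statistic(rec)
        if f <= f_min:
            continue
        out.append(Instrument(gene.gene_id, rec, f))
    out.sort(key=lambda ins: (ins.record.p, -ins.f_stat, ins.rsid))
    return out


def top_snp(instruments: list[Instrument]) -> Instrument:
    """Instrument with the smallest eQTL p; ties broken by larger F, then rsid."""
    if not instruments:
        raise NoInstrumentError("no instruments to choose a top SNP from")
    best = min(instruments, key=lambda ins: (ins.record.p, -ins.f_stat, ins.rsid))
    return replace(best, is_top=True)
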