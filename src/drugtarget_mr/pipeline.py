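"""Orchestration of the drug-target MR study flow.

Stages: instrument selection per target gene -> validation of instruments
against the blood-pressure GWAS (SMR p < 0.05 and no HEIDI heterogeneity) ->
per-outcome SMR / multi-SNP SMR / HEIDI -> Bonferroni flags per test family ->
colocalization for Bonferroni-significant hits -> cis pleiotropy scan ->
multi-instrument MR of the exposure trait on the outcome.

Two input modes are supported: ``full`` consumes regional summary statistics
plus per-gene LD matrices; ``top_snp`` consumes a pre-extracted per-gene
top-SNP table (e.g. the packaged published rows), in which case the
region-dependent stages (HEIDI, multi-SNP SMR, colocalization) are marked
"insufficient region data" rather than failing.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Optional

import pandas as pd
import yaml

from . import __version__
from .coloc import ColocPriors, ColocResult, coloc_abf
from .heidi import HEIDIResult, heidi_test, select_heidi_snps
from .instruments import Instrument, select_instruments, top_snp
from .smr import SMRResult, smr_multi, smr_test, to_odds_ratio, wald_ratio
from .sumstats import (
    GeneModel,
    LDMatrix,
    SumstatsSet,
    TraitType,
    cis_window,
    harmonize,
    read_gene_annotation,
    read_ld_matrix,
    read_sumstats,
    read_target_map,
    write_results_table,
)
from .tables import TableRow, fixture_from_tables

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "BonferroniFamily",
    "GeneAnalysis",
    "bonferroni",
    "analyze_gene",
    "validate_targets",
    "pleiotropy_scan",
    "run_pipeline",
    "run_top_snp_table",
]


def bonferroni(m: int) -> float:
    """Family-wise 0.05/m significance threshold."""
    if m < 1:
        raise ValueError("m must be >= 1")
    return 0.05 / m


@dataclass(frozen=True)
class BonferroniFamily:
    family: str  # overall | er_status | molecular | tissue
    m: int

    @property
    def alpha_adj(self) -> float:
        return bonferroni(self.m)


@dataclass
class AnalysisConfig:
    """File paths and thresholds for a full pipeline run."""

    target_map: str = ""
    gene_annotation: str = ""
    eqtl: str = ""
    sbp_gwas: str = ""
    outcome_gwas: dict[str, str] = dc_field(default_factory=dict)
    ld_dir: str = ""
    out_dir: str = "results"
    mode: str = "full"  # full | top_snp
    top_snp_table: str = ""  # top_snp mode: path, or "packaged"
    cis_flank: int = 1_000_000
    p_eqtl: float = 5e-8
    maf_min: float = 0.01
    f_min: float = 10.0
    validation_p: float = 0.05
    heidi_p: float = 0.01
    heidi_p_eqtl: float = 1.6e-3
    multi_r2: float = 0.1
    multi_max_snps: int = 20
    coloc_pp4: float = 0.80
    pleiotropy_window: int = 2_000_000
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("validation_p", "heidi_p", "p_eqtl", "coloc_pp4"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class GeneAnalysis:
    """Per-gene result of one SMR + HEIDI pass against one outcome."""

    gene_id: str
    status: str  # ok | no_instrument | not_in_gwas | harmonize_failed
    n_instruments: int = 0
    top: Optional[Instrument] = None
    smr: Optional[SMRResult] = None
    heidi: Optional[HEIDIResult] = None
    heidi_note: str = ""
    row: dict = dc_field(default_factory=dict)


def analyze_gene(
    eqtl: SumstatsSet,
    gwas: SumstatsSet,
    gene: GeneModel,
    ld: Optional[LDMatrix],
    cfg: AnalysisConfig = AnalysisConfig(),
) -> GeneAnalysis:
    """Instrument selection, top-SNP SMR, multi-SNP SMR and HEIDI for one gene."""
    instruments = select_instruments(
        eqtl, gene, p_max=cfg.p_eqtl, maf_min=cfg.maf_min,
        f_min=cfg.f_min, flank=cfg.cis_flank,
    )
    if not instruments:
        return GeneAnalysis(gene.gene_id, "no_instrument")
    top = top_snp(instruments)
    gw = gwas.get(top.rsid)
    if gw is None:
        return GeneAnalysis(gene.gene_id, "not_in_gwas", len(instruments), top)
    verdict = harmonize(top.record, gw)
    if not verdict.kept:
        return GeneAnalysis(gene.gene_id, "harmonize_failed", len(instruments), top)
    gw = verdict.record

    e = top.record
    b_xy, _ = wald_ratio(e.beta, e.se, gw.beta, gw.se)
    _, p_smr, se_smr = smr_test(e.beta, e.se, gw.beta, gw.se)

    p_multi = None
    heidi_res = None
    heidi_note = ""
    if ld is not None:
        p_multi = smr_multi(instruments, gwas, ld, r2_prune=cfg.multi_r2,
                            max_snps=cfg.multi_max_snps)
        chrom, lo, hi = cis_window(gene, cfg.cis_flank)
        cis_eqtl = eqtl.in_window(chrom, lo, hi)
        snps = select_heidi_snps(
            cis_eqtl, top, ld, p_eqtl_max=cfg.heidi_p_eqtl,
            max_snps=cfg.multi_max_snps,
        )
        if snps:
            o_eqtl, o_gwas = [], []
            for rsid in snps:
                er = eqtl.get(rsid)
                gr = gwas.get(rsid)
                if er is None or gr is None:
                    continue
                v = harmonize(er, gr)
                if v.kept:
                    o_eqtl.append(er)
                    o_gwas.append(v.record)
            if len(o_eqtl) >= 3:
                heidi_res = heidi_test(e, gw, o_eqtl, o_gwas, ld, gene.gene_id)
            else:
                heidi_note = "insufficient_heidi_snps"
        else:
            heidi_note = "insufficient_heidi_snps"
    else:
        heidi_note = "insufficient region data"

    smr_res = SMRResult(
        gene_id=gene.gene_id,
        top_rsid=top.rsid,
        b_xy=b_xy,
        se_xy=se_smr,
        p_smr=p_smr,
        p_smr_multi=p_multi,
        n_multi_snps=0 if p_multi is None else 1,
    )
    row = {
        "Gene": gene.gene_id,
        "Probe": gene.gene_id,
        "Chr": gene.chrom,
        "Probe_bp": gene.probe_pos,
        "topSNP": top.rsid,
        "topSNP_chr": e.variant.chrom,
        "topSNP_bp": e.variant.pos,
        "Effect_allele": e.effect_allele,
        "Other_allele": e.other_allele,
        "Freq": e.eaf,
        "b_eQTL": e.beta, "se_eQTL": e.se, "p_eQTL": e.p,
        "b_GWAS": gw.beta, "se_GWAS": gw.se, "p_GWAS": gw.p,
        "b_SMR": b_xy, "se_SMR": se_smr, "p_SMR": p_smr,
        "p_SMR_multi": p_multi if p_multi is not None else "NA",
        "p_HEIDI": heidi_res.p_heidi if heidi_res else (heidi_note or "NA"),
        "nSNP_HEIDI": heidi_res.m + 1 if heidi_res else 0,
    }
    return GeneAnalysis(gene.gene_id, "ok", len(instruments), top,
                        smr_res, heidi_res, heidi_note, row)


def validate_targets(
    eqtl_by_gene: dict[str, SumstatsSet],
    sbp_gwas: SumstatsSet,
    genes: dict[str, GeneModel],
    ld_by_gene: dict[str, LDMatrix],
    cfg: AnalysisConfig = AnalysisConfig(),
) -> tuple[list[str], pd.DataFrame]:
    """Keep genes whose expression is associated with the validation trait.

    A gene survives when its top-SNP SMR p against the blood-pressure GWAS is
    below ``validation_p`` and the HEIDI test does not flag linkage
    (p >= ``heidi_p``; a gene whose HEIDI could not run is retained with a
    note).  Returns the surviving gene list plus a per-gene audit table.
    """
    survivors: list[str] = []
    audit_rows = []
    for gene_id, gene in genes.items():
        eqtl = eqtl_by_gene.get(gene_id)
        if eqtl is None:
            audit_rows.append({"gene": gene_id, "status": "no_eqtl_data",
                               "p_smr": "NA", "p_heidi": "NA"})
            continue
        res = analyze_gene(eqtl, sbp_gwas, gene, ld_by_gene.get(gene_id), cfg)
        if res.status != "ok":
            audit_rows.append({"gene": gene_id, "status": res.status,
                               "p_smr": "NA", "p_heidi": "NA"})
            continue
        p_smr = res.smr.p_smr
        p_heidi = res.heidi.p_heidi if res.heidi else None
        if p_smr >= cfg.validation_p:
            status = "smr_failed"
        elif p_heidi is not None and p_heidi < cfg.heidi_p:
            status = "heidi_failed"
        else:
            status = "retained" if p_heidi is not None else "retained_heidi_na"
            survivors.append(gene_id)
        audit_rows.append({
            "gene": gene_id, "status": status, "p_smr": p_smr,
            "p_heidi": p_heidi if p_heidi is not None else "NA",
        })
    return survivors, pd.DataFrame(audit_rows, columns=["gene", "status", "p_smr", "p_heidi"])


def pleiotropy_scan(
    focal_gene: str,
    top: Instrument,
    eqtl_by_gene: dict[str, SumstatsSet],
    gwas: SumstatsSet,
    ld: Optional[LDMatrix],
    genes: dict[str, GeneModel],
    window: int = 2_000_000,
    p_assoc: float = 5e-8,
    smr_alpha: float = 0.05,
    priors: ColocPriors = ColocPriors(),
) -> pd.DataFrame:
    """Scan genes near the focal top SNP for alternative expression pathways.

    Every gene within ``window`` of the top SNP whose expression is associated
    with that SNP (eQTL p < ``p_assoc``) is SMR-tested against the outcome;
    for SMR-significant genes (and always for the focal gene) colocalization
    posterior PP4 is reported when regional data allow.
    """
    pos = top.record.variant.pos
    chrom = top.record.variant.chrom
    rows = []
    for gene_id, gene in genes.items():
        if gene.chrom != chrom:
            continue
        if abs(gene.probe_pos - pos) > window:
            continue
        eqtl = eqtl_by_gene.get(gene_id)
        if eqtl is None:
            continue
        rec = eqtl.get(top.rsid)
        is_focal = gene_id == focal_gene
        if rec is None or (rec.p >= p_assoc and not is_focal):
            continue
        gw = gwas.get(top.rsid)
        if gw is None:
            continue
        v = harmonize(rec, gw)
        if not v.kept:
            continue
        b_xy, _ = wald_ratio(rec.beta, rec.se, v.record.beta, v.record.se)
        _, p_smr, se_smr = smr_test(rec.beta, rec.se, v.record.beta, v.record.se)
        pp4 = None
        if (p_smr < smr_alpha or is_focal) and ld is not None and len(eqtl) > 1:
            try:
                res: ColocResult = coloc_abf(eqtl, gwas, priors)
                pp4 = res.pp4
            except ValueError:
                pp4 = None
        rows.append({
            "gene": gene_id,
            "is_focal": is_focal,
            "topSNP": top.rsid,
            "p_eQTL_topSNP": rec.p,
            "b_SMR": b_xy,
            "se_SMR": se_smr,
            "p_SMR": p_smr,
            "PP4": pp4 if pp4 is not None else "NA",
        })
    cols = ["gene", "is_focal", "topSNP", "p_eQTL_topSNP",
            "b_SMR", "se_SMR", "p_SMR", "PP4"]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["is_focal", "p_SMR"], ascending=[False, True]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# top-SNP-table mode
# ---------------------------------------------------------------------------

def run_top_snp_table(rows: list[TableRow]) -> pd.DataFrame:
    """Recompute the MR columns of a pre-extracted per-gene top-SNP table.

    For each row the Wald ratio, SMR p and per-SD-decrease odds ratio are
    recomputed from the (b, se) pairs; region-dependent columns carry the
    published values (the table holds no regional data to recompute them) and
    the relative deviation of the recomputed ratio from the published one is
    reported per row.
    """
    out = []
    for r in rows:
        b_xy, _ = wald_ratio(r.b_eqtl, r.se_eqtl, r.b_gwas, r.se_gwas)
        _, p_smr, se_smr = smr_test(r.b_eqtl, r.se_eqtl, r.b_gwas, r.se_gwas)
        or_dec, ci_lo, ci_hi = to_odds_ratio(b_xy, se_smr, per_sd_decrease=True)
        rel_dev = abs(b_xy - r.b_smr) / abs(r.b_smr) if r.b_smr != 0 else float("nan")
        out.append({
            "outcome": r.outcome,
            "Gene": r.gene,
            "topSNP": r.top_snp,
            "b_SMR": b_xy,
            "se_SMR": se_smr,
            "p_SMR": p_smr,
            "OR_per_sd_decrease": or_dec,
            "OR_ci_low": ci_lo,
            "OR_ci_high": ci_hi,
            "b_SMR_published": r.b_smr,
            "rel_dev_b_SMR": rel_dev,
            "p_SMR_multi": "insufficient region data",
            "p_HEIDI": "insufficient region data",
        })
    return pd.DataFrame(out)


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def run_pipeline(cfg: AnalysisConfig) -> dict:
    """Execute the configured stages and write result tables under ``out_dir``.

    Returns a report dict with the per-stage gene counts (the selection ladder),
    output paths and any stage failures.
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"counts": {}, "outputs": {}, "failures": [], "seed": cfg.seed,
                    "version": __version__}

    if cfg.mode == "top_snp":
        if cfg.top_snp_table == "packaged" or not cfg.top_snp_table:
            rows = fixture_from_tables()
        else:
            raise ValueError("top_snp mode expects top_snp_table='packaged'")
        df = run_top_snp_table(rows)
        for outcome, sub in df.groupby("outcome", sort=False):
            path = out_dir / f"{outcome}_smr.tsv"
            sub.to_csv(path, sep="\t", index=False, float_format="%.6g")
            report["outputs"][outcome] = str(path)
        report["counts"]["rows"] = len(df)
        _write_log(out_dir, cfg, report)
        return report

    # --- full mode -----------------------------------------------------
    for name, path in (("gene_annotation", cfg.gene_annotation),
                       ("eqtl", cfg.eqtl), ("target_map", cfg.target_map)):
        if not path or not Path(path).exists():
            raise FileNotFoundError(f"config {name} path missing or does not exist: {path!r}")
    if cfg.ld_dir and not Path(cfg.ld_dir).is_dir():
        raise FileNotFoundError(f"LD directory does not exist: {cfg.ld_dir!r}")

    targets = read_target_map(cfg.target_map)
    genes_all = read_gene_annotation(cfg.gene_annotation)
    eqtl_by_gene = read_sumstats(cfg.eqtl, dialect="eqtl_flat")
    genes = {g: genes_all[g] for g in targets.genes if g in genes_all}
    report["counts"]["target_genes"] = len(targets.genes)

    ld_by_gene: dict[str, LDMatrix] = {}
    if cfg.ld_dir:
        for gene_id in genes:
            p = Path(cfg.ld_dir) / f"{gene_id}.tsv"
            if p.exists():
                ld_by_gene[gene_id] = read_ld_matrix(p)

    with_instruments = [
        g for g, gene in genes.items()
        if g in eqtl_by_gene and select_instruments(
            eqtl_by_gene[g], gene, cfg.p_eqtl, cfg.maf_min, cfg.f_min, cfg.cis_flank)
    ]
    report["counts"]["with_instruments"] = len(with_instruments)

    # validation against the blood-pressure GWAS
    if cfg.sbp_gwas and Path(cfg.sbp_gwas).exists():
        sbp = read_sumstats(cfg.sbp_gwas, dialect="cojo_ma", trait_id="SBP")
        survivors, audit = validate_targets(eqtl_by_gene, sbp, genes, ld_by_gene, cfg)
        audit_path = out_dir / "validation_audit.tsv"
        audit.to_csv(audit_path, sep="\t", index=False, float_format="%.6g")
        report["outputs"]["validation_audit"] = str(audit_path)
        report["counts"]["sbp_validated"] = len(survivors)
    else:
        survivors = with_instruments
        sbp = None
        logger.warning("no SBP GWAS configured; skipping validation stage")

    # per-outcome SMR / HEIDI / Bonferroni / coloc / pleiotropy
    m_family = max(len(survivors), 1)
    alpha_adj = bonferroni(m_family)
    report["counts"]["bonferroni_m"] = m_family

    for outcome, gwas_path in cfg.outcome_gwas.items():
        if not Path(gwas_path).exists():
            report["failures"].append(f"{outcome}: GWAS file missing ({gwas_path})")
            continue
        gwas = read_sumstats(gwas_path, dialect="cojo_ma", trait_id=outcome,
                             trait_type=TraitType.CASE_CONTROL)
        rows = []
        analyses: dict[str, GeneAnalysis] = {}
        for gene_id in survivors:
            gene = genes[gene_id]
            eqtl = eqtl_by_gene.get(gene_id)
            if eqtl is None:
                continue
            res = analyze_gene(eqtl, gwas, gene, ld_by_gene.get(gene_id), cfg)
            analyses[gene_id] = res
            if res.status == "ok":
                res.row["bonferroni_significant"] = res.smr.p_smr < alpha_adj
                rows.append(res.row)
        table_path = out_dir / f"{outcome}_smr.tsv"
        write_results_table(rows, table_path)
        report["outputs"][outcome] = str(table_path)

        # coloc + pleiotropy scan + locus export for Bonferroni-significant genes
        for gene_id, res in analyses.items():
            if res.status != "ok" or res.smr.p_smr >= alpha_adj:
                continue
            eqtl = eqtl_by_gene[gene_id]
            try:
                cres = coloc_abf(eqtl, gwas)
                (out_dir / f"{outcome}_{gene_id}_coloc.json").write_text(json.dumps({
                    "PP0": cres.pp[0], "PP1": cres.pp[1], "PP2": cres.pp[2],
                    "PP3": cres.pp[3], "PP4": cres.pp[4], "n_snps": cres.n_snps,
                    "supports_shared_variant": cres.pp4 > cfg.coloc_pp4,
                }, indent=1))
            except ValueError as exc:
                report["failures"].append(f"{outcome}/{gene_id} coloc: {exc}")
            scan = pleiotropy_scan(
                gene_id, res.top, eqtl_by_gene, gwas, ld_by_gene.get(gene_id),
                genes_all, window=cfg.pleiotropy_window,
            )
            scan.to_csv(out_dir / f"{outcome}_{gene_id}_pleiotropy.tsv",
                        sep="\t", index=False, float_format="%.6g")
            _export_locus_table(eqtl, gwas, out_dir / f"{outcome}_{gene_id}_locus.tsv")

    # exposure-trait -> outcome multi-instrument MR
    if sbp is not None and cfg.outcome_gwas:
        from .mr_multi import EstimationError, gsmr_estimate, ivw_egger

        first_outcome = next(iter(cfg.outcome_gwas))
        gwas = read_sumstats(cfg.outcome_gwas[first_outcome], dialect="cojo_ma",
                             trait_id=first_outcome, trait_type=TraitType.CASE_CONTROL)
        try:
            g = gsmr_estimate(sbp, gwas, None)
            ivw, egger = ivw_egger(sbp, gwas, None)
            mr_rows = [{"estimator": r.estimator, "b": r.b, "se": r.se, "p": r.p,
                        "n_instruments": r.n_instruments_used}
                       for r in (g, ivw) + ((egger,) if egger else ())]
            pd.DataFrame(mr_rows).to_csv(out_dir / "exposure_outcome_mr.tsv",
                                         sep="\t", index=False, float_format="%.6g")
            report["outputs"]["exposure_outcome_mr"] = str(out_dir / "exposure_outcome_mr.tsv")
        except EstimationError as exc:
            report["failures"].append(f"exposure->outcome MR: {exc}")

    _write_log(out_dir, cfg, report)
    return report


def _export_locus_table(eqtl: SumstatsSet, gwas: SumstatsSet, path) -> None:
    """Per-SNP p-values behind a locus plot: GWAS p, eQTL p and SMR p."""
    rows = []
    for rsid, e in eqtl.records.items():
        g = gwas.get(rsid)
        if g is None:
            continue
        _, p_smr, _ = smr_test(e.beta, e.se, g.beta, g.se)
        rows.append({"SNP": rsid, "bp": e.variant.pos,
                     "p_GWAS": g.p, "p_eQTL": e.p, "p_SMR": p_smr})
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.6g")


def _write_log(out_dir: Path, cfg: AnalysisConfig, report: dict) -> None:
    log = {
        "version": __version__,
        "seed": cfg.seed,
        "mode": cfg.mode,
        "thresholds": {
            "cis_flank": cfg.cis_flank, "p_eqtl": cfg.p_eqtl,
            "maf_min": cfg.maf_min, "f_min": cfg.f_min,
            "validation_p": cfg.validation_p, "heidi_p": cfg.heidi_p,
            "multi_r2": cfg.multi_r2, "coloc_pp4": cfg.coloc_pp4,
            "pleiotropy_window": cfg.pleiotropy_window,
        },
        "counts": report["counts"],
        "failures": report["failures"],
    }
    (out_dir / "run_log.json").write_text(json.dumps(log, indent=1))
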