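import numpy as np
import pytest
from scipy import stats

from drugtarget_mr.sumstats import AssocRecord, SumstatsSet, TraitType, VariantKey


def make_record(
    rsid="rs1",
    chrom="1",
    pos=1000,
    ea="T",
    oa="C",
    eaf=0.3,
    beta=0.1,
    se=0.02,
    p=None,
    n=None,
):
    """AssocRecord with p defaulting to the Wald p of beta/se."""
    if p is None:
        p = float(max(2 * stats.norm.sf(abs(beta / se)), 1e-300))
    return AssocRecord(
        variant=VariantKey(rsid, chrom, pos),
        effect_allele=ea,
        other_allele=oa,
        eaf=eaf,
        beta=beta,
        se=se,
        p=p,
        n=n,
    )


def make_sumstats(records, trait_id="trait", trait_type=TraitType.QUANTITATIVE, sdY=None):
    ss = SumstatsSet(trait_id, trait_type, sdY)
    for rec in records:
        ss.add(rec)
    return ss


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def heidi_p_for_bundle(bundle):
    """Lean instrument -> top SNP -> HEIDI path (skips multi-SNP SMR)."""
    from drugtarget_mr.heidi import heidi_test, select_heidi_snps
    from drugtarget_mr.instruments import select_instruments, top_snp

    ins = select_instruments(bundle.eqtl, bundle.gene)
    if not ins:
        return None
    top = top_snp(ins)
    gw_top = bundle.gwas.get(top.rsid)
    snps = select_heidi_snps(bundle.eqtl, top, bundle.ld)
    if not snps:
        return None
    o_eqtl = [bundle.eqtl.get(r) for r in snps]
    o_gwas = [bundle.gwas.get(r) for r in snps]
    return heidi_test(top.record, gw_top, o_eqtl, o_gwas, bundle.ld).p_heidi
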