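"""Wald ratio, SMR chi-square test, multi-SNP SMR and the odds-ratio transform."""

import math

import numpy as np
import pytest
from scipy import stats

from drugtarget_mr.instruments import Instrument
from drugtarget_mr.smr import (
    prune_by_ld,
    smr_multi,
    smr_test,
    to_odds_ratio,
    wald_ratio,
)
from drugtarget_mr.sumstats import LDMatrix
from drugtarget_mr.synthetic import Scenario, simulate_pair
from drugtarget_mr.instruments import select_instruments, top_snp

from conftest import make_record, make_sumstats


class TestWaldRatio:
    def test_headline_gene_table_row(self):
        # eQTL beta -0.186, outcome log-odds 0.028 -> printed -0.150
        b_xy, se = wald_ratio(-0.186, 0.009, 0.028, 0.007)
        assert b_xy == pytest.approx(-0.1505, abs=1e-4)
        assert se > 0

    def test_er_positive_pde1b_row(self):
        b_xy, _ = wald_ratio(0.429, 0.009, 0.030, 0.008)
        assert b_xy == pytest.approx(0.0699, abs=1e-4)

    def test_zero_numerator(self):
        b_xy, se = wald_ratio(0.2, 0.02, 0.0, 0.01)
        assert b_xy == 0.0 and se == pytest.approx(0.05)

    def test_zero_exposure_effect_raises(self):
        with pytest.raises(ZeroDivisionError):
            wald_ratio(0.0, 0.02, 0.1, 0.01)

    def test_delta_se_formula(self):
        b_xy, se = wald_ratio(0.5, 0.05, 0.2, 0.04)
        expected = math.sqrt(0.04**2 / 0.25 + 0.04 * 0.05**2 / 0.0625)
        assert se == pytest.approx(expected, rel=1e-12)


class TestSMRTest:
    def test_against_chi_square_oracle(self):
        # z_gx = 20.667, z_gy = 4.0: T = (z_gx^2 z_gy^2)/(z_gx^2+z_gy^2)
        b_gx, se_gx = 20.667 * 0.009, 0.009
        b_gy, se_gy = 4.0 * 0.007, 0.007
        t, p, _ = smr_test(b_gx, se_gx, b_gy, se_gy)
        t_expected = (20.667**2 * 16.0) / (20.667**2 + 16.0)
        assert t == pytest.approx(t_expected, rel=1e-9)
        assert t == pytest.approx(15.42, abs=0.01)
        assert p == pytest.approx(stats.chi2.sf(t_expected, 1), rel=1e-12)
        assert p == pytest.approx(8.6e-5, rel=0.02)

    def test_null_outcome_gives_p_one(self):
        t, p, se = smr_test(0.2, 0.02, 0.0, 0.01)
        assert t == 0.0 and p == 1.0

    def test_infinite_instrument_limit_recovers_gwas_p(self):
        # as z_gx -> inf, T -> z_gy^2 so p -> the GWAS Wald p
        t, p, _ = smr_test(1e6, 1e-3, 0.03, 0.01)
        assert t == pytest.approx(9.0, rel=1e-4)
        assert p == pytest.approx(2 * stats.norm.sf(3.0), rel=1e-3)

    def test_p_invariant_to_simultaneous_sign_flip(self, rng):
        for _ in range(25):
            b_gx, b_gy = rng.normal(size=2) * 0.3
            if abs(b_gx) < 1e-3:
                continue
            se_gx, se_gy = rng.uniform(0.005, 0.05, 2)
            _, p1, _ = smr_test(b_gx, se_gx, b_gy, se_gy)
            _, p2, _ = smr_test(-b_gx, se_gx, -b_gy, se_gy)
            assert p1 == pytest.approx(p2, rel=1e-12)

    def test_p_equals_normal_p_of_ratio_over_smr_se(self, rng):
        for _ in range(25):
            b_gx = rng.uniform(0.1, 0.5) * rng.choice([-1, 1])
            b_gy = rng.uniform(0.005, 0.1) * rng.choice([-1, 1])
            se_gx, se_gy = rng.uniform(0.005, 0.05, 2)
            _, p, se_xy = smr_test(b_gx, se_gx, b_gy, se_gy)
            b_xy, _ = wald_ratio(b_gx, se_gx, b_gy, se_gy)
            p_norm = 2 * stats.norm.sf(abs(b_xy) / se_xy)
            assert p == pytest.approx(p_norm, rel=1e-9)

    def test_smr_se_agrees_with_delta_se_for_strong_signals(self, rng):
        """The two SE constructions agree within 15% when both |z| > 5."""
        for _ in range(200):
            z_gx = rng.uniform(5.5, 60) * rng.choice([-1, 1])
            z_gy = rng.uniform(5.5, 60) * rng.choice([-1, 1])
            se_gx, se_gy = rng.uniform(0.005, 0.05, 2)
            b_gx, b_gy = z_gx * se_gx, z_gy * se_gy
            _, _, se_smr = smr_test(b_gx, se_gx, b_gy, se_gy)
            _, se_delta = wald_ratio(b_gx, se_gx, b_gy, se_gy)
            assert se_smr == pytest.approx(se_delta, rel=0.15)


def _ld_identity(rsids):
    return LDMatrix(rsids, np.eye(len(rsids)))


def _instrument(rsid, beta, se, pos=5_000_000):
    rec = make_record(rsid, chrom="1", pos=pos, beta=beta, se=se)
    return Instrument("G1", rec, (beta / se) ** 2)


class TestSMRMulti:
    def test_single_snp_reduces_to_smr(self):
        ins = _instrument("rs1", 0.3, 0.02)
        gwas = make_sumstats([make_record("rs1", beta=0.02, se=0.007)])
        p_multi = smr_multi([ins], gwas, _ld_identity(["rs1"]))
        _, p_single, _ = smr_test(0.3, 0.02, 0.02, 0.007)
        assert p_multi == pytest.approx(p_single, rel=1e-9)

    def test_two_independent_equal_snps_chi2_2_oracle(self):
        ins = [_instrument("rs1", 0.3, 0.02), _instrument("rs2", 0.3, 0.02, pos=5_500_000)]
        gwas = make_sumstats([
            make_record("rs1", beta=0.02, se=0.007),
            make_record("rs2", beta=0.02, se=0.007),
        ])
        t1, _, _ = smr_test(0.3, 0.02, 0.02, 0.007)
        p_multi = smr_multi(ins, gwas, _ld_identity(["rs1", "rs2"]))
        assert p_multi == pytest.approx(stats.chi2.sf(2 * t1, 2), rel=1e-4)

    def test_no_harmonizable_snp_returns_none(self):
        ins = _instrument("rs1", 0.3, 0.02)
        gwas = make_sumstats([make_record("rs9", beta=0.02, se=0.007)])
        assert smr_multi([ins], gwas, _ld_identity(["rs1"])) is None

    def test_pruning_keeps_low_ld_subset(self):
        r = np.array([[1.0, 0.95, 0.1], [0.95, 1.0, 0.1], [0.1, 0.1, 1.0]])
        ld = LDMatrix(["rs1", "rs2", "rs3"], r)
        ins = [
            _instrument("rs1", 0.40, 0.02),   # smallest p, seeds the pruning
            _instrument("rs2", 0.35, 0.02),   # r2 = 0.9 with rs1 -> pruned
            _instrument("rs3", 0.30, 0.02),
        ]
        kept = prune_by_ld(ins, ld, r2_max=0.1)
        assert [k.rsid for k in kept] == ["rs1", "rs3"]

    def test_multi_gains_power_under_shared_causal(self):
        """Aggregating cis SNPs sharpens the top-SNP signal for instruments of
        moderate strength (eQTL z around 15, mid-range for top cis-eQTLs); with
        an overwhelmingly strong top instrument the extra SNPs only dilute."""
        wins = ties_or_wins = 0
        n_rep = 200
        for i in range(n_rep):
            sc = Scenario(kind="shared_causal", causal_gwas_idx="same",
                          b_xy_true=0.15, n_eqtl=30_000, n_gwas=200_000,
                          b_causal_expr=0.15, seed=60_000 + i)
            bundle = simulate_pair(sc)
            ins = select_instruments(bundle.eqtl, bundle.gene)
            if not ins:
                continue
            top = top_snp(ins)
            g = bundle.gwas.get(top.rsid)
            _, p_top, _ = smr_test(top.record.beta, top.record.se, g.beta, g.se)
            p_multi = smr_multi(ins, bundle.gwas, bundle.ld)
            if p_multi is None:
                continue
            ties_or_wins += 1
            wins += p_multi <= p_top
        assert ties_or_wins > 150
        assert wins / ties_or_wins >= 0.60


class TestOddsRatio:
    def test_headline_or(self):
        odds, lo, hi = to_odds_ratio(-0.1505, 0.0383, per_sd_decrease=True)
        assert round(odds, 2) == 1.16
        assert lo < odds < hi

    def test_er_positive_pde1b_or_and_ci(self):
        odds, lo, hi = to_odds_ratio(0.0699, 0.019, per_sd_decrease=True)
        assert round(odds, 2) == 0.93
        assert round(lo, 2) == 0.90
        assert round(hi, 2) == 0.97

    def test_null_effect(self):
        odds, lo, hi = to_odds_ratio(0.0, 0.05)
        assert odds == 1.0 and lo < 1.0 < hi

    def test_direction_convention(self):
        inc, _, _ = to_odds_ratio(0.2, 0.05, per_sd_decrease=False)
        dec, _, _ = to_odds_ratio(0.2, 0.05, per_sd_decrease=True)
        assert inc == pytest.approx(1 / dec, rel=1e-12)
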