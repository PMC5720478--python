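import math

import numpy as np
import pytest
from hypothesis import assume, given, settings
from hypothesis import strategies as st

from hlaloh.cn_model import (
    BafSite,
    LogRBin,
    PurityPloidy,
    Verdict,
    allele_specific_cn,
    classify_loh,
    compute_baf,
    compute_logr_bins,
    estimate_gene_cn,
    fisher_exact_2x2,
    normalized_allelic_ratio,
    test_allelic_imbalance as imbalance_test,
)
from hlaloh.hla_alleles import MismatchSite
from hlaloh.realignment import CoverageTrack, UniqueSiteCoverage
from oracles import forward_mixture


def _track(depth, allele="h1", sample="t"):
    return CoverageTrack(allele, sample, np.asarray(depth), int(np.sum(depth) // 100 + 1))


def _site(pos=10):
    return MismatchSite("A", pos, pos, "A", "C")


def _baf_site(t1, t2, n1=40, n2=40, pos=10):
    return BafSite(_site(pos), t1, t2, n1, n2, t1, t2, n1, n2)


class TestComputeLogrBins:
    def test_balanced_ratio_gives_zero_logr(self):
        t = (_track([25] * 150), _track([25] * 150))
        g = (_track([50] * 150), _track([50] * 150))
        (b,) = compute_logr_bins(t, g, m_factor=2.0, gene="A")
        assert b.logr == pytest.approx(0.0)
        assert (b.start, b.end) == (1, 150)

    def test_halved_tumor_gives_minus_one(self):
        t = (_track([25] * 150), _track([0] * 150))
        g = (_track([50] * 150), _track([50] * 150))
        (b,) = compute_logr_bins(t, g, m_factor=2.0)
        assert b.logr == pytest.approx(-1.0)

    def test_low_germline_bin_excluded(self):
        t = (_track([10] * 300), _track([10] * 300))
        g = (_track([20] * 150 + [2] * 150), _track([20] * 150 + [2] * 150))
        bins = compute_logr_bins(t, g, m_factor=1.0)
        assert len(bins) == 1 and bins[0].start == 1

    def test_zero_length_gene_rejected(self):
        empty = (_track([]), _track([]))
        with pytest.raises(ValueError):
            compute_logr_bins(empty, empty, m_factor=1.0)


class TestComputeBaf:
    def test_fractions(self):
        sites = [_site(1), _site(2), _site(3)]
        mk = lambda d: UniqueSiteCoverage("h", "t", sites, np.asarray(d))
        out = compute_baf((mk([30, 10, 0]), mk([10, 10, 25])),
                          (mk([20, 20, 20]), mk([20, 20, 20])))
        assert [s.baf for s in out] == [0.75, 0.5, 0.0]

    def test_zero_combined_depth_omitted(self):
        sites = [_site(1)]
        mk = lambda d: UniqueSiteCoverage("h", "t", sites, np.asarray(d))
        assert compute_baf((mk([0]), mk([0])), (mk([5]), mk([5]))) == []


class TestAlleleSpecificCn:
    def test_pure_diploid_balanced(self):
        assert allele_specific_cn(0.5, 0.0, PurityPloidy(1.0, 2.0)) == \
            pytest.approx((1.0, 1.0))

    @pytest.mark.parametrize("state", [(0, 2), (1, 2)])
    def test_forward_mixture_inverts(self, state):
        """The forward mixture for a known tumor state must invert exactly."""
        pp = PurityPloidy(0.5, 2.0)
        baf, logr = forward_mixture(pp.rho, pp.psi, *state)
        cn = allele_specific_cn(baf, logr, pp)
        assert cn == pytest.approx(state, abs=1e-12)

    def test_half_purity_quarter_baf(self):
        cn = allele_specific_cn(0.25, 0.0, PurityPloidy(0.5, 2.0))
        assert cn == pytest.approx((0.0, 2.0))

    @settings(max_examples=120, deadline=None, derandomize=True)
    @given(n1=st.integers(0, 3), n2=st.integers(0, 3),
           rho=st.floats(0.2, 1.0), psi=st.floats(1.5, 3.0))
    def test_inversion_property(self, n1, n2, rho, psi):
        assume(2 * (1 - rho) + rho * (n1 + n2) > 0)  # sample contains DNA
        baf, logr = forward_mixture(rho, psi, n1, n2)
        cn1, cn2 = allele_specific_cn(baf, logr, PurityPloidy(rho, psi))
        assert cn1 == pytest.approx(n1, abs=1e-9)
        assert cn2 == pytest.approx(n2, abs=1e-9)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(baf=st.floats(0.0, 1.0), logr=st.floats(-2.0, 2.0),
           rho=st.floats(0.1, 1.0), psi=st.floats(1.0, 4.0))
    def test_sum_rule_independent_of_baf(self, baf, logr, rho, psi):
        """cn1 + cn2 equals the total-CN closed form for any BAF."""
        pp = PurityPloidy(rho, psi)
        cn1, cn2 = allele_specific_cn(baf, logr, pp)
        total = (2 * (rho - 1) + 2.0**logr * (2 * (1 - rho) + rho * psi)) / rho
        assert cn1 + cn2 == pytest.approx(total, abs=1e-9)

    def test_exchange_symmetry(self):
        pp = PurityPloidy(0.7, 2.2)
        cn = allele_specific_cn(0.3, 0.4, pp)
        swapped = allele_specific_cn(0.7, 0.4, pp)
        assert cn == pytest.approx(swapped[::-1])

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            PurityPloidy(0.0, 2.0)
        with pytest.raises(ValueError):
            allele_specific_cn(1.2, 0.0, PurityPloidy(0.5, 2.0))


class TestEstimateGeneCn:
    def test_uniform_sites_give_unit_copies(self):
        bins = [LogRBin("A", 1, 150, 100, 100, 1.0, 0.0)]
        sites = [_baf_site(20, 20, pos=p) for p in (10, 30, 50, 70, 90)]
        est = estimate_gene_cn(sites, bins, PurityPloidy(1.0, 2.0))
        assert (est.cn1, est.cn2) == pytest.approx((1.0, 1.0))
        assert est.n_sites == 5 and est.n_bins == 1

    def test_gene_value_is_median_of_bin_medians(self):
        pp = PurityPloidy(1.0, 2.0)
        bins, sites = [], []
        # three bins engineered to per-bin median cn1 of 0.1, 0.2, 0.9
        for i, cn1 in enumerate((0.1, 0.2, 0.9)):
            bins.append(LogRBin("A", 150 * i + 1, 150 * (i + 1), 1, 1, 1.0, 0.0))
            baf = cn1 / 2
            t1 = int(round(baf * 1000))
            for j in range(3):
                sites.append(_baf_site(t1, 1000 - t1, pos=150 * i + 10 + j))
        est = estimate_gene_cn(sites, bins, pp)
        assert est.cn1 == pytest.approx(0.2, abs=1e-2)

    def test_too_few_covered_sites_indeterminate(self):
        bins = [LogRBin("A", 1, 150, 100, 100, 1.0, 0.0)]
        sites = [_baf_site(20, 20, pos=200)]  # outside the covered bin
        assert estimate_gene_cn(sites, bins, PurityPloidy(1.0, 2.0)) is None


class TestAllelicImbalance:
    def test_identical_profiles_p_one(self):
        sites = [_baf_site(30, 30, pos=p) for p in range(10, 70, 10)]
        assert imbalance_test(sites) == 1.0

    def test_constant_nonzero_shift_sentinel(self):
        sites = [_baf_site(40, 20, 30, 30, pos=p) for p in range(10, 70, 10)]
        with pytest.warns(UserWarning, match="degenerate"):
            assert imbalance_test(sites) == 1e-16

    def test_too_few_sites_indeterminate(self):
        sites = [_baf_site(40, 20, pos=p) for p in (10, 20)]
        assert imbalance_test(sites) is None

    def test_shifted_profile_rejects(self, rng):
        sites = []
        for p in range(10, 210, 10):
            t1 = int(rng.poisson(60))
            t2 = int(rng.poisson(20))
            sites.append(_baf_site(max(t1, 1), max(t2, 1), 40, 40, pos=p))
        assert imbalance_test(sites) < 1e-4


class TestClassifyLoh:
    def test_loss_calls_argmin_allele(self):
        est = _est(0.1, 1.8)
        assert classify_loh(est, 1e-6) == Verdict.LOH_ALLELE1

    def test_imbalance_without_loss(self):
        assert classify_loh(_est(0.7, 1.5), 0.001) == Verdict.IMBALANCE

    def test_p_value_gate_blocks_loss(self):
        assert classify_loh(_est(0.4, 1.6), 0.05) == Verdict.BALANCED

    def test_indeterminate_propagates(self):
        assert classify_loh(None, 0.5) == Verdict.INDETERMINATE
        assert classify_loh(_est(0.4, 1.6), None) == Verdict.INDETERMINATE


def _est(cn1, cn2):
    from hlaloh.cn_model import AlleleCnEstimate
    return AlleleCnEstimate("A", cn1, cn2, {0: cn1}, {0: cn2}, 10, 1)


class TestNormalizedAllelicRatio:
    @pytest.mark.parametrize("areas,expected", [
        ((200, 100, 100, 100), 2.0),
        ((100, 100, 100, 100), 1.0),
        ((50, 100, 100, 100), 0.5),
    ])
    def test_ratio(self, areas, expected):
        assert normalized_allelic_ratio(*areas) == pytest.approx(expected)

    def test_zero_area_rejected(self):
        with pytest.raises(ValueError):
            normalized_allelic_ratio(1, 0, 1, 1)


class TestFisherExact:
    def test_balanced_table_p_one(self):
        _, p = fisher_exact_2x2([[10, 10], [10, 10]])
        assert p == pytest.approx(1.0)

    def test_strong_association_small_p(self):
        odds, p = fisher_exact_2x2([[20, 1], [1, 20]])
        assert p < 1e-6 and odds > 1

    def test_shape_validated(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, 2, 3], [4, 5, 6]])
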