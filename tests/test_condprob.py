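"""The conditional QTL-genotype laws against independent gamete-enumeration
oracles, plus the coefficient algebra built on them."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import enumerate_conditional
from silkqtl.condprob import (
    ACHIASMATE_IMPOSSIBLE,
    AchiasmateImpossibleError,
    CoeffPair,
    CondProb,
    FlankingContext,
    MissingGenotypeError,
    coefficient_table,
    coefficients,
    cond_prob_achiasmate,
    cond_prob_chiasmate,
    conditional_table,
    epistasis_coefficients,
    genotype_posteriors,
    split_recomb,
    two_point_probs,
    expected_marker_coeffs,
)
from silkqtl.genmap import haldane_to_recomb
from silkqtl.simulate import silkworm_scenario, simulate_f2

R_GRID = [(0.01, 0.04), (0.0476, 0.0476), (0.02, 0.09), (0.09, 0.02),
          (0.08, 0.095), (0.15, 0.2), (0.3, 0.1)]


def _ctx(gl, gr, r1, r2):
    return FlankingContext(left=gl, right=gr, r1=r1, r2=r2)


class TestConditionalLaws:
    @pytest.mark.parametrize("design", ["achiasmate", "chiasmate"])
    @pytest.mark.parametrize("r1,r2", R_GRID)
    def test_matches_gamete_enumeration(self, design, r1, r2):
        oracle = enumerate_conditional(design, r1, r2)
        fn = cond_prob_achiasmate if design == "achiasmate" \
            else cond_prob_chiasmate
        for (gl, gr), expected in oracle.items():
            got = fn(_ctx(gl, gr, r1, r2)).as_array()
            np.testing.assert_allclose(got, expected, atol=1e-10)

    @pytest.mark.parametrize("design", ["achiasmate", "chiasmate"])
    def test_oracle_covers_all_feasible_classes(self, design):
        oracle = enumerate_conditional(design, 0.05, 0.05)
        expected_classes = 7 if design == "achiasmate" else 9
        assert len(oracle) == expected_classes

    @given(r=st.floats(min_value=0.02, max_value=0.45),
           frac=st.floats(min_value=0.01, max_value=0.99))
    @settings(deadline=None, max_examples=60)
    def test_rows_normalize(self, r, frac):
        r1 = r * frac
        r2 = float(split_recomb(r, r1))
        for design in ("achiasmate", "chiasmate"):
            table = conditional_table(design, r1, r2)
            sums = np.nansum(table, axis=2)
            feasible = ~np.isnan(table[..., 0])
            np.testing.assert_allclose(sums[feasible], 1.0, atol=1e-9)

    def test_achiasmate_impossible_classes_raise(self):
        for gl, gr in ACHIASMATE_IMPOSSIBLE:
            with pytest.raises(AchiasmateImpossibleError):
                cond_prob_achiasmate(_ctx(gl, gr, 0.04, 0.05))
        # the same classes are fine under the chiasmate law
        for gl, gr in ACHIASMATE_IMPOSSIBLE:
            cond_prob_chiasmate(_ctx(gl, gr, 0.04, 0.05))

    def test_missing_genotype_distinct_error(self):
        with pytest.raises(MissingGenotypeError):
            cond_prob_achiasmate(_ctx(-1, 2, 0.04, 0.05))

    def test_coincident_locus_point_mass(self):
        for fn in (cond_prob_achiasmate, cond_prob_chiasmate):
            cp = fn(_ctx(2, 2, 0.0, 0.09))
            np.testing.assert_allclose(cp.as_array(), [1, 0, 0], atol=1e-9)

    def test_degenerate_limit_designs_agree(self):
        # as both sub-intervals shrink, the laws converge to point masses
        for gl, gr in [(2, 2), (1, 1), (0, 1), (2, 1)]:
            a = cond_prob_achiasmate(_ctx(gl, gr, 1e-8, 1e-8)).as_array()
            c = cond_prob_chiasmate(_ctx(gl, gr, 1e-8, 1e-8)).as_array()
            np.testing.assert_allclose(a, c, atol=1e-6)

    def test_no_interference_consistency(self):
        ctx = _ctx(2, 2, 0.03, 0.06)
        assert ctx.r == pytest.approx(0.03 * 0.94 + 0.06 * 0.97, abs=1e-12)
        # Haldane distances compose to the same r
        r_direct = haldane_to_recomb(10.0)
        r1 = haldane_to_recomb(4.0)
        r2 = haldane_to_recomb(6.0)
        assert float(split_recomb(r_direct, r1)) == pytest.approx(r2, abs=1e-12)


class TestCoefficients:
    @pytest.mark.parametrize("r1,r2", R_GRID)
    def test_closed_form_identities_achiasmate(self, r1, r2):
        """The expected-coefficient algebra reproduces the achiasmate
        law's closed forms (x_A = s1 s2 / s for the double-dominant class,
        x_D = (r1 r2 - s1 s2) / 2s, and so on)."""
        s1, s2 = 1 - r1, 1 - r2
        r = r1 * s2 + r2 * s1
        s = 1 - r
        cp = cond_prob_achiasmate(_ctx(2, 2, r1, r2))
        pair = coefficients(cp)
        assert pair.xA == pytest.approx(s1 * s2 / s, abs=1e-12)
        assert pair.xD == pytest.approx((r1 * r2 - s1 * s2) / (2 * s), abs=1e-12)
        pair = coefficients(cond_prob_achiasmate(_ctx(1, 1, r1, r2)))
        assert pair.xA == pytest.approx(0.0, abs=1e-12)
        assert pair.xD == pytest.approx((s1 * s2 - r1 * r2) / (2 * s), abs=1e-12)
        pair = coefficients(cond_prob_achiasmate(_ctx(1, 0, r1, r2)))
        assert pair.xA == pytest.approx(-r1 * s2 / r, abs=1e-12)
        assert pair.xD == pytest.approx((s1 * r2 - r1 * s2) / (2 * r), abs=1e-12)

    def test_trivial_examples(self):
        assert coefficients(CondProb(0.25, 0.5, 0.25)) == CoeffPair(0.0, 0.0)
        assert coefficients(CondProb(1.0, 0.0, 0.0)) == CoeffPair(1.0, -0.5)

    def test_epistasis_products(self):
        e = epistasis_coefficients(CoeffPair(1, -0.5), CoeffPair(1, -0.5))
        assert (e.xAA, e.xAD, e.xDA, e.xDD) == (1, -0.5, -0.5, 0.25)
        e = epistasis_coefficients(CoeffPair(0, 0.5), CoeffPair(1, -0.5))
        assert (e.xAA, e.xAD, e.xDA, e.xDD) == (0, 0, 0.5, -0.25)

    @given(r=st.floats(min_value=0.02, max_value=0.45),
           frac1=st.floats(min_value=0.01, max_value=0.99),
           frac2=st.floats(min_value=0.01, max_value=0.99))
    @settings(deadline=None, max_examples=60)
    def test_coefficient_bounds(self, r, frac1, frac2):
        """x_A in [-1, 1], x_D in [-0.5, 0.5], and the product bounds on
        the epistatic coefficients, over random geometries and classes."""
        pairs = []
        for frac in (frac1, frac2):
            r1 = r * frac
            r2 = float(split_recomb(r, r1))
            for design in ("achiasmate", "chiasmate"):
                XA, XD = coefficient_table(design, r1, r2)
                ok = ~np.isnan(XA)
                assert np.all(np.abs(XA[ok]) <= 1 + 1e-12)
                assert np.all(np.abs(XD[ok]) <= 0.5 + 1e-12)
                gl, gr = np.argwhere(ok)[0]
                pairs.append(CoeffPair(XA[gl, gr], XD[gl, gr]))
        e = epistasis_coefficients(pairs[0], pairs[-1])
        assert abs(e.xAA) <= 1 + 1e-12
        assert abs(e.xAD) <= 0.5 + 1e-12
        assert abs(e.xDA) <= 0.5 + 1e-12
        assert abs(e.xDD) <= 0.25 + 1e-12


class TestMissingDataExpectation:
    def test_observed_codes_pass_through(self, silkworm_pop):
        zA, zD = expected_marker_coeffs(silkworm_pop, "M1_5")
        g = silkworm_pop.geno[:, 4]
        np.testing.assert_array_equal(zA, g - 1.0)
        np.testing.assert_array_equal(zD, np.where(g == 1, 0.5, -0.5))

    @pytest.mark.parametrize("design", ["achiasmate", "chiasmate"])
    def test_flanking_plugin_equality(self, design):
        """A missing marker flanked by observed markers 10 cM each side
        gets exactly the flanking-conditional expectation."""
        positions = np.array([0.0, 10.0, 20.0])
        r = haldane_to_recomb(10.0)
        fn = cond_prob_achiasmate if design == "achiasmate" \
            else cond_prob_chiasmate
        for gl, gr in [(2, 2), (1, 1), (2, 1), (0, 0)]:
            post = genotype_posteriors(positions, [gl, -1, gr], design)[1]
            cp = fn(_ctx(gl, gr, r, r))
            np.testing.assert_allclose(post, [cp.pqq, cp.pQq, cp.pQQ],
                                       atol=1e-10)

    def test_one_sided_conditioning_matches_two_point(self):
        positions = np.array([0.0, 10.0])
        r = haldane_to_recomb(10.0)
        for design in ("achiasmate", "chiasmate"):
            for g in (2, 1, 0):
                post = genotype_posteriors(positions, [g, -1], design)[1]
                np.testing.assert_allclose(post, two_point_probs(design, g, r),
                                           atol=1e-10)

    def test_fully_missing_chromosome_marginal(self, silkworm_pop):
        pop = simulate_f2(silkworm_scenario(n=6), seed=3)
        pop.geno[0, :11] = -1  # wipe chromosome 1 for one individual
        with pytest.warns(UserWarning, match="fully missing"):
            zA, zD = expected_marker_coeffs(pop, "M1_3")
        assert zA[0] == pytest.approx(0.0)
        assert zD[0] == pytest.approx(0.0)

    def test_multipoint_uses_nearest_informative_markers(self):
        """With the direct flank missing, conditioning falls back to the
        next markers out: a run of three missing loci between observed
        double-dominant flanks gets a symmetric, high-P(QQ) posterior."""
        positions = np.arange(0.0, 50.0, 10.0)
        post = genotype_posteriors(positions, [2, -1, -1, -1, 2],
                                   "achiasmate")
        assert post[2, 2] > 0.8
        np.testing.assert_allclose(post[1], post[3], atol=1e-12)
        np.testing.assert_allclose(post.sum(axis=1), 1.0, atol=1e-12)
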