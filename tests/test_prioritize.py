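"""MR-IVW, colocalization, LD overlap, evidence scoring, direction rules."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from locus2gene import prioritize as P
from locus2gene.eqtl import InstrumentSet
from locus2gene.syndata import simulate_genotypes, uniform_layout


def _instruments(beta_x, se_x=None):
    k = len(beta_x)
    return InstrumentSet(
        gene_id="g",
        table=pd.DataFrame(
            {
                "variant_id": [f"v{j}" for j in range(k)],
                "beta": beta_x,
                "se": se_x if se_x is not None else [1e-8] * k,
                "p_value": [1e-10] * k,
                "step": range(1, k + 1),
            }
        ),
    )


def _gwas(beta_y, se_y):
    k = len(beta_y)
    return pd.DataFrame(
        {
            "variant_id": [f"v{j}" for j in range(k)],
            "effect_allele": "G",
            "other_allele": "A",
            "beta": beta_y,
            "se": se_y,
        }
    )


class TestHarmonize:
    def test_matching_alleles_identity(self):
        beta, status = P.harmonize("G", "A", "G", "A", 0.2)
        assert beta == 0.2 and status == "ok"

    def test_swapped_alleles_flip_sign(self):
        beta, status = P.harmonize("G", "A", "A", "G", 0.2)
        assert beta == -0.2 and status == "ok"

    def test_palindromic_flagged(self):
        _, status = P.harmonize("A", "T", "A", "T", 0.2)
        assert status == "palindromic"
        _, status = P.harmonize("C", "G", "G", "C", 0.2)
        assert status == "palindromic"

    def test_incompatible_sets_rejected(self):
        with pytest.raises(ValueError, match="incompatible"):
            P.harmonize("G", "A", "C", "T", 0.2)


class TestMrIvw:
    def test_homogeneous_ratios_give_exact_estimate_and_zero_q(self):
        res = P.mr_ivw(_instruments([1.0, 0.5, 0.25]), _gwas([0.5, 0.25, 0.125],
                                                             [0.1, 0.1, 0.1]))
        assert res.estimate == pytest.approx(0.5, abs=1e-12)
        assert res.cochran_q == pytest.approx(0.0, abs=1e-12)

    def test_matches_weighted_ls_through_origin_oracle(self):
        beta_x = np.array([1.0, 0.5, 0.25])
        beta_y = np.array([0.3, 0.2, 0.05])
        se_y = np.array([0.1, 0.1, 0.1])
        res = P.mr_ivw(_instruments(beta_x), _gwas(beta_y, se_y))
        w = se_y**-2
        theta_wls = (w * beta_x * beta_y).sum() / (w * beta_x**2).sum()
        assert res.estimate == pytest.approx(theta_wls, abs=1e-8)
        se_wls = ((w * beta_x**2).sum()) ** -0.5
        assert res.se == pytest.approx(se_wls, abs=1e-8)

    def test_scale_equivariance(self):
        beta_x = [1.0, 0.5, 0.25]
        a = P.mr_ivw(_instruments(beta_x), _gwas([0.3, 0.2, 0.05], [0.1] * 3))
        b = P.mr_ivw(_instruments(beta_x), _gwas([0.6, 0.4, 0.10], [0.2] * 3))
        assert b.estimate == pytest.approx(2 * a.estimate, rel=1e-10)

    def test_null_outcome_gives_zero_estimate_p_one(self):
        res = P.mr_ivw(_instruments([1.0, 0.5, 0.25]), _gwas([0.0, 0.0, 0.0],
                                                             [0.1] * 3))
        assert res.estimate == 0.0
        assert res.p_value == pytest.approx(1.0)

    def test_zero_exposure_instrument_dropped_below_minimum_not_testable(self):
        res = P.mr_ivw(_instruments([1.0, 0.5, 0.0]), _gwas([0.3, 0.2, 0.1],
                                                            [0.1] * 3))
        assert res is None

    def test_weighted_median_bootstrap_reproducible(self):
        args = (_instruments([1.0, 0.5, 0.25, 0.7]),
                _gwas([0.3, 0.2, 0.05, 0.25], [0.1] * 4))
        a = P.mr_ivw(*args, seed=42)
        b = P.mr_ivw(*args, seed=42)
        assert a.weighted_median_se == b.weighted_median_se


class TestColoc:
    def _slices(self, z_gwas, z_eqtl, se=0.05):
        n = len(z_gwas)
        ids = [f"v{j}" for j in range(n)]
        gw = pd.DataFrame({"variant_id": ids, "beta": np.array(z_gwas) * se, "se": se})
        eq = pd.DataFrame({"variant_id": ids, "beta": np.array(z_eqtl) * se, "se": se})
        return gw, eq

    def test_posteriors_sum_to_one(self):
        gw, eq = self._slices([1.0, 5.0, 0.5], [0.2, 4.0, 0.1])
        res = P.coloc_abf(gw, eq)
        assert res.pp.sum() == pytest.approx(1.0, abs=1e-8)
        assert (res.pp >= 0).all()

    def test_double_null_favors_h0(self):
        gw, eq = self._slices([0.0] * 20, [0.0] * 20)
        res = P.coloc_abf(gw, eq)
        assert res.best_hypothesis() == 0

    def test_strong_shared_signal_gives_h4(self):
        z = [0.0] * 50
        z[17] = 9.0
        gw, eq = self._slices(z, z)
        res = P.coloc_abf(gw, eq)
        assert res.pp_h4 > 0.99

    def test_matches_brute_force_configuration_sums(self):
        rng = np.random.default_rng(5)
        gw, eq = self._slices(rng.normal(0, 2, 12), rng.normal(0, 2, 12))
        res = P.coloc_abf(gw, eq)
        # plain-exponential-space enumeration over all variant configurations
        bf_g = np.exp(P.wakefield_labf(gw["beta"].to_numpy(), gw["se"].to_numpy(), 0.2))
        bf_e = np.exp(P.wakefield_labf(eq["beta"].to_numpy(), eq["se"].to_numpy(), 0.15))
        p1 = p2 = 1e-4
        p12 = 1e-5
        h = np.array(
            [
                1.0,
                p1 * bf_g.sum(),
                p2 * bf_e.sum(),
                p1 * p2 * sum(bf_g[i] * bf_e[j] for i in range(12) for j in range(12)
                              if i != j),
                p12 * (bf_g * bf_e).sum(),
            ]
        )
        np.testing.assert_allclose(res.pp, h / h.sum(), rtol=1e-8)

    def test_distinct_signals_favor_h3(self):
        z_g = [0.0] * 30
        z_e = [0.0] * 30
        z_g[5] = 9.0
        z_e[25] = 9.0
        gw, eq = self._slices(z_g, z_e)
        res = P.coloc_abf(gw, eq)
        assert res.best_hypothesis() == 3

    def test_h4_monotone_in_p12(self):
        rng = np.random.default_rng(6)
        gw, eq = self._slices(rng.normal(0, 3, 15), rng.normal(0, 3, 15))
        pps = [P.coloc_abf(gw, eq, p12=p12).pp_h4 for p12 in (1e-6, 1e-5, 1e-4)]
        assert pps[0] <= pps[1] <= pps[2]

    def test_too_few_shared_variants_not_testable(self):
        gw, eq = self._slices([1.0], [1.0])
        assert P.coloc_abf(gw, eq) is None


class TestLdOverlap:
    @pytest.fixture(scope="class")
    def geno(self):
        return simulate_genotypes(
            500, uniform_layout(20, maf=0.3), [(0, 10, 12), (10, 20, 12)], seed=3
        )

    def test_same_variant_true(self, geno):
        vid = geno.variants.iloc[0]["variant_id"]
        assert P.ld_overlap(vid, vid, geno) is True

    def test_independent_blocks_false(self, geno):
        a = geno.variants.iloc[2]["variant_id"]
        b = geno.variants.iloc[15]["variant_id"]
        assert P.ld_overlap(a, b, geno) is False

    def test_threshold_uses_pearson_squared_oracle(self, geno):
        from locus2gene.stats import pearson_r

        a = geno.variants.iloc[2]["variant_id"]
        b = geno.variants.iloc[5]["variant_id"]
        r2 = pearson_r(geno.dosage_of(a), geno.dosage_of(b)) ** 2
        assert P.ld_overlap(a, b, geno, r2_thresh=r2 - 1e-9) is True
        assert P.ld_overlap(a, b, geno, r2_thresh=r2 + 1e-9) is False

    def test_monomorphic_not_testable(self, geno):
        import copy

        g2 = copy.deepcopy(geno)
        g2.dosages[:, 0] = 1.0
        vid = g2.variants.iloc[0]["variant_id"]
        other = g2.variants.iloc[1]["variant_id"]
        assert P.ld_overlap(vid, other, g2) is None


class TestAggregateEvidence:
    def _mr(self, p):
        return P.MrResult("g", 0.4, 0.1, p, 3, 0.0, 1.0, 0.4, 0.1)

    def _coloc(self, h4):
        pp = np.array([0, 0, 0, 1 - h4, h4], float)
        return P.ColocResult("g", "r", pp, (1e-4, 1e-4, 1e-5), 10)

    def test_all_four_significant_gives_four_lines(self):
        rec = P.aggregate_evidence("g", self._mr(1e-6), self._coloc(0.95), True,
                                   True, mr_alpha=3.1e-4)
        assert rec.lines_of_evidence == 4

    def test_coloc_alone_prioritizes(self):
        rec = P.aggregate_evidence("g", None, self._coloc(0.95), None, None,
                                   mr_alpha=3.1e-4)
        assert rec.lines_of_evidence == 1
        assert rec.prioritized
        assert rec.mr_ivw is None

    def test_not_testable_differs_from_false(self):
        rec = P.aggregate_evidence("g", self._mr(0.5), None, False, None,
                                   mr_alpha=3.1e-4)
        assert rec.mr_ivw is False and rec.coloc is None and rec.ld_overlap is False
        assert rec.lines_of_evidence == 0

    def test_bonferroni_threshold_for_162_genes(self):
        alpha = P.bonferroni_alpha(0.05, 162)
        assert f"{alpha:.1e}" == "3.1e-04"


def direction_oracle(concordant, e_sig_both, g_sig_both, e_gw, g_gw, mr_dir):
    """Independent hand-enumerated decision table for the six rules."""
    if concordant:
        if e_sig_both and g_sig_both:
            return "+"  # concordant sign fixed to + in the enumeration below
        return mr_dir or "?"
    if e_sig_both and g_sig_both:
        return mr_dir or "?"
    if e_gw and not g_gw:
        return "+"      # eQTL top pair sign fixed to + below
    if g_gw and not e_gw:
        return "-"      # GWAS top pair sign fixed to - below
    return "?"


class TestAssignDirection:
    def _pair(self, sign, p_eqtl, p_gwas):
        return P.TopVariantPair("v", 1.0, p_eqtl, float(sign), p_gwas)

    def test_rule1_concordant_significant(self):
        e = self._pair(+1, 1e-10, 1e-10)
        g = self._pair(+1, 1e-10, 1e-10)
        assert P.assign_direction(e, g, None) == "+"

    def test_rule3_discordant_mr_override(self):
        e = self._pair(+1, 1e-10, 1e-10)
        g = self._pair(-1, 1e-10, 1e-10)
        mr = P.MrResult("g", -0.4, 0.05, 1e-9, 3, 0, 1, -0.4, 0.05)
        assert P.assign_direction(e, g, mr) == "-"

    def test_palindromic_top_variant_gives_question(self):
        e = P.TopVariantPair("v", 1.0, 1e-10, 1.0, 1e-10, palindromic=True)
        g = self._pair(+1, 1e-10, 1e-10)
        assert P.assign_direction(e, g, None) == "?"

    def test_exhaustive_truth_table_matches_oracle(self):
        sig, nonsig = 1e-10, 1e-3
        gw, non_gw = 1e-10, 1e-7  # gw < 5e-8 <= non_gw
        mr_sig = P.MrResult("g", 0.4, 0.05, 1e-9, 3, 0, 1, 0.4, 0.05)
        for concordant, e_s, g_s, e_gw, g_gw, use_mr in itertools.product(
            [True, False], repeat=6
        ):
            # eQTL pair sign +; GWAS pair sign + if concordant else -
            p_e_eqtl = gw if e_gw else non_gw
            p_g_gwas = gw if g_gw else non_gw
            e_pair = P.TopVariantPair(
                "ve", 1.0, p_e_eqtl, 1.0,
                sig if e_s else nonsig,
            )
            # significance-in-both for a pair: p_eqtl and p_gwas both < 5e-6;
            # p_e_eqtl (1e-10 or 1e-7) is always significant at 5e-6
            g_pair = P.TopVariantPair(
                "vg", 1.0, sig if g_s else nonsig,
                1.0 if concordant else -1.0, p_g_gwas,
            )
            e_sig_both = (p_e_eqtl < 5e-6) and (e_pair.p_gwas < 5e-6)
            g_sig_both = (g_pair.p_eqtl < 5e-6) and (p_g_gwas < 5e-6)
            got = P.assign_direction(e_pair, g_pair, mr_sig if use_mr else None)
            expected = direction_oracle(
                concordant, e_sig_both, g_sig_both, e_gw, g_gw,
                "+" if use_mr else None,
            )
            assert got == expected, (concordant, e_s, g_s, e_gw, g_gw, use_mr)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        be=st.floats(-2, 2), bg=st.floats(-2, 2),
        pe=st.floats(1e-12, 1.0), pg=st.floats(1e-12, 1.0),
    )
    def test_total_function_and_allele_flip_invariance(self, be, bg, pe, pg):
        e = P.TopVariantPair("v", be, pe, bg, pg)
        g = P.TopVariantPair("w", be, pe, bg, pg)
        out = P.assign_direction(e, g, None)
        assert out in {"+", "-", "?"}
        # flipping the counted allele in both datasets flips both betas
        e2 = P.TopVariantPair("v", -be, pe, -bg, pg)
        g2 = P.TopVariantPair("w", -be, pe, -bg, pg)
        assert P.assign_direction(e2, g2, None) == out
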