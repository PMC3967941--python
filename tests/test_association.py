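import itertools
import math

import numpy as np
import pytest
from scipy import stats

from popsel.association import (
    GenotypeCounts, PenetranceModel, exact_association_pvalue,
    genotype_frequencies, hwe_exact_test, model_probabilities,
    permutation_association, select_best_model_aic,
)
from popsel.synthesis import simulate_case_control_counts


def hwe_enumeration_oracle(counts: GenotypeCounts) -> float:
    """Full enumeration of genotype configurations conditional on allele counts."""
    n = counts.total
    n_rare = 2 * counts.rare_hom + counts.het
    m = min(n_rare, 2 * n - n_rare)
    if m == 0:
        return 1.0
    probs = {}
    for het in range(m % 2, m + 1, 2):
        hom_min = (m - het) // 2
        hom_maj = n - het - hom_min
        if hom_maj < 0:
            continue
        ln = (math.lgamma(n + 1) - math.lgamma(hom_min + 1)
              - math.lgamma(het + 1) - math.lgamma(hom_maj + 1)
              + het * math.log(2))
        probs[het] = math.exp(ln)
    tot = sum(probs.values())
    p_obs = probs[counts.het] / tot
    return min(1.0, sum(v for v in probs.values()
                        if v / tot <= p_obs * (1 + 1e-12)) / tot)


class TestHWEExact:
    def test_hesn_table(self, table4_counts):
        hesn, ctr = table4_counts
        assert hwe_exact_test(hesn) == pytest.approx(0.04, abs=0.005)
        assert hwe_exact_test(ctr) > 0.99

    def test_monomorphic(self):
        assert hwe_exact_test(GenotypeCounts("x", 0, 0, 50)) == 1.0

    @pytest.mark.parametrize("counts", [
        (0, 10, 0), (5, 0, 5), (1, 2, 3), (4, 4, 4), (0, 1, 20), (7, 1, 1),
        (2, 9, 14), (3, 12, 30),
    ])
    def test_recurrence_matches_enumeration(self, counts):
        gc = GenotypeCounts("x", *counts)
        assert hwe_exact_test(gc) == pytest.approx(hwe_enumeration_oracle(gc),
                                                   abs=1e-10)

    def test_all_small_tables_match_enumeration(self):
        for tot in (6, 11):
            for rh, het in itertools.product(range(tot + 1), range(tot + 1)):
                ch = tot - rh - het
                if ch < 0:
                    continue
                gc = GenotypeCounts("x", rh, het, ch)
                assert hwe_exact_test(gc) == pytest.approx(
                    hwe_enumeration_oracle(gc), abs=1e-10)


class TestPenetranceModel:
    def test_reference_recessive_fit(self, table4_counts):
        hesn, ctr = table4_counts
        fit = PenetranceModel(hesn, ctr, kp=0.20).fit("recessive", seed=1)
        assert fit.q == pytest.approx(0.079, abs=0.002)
        assert round(fit.alpha, 2) == pytest.approx(0.20)
        assert fit.gamma == pytest.approx(3.23, abs=0.05)
        assert fit.chi2 == pytest.approx(1.81, abs=0.05)
        assert fit.df == 2
        assert fit.pvalue == pytest.approx(0.40, abs=0.01)
        assert fit.beta == 1.0

    def test_counts_at_model_expectations_recover_parameters(self):
        q, gamma, kp = 0.15, 2.5, 0.2
        probs = model_probabilities(q, 1.0, gamma, kp)
        case_p, ctrl_p, _ = probs
        cases = GenotypeCounts("c", *np.round(case_p * 2000).astype(int))
        controls = GenotypeCounts("k", *np.round(ctrl_p * 8000).astype(int))
        fit = PenetranceModel(cases, controls, kp).fit("recessive", seed=0)
        assert fit.chi2 < 0.01
        assert fit.q == pytest.approx(q, abs=0.01)
        assert fit.gamma == pytest.approx(gamma, abs=0.1)

    def test_kp_identity_holds_at_optimum(self, table4_counts):
        hesn, ctr = table4_counts
        fit = PenetranceModel(hesn, ctr, kp=0.20).fit("recessive", seed=0)
        kp = fit.alpha * ((1 - fit.q) ** 2 + 2 * fit.q * (1 - fit.q) * fit.beta
                          + fit.q ** 2 * fit.gamma)
        assert kp == pytest.approx(0.20, abs=1e-9)

    def test_constraints_respected(self, table4_counts):
        hesn, ctr = table4_counts
        model = PenetranceModel(hesn, ctr, kp=0.20)
        dom = model.fit("dominant", seed=0)
        assert dom.beta == pytest.approx(dom.gamma)
        add = model.fit("additive", seed=0)
        assert add.beta == pytest.approx((add.gamma + 1) / 2)
        mul = model.fit("multiplicative", seed=0)
        assert mul.beta == pytest.approx(math.sqrt(mul.gamma))
        gen = model.fit("general", seed=0)
        assert gen.df == 1 and dom.df == 2

    def test_scaling_cohorts_preserves_estimates(self, table4_counts):
        hesn, ctr = table4_counts
        f1 = PenetranceModel(hesn, ctr, 0.20).fit("recessive", seed=0)
        big = (GenotypeCounts("c", 30, 120, 720), GenotypeCounts("k", 20, 590, 3750))
        f10 = PenetranceModel(*big, 0.20).fit("recessive", seed=0)
        assert f10.q == pytest.approx(f1.q, abs=1e-3)
        assert f10.gamma == pytest.approx(f1.gamma, abs=0.02)
        assert f10.chi2 == pytest.approx(10 * f1.chi2, rel=0.01)


class TestModelSelection:
    def test_reference_data_selects_recessive(self, table4_counts):
        hesn, ctr = table4_counts
        fits = PenetranceModel(hesn, ctr, kp=0.20).fit_all(seed=1)
        assert select_best_model_aic(fits).model == "recessive"

    def test_tie_broken_toward_fewer_parameters(self, table4_counts):
        hesn, ctr = table4_counts
        fits = PenetranceModel(hesn, ctr, 0.20).fit_all(seed=0)
        general = next(f for f in fits if f.model == "general")
        rec = next(f for f in fits if f.model == "recessive")
        general.aic = rec.aic  # force a tie
        assert select_best_model_aic([general, rec]).model == "recessive"

    def test_dominant_data_recovers_dominant(self, rng):
        hits = 0
        for _ in range(30):
            cases, controls = simulate_case_control_counts(
                0.2, 3.0, 3.0, 0.2, 2000, 2000, rng)
            fits = PenetranceModel(cases, controls, 0.2).fit_all(
                n_starts=10, seed=0)
            if select_best_model_aic(fits).model == "dominant":
                hits += 1
        assert hits >= 24  # >= 80%


class TestPermutation:
    def test_reference_table_pvalues(self, table4_counts):
        """The Monte-Carlo permutation p must match the exact conditional
        label-swap distribution of the printed counts (binomial MC error)."""
        hesn, ctr = table4_counts
        for model in ("genotypic", "recessive"):
            exact = exact_association_pvalue(hesn, ctr, model)
            mc = permutation_association(hesn, ctr, model, b=10_000, seed=5)
            se = math.sqrt(exact * (1 - exact) / 10_000)
            assert mc == pytest.approx(exact, abs=4 * se + 2e-4)

    def test_tiny_table_matches_exhaustive_enumeration(self):
        cases = GenotypeCounts("c", 2, 3, 1)
        controls = GenotypeCounts("k", 0, 2, 4)
        for model in ("genotypic", "recessive"):
            exact = exact_association_pvalue(cases, controls, model)
            mc = permutation_association(cases, controls, model, b=40_000, seed=9)
            assert mc == pytest.approx(exact, abs=0.01)

    def test_degenerate_table(self):
        assert permutation_association(GenotypeCounts("c", 0, 0, 10),
                                       GenotypeCounts("k", 0, 0, 20)) == 1.0

    def test_no_signal_is_not_significant(self, rng):
        cases = GenotypeCounts("c", 4, 32, 64)
        controls = GenotypeCounts("k", 8, 64, 128)
        p = permutation_association(cases, controls, "genotypic", 2000, rng)
        assert p > 0.5


class TestFrequencies:
    def test_reference_proportions(self, table4_counts):
        hesn, ctr = table4_counts
        assert genotype_frequencies(hesn)["rare_hom_proportion"] * 100 == \
            pytest.approx(3.45, abs=0.005)
        assert genotype_frequencies(ctr)["rare_hom_proportion"] * 100 == \
            pytest.approx(0.46, abs=0.005)

    def test_absent_allele(self):
        f = genotype_frequencies(GenotypeCounts("x", 0, 0, 33))
        assert f["rare_hom_proportion"] == 0.0
        assert f["rare_allele_frequency"] == 0.0
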