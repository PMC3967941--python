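import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from popsel.haplotypes import HaplotypeMatrix
from popsel.outliers import build_empirical_null
from popsel.sfs import (
    SFSCounts, fay_wu_h_norm, fu_li_star, nucleotide_diversity_pi,
    sfs_counts, sliding_window_stat, tajimas_d, watterson_theta,
)


def pairwise_diff_oracle(calls: np.ndarray) -> float:
    """Quadratic-time enumeration of Hamming distances over all pairs."""
    n = calls.shape[0]
    return float(sum((calls[i] != calls[j]).sum()
                     for i, j in itertools.combinations(range(n), 2)))


def random_matrix(rng, n, m) -> HaplotypeMatrix:
    calls = rng.integers(0, 2, size=(n, m)).astype(np.int8)
    return HaplotypeMatrix("r", "1", np.arange(1, m + 1), [("A", "G")] * m,
                           calls, np.array(["p"] * n, object))


class TestWattersonAndPi:
    def test_toy_values(self, toy_t4):
        c = sfs_counts(toy_t4, L=100)
        assert watterson_theta(c) == pytest.approx(3 / (1 + 1 / 2 + 1 / 3))
        assert watterson_theta(c) == pytest.approx(1.63636, abs=1e-5)
        assert watterson_theta(c, per_site=True) == pytest.approx(0.016364, abs=1e-6)
        assert nucleotide_diversity_pi(c) == pytest.approx(10 / 6)

    def test_edge_cases(self):
        assert watterson_theta(SFSCounts(4, 0, [0, 0, 0], 0, 0.0)) == 0.0
        assert watterson_theta(SFSCounts(2, 7, [7], 7, 7.0)) == 7.0  # a_2 = 1

    def test_pi_matches_pair_enumeration_on_random_matrices(self, rng):
        for _ in range(100):
            n = int(rng.integers(3, 12))
            m = int(rng.integers(1, 30))
            hap = random_matrix(rng, n, m)
            c = sfs_counts(hap)
            expected = pairwise_diff_oracle(hap.calls) / math.comb(n, 2)
            assert nucleotide_diversity_pi(c) == pytest.approx(expected)

    def test_spectrum_formula_equals_pair_enumeration(self, rng):
        # sum_j 2 c_j (n - c_j) / (n (n-1)) is the same quantity
        hap = random_matrix(rng, 8, 40)
        c = sfs_counts(hap)
        counts = hap.calls.sum(axis=0)
        alt = (2.0 * counts * (8 - counts)).sum() / (8 * 7)
        assert nucleotide_diversity_pi(c) == pytest.approx(alt)


class TestTajimasD:
    def test_toy_value(self, toy_t4):
        # hand evaluation: e1=0.0055096, e2=0.0026909 for n=4
        assert tajimas_d(sfs_counts(toy_t4)) == pytest.approx(0.16766, abs=1e-4)

    def test_monomorphic_is_missing_not_zero(self):
        assert math.isnan(tajimas_d(SFSCounts(4, 0, [0, 0, 0], 0, 0.0)))

    def test_zero_numerator(self):
        # n=4: a_n = 11/6, so S=11 gives thetaW = 6; dsum=36 gives pi = 6
        c = SFSCounts(4, 11, [4, 4, 3], 2, 36.0)
        assert tajimas_d(c) == pytest.approx(0.0)
        # n=2 is degenerate (pi == S identically): reported missing
        assert math.isnan(tajimas_d(SFSCounts(2, 5, [5], 5, 5.0)))

    def test_matches_independent_transcription(self, rng):
        for _ in range(60):
            n = int(rng.integers(4, 15))
            hap = random_matrix(rng, n, int(rng.integers(2, 25)))
            c = sfs_counts(hap)
            if c.S == 0:
                continue
            pi = pairwise_diff_oracle(hap.calls) / math.comb(n, 2)
            a1 = sum(1 / i for i in range(1, n))
            a2 = sum(1 / i**2 for i in range(1, n))
            b1 = (n + 1) / (3 * (n - 1))
            b2 = 2 * (n * n + n + 3) / (9 * n * (n - 1))
            c1 = b1 - 1 / a1
            c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
            var = (c1 / a1) * c.S + (c2 / (a1**2 + a2)) * c.S * (c.S - 1)
            expected = (pi - c.S / a1) / math.sqrt(var)
            assert tajimas_d(c) == pytest.approx(expected)


class TestFuLiStar:
    def test_toy_values_frozen(self, toy_t4):
        dstar, fstar = fu_li_star(sfs_counts(toy_t4))
        assert dstar == pytest.approx(0.167656, abs=1e-5)
        assert fstar == pytest.approx(0.081777, abs=1e-5)

    def test_all_singletons_negative(self):
        # 10 sites, every derived allele a singleton: excess of external-branch
        # mutations drives D* below zero
        n = 10
        calls = np.zeros((n, n), np.int8)
        np.fill_diagonal(calls, 1)
        hap = HaplotypeMatrix("r", "1", np.arange(1, n + 1), [("A", "G")] * n,
                              calls, np.array(["p"] * n, object))
        dstar, fstar = fu_li_star(sfs_counts(hap))
        assert dstar < 0 and fstar < 0

    def test_monomorphic_missing(self):
        d, f = fu_li_star(SFSCounts(5, 0, [0] * 4, 0, 0.0))
        assert math.isnan(d) and math.isnan(f)

    def test_standardized_statistic_is_calibrated_under_neutrality(self, rng):
        """Wrong normalizing constants would shift the neutral sd of D*/F*
        away from 1 and their mean away from 0; the simulator provides the
        independent reference distribution."""
        from popsel.coalescent import simulate_coalescent_locus

        ds, fs = [], []
        for _ in range(2500):
            c = sfs_counts(simulate_coalescent_locus(10, 3.0, rng=rng))
            if c.S == 0:
                continue
            d, f = fu_li_star(c)
            ds.append(d)
            fs.append(f)
        assert abs(np.mean(ds)) < 0.12 and abs(np.mean(fs)) < 0.12
        assert 0.8 < np.std(ds) < 1.2 and 0.75 < np.std(fs) < 1.2


class TestFayWuH:
    def test_toy_value(self, toy_t4):
        c = sfs_counts(toy_t4)
        i = np.arange(1, 4)
        theta_l = float((i * c.xi).sum()) / 3
        assert theta_l == pytest.approx(2.0)
        assert (nucleotide_diversity_pi(c) - theta_l) == pytest.approx(-1 / 3)
        assert fay_wu_h_norm(c) == pytest.approx(-0.709, abs=1e-3)

    def test_all_singletons_positive(self):
        c = SFSCounts(10, 5, [5] + [0] * 8, 5, 5 * 9.0)
        assert fay_wu_h_norm(c) > 0

    def test_no_resolved_sites_missing(self):
        c = SFSCounts(6, 3, [0] * 5, 1, 4.0, S_resolved=0)
        assert math.isnan(fay_wu_h_norm(c))


class TestInvariances:
    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_relabeling_and_length_invariance(self, seed):
        rng = np.random.default_rng(seed)
        n, m = int(rng.integers(4, 10)), int(rng.integers(3, 20))
        hap = random_matrix(rng, n, m)
        c1 = sfs_counts(hap, L=100.0)
        c2 = sfs_counts(hap, L=7777.0)
        for fn in (tajimas_d, fay_wu_h_norm, lambda c: fu_li_star(c)[0],
                   lambda c: fu_li_star(c)[1]):
            v1, v2 = fn(c1), fn(c2)
            assert (math.isnan(v1) and math.isnan(v2)) or v1 == pytest.approx(v2)
        assert watterson_theta(c1) >= 0 and nucleotide_diversity_pi(c1) >= 0
        assert watterson_theta(c1, per_site=True) * c1.L == pytest.approx(
            watterson_theta(c1))


class TestSlidingWindows:
    def make_region(self, rng, length=20_000, n_sites=200):
        pos = np.sort(rng.choice(np.arange(1, length + 1), n_sites, replace=False))
        calls = rng.integers(0, 2, size=(8, n_sites)).astype(np.int8)
        return HaplotypeMatrix("r", "1", pos, [("A", "G")] * n_sites, calls,
                               np.array(["p"] * 8, object), start=1, end=length)

    def test_window_count(self, rng):
        hap = self.make_region(rng)
        wins = sliding_window_stat(hap, "D", span=5000, step=500)
        assert len(wins) == (20_000 - 5000) // 500 + 1 == 31

    def test_empty_window_missing_without_flag(self, rng):
        hap = self.make_region(rng, n_sites=5)
        # push all sites into the first kb so later windows are empty
        hap.positions = np.arange(1, 6)
        wins = sliding_window_stat(hap, "pi", span=5000, step=500)
        tail = wins[-1]
        assert math.isnan(tail.value) and not tail.below_5th

    def test_flags_match_brute_force_percentile(self, rng):
        panel = [self.make_region(rng) for _ in range(10)]
        values = []
        for hap in panel:
            values += [w.value for w in sliding_window_stat(hap, "D", 5000, 500)
                       if not math.isnan(w.value)]
        null = build_empirical_null(np.asarray(values), statistic="D")
        hap = self.make_region(rng)
        wins = sliding_window_stat(hap, "D", 5000, 500, null=null)
        p5 = float(np.percentile(values, 5.0))
        for w in wins:
            if math.isnan(w.value):
                assert not w.below_5th
            else:
                assert w.below_5th == (w.value < p5)

    def test_span_must_cover_step(self, toy_t4):
        with pytest.raises(ValueError):
            sliding_window_stat(toy_t4, "D", span=100, step=500)
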