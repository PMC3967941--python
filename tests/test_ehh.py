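import math

import numpy as np
import pandas as pd
import pytest

from popsel.ehh import (
    apply_dind_cap, dind_statistic, dind_table, ehh_curve, ehhs_ies,
    ihs_unstandardized, lnrsb_unnormalized, normalize_lnrsb, standardize_ihs,
)
from popsel.haplotypes import HaplotypeMatrix


def matrix(calls, positions=None, pops=None):
    calls = np.asarray(calls, np.int8)
    n, m = calls.shape
    positions = np.asarray(positions if positions is not None
                           else np.arange(1, m + 1) * 100)
    return HaplotypeMatrix("r", "1", positions, [("A", "G")] * m, calls,
                           np.asarray(pops if pops is not None else ["p"] * n,
                                      object))


class TestEHHCurve:
    def test_identical_core_haplotypes_stay_at_one(self):
        calls = np.array([[1, 1, 0, 1], [1, 1, 0, 1], [1, 1, 0, 1], [1, 1, 0, 1],
                          [0, 0, 1, 0], [0, 0, 1, 0]])
        hap = matrix(calls)
        r = ehh_curve(hap, 300, "derived", "right")
        assert r.ehh.tolist() == [1.0, 1.0]

    def test_two_two_split(self):
        # 4 derived carriers split 2/2 at the next site: (1+1)/C(4,2)
        calls = np.array([[1, 0], [1, 0], [1, 1], [1, 1], [0, 0]])
        r = ehh_curve(matrix(calls), 100, "derived", "right")
        assert r.ehh[-1] == pytest.approx(1 / 3)

    def test_all_distinct_reaches_zero(self):
        calls = np.array([[1, 0, 0], [1, 0, 1], [1, 1, 0], [1, 1, 1]])
        r = ehh_curve(matrix(calls), 100, "derived", "right")
        assert r.ehh[-1] == 0.0 and r.truncation == "floor"

    def test_monotone_non_increasing(self, rng):
        calls = rng.integers(0, 2, size=(20, 40))
        calls[:, 20] = np.repeat([0, 1], 10)
        hap = matrix(calls)
        for side in ("left", "right"):
            r = ehh_curve(hap, 2100, "derived", side)
            assert np.all(np.diff(r.ehh) <= 1e-12)
            assert r.ehh[0] == 1.0
            assert ((0 <= r.ehh) & (r.ehh <= 1)).all()

    def test_max_extent_truncation(self):
        calls = np.tile([[1, 1], [1, 1], [0, 0]], 1)
        hap = matrix(calls, positions=[100, 300_000])
        r = ehh_curve(hap, 100, "derived", "right")
        assert r.truncation == "max_extent" and len(r.ehh) == 1


IHS_TOY = np.array([
    # pos:  100 200 300 400 500 600 ; focal = 300
    [0, 0, 0, 0, 0, 1],
    [0, 0, 0, 0, 1, 1],
    [1, 0, 0, 1, 0, 0],
    [0, 0, 0, 1, 1, 0],
    [0, 1, 1, 0, 0, 1],
    [1, 1, 1, 0, 0, 1],
    [0, 0, 1, 0, 0, 0],
    [1, 1, 1, 0, 0, 0],
])


class TestIHS:
    def test_hand_trapezoid_on_toy(self):
        """Hand-enumerated EHH points for the 8x6 fixture (focal = 300):
        ancestral right (1, 1/3, 0) -> 83.33; ancestral left (1, 1, 1/2) -> 175;
        derived right (1, 1, 1, 1/3) -> 266.67; derived left (1, 1/2, 1/6)
        -> 108.33.  iHS = ln(258.33 / 375)."""
        hap = matrix(IHS_TOY)
        a_r = ehh_curve(hap, 300, "ancestral", "right")
        assert a_r.ehh.tolist() == pytest.approx([1, 1 / 3, 0])
        assert a_r.ihh == pytest.approx(250 / 3)
        a_l = ehh_curve(hap, 300, "ancestral", "left")
        assert a_l.ehh.tolist() == pytest.approx([1, 1, 1 / 2])
        assert a_l.ihh == pytest.approx(175.0)
        d_r = ehh_curve(hap, 300, "derived", "right")
        assert d_r.ihh == pytest.approx(800 / 3)
        d_l = ehh_curve(hap, 300, "derived", "left")
        assert d_l.ehh.tolist() == pytest.approx([1, 1 / 2, 1 / 6])
        assert d_l.ihh == pytest.approx(75 + 100 / 3)
        v = ihs_unstandardized(hap, 300)
        assert v == pytest.approx(math.log((250 / 3 + 175) / (800 / 3 + 75 + 100 / 3)))

    def test_symmetric_structure_gives_zero(self):
        block = np.array([[0, 0, 0], [0, 1, 0], [1, 0, 1], [1, 1, 1]])
        calls = np.hstack([block[:, :1] * 0 + block, block])  # same pattern
        calls = np.hstack([block, np.array([[0], [0], [1], [1]]), block])
        hap = matrix(calls)
        assert ihs_unstandardized(hap, 400) == pytest.approx(0.0)

    def test_homogeneous_derived_class_negative(self):
        rngl = np.random.default_rng(0)
        anc = rngl.integers(0, 2, size=(6, 20))
        der = np.tile(anc[0], (6, 1))
        calls = np.vstack([anc, der])
        calls[:, 10] = np.repeat([0, 1], 6)
        hap = matrix(calls)
        v = ihs_unstandardized(hap, 1100)
        assert v < 0

    def test_missing_when_class_degenerate(self):
        calls = np.array([[1, 1, 1], [0, 0, 0], [0, 0, 0], [0, 0, 1]])
        hap = matrix(calls)  # single derived carrier at focal 200
        assert math.isnan(ihs_unstandardized(hap, 200))


class TestStandardize:
    def test_self_standardization_centers_each_bin(self, rng):
        daf = rng.uniform(0.02, 0.98, 3000)
        raw = 0.8 * daf + rng.normal(0, 0.3, 3000)  # DAF-dependent mean
        z = standardize_ihs(raw, daf, n_bins=50, min_bin=10)
        edges = np.linspace(0, 1, 51)
        bins = np.digitize(daf, edges) - 1
        for b in np.unique(bins):
            sel = bins == b
            if sel.sum() >= 20:
                assert abs(z[sel].mean()) < 1e-9
                assert z[sel].std(ddof=1) == pytest.approx(1.0, abs=1e-9)

    def test_constant_raw_maps_to_zero(self):
        z = standardize_ihs(np.full(40, 1.7), np.linspace(0.1, 0.9, 40),
                            n_bins=5, min_bin=1)
        assert np.allclose(z, 0.0)

    def test_empty_calibration_bin_is_missing(self):
        z = standardize_ihs(np.array([1.0]), np.array([0.95]),
                            cal_raw=np.array([0.5, 0.6]),
                            cal_daf=np.array([0.1, 0.12]), n_bins=10, min_bin=1)
        assert math.isnan(z[0])


class TestLnRsb:
    def test_identical_populations_give_zero(self, rng):
        calls = rng.integers(0, 2, size=(12, 30))
        calls[:, 15] = rng.permutation(np.repeat([0, 1], 6))
        hap = matrix(calls)
        assert lnrsb_unnormalized(hap, hap, 1600) == pytest.approx(0.0)

    def test_normalization_centers_median(self, rng):
        cal = rng.normal(2.0, 1.0, 500)
        z = normalize_lnrsb(cal, cal)
        assert np.median(z) == pytest.approx(0.0, abs=1e-12)

    def test_long_homozygosity_raises_ies(self, rng):
        base = rng.integers(0, 2, size=(12, 40))
        swept = np.tile(base[0], (12, 1))
        swept[:, 20] = base[:, 20] = np.repeat([0, 1], 6)
        v = lnrsb_unnormalized(matrix(swept), matrix(base), 2100)
        assert v > 0


class TestDIND:
    def make_flanked(self, focal_col, n=12, m=41, seed=5):
        rngl = np.random.default_rng(seed)
        calls = rngl.integers(0, 2, size=(n, m))
        calls[:, 20] = focal_col
        return matrix(calls)

    def test_ratio_arithmetic(self):
        r_a, r_d = 0.004, 0.001
        assert r_a / r_d == pytest.approx(4.0)

    def test_equal_diversity_gives_one(self):
        rngl = np.random.default_rng(3)
        half = rngl.integers(0, 2, size=(6, 41))
        calls = np.vstack([half, half])  # derived class mirrors ancestral
        calls[:, 20] = np.repeat([0, 1], 6)
        hap = matrix(calls)
        r = dind_statistic(hap, 2100)
        assert r.dind == pytest.approx(1.0)
        assert r.ipi_a == pytest.approx(r.ipi_d)

    def test_capped_when_derived_identical(self):
        rngl = np.random.default_rng(4)
        anc = rngl.integers(0, 2, size=(6, 41))
        der = np.tile(anc[2], (6, 1))
        calls = np.vstack([anc, der])
        calls[:, 20] = np.repeat([0, 1], 6)
        r = dind_statistic(matrix(calls), 2100)
        assert r.capped and r.ipi_d == 0.0 and math.isnan(r.dind)

    def test_cap_rule_adds_twenty_to_panel_maximum(self):
        df = pd.DataFrame({"dind": [7.3, 2.0, np.nan], "capped": [False, False, True]})
        out = apply_dind_cap(df)
        assert out.loc[2, "dind"] == pytest.approx(27.3)

    def test_requires_full_flanks(self):
        rngl = np.random.default_rng(6)
        calls = rngl.integers(0, 2, size=(8, 30))
        calls[:, 5] = np.repeat([0, 1], 4)  # only 5 variants on the left
        assert dind_statistic(matrix(calls), 600) is None

    def test_relabeling_within_classes_invariant(self, rng):
        calls = rng.integers(0, 2, size=(12, 41))
        calls[:, 20] = np.repeat([0, 1], 6)
        hap = matrix(calls)
        r0 = dind_statistic(hap, 2100)
        perm = np.r_[rng.permutation(6), 6 + rng.permutation(6)]
        hap2 = matrix(calls[perm])
        r1 = dind_statistic(hap2, 2100)
        assert r0.dind == pytest.approx(r1.dind)
        assert r0.ipi_a == pytest.approx(r1.ipi_a)
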