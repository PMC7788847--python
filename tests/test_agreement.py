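"""Agreement statistics: Spearman, Lin's CCC, Bland-Altman, composition."""

import json

import numpy as np
import pytest
from scipy import stats

from calciquant.agreement import (
    AgreementResult,
    ConstantSeriesError,
    PairedSeries,
    bland_altman,
    lin_ccc,
    spearman,
    validate,
)


def series(x, y):
    return PairedSeries.from_arrays(np.asarray(x, float), np.asarray(y, float))


class TestPairedSeries:
    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            series([1, 2], [3, 4])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            series([1, 2, np.nan], [1, 2, 3])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            PairedSeries(labels=("a", "b"), x=np.arange(3.0), y=np.arange(3.0))


class TestSpearman:
    def test_perfect_monotone(self):
        rho, _ = spearman(series([1, 2, 3, 4, 5], [2, 4, 6, 8, 10]))
        assert rho == pytest.approx(1.0)

    def test_perfect_antitone(self):
        rho, _ = spearman(series([1, 2, 3, 4, 5], [10, 8, 6, 4, 2]))
        assert rho == pytest.approx(-1.0)

    def test_hand_computed_four_points(self):
        rho, _ = spearman(series([1, 2, 3, 4], [1, 3, 2, 4]))
        assert rho == pytest.approx(0.8)

    def test_matches_scipy_at_n31(self):
        rng = np.random.default_rng(2)
        x = rng.uniform(0, 40, 31)
        y = x + rng.normal(0, 4, 31)
        rho, p = spearman(series(x, y))
        ref = stats.spearmanr(x, y)
        assert rho == pytest.approx(ref.statistic, abs=1e-12)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_permutation_p_small_n(self):
        # 4 distinct ranks: 24 permutations; |rho| >= 1 occurs twice -> p = 1/12
        _, p = spearman(series([1, 2, 3, 4], [10, 20, 30, 40]))
        assert p == pytest.approx(2 / 24)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(7)
        x = rng.uniform(1, 50, 15)
        y = x + rng.normal(0, 5, 15)
        base = spearman(series(x, y))[0]
        assert spearman(series(np.log(x), y))[0] == pytest.approx(base)
        assert spearman(series(x, y**3))[0] == pytest.approx(base)

    def test_order_invariance(self):
        rng = np.random.default_rng(8)
        x = rng.uniform(0, 10, 12)
        y = x + rng.normal(0, 1, 12)
        perm = rng.permutation(12)
        assert spearman(series(x, y)) == pytest.approx(spearman(series(x[perm], y[perm])))

    def test_constant_series_error(self):
        with pytest.raises(ConstantSeriesError):
            spearman(series([1, 1, 1], [1, 2, 3]))


class TestLinCCC:
    def test_perfect_concordance(self):
        ccc, lo, hi = lin_ccc(series([1, 2, 3, 4], [1, 2, 3, 4]))
        assert ccc == pytest.approx(1.0)
        assert lo <= ccc <= hi

    def test_hand_computed_shifted_series(self):
        # cov = 2/3, var = 2/3 each, mean shift 1 -> ccc = (4/3) / (7/3) = 4/7
        ccc, _, _ = lin_ccc(series([1, 2, 3], [2, 3, 4]))
        assert ccc == pytest.approx(4 / 7, abs=1e-12)

    def test_anticorrelated_is_negative(self):
        ccc, _, _ = lin_ccc(series([1, 2, 3], [3, 2, 1]))
        assert ccc < 0

    def test_attenuation_vs_pearson(self):
        """|ccc| <= |r| always; equality only when means and variances match."""
        for i in range(1000):
            rng = np.random.default_rng(i)
            x = rng.normal(size=8)
            y = rng.normal(size=8)
            ccc, _, _ = lin_ccc(series(x, y))
            r = np.corrcoef(x, y)[0, 1]
            assert abs(ccc) <= abs(r) + 1e-12

    def test_ci_brackets_estimate(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 40, 31)
        y = x + rng.normal(0, 3, 31)
        ccc, lo, hi = lin_ccc(series(x, y))
        assert lo <= ccc <= hi
        assert -1 <= lo and hi <= 1

    def test_fisher_and_bootstrap_ci_agree_roughly(self):
        rng = np.random.default_rng(4)
        x = rng.uniform(0, 40, 31)
        y = x + rng.normal(0, 3, 31)
        s = series(x, y)
        _, flo, fhi = lin_ccc(s, ci="fisher")
        _, blo, bhi = lin_ccc(s, ci="bootstrap", seed=0)
        assert abs(flo - blo) < 0.1 and abs(fhi - bhi) < 0.1

    def test_constant_series_error(self):
        with pytest.raises(ConstantSeriesError):
            lin_ccc(series([2, 2, 2], [1, 2, 3]))


class TestBlandAltman:
    def test_identical_series_zero_bias_zero_limits(self):
        ba = bland_altman(series([1, 2, 3], [1, 2, 3]))
        assert ba.bias == 0.0 and ba.loa_low == 0.0 and ba.loa_high == 0.0

    def test_hand_computed(self):
        ba = bland_altman(series([1, 2, 3], [2, 4, 6]))
        assert ba.bias == pytest.approx(-2.0, abs=1e-12)
        assert ba.sd_diff == pytest.approx(1.0, abs=1e-12)
        assert ba.loa_low == pytest.approx(-3.96, abs=1e-12)
        assert ba.loa_high == pytest.approx(-0.04, abs=1e-12)

    def test_translation_equivariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        base = bland_altman(series(x, y))
        shifted = bland_altman(series(x + 7.5, y))
        assert shifted.bias == pytest.approx(base.bias + 7.5)
        assert shifted.loa_low == pytest.approx(base.loa_low + 7.5)
        assert shifted.loa_high == pytest.approx(base.loa_high + 7.5)

    def test_limits_cover_95_percent_of_normal_differences(self):
        rng = np.random.default_rng(6)
        n = 10_000
        x = rng.normal(0, 1, n)
        y = x + rng.normal(0.5, 2.0, n)
        ba = bland_altman(series(x, y))
        inside = np.mean((ba.diffs >= ba.loa_low) & (ba.diffs <= ba.loa_high))
        assert abs(inside - 0.95) <= 0.01

    def test_order_invariance(self):
        rng = np.random.default_rng(9)
        x = rng.normal(size=12)
        y = rng.normal(size=12)
        perm = rng.permutation(12)
        a, b = bland_altman(series(x, y)), bland_altman(series(x[perm], y[perm]))
        assert (a.bias, a.loa_low, a.loa_high) == pytest.approx((b.bias, b.loa_low, b.loa_high))


class TestValidate:
    def test_assembles_all_statistics_and_files(self, tmp_path):
        rng = np.random.default_rng(0)
        x = rng.uniform(0.5, 48, 31)
        y = x + rng.normal(0, 2, 31)
        res = validate(series(x, y), alpha=0.05, out_dir=tmp_path)
        assert isinstance(res, AgreementResult)
        assert res.n == 31
        assert res.ccc_ci_low <= res.ccc <= res.ccc_ci_high
        assert res.loa_low == pytest.approx(res.bias - 1.96 * res.sd_diff)
        assert res.loa_high == pytest.approx(res.bias + 1.96 * res.sd_diff)
        assert res.significant
        for name in ("scatter.png", "bland_altman.png", "plot_data.csv", "agreement.json"):
            assert (tmp_path / name).exists()
        saved = json.loads((tmp_path / "agreement.json").read_text())
        assert saved["n"] == 31

    def test_high_concordance_regime(self):
        """Low-noise paired areas at n=31 reproduce the expected pattern:
        near-unity ccc and near-zero bias."""
        passed = 0
        sigma = 3.0
        for rep in range(200):
            rng = np.random.default_rng(10_000 + rep)
            x = rng.uniform(0.5, 48, 31)
            y = x + rng.normal(0, sigma, 31)
            res = validate(series(x, y))
            if res.ccc >= 0.9 and abs(res.bias) <= 2 * sigma:
                passed += 1
        assert passed >= 0.95 * 200

    def test_constant_series_surfaces_error(self):
        with pytest.raises(ConstantSeriesError):
            validate(series([3, 3, 3], [1, 2, 3]))

    def test_too_small_series_rejected(self):
        with pytest.raises(ValueError):
            series([1, 2], [1, 2])
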