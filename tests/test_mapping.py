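"""ΔR1 maps, colour classification, ROI curves, CoV and regression."""

import numpy as np
import pytest

from dcehybrid import ConcCurve, si_curve_from_conc, spgr_signal
from dcehybrid.errors import (
    EmptyRegionError,
    FitFailureError,
    InsufficientDataError,
    InvalidInputError,
    UndefinedStatisticError,
)
from dcehybrid.mapping import (
    ColorLabel,
    anova_tukey,
    classify_wm,
    cov,
    delta_r1_map,
    regress_dr1_ktrans,
    roi_average_curve,
    wm_mask,
)


class TestClassifyWm:
    @pytest.mark.parametrize(
        "dr1,vp,expected",
        [
            (0.030, 0.02, ColorLabel.yellow),
            (0.020, 0.005, ColorLabel.blue),   # low vp overrides band
            (-0.001, 0.02, ColorLabel.blue),
            (0.005, 0.02, ColorLabel.green),
            (0.012, 0.02, ColorLabel.red),     # lower red bound inclusive
            (0.025, 0.02, ColorLabel.yellow),  # lower yellow bound inclusive
            (0.0, 0.02, ColorLabel.blue),      # dr1 == 0 completes to blue
            (0.02, 0.01, ColorLabel.blue),     # vp == 0.01 completes to blue
        ],
    )
    def test_threshold_table(self, dr1, vp, expected):
        assert classify_wm(dr1, vp) is expected

    def test_partition_is_exhaustive_and_exclusive(self):
        dr1, vp = np.meshgrid(
            np.linspace(-0.05, 0.06, 111), np.linspace(0.0, 0.05, 51), indexing="ij"
        )
        codes = classify_wm(dr1, vp)
        assert set(np.unique(codes)) <= {0, 1, 2, 3}

    def test_nan_gets_sentinel(self):
        codes = classify_wm(np.array([np.nan, 0.03]), np.array([0.02, 0.02]))
        assert codes[0] == 255 and codes[1] == ColorLabel.yellow.value
        assert classify_wm(np.nan, 0.02) is None


class TestWmMask:
    def test_strict_threshold(self):
        m = wm_mask(np.array([0.95, 1.0, 0.9501, 0.0]))
        assert m.tolist() == [False, True, True, False]

    def test_count_matches_brute_force(self, rng):
        p = rng.uniform(0, 1, (8, 8, 4))
        m = wm_mask(p)
        assert m.sum() == sum(1 for v in p.ravel() if v > 0.95)

    def test_out_of_range_raises(self):
        with pytest.raises(InvalidInputError):
            wm_mask(np.array([1.2]))


class TestDeltaR1Map:
    FLIP, TR, R10 = 20.0, 0.005, 1.0 / 0.6

    def _phantom(self, conc_end, n_t=60, n_baseline=20):
        """Single-voxel dynamic series ramping to a plateau at conc_end."""
        t = np.arange(n_t) * 1.03
        c = np.concatenate(
            [np.zeros(n_baseline), np.linspace(0, conc_end, 10), np.full(n_t - n_baseline - 10, conc_end)]
        )
        dyn = si_curve_from_conc(ConcCurve(t, c, n_baseline), 470.0, self.R10,
                                 flip_deg=self.FLIP, tr=self.TR)
        return dyn.si

    def test_no_enhancement_gives_zero(self):
        si = np.full((2, 2, 1, 40), 470.0)
        m0 = np.full((2, 2, 1), 470.0 / spgr_signal(1.0, self.R10, self.FLIP, self.TR))
        r1n = np.full((2, 2, 1), self.R10)
        dr1, nf = delta_r1_map(si, r1n, m0, n_baseline=20, flip_deg=self.FLIP, tr=self.TR)
        assert nf == 0
        assert np.allclose(dr1, 0.0, atol=1e-10)

    def test_known_plateau_round_trip(self):
        c_end = 0.0088
        si = self._phantom(c_end)[None, None, None, :]
        m0 = np.full((1, 1, 1), 470.0 / spgr_signal(1.0, self.R10, self.FLIP, self.TR))
        r1n = np.full((1, 1, 1), self.R10)
        dr1, _ = delta_r1_map(si, r1n, m0, n_baseline=20, flip_deg=self.FLIP, tr=self.TR)
        assert dr1[0, 0, 0] == pytest.approx(4.39 * c_end, abs=1e-6)

    def test_map_path_equals_scalar_path(self, rng):
        """10x10x3 mixed phantom: vectorised map equals voxel-by-voxel loop."""
        from dcehybrid.signal_model import r1_from_signal

        shape = (10, 10, 3)
        n_t, nb = 50, 20
        si = np.empty(shape + (n_t,))
        for idx in np.ndindex(shape):
            c_end = rng.uniform(-0.001, 0.01)
            si[idx] = self._phantom(c_end, n_t=n_t, n_baseline=nb)
        si += rng.normal(0, 2.0, si.shape)
        m0 = np.full(shape, 470.0 / spgr_signal(1.0, self.R10, self.FLIP, self.TR))
        r1n = np.full(shape, self.R10)
        dr1, _ = delta_r1_map(si, r1n, m0, n_baseline=nb, flip_deg=self.FLIP, tr=self.TR)
        for idx in np.ndindex(shape):
            pre = si[idx][:nb].mean()
            post = si[idx][-10:].mean()
            target = spgr_signal(m0[idx], r1n[idx], self.FLIP, self.TR) + (post - pre)
            expect = r1_from_signal(float(target), m0[idx], self.FLIP, self.TR) - r1n[idx]
            assert dr1[idx] == pytest.approx(expect, abs=1e-12)


class TestRoiAverage:
    def _data(self):
        t = np.arange(30) * 1.03
        dyn = np.zeros((4, 4, 1, 30))
        labels = np.full((4, 4, 1), ColorLabel.blue.value, dtype=np.uint8)
        dyn[0, 0, 0] = 470 + np.arange(30)
        dyn[0, 1, 0] = 470 + 2 * np.arange(30)
        labels[0, 0, 0] = labels[0, 1, 0] = ColorLabel.yellow.value
        return dyn, labels, t

    def test_single_voxel_region_returns_its_curve(self):
        dyn, labels, t = self._data()
        labels[0, 1, 0] = ColorLabel.blue.value
        out = roi_average_curve(dyn, labels, ColorLabel.yellow, t, 10)
        assert np.allclose(out.si, dyn[0, 0, 0])

    def test_mean_matches_explicit_per_frame_oracle(self):
        dyn, labels, t = self._data()
        out = roi_average_curve(dyn, labels, ColorLabel.yellow, t, 10)
        expect = [(dyn[0, 0, 0, k] + dyn[0, 1, 0, k]) / 2 for k in range(30)]
        assert np.allclose(out.si, expect)

    def test_empty_region_raises(self):
        dyn, labels, t = self._data()
        with pytest.raises(EmptyRegionError):
            roi_average_curve(dyn, labels, ColorLabel.red, t, 10)


class TestCov:
    def test_simple_value(self):
        assert 100 * cov([1.0, 2.0, 3.0]) == pytest.approx(50.0)

    def test_equal_values_give_zero(self):
        assert cov([0.019, 0.019, 0.019, 0.019]) == 0.0

    def test_undefined_near_zero_mean(self):
        with pytest.raises(UndefinedStatisticError):
            cov([-1.0, 1.0])

    def test_needs_two_values(self):
        with pytest.raises(InsufficientDataError):
            cov([1.0])


class TestRegression:
    def test_collinear_pairs_r2_one(self):
        pairs = [(0.01 * k, 0.17 * 0.01 * k - 0.001) for k in range(1, 6)]
        slope, intercept, r2 = regress_dr1_ktrans(pairs)
        assert r2 == pytest.approx(1.0)
        assert slope == pytest.approx(0.17)
        assert intercept == pytest.approx(-0.001)

    def test_matches_closed_form_ols(self, rng):
        x = rng.uniform(0, 0.04, 12)
        y = 0.17 * x + rng.normal(0, 1e-3, 12)
        slope, intercept, _ = regress_dr1_ktrans(np.column_stack([x, y]))
        n = x.size
        denom = n * (x**2).sum() - x.sum() ** 2
        s = (n * (x * y).sum() - x.sum() * y.sum()) / denom
        assert slope == pytest.approx(s, abs=1e-12)
        assert intercept == pytest.approx(y.mean() - s * x.mean(), abs=1e-12)

    def test_degenerate_raises(self):
        with pytest.raises(FitFailureError):
            regress_dr1_ktrans([(0.01, 0.001), (0.01, 0.002)])


class TestAnovaTukey:
    def test_separated_groups_are_significant(self, rng):
        groups = {
            "green": rng.normal(0.000, 0.0002, 7),
            "red": rng.normal(0.002, 0.0002, 7),
            "yellow": rng.normal(0.005, 0.0002, 7),
        }
        df = anova_tukey(groups)
        assert df.iloc[0]["p_value"] < 1e-6
        assert (df.iloc[1:]["p_value"] < 0.05).all()
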