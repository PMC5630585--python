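import numpy as np
import pytest

from uscut.image_io import BinaryMask
from uscut.metrics import bootstrap_median_ci, diameters, dice, hausdorff, icc_dsc


def _mask(a):
    return BinaryMask(np.asarray(a, dtype=np.uint8))


def _square(size, x0, y0, side):
    m = np.zeros((size, size), dtype=np.uint8)
    m[y0 : y0 + side, x0 : x0 + side] = 1
    return _mask(m)


def brute_hausdorff(a, b):
    pa = np.argwhere(a.pixels).astype(float)
    pb = np.argwhere(b.pixels).astype(float)
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    return max(d.min(axis=1).max(), d.min(axis=0).max())


class TestDice:
    def test_identical(self):
        m = _square(32, 5, 5, 10)
        assert dice(m, m) == 100.0

    def test_disjoint(self):
        assert dice(_square(32, 0, 0, 5), _square(32, 20, 20, 5)) == 0.0

    def test_half_overlap_strip(self):
        a = _square(32, 0, 0, 10)
        b = _square(32, 5, 0, 10)  # overlap is a 5x10 strip
        assert dice(a, b) == 50.0

    def test_both_empty_defined_as_100(self):
        e = _mask(np.zeros((16, 16)))
        assert dice(e, e) == 100.0

    def test_symmetry_and_translation_invariance(self, rng):
        a = _mask(rng.random((32, 32)) < 0.3)
        b = _mask(rng.random((32, 32)) < 0.3)
        assert dice(a, b) == dice(b, a)
        ta = _mask(np.roll(a.pixels, (3, 4), (0, 1)))
        tb = _mask(np.roll(b.pixels, (3, 4), (0, 1)))
        assert dice(ta, tb) == pytest.approx(dice(a, b))

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            dice(_mask(np.zeros((16, 16))), _mask(np.zeros((16, 17))))


class TestHausdorff:
    def test_identical_zero(self):
        m = _square(32, 4, 4, 9)
        assert hausdorff(m, m) == 0.0

    def test_two_single_pixels(self):
        a = np.zeros((16, 16), dtype=np.uint8)
        b = np.zeros((16, 16), dtype=np.uint8)
        a[0, 0] = 1
        b[3, 4] = 1
        assert hausdorff(_mask(a), _mask(b)) == 5.0

    def test_dilated_square_matches_bruteforce(self):
        from scipy.ndimage import grey_dilation

        a = _square(40, 10, 10, 10)
        b = _mask(grey_dilation(a.pixels, size=(7, 7)))  # Chebyshev dilation by 3
        assert hausdorff(a, b) == pytest.approx(brute_hausdorff(a, b))

    def test_random_masks_match_bruteforce(self, rng):
        for _ in range(10):
            a = _mask(rng.random((24, 24)) < 0.2)
            b = _mask(rng.random((24, 24)) < 0.2)
            if a.area_px() == 0 or b.area_px() == 0:
                continue
            assert hausdorff(a, b) == pytest.approx(brute_hausdorff(a, b))
            assert hausdorff(a, b) == hausdorff(b, a)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            hausdorff(_mask(np.zeros((16, 16))), _square(16, 2, 2, 4))


class TestDiameters:
    def test_disc(self):
        ys, xs = np.mgrid[0:80, 0:80]
        m = _mask(np.hypot(xs - 40, ys - 40) <= 30)
        d = diameters(m, 1.0)
        assert d.a == pytest.approx(61.0, abs=1.0)
        assert d.b == pytest.approx(61.0, abs=1.0)

    def test_axis_aligned_ellipse(self):
        ys, xs = np.mgrid[0:100, 0:100]
        m = _mask(((xs - 50) / 40.0) ** 2 + ((ys - 50) / 20.0) ** 2 <= 1.0)
        d = diameters(m, 1.0)
        assert d.a == pytest.approx(81.0, abs=1.0)
        assert d.b == pytest.approx(41.0, abs=1.0)

    def test_single_pixel(self):
        m = np.zeros((16, 16), dtype=np.uint8)
        m[5, 7] = 1
        d = diameters(_mask(m), 0.5)
        assert d.a == pytest.approx(0.5)
        assert d.b == pytest.approx(0.5)

    def test_rotation_90_invariance(self, rng):
        m = _mask(rng.random((40, 40)) < 0.15)
        if m.area_px() < 3:
            m = _square(40, 5, 10, 7)
        d1 = diameters(m, 1.0)
        d2 = diameters(_mask(np.rot90(m.pixels)), 1.0)
        assert d1.a == pytest.approx(d2.a)

    def test_segments_perpendicular(self):
        ys, xs = np.mgrid[0:100, 0:100]
        m = _mask(((xs - 50) / 35.0) ** 2 + ((ys - 50) / 15.0) ** 2 <= 1.0)
        d = diameters(m, 1.0)
        ua = np.subtract(d.a_endpoints[1], d.a_endpoints[0])
        ub = np.subtract(d.b_endpoints[1], d.b_endpoints[0])
        assert abs(np.dot(ua, ub)) / (np.linalg.norm(ua) * np.linalg.norm(ub)) < 1e-6

    def test_spacing_scales_mm(self):
        m = _square(32, 4, 4, 10)
        d1 = diameters(m, 1.0)
        d2 = diameters(m, 0.25)
        assert d2.a == pytest.approx(d1.a * 0.25)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            diameters(_mask(np.zeros((16, 16))), 1.0)


class TestICC:
    def test_perfect_agreement(self):
        x = [70.0, 80.0, 90.0, 60.0, 85.0]
        assert icc_dsc(x, x) == pytest.approx(1.0)

    def test_constant_offset_kills_absolute_agreement(self):
        x = np.array([80.0, 80.2, 79.8, 80.1, 79.9])
        y = x + 15.0  # offset dwarfs the tiny case variance
        assert abs(icc_dsc(x, y)) < 0.1

    def test_zero_rater_variance_positive_case_variance(self):
        x = np.array([60.0, 70.0, 80.0, 90.0])
        assert icc_dsc(x, x.copy()) == pytest.approx(1.0)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        for _ in range(5):
            n = int(rng.integers(5, 30))
            x = rng.normal(80, 8, n)
            y = x + rng.normal(0, 4, n) + rng.normal(0, 2)
            df = pd.DataFrame(
                {
                    "case": np.r_[np.arange(n), np.arange(n)],
                    "rater": ["a"] * n + ["b"] * n,
                    "score": np.r_[x, y],
                }
            )
            ref = pg.intraclass_corr(df, targets="case", raters="rater", ratings="score")
            icc2 = float(ref.loc[ref.Type == "ICC(A,1)", "ICC"].iloc[0])
            assert icc_dsc(x, y) == pytest.approx(icc2, abs=1e-9)

    def test_parameter_recovery_n88(self):
        # two-way random table: var(case)=64, var(rater)=1, var(err)=16
        rng = np.random.default_rng(88)
        sc, sr, se = 8.0, 1.0, 4.0
        truth = sc**2 / (sc**2 + sr**2 + se**2)
        estimates = []
        for _ in range(20):
            case = rng.normal(0, sc, 88)
            rater = rng.normal(0, sr, 2)
            tab = case[:, None] + rater[None, :] + rng.normal(0, se, (88, 2))
            estimates.append(icc_dsc(tab[:, 0], tab[:, 1]))
        assert np.mean(estimates) == pytest.approx(truth, abs=0.1)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            icc_dsc([1.0, 2.0], [1.0])


class TestBootstrapMedianCI:
    def test_constant_list_collapses(self):
        med, lo, hi = bootstrap_median_ci([7.0] * 20, 200, seed=1)
        assert med == lo == hi == 7.0

    def test_contains_median(self):
        med, lo, hi = bootstrap_median_ci(list(range(1, 102)), 500, seed=2)
        assert med == 51.0
        assert lo <= 51.0 <= hi

    def test_seed_reproducibility(self):
        vals = list(np.random.default_rng(3).normal(10, 2, 40))
        assert bootstrap_median_ci(vals, 300, seed=9) == bootstrap_median_ci(vals, 300, seed=9)
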