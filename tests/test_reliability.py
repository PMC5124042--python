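"""Dice overlap, ICC ANOVA algebra, and boundary-perturbation stability."""

import numpy as np
import pytest

from t2contrast import (
    AcquisitionSpec,
    RatingMatrix,
    TissueSpec,
    build_geometry,
    dice_kappa,
    extract_roi,
    compute_gwr,
    fit_t2_loglinear,
    icc,
    perturb_mask,
    perturbation_analysis,
    simulate_echo_train,
)


class TestDice:
    def test_identical_nonempty_masks(self, sphere_mask):
        assert dice_kappa(sphere_mask, sphere_mask).value == 1.0

    def test_disjoint_masks(self):
        a = np.zeros((6, 6, 6), bool)
        b = np.zeros((6, 6, 6), bool)
        a[:2], b[4:] = True, True
        assert dice_kappa(a, b).value == 0.0

    def test_counts_formula(self):
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a.ravel()[:100] = True
        b.ravel()[20:120] = True  # overlap 80
        res = dice_kappa(a, b)
        assert res.value == pytest.approx(2 * 80 / 200)
        assert (res.n_a, res.n_b, res.n_intersection) == (100, 100, 80)

    def test_symmetric_and_one_only_when_identical(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            a = rng.random((8, 8, 8)) < 0.4
            b = rng.random((8, 8, 8)) < 0.4
            if not (a.any() or b.any()):
                continue
            d1, d2 = dice_kappa(a, b), dice_kappa(b, a)
            assert d1.value == d2.value
            expected = 2 * (a & b).sum() / (a.sum() + b.sum())
            assert d1.value == pytest.approx(expected, rel=1e-15)
            if d1.value == 1.0:
                assert np.array_equal(a, b)

    def test_both_empty_rejected(self):
        with pytest.raises(ValueError, match="both masks empty"):
            dice_kappa(np.zeros((4, 4, 4), bool), np.zeros((4, 4, 4), bool))


def _icc_oracle(x, model, measures):
    """From-scratch ANOVA via explicit python-loop summation."""
    n, k = x.shape
    grand = sum(x[i, j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(x[i, j] for j in range(k)) / k for i in range(n)]
    col = [sum(x[i, j] for i in range(n)) / n for j in range(k)]
    ssb = k * sum((r - grand) ** 2 for r in row)
    ssw = sum((x[i, j] - row[i]) ** 2 for i in range(n) for j in range(k))
    ssc = n * sum((c - grand) ** 2 for c in col)
    sst = sum((x[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    msb = ssb / (n - 1)
    msw = ssw / (n * (k - 1))
    msc = ssc / (k - 1)
    mse = (sst - ssb - ssc) / ((n - 1) * (k - 1))
    if model == "oneway":
        if measures == "single":
            return (msb - msw) / (msb + (k - 1) * msw)
        return (msb - msw) / msb
    if model == "twoway_consistency":
        if measures == "single":
            return (msb - mse) / (msb + (k - 1) * mse)
        return (msb - mse) / msb
    if measures == "single":
        return (msb - mse) / (msb + (k - 1) * mse + k * (msc - mse) / n)
    return (msb - mse) / (msb + (msc - mse) / n)


class TestICC:
    def test_perfect_agreement(self):
        x = np.column_stack([np.arange(6.0), np.arange(6.0)])
        res = icc(x, "twoway_consistency", "average")
        assert res.estimate == pytest.approx(1.0)

    @pytest.mark.parametrize("model", ["oneway", "twoway_consistency", "twoway_agreement"])
    @pytest.mark.parametrize("measures", ["single", "average"])
    def test_matches_bruteforce_anova_oracle(self, model, measures):
        rng = np.random.default_rng(8)
        for _ in range(100):
            n = rng.integers(4, 12)
            k = rng.integers(2, 5)
            x = rng.normal(0, 1, (n, k)) + rng.normal(0, 2, (n, 1)) \
                + rng.normal(0, 0.5, (1, k))
            res = icc(x, model, measures)
            assert res.estimate == pytest.approx(_icc_oracle(x, model, measures),
                                                 rel=1e-10, abs=1e-12)

    def test_consistency_average_identity_with_f(self):
        """ICC(C,k) = 1 - 1/F exactly, F = MSB/MSE."""
        rng = np.random.default_rng(9)
        for _ in range(25):
            x = rng.normal(0, 1, (8, 2)) + rng.normal(0, 2, (8, 1))
            res = icc(x, "twoway_consistency", "average")
            assert res.estimate == 1.0 - 1.0 / res.f_value

    def test_equal_dfs_for_two_raters(self):
        x = np.random.default_rng(1).normal(0, 1, (63, 2)) \
            + np.random.default_rng(2).normal(0, 3, (63, 1))
        res = icc(x, "twoway_consistency", "average")
        assert res.df1 == 62 and res.df2 == 62
        assert 0 < res.p_value < 1
        assert res.ci95_low < res.estimate < res.ci95_high

    def test_matches_pingouin_cross_check(self):
        """Independent library oracle for estimates, F, p and CI."""
        pg = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(12)
        x = rng.normal(0, 1, (10, 3)) + rng.normal(0, 2, (10, 1))
        df = pd.DataFrame({
            "t": np.repeat(np.arange(10), 3),
            "r": np.tile(np.arange(3), 10),
            "v": x.ravel(),
        })
        ref = pg.intraclass_corr(df, targets="t", raters="r", ratings="v")
        # pingouin row order: ICC1, ICC2, ICC3, ICC1k, ICC2k, ICC3k
        variants = [
            ("oneway", "single"), ("twoway_agreement", "single"),
            ("twoway_consistency", "single"),
            ("oneway", "average"), ("twoway_agreement", "average"),
            ("twoway_consistency", "average"),
        ]
        for i, (model, measures) in enumerate(variants):
            mine = icc(x, model, measures)
            assert mine.estimate == pytest.approx(ref.iloc[i]["ICC"], abs=1e-9)
            assert mine.f_value == pytest.approx(ref.iloc[i]["F"], abs=1e-9)
            assert mine.p_value == pytest.approx(ref.iloc[i]["pval"], abs=1e-12)

    def test_constant_matrix_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            icc(np.full((5, 3), 2.0))

    def test_matrix_invariants_enforced(self):
        with pytest.raises(ValueError):
            RatingMatrix(measurements=np.ones((1, 3)))
        with pytest.raises(ValueError):
            RatingMatrix(measurements=np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestPerturbMask:
    def test_magnitude_zero_is_identity(self, sphere_mask):
        out = perturb_mask(sphere_mask, 0.0, seed=5)
        assert np.array_equal(out.mask, sphere_mask)

    def test_seeded_reproducibility(self, sphere_mask):
        a = perturb_mask(sphere_mask, 1.0, seed=5)
        b = perturb_mask(sphere_mask, 1.0, seed=5)
        assert np.array_equal(a.mask, b.mask)

    def test_sphere_dice_range_at_magnitude_one(self, sphere_mask):
        """Radius-8 sphere, magnitude 1: mean Dice to original in [0.80, 0.99]."""
        vals = [dice_kappa(sphere_mask, perturb_mask(sphere_mask, 1.0, seed=s).mask).value
                for s in range(50)]
        assert 0.80 <= np.mean(vals) <= 0.99

    def test_interior_untouched(self, sphere_mask):
        from scipy import ndimage

        out = perturb_mask(sphere_mask, 1.0, seed=2).mask
        core = ndimage.binary_erosion(sphere_mask, iterations=2)
        assert (out & core).sum() == core.sum()

    def test_emptying_perturbation_rejected(self):
        tiny = np.zeros((5, 5, 5), bool)
        tiny[2, 2, 2] = True
        with pytest.raises(ValueError):
            # magnitude 2 -> the single voxel flips with certainty eventually
            for s in range(200):
                perturb_mask(tiny, 2.0, seed=s)


@pytest.fixture(scope="module")
def phantom_t2():
    g = build_geometry((16, 16, 16))
    tis = {1: TissueSpec("GM", 1000, 90), 2: TissueSpec("WM", 1000, 70)}
    acq = AcquisitionSpec(noise_sigma=0, first_echo_gain=1.0)
    vol, _ = simulate_echo_train(g, tis, acq, seed=0)
    return g, fit_t2_loglinear(vol).t2_ms


class TestPerturbationAnalysis:

    def test_magnitude_zero_reproduces_unperturbed_metric(self, phantom_t2):
        g, t2 = phantom_t2
        res = perturbation_analysis(t2, g.mask(1), g.mask(2), "GWR", [0.0],
                                    n_iter=5, seed=1)[0]
        unperturbed = compute_gwr(extract_roi(t2, g.mask(1)),
                                  extract_roi(t2, g.mask(2))).gwr
        assert res.metric_sd == 0.0
        assert res.metric_mean == pytest.approx(unperturbed, rel=1e-15)
        assert res.dice_to_original_mean == 1.0

    def test_dice_decreases_with_magnitude(self, phantom_t2):
        g, t2 = phantom_t2
        out = perturbation_analysis(t2, g.mask(1), g.mask(2), "GWR",
                                    [0.0, 0.5, 1.0], n_iter=50, seed=2)
        dices = [s.dice_to_original_mean for s in out]
        assert all(a >= b for a, b in zip(dices, dices[1:]))
        assert dices[0] > dices[-1]

    def test_gwr_stable_within_5pct_at_magnitude_one(self, phantom_t2):
        g, t2 = phantom_t2
        out = perturbation_analysis(t2, g.mask(1), g.mask(2), "GWR", [1.0],
                                    n_iter=50, seed=3)[0]
        unperturbed = 90.0 / 70.0
        assert abs(out.metric_mean - unperturbed) / unperturbed < 0.05

    def test_unknown_metric_rejected(self, phantom_t2):
        g, t2 = phantom_t2
        with pytest.raises(ValueError, match="unknown metric"):
            perturbation_analysis(t2, g.mask(1), g.mask(2), "SNR", [0.5],
                                  n_iter=5, seed=0)
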