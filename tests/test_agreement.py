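"""ICC, interpretation bands, cross-system correlation, Bland-Altman."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from pragmascore.agreement import (
    bland_altman_plot,
    bland_altman_standardized,
    classify_icc,
    correlate_systems,
    icc_two_way,
    scatter_plot,
)


def icc_oracle(x: np.ndarray) -> float:
    """Brute-force two-way ANOVA mean squares, written as plain loops."""
    n, k = x.shape
    grand = sum(x[i][j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(x[i][j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    msr = k * sum((rm - grand) ** 2 for rm in row_means) / (n - 1)
    mse = sum(
        (x[i][j] - row_means[i] - col_means[j] + grand) ** 2
        for i in range(n)
        for j in range(k)
    ) / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse)


class TestIcc:
    def test_identical_occasions_give_perfect_agreement(self):
        x = np.column_stack([[1.0, 5.0, 9.0, 2.0], [1.0, 5.0, 9.0, 2.0]])
        res = icc_two_way(x)
        assert res.icc == pytest.approx(1.0, abs=1e-12)
        assert res.band == "excellent"

    def test_constant_table_is_degenerate(self):
        res = icc_two_way(np.zeros((6, 2)))
        assert res.degenerate and res.band == "undefined"
        assert math.isnan(res.icc)

    def test_zero_between_subject_variance_is_degenerate(self):
        # occasion effects only: every subject identical
        x = np.tile([1.0, 2.0], (5, 1))
        res = icc_two_way(x)
        assert res.degenerate
        assert "between-subject" in res.reason

    @given(
        arrays(
            float,
            (6, 2),
            elements=st.floats(min_value=-10, max_value=10, allow_nan=False, width=32),
        ).filter(lambda x: np.ptp(x) > 0.1 and np.ptp(x.mean(axis=1)) > 1e-3)
    )
    def test_matches_brute_force_anova(self, x):
        res = icc_two_way(x)
        if not res.degenerate:
            assert res.icc == pytest.approx(icc_oracle(x), abs=1e-10)

    def test_matches_pingouin_consistency_icc(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(1)
        x = rng.normal(5, 2, (15, 2))
        x[:, 1] = x[:, 0] + rng.normal(0, 0.7, 15)
        res = icc_two_way(x)
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(15), 2),
                "rater": np.tile([0, 1], 15),
                "score": x.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(long, "subject", "rater", "score")
        icc_c1 = float(ref.loc[ref["Type"].isin(["ICC3", "ICC(C,1)"]), "ICC"].iloc[0])
        assert res.icc == pytest.approx(icc_c1, abs=1e-10)

    def test_consistency_icc_invariances(self):
        rng = np.random.default_rng(2)
        x = rng.normal(0, 1, (10, 2))
        base = icc_two_way(x).icc
        shifted = x.copy()
        shifted[:, 1] += 3.7  # constant shift of one occasion
        assert icc_two_way(shifted).icc == pytest.approx(base, abs=1e-12)
        assert icc_two_way(2.5 * x + 1.0).icc == pytest.approx(base, abs=1e-12)

    @pytest.mark.parametrize(
        "bad", [np.zeros((1, 2)), np.zeros((3, 1)), np.array([[1.0, np.nan], [2.0, 3.0]])]
    )
    def test_invalid_tables_rejected(self, bad):
        with pytest.raises(ValueError):
            icc_two_way(bad)


class TestClassifyIcc:
    @pytest.mark.parametrize(
        "value, band",
        [
            (-1.0, "poor"),
            (0.0, "poor"),
            (0.39, "poor"),
            (0.4, "moderate"),
            (0.5, "moderate"),
            (0.6, "good"),
            (0.79, "good"),
            (0.8, "good"),
            (0.81, "excellent"),
            (0.85, "excellent"),
            (1.0, "excellent"),
        ],
    )
    def test_band_mapping(self, value, band):
        assert classify_icc(value) == band

    def test_monotone_total_step_function(self):
        order = {"poor": 0, "moderate": 1, "good": 2, "excellent": 3}
        grid = np.linspace(-1, 1, 401)
        bands = [order[classify_icc(v)] for v in grid]
        assert bands == sorted(bands)

    @pytest.mark.parametrize("value", [-1.01, 1.2])
    def test_out_of_range_rejected(self, value):
        with pytest.raises(ValueError):
            classify_icc(value)


class TestCorrelation:
    def test_identity_gives_perfect_correlation(self):
        x = np.arange(10, dtype=float)
        res = correlate_systems(x, x)
        assert res.r == pytest.approx(1.0) and res.slope == pytest.approx(1.0)
        assert np.sign(res.r) == np.sign(res.slope)

    def test_five_point_toy_matches_product_moment_formula(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 8.0])
        y = np.array([2.0, 1.0, 5.0, 4.0, 9.0])
        res = correlate_systems(x, y)
        # textbook formula, evaluated independently
        r = float(np.sum((x - x.mean()) * (y - y.mean()))
                  / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
        assert res.r == pytest.approx(r, abs=1e-12)
        t = r * math.sqrt(3 / (1 - r**2))
        from scipy import stats

        assert res.p_value == pytest.approx(2 * stats.t.sf(abs(t), 3), abs=1e-12)

    def test_sqrt_transform_is_applied_first(self):
        x = np.array([1.0, 4.0, 9.0, 16.0])
        y = 4.0 * x  # sqrt(y) = 2 sqrt(x): linear only on the sqrt scale
        res = correlate_systems(x, y, sqrt_transform=True)
        assert res.transform_applied
        assert res.r == pytest.approx(1.0, abs=1e-12)
        assert res.slope == pytest.approx(2.0, abs=1e-12)
        raw = correlate_systems(x, y, sqrt_transform=False)
        assert not raw.transform_applied and raw.slope == pytest.approx(4.0, abs=1e-12)

    def test_degenerate_inputs_rejected(self):
        x = np.arange(5, dtype=float)
        with pytest.raises(ValueError, match="zero variance"):
            correlate_systems(x, np.ones(5))
        with pytest.raises(ValueError, match="negative"):
            correlate_systems(x - 3, x, sqrt_transform=True)
        with pytest.raises(ValueError):
            correlate_systems(x[:2], x[:2])


class TestBlandAltman:
    def test_affine_pairs_have_zero_spread(self):
        x = np.array([1.0, 3.0, 5.0, 9.0])
        res = bland_altman_standardized(x, 2 * x + 3)
        assert res.bias == pytest.approx(0.0, abs=1e-12)
        assert res.loa_high - res.loa_low == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(res.points[:, 1], 0.0, atol=1e-12)

    @given(
        arrays(
            float,
            (8, 2),
            elements=st.floats(min_value=-50, max_value=50, allow_nan=False, width=32),
        ).filter(lambda a: a[:, 0].std() > 1e-3 and a[:, 1].std() > 1e-3)
    )
    def test_bias_is_always_zero(self, pairs):
        res = bland_altman_standardized(pairs[:, 0], pairs[:, 1])
        assert abs(res.bias) < 1e-12

    def test_affine_invariance(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 1, 12), rng.normal(0, 1, 12)
        base = bland_altman_standardized(x, y)
        other = bland_altman_standardized(5 * x - 2, 0.1 * y + 40)
        assert other.loa_low == pytest.approx(base.loa_low, abs=1e-9)
        assert other.loa_high == pytest.approx(base.loa_high, abs=1e-9)
        assert np.allclose(other.points, base.points, atol=1e-9)

    def test_four_pair_hand_computation(self):
        x = np.array([1.0, 2.0, 3.0, 6.0])
        y = np.array([2.0, 1.0, 5.0, 4.0])
        res = bland_altman_standardized(x, y)
        zx = (x - x.mean()) / x.std(ddof=1)
        zy = (y - y.mean()) / y.std(ddof=1)
        diff = zx - zy
        assert res.bias == pytest.approx(diff.mean(), abs=1e-12)
        assert res.loa_low == pytest.approx(diff.mean() - 1.96 * diff.std(ddof=1), abs=1e-12)
        assert res.loa_high == pytest.approx(diff.mean() + 1.96 * diff.std(ddof=1), abs=1e-12)

    def test_constant_vector_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            bland_altman_standardized(np.ones(5), np.arange(5, dtype=float))


def test_plot_helpers_write_files(tmp_path):
    rng = np.random.default_rng(4)
    x = rng.uniform(1, 20, 30)
    y = 0.5 * x + rng.normal(0, 2, 30) + 10
    corr = correlate_systems(x, y)
    ba = bland_altman_standardized(x, y)
    scatter_plot(x, y, corr, tmp_path / "scatter.png")
    bland_altman_plot(ba, tmp_path / "ba.png", title="demo")
    assert (tmp_path / "scatter.png").stat().st_size > 0
    assert (tmp_path / "ba.png").stat().st_size > 0
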