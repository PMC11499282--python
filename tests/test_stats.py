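"""Agreement and comparison statistics against independent oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.stats import rankdata

from pedgait.stats import (
    age_group_anova,
    comfort_total,
    comfort_totals_frame,
    icc_2_1,
    icc_category,
    paired_wilcoxon,
    pearson_r,
    setting_contrast_mmrm,
)
from pedgait.synth import simulate_agreement_matrix, simulate_setting_dataset


def icc_oracle(y):
    """Brute-force two-way ANOVA sums of squares, written longhand."""
    n, k = y.shape
    grand = sum(y[i, j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(y[i, j] for j in range(k)) / k for i in range(n)]
    col = [sum(y[i, j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((r - grand) ** 2 for r in row)
    ssc = n * sum((c - grand) ** 2 for c in col)
    sse = sum(
        (y[i, j] - row[i] - col[j] + grand) ** 2 for i in range(n) for j in range(k)
    )
    msr, msc, mse = ssr / (n - 1), ssc / (k - 1), sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestICC:
    def test_identical_columns_perfect(self):
        y = np.column_stack([np.arange(5.0) + 1, np.arange(5.0) + 1])
        assert icc_2_1(y).estimate == pytest.approx(1.0)

    def test_offset_penalized_but_pearson_perfect(self):
        x = np.arange(8.0) + 1
        y = np.column_stack([x, x + 0.5])
        res = icc_2_1(y)
        r, _ = pearson_r(x, x + 0.5)
        assert res.estimate < 1.0
        assert r == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(30):
            n, k = int(rng.integers(4, 13)), int(rng.integers(2, 4))
            y = rng.normal(1, 0.3, (n, 1)) + rng.normal(0, 0.1, (1, k)) + rng.normal(0, 0.2, (n, k))
            assert icc_2_1(y).estimate == pytest.approx(icc_oracle(y), abs=1e-10)

    def test_matches_pingouin_estimate_and_ci(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        y = rng.normal(1, 0.3, (10, 1)) + rng.normal(0, 0.1, (1, 2)) + rng.normal(0, 0.2, (10, 2))
        res = icc_2_1(y)
        df = pd.DataFrame(
            {"t": np.repeat(np.arange(10), 2), "r": np.tile(np.arange(2), 10), "v": y.ravel()}
        )
        tab = pg.intraclass_corr(df, targets="t", raters="r", ratings="v")
        row = tab[tab.Type == "ICC(A,1)"].iloc[0]
        assert res.estimate == pytest.approx(row.ICC, abs=1e-10)
        lo, hi = row.CI95
        assert res.ci_low == pytest.approx(lo, abs=0.01)
        assert res.ci_high == pytest.approx(hi, abs=0.01)

    def test_constant_shift_invariance(self):
        y = simulate_agreement_matrix(10, 2, 1.0, 0.05, 0.1, seed=1)
        assert icc_2_1(y + 7.0).estimate == pytest.approx(icc_2_1(y).estimate, abs=1e-12)
        shifted = y.copy()
        shifted[:, 1] += 1.0
        assert icc_2_1(shifted).estimate < icc_2_1(y).estimate

    def test_zero_variance_degenerate(self):
        with pytest.warns(UserWarning):
            res = icc_2_1(np.full((5, 2), 3.0))
        assert res.estimate == 1.0 and res.ci_low == 1.0

    def test_ci_brackets_estimate(self):
        y = simulate_agreement_matrix(12, 2, 1.0, 0.1, 0.2, seed=5)
        res = icc_2_1(y)
        assert res.ci_low <= res.estimate <= res.ci_high

    @pytest.mark.parametrize(
        "value,expected",
        [(0.971, "excellent"), (0.578, "moderate"), (0.40, "poor"),
         (0.62, "good"), (0.748, "good"), (0.75, "excellent"), (-0.2, "poor")],
    )
    def test_benchmark_categories(self, value, expected):
        assert icc_category(value) == expected


class TestPearson:
    def test_identity_and_reflection(self):
        x = np.arange(10.0)
        assert pearson_r(x, x)[0] == pytest.approx(1.0)
        assert pearson_r(x, -x)[0] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=50), rng.normal(size=50)
        r, _ = pearson_r(x, y)
        manual = ((x - x.mean()) * (y - y.mean())).sum() / np.sqrt(
            ((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum()
        )
        assert r == pytest.approx(manual, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            pearson_r(np.ones(5), np.arange(5.0))


def wilcoxon_enumeration_oracle(x, y):
    d = x - y
    d = d[d != 0]
    ranks = rankdata(np.abs(d))
    w = ranks[d > 0].sum()
    ws = np.array(
        [sum(r for r, s in zip(ranks, signs) if s > 0)
         for signs in itertools.product([1, -1], repeat=d.size)]
    )
    p = min(1.0, 2 * min((ws <= w + 1e-12).mean(), (ws >= w - 1e-12).mean()))
    return w, p


class TestWilcoxon:
    def test_single_nonzero_pair(self):
        x = np.array([1.0, 2.0, 3.0])
        y = np.array([1.0, 2.0, 2.0])
        w, p = paired_wilcoxon(x, y)
        assert w == 1.0 and p == 1.0  # n=1: both tails equal, smallest possible

    def test_exact_matches_enumeration(self):
        rng = np.random.default_rng(2)
        checked = 0
        while checked < 40:
            n = int(rng.integers(3, 11))
            x = rng.integers(0, 6, n).astype(float)
            y = rng.integers(0, 6, n).astype(float)
            if not np.any(x != y):
                continue
            w1, p1 = paired_wilcoxon(x, y)
            w2, p2 = wilcoxon_enumeration_oracle(x, y)
            assert w1 == pytest.approx(w2)
            assert p1 == pytest.approx(p2, abs=1e-12)
            checked += 1

    def test_swap_symmetry(self):
        rng = np.random.default_rng(5)
        x, y = rng.normal(size=9), rng.normal(size=9)
        w_xy, p_xy = paired_wilcoxon(x, y)
        w_yx, p_yx = paired_wilcoxon(y, x)
        n = 9
        assert w_xy + w_yx == pytest.approx(n * (n + 1) / 2)
        assert p_xy == pytest.approx(p_yx)

    def test_large_n_close_to_scipy(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(6)
        x = rng.normal(0.3, 1, 40)
        y = rng.normal(0.0, 1, 40)
        _, p = paired_wilcoxon(x, y)
        ref = scipy_wilcoxon(x, y, correction=True, mode="approx").pvalue
        assert p == pytest.approx(ref, rel=0.05)

    def test_all_zero_differences_error(self):
        with pytest.raises(ValueError):
            paired_wilcoxon(np.ones(4), np.ones(4))


class TestSettingContrast:
    def test_null_case_difference_zero(self):
        df = simulate_setting_dataset(n_subjects=12, clinic_effect=0.0, sd_day=0.0, seed=0)
        res = setting_contrast_mmrm(df)
        assert res["difference"] == pytest.approx(0.0, abs=1e-8)
        assert res["ci_low"] <= 0.0 <= res["ci_high"]

    def test_recovers_planted_effect(self):
        df = simulate_setting_dataset(n_subjects=40, clinic_effect=0.07, seed=1)
        res = setting_contrast_mmrm(df)
        assert res["difference"] == pytest.approx(0.07, abs=0.04)
        assert res["ci_low"] <= 0.07 <= res["ci_high"]

    def test_age_covariate_minor_on_balanced_design(self):
        df = simulate_setting_dataset(n_subjects=30, clinic_effect=0.05, seed=2)
        full = setting_contrast_mmrm(df)
        no_age = df.assign(age_group="all")
        res2 = setting_contrast_mmrm(no_age)
        assert abs(full["difference"] - res2["difference"]) < full["se"]

    def test_single_setting_rejected(self):
        df = simulate_setting_dataset(n_subjects=6, seed=3)
        with pytest.raises(ValueError):
            setting_contrast_mmrm(df[df["setting"] == "at_home"])


class TestAnova:
    def test_detects_planted_group_effect(self):
        from pedgait.synth import simulate_age_group_values

        df = simulate_age_group_values(group_means=(1.0, 1.1, 1.2), sd=0.05, seed=0)
        res = age_group_anova(df)
        assert res["p"] < 0.001
        assert len(res["pairwise"]) == 3

    def test_adjustment_modes(self):
        from pedgait.synth import simulate_age_group_values

        df = simulate_age_group_values(seed=1)
        for mode in ("tukey", "bonferroni", "none"):
            res = age_group_anova(df, adjust=mode)
            assert len(res["pairwise"]) == 3
        with pytest.raises(ValueError):
            age_group_anova(df, adjust="holm")

    def test_degenerate_groups_rejected(self):
        df = pd.DataFrame({"age_group": ["a", "a", "b"], "value": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            age_group_anova(df)


class TestComfort:
    def test_extreme_sheets(self):
        assert comfort_total([4] * 10)["total"] == 40
        assert comfort_total([0] * 10)["total"] == 0

    def test_reverse_keyed_items(self):
        resp = [4] * 10
        out = comfort_total(resp, reverse_keyed=(0, 5))
        assert out["total"] == 32  # two items flip to 0

    def test_mixed_sheet_manual_oracle(self):
        resp = [3, 1, 4, 0, 2, 4, 4, 1, 3, 2]
        key = (1, 7)
        manual = sum(
            (4 - v) if i in key else v for i, v in enumerate(resp)
        )
        assert comfort_total(resp, reverse_keyed=key)["total"] == manual

    def test_missing_or_invalid_rejected(self):
        with pytest.raises(ValueError):
            comfort_total([4] * 9)
        with pytest.raises(ValueError):
            comfort_total([4] * 9 + [None])
        with pytest.raises(ValueError):
            comfort_total([5] + [0] * 9)

    def test_frame_scoring(self):
        sheet = pd.DataFrame([[4] * 10, [0] * 10])
        totals = comfort_totals_frame(sheet)
        assert list(totals) == [40, 0]
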