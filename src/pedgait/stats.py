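"""Validation and comparison statistics.

Implements the agreement and group-comparison analyses of a device
validation study: ICC(2,1) — two-way random effects, absolute agreement,
single measurement — with its F-based confidence interval and the
conventional qualitative benchmarks; Pearson correlation; the paired
Wilcoxon signed-rank test with an exact enumeration branch; a
repeated-measures mixed-model contrast of in-clinic vs at-home
measurements adjusted for age group; one-way age-group ANOVA with pairwise
comparisons; and Likert comfort-questionnaire scoring on the 0-40 scale.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sst

@dataclass(frozen=True)
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    category: str
    n: int
    k: int


def icc_category(estimate: float) -> str:
    """Qualitative agreement benchmark for an ICC estimate.

    <= 0.4 poor; 0.4-0.59 moderate; 0.6-0.74 good; 0.75-1 excellent.
    """
    if estimate > 1:
        raise ValueError("ICC estimate cannot exceed 1")
    if estimate <= 0.4:
        return "poor"
    if estimate < 0.6:
        return "moderate"
    if estimate < 0.75:
        return "good"
    return "excellent"


def _two_way_mean_squares(y: np.ndarray):
    """MSR (rows/subjects), MSC (columns/raters), MSE of the two-way layout."""
    n, k = y.shape
    grand = y.mean()
    row_means = y.mean(axis=1)
    col_means = y.mean(axis=0)
    ssr = k * np.sum((row_means - grand) ** 2)
    ssc = n * np.sum((col_means - grand) ** 2)
    sst_ = np.sum((y - grand) ** 2)
    sse = sst_ - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_2_1(table, alpha: float = 0.05) -> ICCResult:
    """ICC(2,1): two-way random effects, absolute agreement, single rater.

    ``table`` is an (n subjects x k raters) array with no missing cells.
    The confidence interval is the F-based interval for this form. A table
    with zero total variance (all cells identical) returns estimate 1 with
    a degenerate interval and a warning.
    """
    y = np.asarray(table, dtype=float)
    if y.ndim != 2:
        raise ValueError("table must be 2-D (subjects x raters)")
    n, k = y.shape
    if n < 3 or k < 2:
        raise ValueError("need at least 3 subjects and 2 raters")
    if np.any(np.isnan(y)):
        raise ValueError("missing cells are not allowed (complete-case)")

    if np.allclose(y, y.flat[0]):
        warnings.warn("zero total variance: ICC defined as 1 with degenerate CI")
        return ICCResult(1.0, 1.0, 1.0, "excellent", n, k)

    msr, msc, mse = _two_way_mean_squares(y)
    est = (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))

    # F-based interval (McGraw & Wong form for absolute agreement, single score)
    a = (k * est) / (n * (1 - est)) if est < 1 else np.inf
    b = 1 + (k * est * (n - 1)) / (n * (1 - est)) if est < 1 else np.inf
    if np.isfinite(a) and mse > 0:
        v_num = (a * msc + b * mse) ** 2
        v_den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        v = v_num / v_den
        f_l = sst.f.ppf(1 - alpha / 2, n - 1, v)
        f_u = sst.f.ppf(1 - alpha / 2, v, n - 1)
        lo = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
        hi = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)
    else:
        lo = hi = est
    return ICCResult(float(est), float(lo), float(hi), icc_category(float(est)), n, k)


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with the two-sided t-transform p value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need equal-length samples of size >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance input")
    r, p = sst.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# paired Wilcoxon signed rank
# ---------------------------------------------------------------------------

def _signed_rank_statistic(d: np.ndarray):
    """(W+, doubled integer ranks) on nonzero differences, ties mid-ranked."""
    d = d[d != 0]
    ranks = sst.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    ranks2 = np.rint(2 * ranks).astype(int)  # doubled mid-ranks are integers
    return w_pos, ranks2


def _exact_sf_table(ranks2: np.ndarray) -> np.ndarray:
    """Distribution of 2*W+ over all sign assignments via generating function."""
    total = int(ranks2.sum())
    counts = np.zeros(total + 1)
    counts[0] = 1.0
    for r in ranks2:
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[: counts.size - r]
        counts = counts + shifted
    return counts  # index = 2*W+, value = number of assignments


def paired_wilcoxon(x, y, exact_limit: int = 12) -> tuple[float, float]:
    """Paired Wilcoxon signed-rank test of x vs y (two-sided).

    Zero differences are dropped; ties in |d| get mid-ranks. With at most
    ``exact_limit`` nonzero pairs the null distribution of W+ is obtained
    exactly from the sign-flip generating function (valid under ties);
    otherwise a normal approximation with tie correction and continuity
    correction is used. Returns (W+, p).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all differences are zero")
    w_pos, ranks2 = _signed_rank_statistic(d)

    if n <= exact_limit:
        counts = _exact_sf_table(ranks2)
        total = counts.sum()
        w2 = int(round(2 * w_pos))
        p_le = counts[: w2 + 1].sum() / total
        p_ge = counts[w2:].sum() / total
        p = min(1.0, 2.0 * min(p_le, p_ge))
        return w_pos, float(p)

    mean = n * (n + 1) / 4.0
    ranks = ranks2 / 2.0
    var = np.sum(ranks**2) / 4.0  # equals n(n+1)(2n+1)/24 - tie correction
    if var == 0:
        raise ValueError("degenerate rank variance")
    z = (w_pos - mean - 0.5 * np.sign(w_pos - mean)) / math.sqrt(var)
    p = 2.0 * sst.norm.sf(abs(z))
    return w_pos, float(min(1.0, p))


# ---------------------------------------------------------------------------
# setting contrast (MMRM) and age-group ANOVA
# ---------------------------------------------------------------------------

def setting_contrast_mmrm(data: pd.DataFrame, value_col: str = "value",
                          alpha: float = 0.05) -> dict:
    """In-clinic minus at-home contrast from a random-intercept mixed model.

    ``data`` is long format with columns ``subject``, ``setting``
    ('in_clinic' / 'at_home'), ``age_group`` and the outcome. The model has
    fixed effects for setting and age group and a subject-level random
    intercept, fitted by REML; the contrast carries a Wald CI.
    """
    import statsmodels.formula.api as smf

    settings = set(data["setting"].unique())
    if settings != {"in_clinic", "at_home"}:
        raise ValueError("both settings must be present")
    counts = data.groupby("subject")["setting"].nunique()
    if (counts == 2).sum() < 3:
        raise ValueError("need both settings for at least 3 subjects")

    df = data.copy()
    df["setting"] = pd.Categorical(df["setting"], categories=["at_home", "in_clinic"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(f"{value_col} ~ setting + C(age_group)", df, groups=df["subject"])
        fit = model.fit(reml=True)
    name = "setting[T.in_clinic]"
    est = float(fit.params[name])
    se = float(fit.bse[name])
    # t reference with between-within df (standard small-sample MMRM practice);
    # the plain normal Wald interval under-covers at typical cohort sizes
    n_subjects = df["subject"].nunique()
    dof = max(n_subjects - fit.k_fe, 1)
    q = sst.t.ppf(1 - alpha / 2, dof)
    p = float(2 * sst.t.sf(abs(est / se), dof))
    return {"difference": est, "ci_low": est - q * se, "ci_high": est + q * se,
            "se": se, "p": p, "df": dof}


def age_group_anova(data: pd.DataFrame, value_col: str = "value",
                    adjust: str = "tukey") -> dict:
    """One-way ANOVA of per-subject summaries across age groups.

    Returns the F test plus all pairwise comparisons; multiplicity
    adjustment is 'tukey' (default), 'bonferroni' or 'none'.
    """
    groups = [g[value_col].to_numpy() for _, g in data.groupby("age_group")]
    if len(groups) < 2 or any(len(g) < 2 for g in groups):
        raise ValueError("need >= 2 groups with >= 2 subjects each")
    f, p = sst.f_oneway(*groups)

    pairs = []
    if adjust == "tukey":
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        res = pairwise_tukeyhsd(data[value_col].to_numpy(), data["age_group"].to_numpy())
        for row in res.summary().data[1:]:
            pairs.append({"group1": str(row[0]), "group2": str(row[1]),
                          "diff": float(row[2]), "p": float(row[3])})
    elif adjust in ("bonferroni", "none"):
        keys = sorted(data["age_group"].unique())
        raw = []
        for i in range(len(keys)):
            for j in range(i + 1, len(keys)):
                a = data.loc[data["age_group"] == keys[i], value_col]
                b = data.loc[data["age_group"] == keys[j], value_col]
                t, pp = sst.ttest_ind(a, b)
                raw.append((keys[i], keys[j], float(a.mean() - b.mean()), float(pp)))
        m = len(raw)
        for g1, g2, diff, pp in raw:
            adj = min(1.0, pp * m) if adjust == "bonferroni" else pp
            pairs.append({"group1": g1, "group2": g2, "diff": diff, "p": adj})
    else:
        raise ValueError("adjust must be 'tukey', 'bonferroni' or 'none'")
    return {"F": float(f), "p": float(p), "pairwise": pairs}


# ---------------------------------------------------------------------------
# comfort questionnaire scoring
# ---------------------------------------------------------------------------

def comfort_total(responses, reverse_keyed: tuple = ()) -> dict:
    """Score a 10-item Likert sheet onto the 0-40 comfort scale.

    ``responses`` holds 10 integers in 0-4 (0 = strongly disagree). Items
    listed in ``reverse_keyed`` (0-based positions) are negatively worded
    and scored 4 - level; 40 is the best comfortability, 0 the worst.
    """
    arr = np.asarray(responses)
    if arr.shape != (10,):
        raise ValueError("exactly 10 items required")
    if np.any(pd.isna(arr)):
        raise ValueError("missing item response")
    arr = arr.astype(int)
    if arr.min() < 0 or arr.max() > 4:
        raise ValueError("item levels must be in 0..4")
    scores = arr.copy()
    for i in reverse_keyed:
        scores[i] = 4 - scores[i]
    return {"item_scores": scores.tolist(), "total": int(scores.sum())}


def comfort_totals_frame(sheet: pd.DataFrame, reverse_keyed: tuple = ()) -> pd.Series:
    """Total comfort score per subject for a (subjects x 10 items) sheet."""
    return sheet.apply(lambda row: comfort_total(row.to_numpy(), reverse_keyed)["total"], axis=1)
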