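"""Psychometric and brain-behavior statistics.

Covers the full decision machinery of the behavioral analysis: emotion
confusion matrices per naturalness level, repeated-measures omnibus tests
with the normality/sphericity decision path (RM-ANOVA with
Greenhouse-Geisser vs Friedman, Tukey vs Conover-Holm post-hocs), paired
contrasts (t vs Wilcoxon on Shapiro-Wilk of the differences), Spearman
correlation between single-trial fractal dimension and block ratings,
LOO-cross-validated smoothing-spline regression, and the Monte-Carlo
a-priori power analysis for the within-subject design.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import make_smoothing_spline
from statsmodels.stats.multitest import multipletests

from .editing import EMOTIONS, LEVELS
from .errors import DataError, DegenerateInputError, DesignError

__all__ = [
    "RATINGS_COLUMNS",
    "validate_ratings",
    "ConfusionMatrix",
    "confusion_metrics",
    "TestReport",
    "omnibus_repeated_test",
    "paired_contrast",
    "correlate_hfd_ratings",
    "SplineFit",
    "smoothing_spline_fit",
    "min_sample_size_power",
]

RATINGS_COLUMNS = (
    "subject block emotion level naturalness intelligibility valence "
    "arousal chosen_emotion"
).split()


def validate_ratings(df: pd.DataFrame) -> pd.DataFrame:
    """Check the ratings-table schema and scale bounds."""
    missing = set(RATINGS_COLUMNS) - set(df.columns)
    if missing:
        raise DataError(f"missing rating columns: {sorted(missing)}")
    bad = set(df["chosen_emotion"]) - set(EMOTIONS)
    if bad:
        raise DataError(f"unknown emotion labels: {sorted(bad)}")
    bad = set(df["emotion"]) - set(EMOTIONS)
    if bad:
        raise DataError(f"unknown target emotions: {sorted(bad)}")
    for col, lo, hi in (
        ("naturalness", 1, 5),
        ("intelligibility", 1, 5),
        ("valence", 1, 9),
        ("arousal", 1, 9),
    ):
        v = df[col]
        if (v < lo).any() or (v > hi).any():
            raise DataError(f"{col} outside the {lo}-{hi} scale")
    if df.duplicated(subset=["subject", "block"]).any():
        raise DataError("more than one rating row per subject x block")
    return df


# --------------------------------------------------------------------------
# confusion matrices
# --------------------------------------------------------------------------

@dataclass
class ConfusionMatrix:
    """Predicted x target emotion counts with the derived percentages."""

    counts: pd.DataFrame  # rows = predicted, columns = target
    precision: pd.Series  # % per predicted class
    recall: pd.Series  # % per target class
    false_discovery: pd.Series
    false_negative: pd.Series
    accuracy: float  # %

    @property
    def level_names(self):
        return list(self.counts.columns)


def confusion_metrics(
    ratings: pd.DataFrame, level: str, require_all_targets: bool = True
) -> ConfusionMatrix:
    """Emotion-recognition confusion matrix for one naturalness level.

    precision + false-discovery = 100 % per predicted class,
    recall + false-negative = 100 % per target class,
    accuracy = trace / total.  With `require_all_targets` an emotion
    without any rating is a data error; otherwise its row/column stays
    zero (percentages 0).
    """
    if level not in LEVELS:
        raise DataError(f"unknown level {level!r}")
    sub = ratings[ratings["level"] == level]
    bad = (set(sub["chosen_emotion"]) | set(sub["emotion"])) - set(EMOTIONS)
    if bad:
        raise DataError(f"unknown emotion labels {sorted(bad)}")
    empty = [e for e in EMOTIONS if (sub["emotion"] == e).sum() == 0]
    if empty and require_all_targets:
        raise DataError(f"no ratings for target emotion(s) {empty}")
    counts = pd.crosstab(sub["chosen_emotion"], sub["emotion"]).reindex(
        index=list(EMOTIONS), columns=list(EMOTIONS), fill_value=0
    )
    diag = pd.Series(np.diag(counts), index=list(EMOTIONS), dtype=float)
    row = counts.sum(axis=1).astype(float)
    col = counts.sum(axis=0).astype(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        precision = (100.0 * diag / row).fillna(0.0)
        recall = (100.0 * diag / col).fillna(0.0)
    return ConfusionMatrix(
        counts=counts,
        precision=precision,
        recall=recall,
        false_discovery=100.0 - precision,
        false_negative=100.0 - recall,
        accuracy=float(100.0 * diag.sum() / counts.to_numpy().sum()),
    )


# --------------------------------------------------------------------------
# omnibus repeated-measures test
# --------------------------------------------------------------------------

@dataclass
class TestReport:
    """Outcome of a decision-path statistical test."""

    branch: str  # which test actually ran
    statistic: float
    df: tuple
    p: float
    effect_size: float | None = None
    effect_size_name: str | None = None
    posthoc: pd.DataFrame | None = None
    details: dict = field(default_factory=dict)


def _additive_residuals(wide: np.ndarray) -> np.ndarray:
    """Residuals of the subject + condition additive model."""
    grand = wide.mean()
    return wide - wide.mean(axis=1, keepdims=True) - wide.mean(axis=0, keepdims=True) + grand


def _tukey_posthoc(wide: np.ndarray, names, ms_error: float, df_error: int) -> pd.DataFrame:
    n, k = wide.shape
    means = wide.mean(axis=0)
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            q = abs(means[i] - means[j]) / np.sqrt(ms_error / n)
            p = float(stats.studentized_range.sf(q, k, df_error))
            rows.append({"A": names[i], "B": names[j], "statistic": q, "p": p})
    return pd.DataFrame(rows)


def _conover_posthoc(wide: np.ndarray, names) -> pd.DataFrame:
    """Conover's post-hoc after Friedman, Holm-adjusted p-values."""
    n, k = wide.shape
    ranks = stats.rankdata(wide, axis=1)
    rsum = ranks.sum(axis=0)
    a1 = float((ranks**2).sum())
    c1 = n * k * (k + 1) ** 2 / 4.0
    df = (n - 1) * (k - 1)
    denom = np.sqrt(2.0 * n * (a1 - c1) / df) if a1 > c1 else np.nan
    rows = []
    for i in range(k):
        for j in range(i + 1, k):
            t = abs(rsum[i] - rsum[j]) / denom if denom and np.isfinite(denom) else 0.0
            p = float(2 * stats.t.sf(t, df)) if np.isfinite(t) else 1.0
            rows.append({"A": names[i], "B": names[j], "statistic": t, "p": p})
    out = pd.DataFrame(rows)
    out["p_holm"] = multipletests(out["p"], method="holm")[1]
    return out


def rm_anova_f(wide: np.ndarray):
    """First-principles one-way repeated-measures ANOVA.

    Returns (F, df_cond, df_error, ms_error, generalized eta squared).
    """
    n, k = wide.shape
    grand = wide.mean()
    ss_cond = n * np.sum((wide.mean(axis=0) - grand) ** 2)
    ss_subj = k * np.sum((wide.mean(axis=1) - grand) ** 2)
    ss_tot = np.sum((wide - grand) ** 2)
    ss_err = ss_tot - ss_cond - ss_subj
    df_c, df_e = k - 1, (n - 1) * (k - 1)
    ms_err = ss_err / df_e
    if ms_err > 0:
        f = (ss_cond / df_c) / ms_err
    else:
        f = 0.0 if ss_cond <= 1e-12 else np.inf
    denom = ss_cond + ss_subj + ss_err
    ges = ss_cond / denom if denom > 0 else 0.0
    return f, df_c, df_e, ms_err, ges


def omnibus_repeated_test(
    table: pd.DataFrame, alpha: float = 0.05
) -> TestReport:
    """Within-subject omnibus test over a subject x condition table.

    Decision path: Shapiro-Wilk on the additive-model residuals decides
    RM-ANOVA vs Friedman; under RM-ANOVA, Mauchly's test decides whether
    the Greenhouse-Geisser correction applies; post-hocs are Tukey
    (studentized range on the RM error term) after ANOVA and
    Conover-Holm after Friedman.  Missing cells are a design error.
    """
    if table.isna().any().any():
        raise DesignError("missing cells; repeated-measures design must be complete")
    wide = table.to_numpy(dtype=float)
    n, k = wide.shape
    if n < 3 or k < 2:
        raise DesignError("need >= 3 subjects and >= 2 conditions")
    names = list(table.columns)
    if np.max(np.ptp(wide, axis=1)) == 0:
        # every subject rated all conditions identically: no effect
        return TestReport(
            branch="rm_anova", statistic=0.0, df=(k - 1, (n - 1) * (k - 1)),
            p=1.0, effect_size=0.0, effect_size_name="ng2",
            posthoc=None, details={"degenerate": True},
        )
    resid = _additive_residuals(wide)
    if np.ptp(resid) < 1e-12 * max(1.0, np.ptp(wide)):
        norm_p = 1.0  # additive table: no evidence against normality
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            norm_p = float(stats.shapiro(resid.ravel()).pvalue)

    if norm_p < alpha:
        import pingouin as pg

        long = table.reset_index(names="subject").melt(
            id_vars="subject", var_name="condition", value_name="y"
        )
        fr = pg.friedman(data=long, dv="y", within="condition",
                         subject="subject", method="chisq")
        q = float(fr["Q"].iloc[0])
        p = float(fr["p_unc"].iloc[0])
        w = float(fr["W"].iloc[0])
        return TestReport(
            branch="friedman",
            statistic=q,
            df=(k - 1,),
            p=p,
            effect_size=w,
            effect_size_name="kendall_w",
            posthoc=_conover_posthoc(wide, names),
            details={"normality_p": norm_p},
        )

    f, df_c, df_e, ms_err, ges = rm_anova_f(wide)
    if ms_err <= 0 or f == 0.0:
        # identical conditions (or an error-free additive table): no
        # evidence of a condition effect; sphericity is moot
        return TestReport(
            branch="rm_anova", statistic=float(f), df=(df_c, df_e),
            p=1.0 if f == 0.0 else 0.0,
            effect_size=ges, effect_size_name="ng2",
            posthoc=None, details={"normality_p": norm_p},
        )
    import pingouin as pg

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        spher = pg.sphericity(table)
        mauchly_w, mauchly_p = float(spher.W), float(spher.pval)
        eps = float(pg.epsilon(table, correction="gg"))
    if mauchly_p < alpha and k > 2:
        p = float(stats.f.sf(f, df_c * eps, df_e * eps))
        corrected = True
    else:
        p = float(stats.f.sf(f, df_c, df_e))
        corrected = False
    return TestReport(
        branch="rm_anova",
        statistic=f,
        df=(df_c, df_e),
        p=p,
        effect_size=ges,
        effect_size_name="ng2",
        posthoc=_tukey_posthoc(wide, names, ms_err, df_e),
        details={
            "normality_p": norm_p,
            "mauchly_w": mauchly_w,
            "mauchly_p": mauchly_p,
            "gg_epsilon": eps,
            "gg_corrected": corrected,
        },
    )


def paired_contrast(a, b, alpha: float = 0.05) -> TestReport:
    """Paired comparison: t-test, or Wilcoxon when differences deviate
    from normality (Shapiro-Wilk), with the degenerate all-equal path
    reported as t = 0, p = 1."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise DesignError("paired samples must be 1-D and equally long")
    if a.size < 3:
        raise DesignError("need >= 3 pairs")
    d = a - b
    if np.all(d == 0):
        return TestReport(branch="ttest", statistic=0.0, df=(a.size - 1,), p=1.0,
                          details={"degenerate": True})
    if np.ptp(d) == 0:  # constant non-zero difference: trivially significant
        return TestReport(branch="ttest", statistic=np.inf, df=(a.size - 1,), p=0.0,
                          details={"degenerate": True})
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        norm_p = float(stats.shapiro(d).pvalue)
    if norm_p < alpha:
        res = stats.wilcoxon(a, b)
        return TestReport(branch="wilcoxon", statistic=float(res.statistic),
                          df=(a.size,), p=float(res.pvalue),
                          details={"normality_p": norm_p})
    res = stats.ttest_rel(a, b)
    return TestReport(branch="ttest", statistic=float(res.statistic),
                      df=(a.size - 1,), p=float(res.pvalue),
                      details={"normality_p": norm_p})


# --------------------------------------------------------------------------
# HFD-rating correlation and spline regression
# --------------------------------------------------------------------------

def correlate_hfd_ratings(
    hfd: pd.DataFrame, ratings: pd.DataFrame, dimension: str
) -> tuple:
    """Spearman correlation between per-trial HFD and block ratings.

    `hfd` has columns (subject, block, hfd), one row per trial; the
    block-level rating of `dimension` (valence or arousal) is expanded to
    the block's trials by the merge.  Returns (rho, p).
    """
    if dimension not in ("valence", "arousal"):
        raise ValueError("dimension must be valence or arousal")
    merged = hfd.merge(
        ratings[["subject", "block", dimension]], on=["subject", "block"], how="inner"
    )
    if len(merged) < 10:
        raise DesignError("need >= 10 HFD/rating pairs")
    x = merged["hfd"].to_numpy()
    y = merged[dimension].to_numpy()
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise DegenerateInputError("constant input: correlation undefined")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


@dataclass
class SplineFit:
    spline: object
    lam: float
    rmse: float  # LOO-CV root mean squared error at the chosen smoothing
    r2: float  # of the final fit

    def __call__(self, x):
        return self.spline(x)


def _collapse_duplicates(x: np.ndarray, y: np.ndarray):
    """Group duplicate abscissae: unique x, group means, counts."""
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    ux, inv = np.unique(xs, return_inverse=True)
    sums = np.bincount(inv, weights=ys)
    counts = np.bincount(inv)
    return ux, sums / counts, counts.astype(float), order, inv


def _fit_spline(ux, uy, w, lam):
    return make_smoothing_spline(ux, uy, w=w, lam=lam)


def smoothing_spline_fit(
    x, y, lambdas: np.ndarray | None = None
) -> SplineFit:
    """Cubic smoothing spline with exact leave-one-out CV smoothing choice.

    The smoothing parameter minimizing the LOO-CV RMSE over a log-spaced
    grid is selected; duplicate abscissae are handled by weighted fitting
    on the group means (equivalent for the penalized criterion).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 10:
        raise DesignError("need >= 10 (x, y) points")
    if np.ptp(x) == 0:
        raise DesignError("degenerate x: all abscissae equal")
    ux, uy, w, order, inv = _collapse_duplicates(x, y)
    if ux.size < 4:
        raise DesignError("need >= 4 distinct abscissae for a cubic spline")
    if lambdas is None:
        scale = np.ptp(ux) ** 3  # natural units of the roughness penalty
        lambdas = scale * np.logspace(-8, 2, 13)
    xs, ys = x[order], y[order]

    def loo_rmse(lam: float) -> float:
        err2 = 0.0
        for i in range(xs.size):
            g = inv[i]
            w2 = w.copy()
            uy2 = uy.copy()
            if w[g] > 1:
                w2[g] = w[g] - 1
                uy2[g] = (uy[g] * w[g] - ys[i]) / (w[g] - 1)
                spl = _fit_spline(ux, uy2, w2, lam)
            else:
                keep = np.arange(ux.size) != g
                if keep.sum() < 4:
                    return np.inf
                spl = _fit_spline(ux[keep], uy2[keep], w2[keep], lam)
            err2 += (float(spl(xs[i])) - ys[i]) ** 2
        return float(np.sqrt(err2 / xs.size))

    rmses = np.array([loo_rmse(l) for l in lambdas])
    best = int(np.argmin(rmses))
    lam = float(lambdas[best])
    spl = _fit_spline(ux, uy, w, lam)
    pred = spl(x)
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return SplineFit(spline=spl, lam=lam, rmse=float(rmses[best]), r2=r2)


# --------------------------------------------------------------------------
# a-priori power analysis
# --------------------------------------------------------------------------

def _simulated_power(
    means: np.ndarray, sd: float, rho: float, n: int, alpha: float,
    reps: int, rng,
) -> float:
    """Monte-Carlo power of the within-subject omnibus F for n subjects."""
    k = means.size
    subj = rng.standard_normal((reps, n, 1)) * (sd * np.sqrt(rho))
    eps = rng.standard_normal((reps, n, k)) * (sd * np.sqrt(1.0 - rho))
    y = means[None, None, :] + subj + eps
    grand = y.mean(axis=(1, 2), keepdims=True)
    cond_m = y.mean(axis=1, keepdims=True)
    subj_m = y.mean(axis=2, keepdims=True)
    ss_cond = n * ((cond_m - grand) ** 2).sum(axis=(1, 2))
    ss_err = ((y - cond_m - subj_m + grand) ** 2).sum(axis=(1, 2))
    df_c, df_e = k - 1, (n - 1) * (k - 1)
    f = (ss_cond / df_c) / (ss_err / df_e)
    crit = stats.f.isf(alpha, df_c, df_e)
    return float(np.mean(f > crit))


def min_sample_size_power(
    means,
    sd: float,
    rho: float,
    target_power: float = 0.9,
    alpha: float = 0.05,
    reps: int = 2000,
    seed: int = 0,
    n_max: int = 200,
) -> dict:
    """Smallest number of subjects reaching the target power.

    Subjects are simulated from a multivariate normal with the given
    condition means, common SD and compound-symmetry correlation `rho`;
    the decision rule is the within-subject omnibus F at `alpha`.  Binary
    search over n; returns a dict with n, the power estimates per probed
    n, and the settings.
    """
    means = np.asarray(means, dtype=float)
    if means.size < 2:
        raise DesignError("need >= 2 condition means")
    if sd <= 0 or not (0 <= rho < 1):
        raise DesignError("need sd > 0 and 0 <= rho < 1")
    if np.ptp(means) == 0 and target_power > alpha:
        raise DesignError("no finite n: condition means are all equal")
    rng = np.random.default_rng(seed)
    if target_power <= alpha:
        return {"n": 2, "powers": {}, "reps": reps, "seed": seed}

    powers: dict = {}

    def power(n: int) -> float:
        if n not in powers:
            powers[n] = _simulated_power(means, sd, rho, n, alpha, reps, rng)
        return powers[n]

    lo, hi = 2, 4
    while power(hi) < target_power:
        lo, hi = hi, hi * 2
        if hi > n_max:
            raise DesignError(f"target power not reached by n = {n_max}")
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if power(mid) >= target_power:
            hi = mid
        else:
            lo = mid
    return {"n": hi, "powers": powers, "reps": reps, "seed": seed}
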