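import numpy as np
import pandas as pd
import pytest
from scipy import stats

from voxnat.behavioral import (
    confusion_metrics,
    correlate_hfd_ratings,
    min_sample_size_power,
    omnibus_repeated_test,
    paired_contrast,
    rm_anova_f,
    smoothing_spline_fit,
    validate_ratings,
)
from voxnat.editing import EMOTIONS
from voxnat.errors import DataError, DegenerateInputError, DesignError


def rating_row(i, emotion, chosen, level="human", valence=5, arousal=5):
    return dict(subject=i, block=i, emotion=emotion, level=level, naturalness=4,
                intelligibility=4, valence=valence, arousal=arousal,
                chosen_emotion=chosen)


# --------------------------------------------------------------------------
# confusion matrices
# --------------------------------------------------------------------------

def test_perfect_recognition_is_identity():
    rows = [rating_row(i * 6 + j, e, e) for i in range(3) for j, e in enumerate(EMOTIONS)]
    cm = confusion_metrics(pd.DataFrame(rows), "human")
    assert cm.accuracy == 100.0
    assert (cm.precision == 100.0).all()
    assert (cm.recall == 100.0).all()
    np.testing.assert_array_equal(np.diag(cm.counts), 3)


def test_confusion_toy_two_classes():
    rows = []
    rows += [rating_row(len(rows) + k, "anger", "anger") for k in range(15)]
    rows += [rating_row(100 + len(rows), "anger", "disgust") for _ in range(5)]
    rows += [rating_row(200 + len(rows), "disgust", "disgust") for _ in range(18)]
    rows += [rating_row(300 + len(rows), "disgust", "anger") for _ in range(2)]
    cm = confusion_metrics(pd.DataFrame(rows), "human", require_all_targets=False)
    assert cm.precision["anger"] == pytest.approx(100 * 15 / 17, abs=0.1)
    assert cm.recall["anger"] == pytest.approx(75.0)
    assert cm.accuracy == pytest.approx(82.5)


def test_confusion_identities_on_random_tables(rng):
    for _ in range(20):
        rows = [
            rating_row(i, rng.choice(EMOTIONS), rng.choice(EMOTIONS))
            for i in range(60)
        ]
        cm = confusion_metrics(pd.DataFrame(rows), "human", require_all_targets=False)
        np.testing.assert_allclose(cm.precision + cm.false_discovery, 100.0)
        np.testing.assert_allclose(cm.recall + cm.false_negative, 100.0)
        assert cm.accuracy == pytest.approx(
            100.0 * np.trace(cm.counts) / cm.counts.to_numpy().sum()
        )


def test_confusion_empty_target_class_rejected():
    rows = [rating_row(i, "anger", "anger") for i in range(5)]
    with pytest.raises(DataError):
        confusion_metrics(pd.DataFrame(rows), "human")


def test_validate_ratings_rejects_out_of_scale():
    rows = [rating_row(0, "anger", "anger", valence=11)]
    with pytest.raises(DataError):
        validate_ratings(pd.DataFrame(rows))


# --------------------------------------------------------------------------
# omnibus repeated-measures test
# --------------------------------------------------------------------------

def test_identical_conditions_null(rng):
    tab = pd.DataFrame(np.tile(rng.normal(0, 1, (8, 1)), (1, 3)), columns=list("abc"))
    rep = omnibus_repeated_test(tab)
    assert rep.p == 1.0
    assert rep.effect_size == 0.0


def test_rm_anova_matches_pingouin_oracle(rng):
    import pingouin as pg

    for _ in range(25):
        n, k = rng.integers(6, 15), rng.integers(2, 5)
        tab = pd.DataFrame(
            rng.normal(0, 1, (n, k)) + rng.normal(0, 0.5, k)[None, :],
            columns=[f"c{j}" for j in range(k)],
        )
        f_own, df_c, df_e, _, ges_own = rm_anova_f(tab.to_numpy())
        long = tab.reset_index(names="s").melt(id_vars="s", var_name="c", value_name="y")
        res = pg.rm_anova(data=long, dv="y", within="c", subject="s", detailed=True,
                          effsize="ng2")
        assert f_own == pytest.approx(float(res["F"].iloc[0]), abs=1e-8)
        assert ges_own == pytest.approx(float(res["ng2"].iloc[0]), abs=1e-8)


def test_omnibus_friedman_branch(rng):
    base = rng.normal(0, 1, (12, 3))
    base[::3] += rng.exponential(8, (4, 3)) * np.array([1, -1, 1])
    tab = pd.DataFrame(base + [[0, 1, 2]], columns=list("abc"))
    rep = omnibus_repeated_test(tab)
    assert rep.branch == "friedman"
    assert rep.effect_size_name == "kendall_w"
    assert {"A", "B", "statistic", "p", "p_holm"} <= set(rep.posthoc.columns)
    q, p = stats.friedmanchisquare(*(tab[c] for c in tab.columns))
    assert rep.statistic == pytest.approx(q, abs=1e-8)
    assert rep.p == pytest.approx(p, abs=1e-8)


def test_omnibus_anova_branch_posthoc(rng):
    tab = pd.DataFrame(
        rng.normal([[0.0, 0.8, 1.6]], 1.0, (12, 3)), columns=list("abc")
    )
    rep = omnibus_repeated_test(tab)
    assert rep.branch == "rm_anova"
    assert rep.posthoc is not None and len(rep.posthoc) == 3
    assert rep.details["mauchly_p"] >= 0.0


def test_omnibus_missing_cells_rejected(rng):
    tab = pd.DataFrame(rng.normal(0, 1, (6, 3)), columns=list("abc"))
    tab.iloc[2, 1] = np.nan
    with pytest.raises(DesignError):
        omnibus_repeated_test(tab)


# --------------------------------------------------------------------------
# paired contrasts
# --------------------------------------------------------------------------

def test_paired_equal_samples_degenerate(rng):
    a = rng.normal(0, 1, 8)
    rep = paired_contrast(a, a)
    assert rep.statistic == 0.0 and rep.p == 1.0


def test_paired_t_matches_hand_formula(rng):
    a = rng.normal(0, 1, 6)
    d = rng.normal(0.5, 1, 6)
    rep = paired_contrast(a + d, a)
    hand = np.mean(d) / (np.std(d, ddof=1) / np.sqrt(6))
    assert rep.branch == "ttest"
    assert rep.statistic == pytest.approx(hand, abs=1e-10)


def test_paired_wilcoxon_branch(rng):
    a = rng.normal(0, 1, 30)
    d = np.exp(rng.normal(0, 1.5, 30))  # heavily skewed differences
    rep = paired_contrast(a + d, a)
    assert rep.branch == "wilcoxon"
    v = stats.wilcoxon(a + d, a).statistic
    assert rep.statistic == pytest.approx(v)


def test_paired_length_mismatch(rng):
    with pytest.raises(DesignError):
        paired_contrast(rng.normal(0, 1, 5), rng.normal(0, 1, 6))


# --------------------------------------------------------------------------
# Spearman HFD-rating correlation
# --------------------------------------------------------------------------

def hfd_frame(values):
    return pd.DataFrame(
        {"subject": 0, "block": np.arange(len(values)), "hfd": values}
    )


def ratings_frame(valence):
    rows = [
        rating_row(0, "anger", "anger", valence=v) for v in valence
    ]
    df = pd.DataFrame(rows)
    df["block"] = np.arange(len(valence))
    return df


def test_spearman_perfect_monotone():
    vals = np.arange(12, dtype=float)
    rho, _ = correlate_hfd_ratings(hfd_frame(vals), ratings_frame((vals % 9) + 1), "valence")
    # hfd strictly increasing, valence increasing with wrap: use clean case
    rho, _ = correlate_hfd_ratings(hfd_frame(vals), ratings_frame(np.linspace(1, 9, 12)), "valence")
    assert rho == pytest.approx(1.0)
    rho, _ = correlate_hfd_ratings(hfd_frame(vals[::-1]), ratings_frame(np.linspace(1, 9, 12)), "valence")
    assert rho == pytest.approx(-1.0)


def test_spearman_monotone_transform_invariance(rng):
    vals = rng.normal(0, 1, 20)
    val_r = np.clip(np.round(rng.uniform(1, 9, 20)), 1, 9)
    r1, _ = correlate_hfd_ratings(hfd_frame(vals), ratings_frame(val_r), "valence")
    r2, _ = correlate_hfd_ratings(hfd_frame(np.exp(vals)), ratings_frame(val_r), "valence")
    assert r1 == pytest.approx(r2, abs=1e-12)


def test_spearman_constant_rejected():
    with pytest.raises(DegenerateInputError):
        correlate_hfd_ratings(hfd_frame(np.ones(12)), ratings_frame(np.linspace(1, 9, 12)), "valence")


# --------------------------------------------------------------------------
# smoothing splines
# --------------------------------------------------------------------------

def test_spline_noise_free_line(rng):
    x = np.linspace(0, 10, 60)
    fit = smoothing_spline_fit(x, 2 * x + 1)
    assert fit.rmse < 1e-6
    np.testing.assert_allclose(fit(x), 2 * x + 1, atol=1e-6)


def test_spline_matches_brute_force_loo(rng):
    x = np.linspace(0, 10, 60)
    y = np.sin(x) + rng.normal(0, 0.3, 60)
    fit = smoothing_spline_fit(x, y)
    # independent brute-force LOO scan over the same grid
    from scipy.interpolate import make_smoothing_spline

    lambdas = np.ptp(x) ** 3 * np.logspace(-8, 2, 13)
    best_rmse = np.inf
    best_lam = None
    for lam in lambdas:
        errs = []
        for i in range(x.size):
            keep = np.arange(x.size) != i
            spl = make_smoothing_spline(x[keep], y[keep], lam=lam)
            errs.append((float(spl(x[i])) - y[i]) ** 2)
        rmse = np.sqrt(np.mean(errs))
        if rmse < best_rmse:
            best_rmse, best_lam = rmse, lam
    idx_sel = int(np.argmin(np.abs(lambdas - fit.lam)))
    idx_best = int(np.argmin(np.abs(lambdas - best_lam)))
    assert abs(idx_sel - idx_best) <= 1
    assert fit.rmse == pytest.approx(best_rmse, rel=0.05)


def test_spline_infinite_smoothing_is_ols_line(rng):
    x = np.linspace(0, 10, 80)
    y = 0.5 * x + rng.normal(0, 0.2, 80)
    from scipy.interpolate import make_smoothing_spline

    from voxnat.behavioral import _collapse_duplicates, _fit_spline

    ux, uy, w, _, _ = _collapse_duplicates(x, y)
    spl = _fit_spline(ux, uy, w, 1e6)
    coef = np.polyfit(x, y, 1)
    np.testing.assert_allclose(spl(x), np.polyval(coef, x), atol=1e-3)


def test_spline_handles_duplicate_abscissae(rng):
    x = np.repeat(np.arange(12.0), 3)
    y = x * 0.7 + rng.normal(0, 0.1, x.size)
    fit = smoothing_spline_fit(x, y)
    assert np.isfinite(fit.rmse)


def test_spline_degenerate_x():
    with pytest.raises(DesignError):
        smoothing_spline_fit(np.ones(20), np.arange(20.0))


# --------------------------------------------------------------------------
# a-priori power analysis
# --------------------------------------------------------------------------

def test_power_monotone_in_sd():
    n1 = min_sample_size_power((4, 2, 3, 4, 1, 3), 3.0, 0.5, reps=400, seed=0)["n"]
    n2 = min_sample_size_power((4, 2, 3, 4, 1, 3), 6.0, 0.5, reps=400, seed=0)["n"]
    assert n2 > n1


def test_power_trivial_target():
    assert min_sample_size_power((1, 2), 1.0, 0.0, target_power=0.05)["n"] == 2


def test_power_zero_spread_rejected():
    with pytest.raises(DesignError):
        min_sample_size_power((3, 3, 3), 3.0, 0.5)


def test_power_boundary_consistency():
    res = min_sample_size_power((4, 2, 3, 4, 1, 3), 3.0, 0.5, reps=800, seed=1)
    n = res["n"]
    assert res["powers"][n] >= 0.9
    assert res["powers"].get(n - 1, 0.0) < 0.9
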