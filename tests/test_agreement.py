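import json
import os

import numpy as np
import pandas as pd
import pytest

from ctmotion.agreement import (PairedMeasurements, agreement_suite,
                                bland_altman, ci_mean_halfwidth_from_loa, icc,
                                shapiro_wilk)
from ctmotion.migration import MigrationResult

DATA = os.path.join(os.path.dirname(__file__), "data")


def paired(a, b, name=""):
    return PairedMeasurements(tuple(range(len(a))), np.asarray(a), np.asarray(b), name)


# -- Bland-Altman -----------------------------------------------------------

def test_identical_series_degenerate_loa():
    a = np.array([0.1, 0.5, 0.9, 1.3])
    with pytest.warns(UserWarning):
        rep = bland_altman(paired(a, a))
    assert rep.mean_diff == 0.0
    assert rep.loa_lower == rep.loa_upper == 0.0


def test_loa_bounds_reconstruct_from_mean_and_sd(rng):
    a = rng.normal(0, 1, 24)
    b = a + rng.normal(0.1, 0.4, 24)
    rep = bland_altman(paired(a, b))
    assert rep.loa_upper - rep.loa_lower == pytest.approx(2 * 1.96 * rep.sd_diff, abs=1e-12)
    assert rep.loa_lower <= rep.mean_diff <= rep.loa_upper
    d = a - b
    assert rep.mean_diff == pytest.approx(d.mean(), abs=1e-12)
    assert rep.sd_diff == pytest.approx(d.std(ddof=1), abs=1e-12)


def test_translation_equivariance(rng):
    a = rng.normal(0, 1, 30)
    b = a + rng.normal(0, 0.3, 30)
    r0 = bland_altman(paired(a, b))
    r1 = bland_altman(paired(a + 2.5, b))
    assert r1.mean_diff == pytest.approx(r0.mean_diff + 2.5, abs=1e-10)
    assert r1.sd_diff == pytest.approx(r0.sd_diff, abs=1e-12)


@pytest.mark.parametrize("loa, printed_ci", [
    ((-0.91, 0.66), 0.17),   # MTPM, method comparison
    ((-0.37, 0.41), 0.08),   # subsidence (Ty)
    ((-0.91, 0.99), 0.20),   # anterior tilt (Rx)
    ((-0.17, 0.24), 0.04),   # MTPM, interobserver
])
def test_printed_ci_halfwidths_recover_from_printed_loa(loa, printed_ci):
    """With n = 24, inverting LOA to sd and applying the t-based CI formula
    reproduces the published CI half-widths after rounding to 2 decimals."""
    ci = ci_mean_halfwidth_from_loa(loa[0], loa[1], n=24)
    assert round(ci, 2) == printed_ci


def test_ci_formulas_use_t_quantile(rng):
    from scipy import stats
    a = rng.normal(0, 1, 24)
    b = a + rng.normal(0, 0.5, 24)
    rep = bland_altman(paired(a, b))
    tq = stats.t.ppf(0.975, 23)
    assert rep.ci_mean_halfwidth == pytest.approx(tq * rep.sd_diff / np.sqrt(24), abs=1e-12)
    assert rep.ci_loa_halfwidth == pytest.approx(tq * rep.sd_diff * np.sqrt(3 / 24), abs=1e-12)


def test_too_short_series_rejected():
    with pytest.raises(ValueError):
        paired([1.0, 2.0], [1.0, 2.0])


# -- ICC --------------------------------------------------------------------

def brute_force_icc21(a, b):
    """Direct sum-of-squares two-way ANOVA, scalar loops only."""
    y = np.stack([a, b], axis=1)
    n, k = y.shape
    gm = y.mean()
    ss_rows = sum(k * (y[i].mean() - gm) ** 2 for i in range(n))
    ss_cols = sum(n * (y[:, j].mean() - gm) ** 2 for j in range(k))
    ss_tot = sum((y[i, j] - gm) ** 2 for i in range(n) for j in range(k))
    mse = (ss_tot - ss_rows - ss_cols) / ((n - 1) * (k - 1))
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def test_icc_matches_bruteforce_sum_of_squares(rng):
    for _ in range(5):
        a = rng.normal(0, 2, 15)
        b = a + rng.normal(0.2, 0.7, 15)
        rep = icc(paired(a, b))
        assert rep.icc == pytest.approx(brute_force_icc21(a, b), abs=1e-10)


def test_icc_duplicated_series_is_one(rng):
    a = rng.normal(0, 1, 12)
    rep = icc(paired(a, a.copy()))
    assert rep.icc == pytest.approx(1.0, abs=1e-12)
    assert rep.ci_lower == pytest.approx(1.0, abs=1e-9)


def test_icc_matches_reference_implementation(rng):
    pg = pytest.importorskip("pingouin")
    for _ in range(3):
        a = rng.normal(0, 1.5, 24)
        b = a + rng.normal(0.1, 0.5, 24)
        mine = icc(paired(a, b))
        mine3 = icc(paired(a, b), model="ICC(3,1)")
        df = pd.DataFrame({"subj": list(range(24)) * 2,
                           "rater": ["A"] * 24 + ["B"] * 24,
                           "y": np.concatenate([a, b])})
        ref = pg.intraclass_corr(df, targets="subj", raters="rater", ratings="y")
        row2 = ref[ref.Type == "ICC(A,1)"].iloc[0]
        row3 = ref[ref.Type == "ICC(C,1)"].iloc[0]
        assert mine.icc == pytest.approx(row2.ICC, abs=1e-10)
        assert mine3.icc == pytest.approx(row3.ICC, abs=1e-10)
        # pingouin prints its CI rounded to 2 decimals
        assert mine.ci_lower == pytest.approx(row2.CI95[0], abs=5.1e-3)
        assert mine.ci_upper == pytest.approx(row2.CI95[1], abs=5.1e-3)


def test_icc_invariances(rng):
    a = rng.normal(0, 2, 20)
    b = a + rng.normal(0, 0.5, 20)
    base = icc(paired(a, b)).icc
    assert icc(paired(a + 7.0, b + 7.0)).icc == pytest.approx(base, abs=1e-10)
    assert icc(paired(3.0 * a, 3.0 * b)).icc == pytest.approx(base, abs=1e-10)


def test_icc_zero_between_subject_variance_errors():
    with pytest.raises(ValueError):
        icc(paired([1.0, 1.0, 1.0, 1.0], [1.0, 1.0, 1.0, 1.0]))


def test_icc_generative_model_recovery():
    """b = a + noise with variance ratio 9:1 has population ICC 0.9."""
    gen = np.random.default_rng(5)
    subj = gen.normal(0, 3.0, 4000)          # var 9
    a = subj + gen.normal(0, 1.0, 4000)      # error var 1 per rating
    b = subj + gen.normal(0, 1.0, 4000)
    rep = icc(paired(a, b))
    assert rep.icc == pytest.approx(0.9, abs=0.02)


# -- Shapiro-Wilk -----------------------------------------------------------

def test_shapiro_matches_reference_values():
    """W agrees with an independently computed reference (R's shapiro.test)
    on 20 frozen vectors to 1e-6."""
    with open(os.path.join(DATA, "shapiro_reference.json")) as fh:
        cases = json.load(fh)
    assert len(cases) == 20
    for case in cases:
        w, p = shapiro_wilk(np.array(case["x"]))
        assert w == pytest.approx(case["w"], abs=1e-6)
        assert p == pytest.approx(case["p"], rel=1e-3, abs=1e-6)


def test_shapiro_normal_scores_score_high():
    from scipy import stats
    x = stats.norm.ppf((np.arange(1, 101) - 0.5) / 100)
    w, _ = shapiro_wilk(x)
    assert w > 0.995


def test_shapiro_rejects_heavy_bimodal():
    gen = np.random.default_rng(9)
    rejected = 0
    for _ in range(40):
        x = np.concatenate([gen.normal(-3, 0.3, 25), gen.normal(3, 0.3, 25)])
        _, p = shapiro_wilk(x)
        rejected += p < 0.05
    assert rejected >= 38  # high power under this alternative


def test_shapiro_input_validation():
    with pytest.raises(ValueError):
        shapiro_wilk([1.0, 1.0, 1.0, 1.0])
    with pytest.raises(ValueError):
        shapiro_wilk([1.0, 2.0])


# -- suite ------------------------------------------------------------------

def result_table(rng, n=10, shift=0.0, noise=0.0):
    rows = []
    for i in range(n):
        vals = rng.normal(0, 0.8, 9)
        rows.append({"subject": f"P{i:02d}",
                     **{k: v + shift + (rng.normal(0, noise) if noise else 0.0)
                        for k, v in zip(MigrationResult.PARAMETERS, vals)}})
    return pd.DataFrame(rows)


def test_suite_self_comparison(rng):
    a = result_table(rng)
    summary, plot = agreement_suite(a, a.copy())
    assert list(summary["parameter"]) == list(MigrationResult.PARAMETERS)
    assert np.allclose(summary["mean_diff"], 0.0)
    assert np.allclose(summary["icc"], 1.0, atol=1e-9)


def test_suite_table_layout_and_plot_consistency(rng):
    a = result_table(rng)
    b = result_table(rng)
    b[list(MigrationResult.PARAMETERS)] = (
        a[list(MigrationResult.PARAMETERS)] + rng.normal(0.05, 0.2, (len(a), 9)))
    summary, plot = agreement_suite(a, b)
    assert summary.shape[0] == 9
    for col in ("mean_a", "sd_a", "mean_b", "sd_b", "icc",
                "icc_ci_lower", "icc_ci_upper", "loa_lower", "loa_upper"):
        assert col in summary.columns
    # plot line positions must reproduce the report fields exactly
    for param, sub in plot.groupby("parameter"):
        row = summary[summary.parameter == param].iloc[0]
        assert np.allclose(sub["line_mean"], row["mean_diff"])
        assert np.allclose(sub["line_loa_lower"], row["loa_lower"])
        assert np.allclose(sub["line_loa_upper"], row["loa_upper"])
        assert np.allclose(sub["difference"].mean(), row["mean_diff"], atol=1e-12)


def test_suite_subject_mismatch_lists_unpaired(rng):
    a = result_table(rng)
    b = result_table(rng).drop(index=0)
    with pytest.raises(ValueError, match="P00"):
        agreement_suite(a, b)
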