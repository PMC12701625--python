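"""Method-comparison statistics for paired migration series.

Implements the validation toolkit used to compare two migration measurement
routes (two software methods, or two observers of the same method):

* Bland–Altman analysis: mean difference, limits of agreement
  LOA = mean ± 1.96·SD, with t-based 95% CIs for the mean difference
  (``t₀.₉₇₅,ₙ₋₁·SD/√n``) and for the LOA (the Bland–Altman ``√(3/n)``
  standard-error approximation, ``t₀.₉₇₅,ₙ₋₁·SD·√(3/n)``);
* two-way random-effects, absolute-agreement, single-measurement intraclass
  correlation ICC(2,1), with an F-based 95% CI (McGraw & Wong);
* Shapiro–Wilk normality check of the paired differences.

The LOA multiplier is fixed at exactly 1.96; the CI of the mean uses the t
distribution with n−1 degrees of freedom. No multiple-testing adjustment is
applied across migration parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .migration import MigrationResult

__all__ = [
    "PairedMeasurements", "BlandAltmanReport", "ICCReport",
    "bland_altman", "icc", "shapiro_wilk", "agreement_suite",
]

LOA_MULTIPLIER = 1.96


@dataclass(frozen=True)
class PairedMeasurements:
    """Two measurement series of the same parameter on the same subjects."""

    labels: tuple
    series_a: np.ndarray
    series_b: np.ndarray
    parameter_name: str = ""

    def __post_init__(self):
        a = np.asarray(self.series_a, dtype=float).ravel()
        b = np.asarray(self.series_b, dtype=float).ravel()
        labels = tuple(self.labels) if len(self.labels) else tuple(range(len(a)))
        if len(a) != len(b) or len(a) != len(labels):
            raise ValueError("paired series and labels must have equal length")
        if len(a) < 3:
            raise ValueError("paired analysis requires n >= 3")
        if np.isnan(a).any() or np.isnan(b).any():
            raise ValueError("paired series must not contain missing values")
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "series_a", a)
        object.__setattr__(self, "series_b", b)

    @property
    def n(self) -> int:
        return len(self.series_a)

    @property
    def differences(self) -> np.ndarray:
        return self.series_a - self.series_b


@dataclass(frozen=True)
class BlandAltmanReport:
    n: int
    mean_diff: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    ci_mean_halfwidth: float
    ci_loa_halfwidth: float
    shapiro_w: float
    shapiro_p: float
    parameter_name: str = ""
    loa_multiplier: float = LOA_MULTIPLIER
    loa_se_method: str = "bland-altman sqrt(3/n)"


@dataclass(frozen=True)
class ICCReport:
    icc: float
    ci_lower: float
    ci_upper: float
    model: str
    n_subjects: int
    n_raters: int


def ci_mean_halfwidth_from_loa(loa_lower: float, loa_upper: float, n: int) -> float:
    """Half-width of the t-based 95% CI of the mean difference, recovered
    from printed limits of agreement (sd = (upper − lower) / (2·1.96))."""
    sd = (loa_upper - loa_lower) / (2.0 * LOA_MULTIPLIER)
    return float(stats.t.ppf(0.975, n - 1) * sd / np.sqrt(n))


def bland_altman(data: PairedMeasurements) -> BlandAltmanReport:
    """Bland–Altman agreement analysis of two paired series."""
    d = data.differences
    n = data.n
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    tq = float(stats.t.ppf(0.975, n - 1))
    if sd == 0:
        warnings.warn("zero variance of paired differences: degenerate limits of agreement")
        w, p = float("nan"), float("nan")
    else:
        w, p = shapiro_wilk(d)
    return BlandAltmanReport(
        n=n,
        mean_diff=mean,
        sd_diff=sd,
        loa_lower=mean - LOA_MULTIPLIER * sd,
        loa_upper=mean + LOA_MULTIPLIER * sd,
        ci_mean_halfwidth=tq * sd / np.sqrt(n),
        ci_loa_halfwidth=tq * sd * np.sqrt(3.0 / n),
        shapiro_w=w,
        shapiro_p=p,
        parameter_name=data.parameter_name,
    )


def _anova_mean_squares(y: np.ndarray):
    """Two-way (subjects × raters) ANOVA mean squares, no replication."""
    n, k = y.shape
    gm = y.mean()
    ssr = k * ((y.mean(axis=1) - gm) ** 2).sum()      # between subjects
    ssc = n * ((y.mean(axis=0) - gm) ** 2).sum()      # between raters
    sst = ((y - gm) ** 2).sum()
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc(data: PairedMeasurements, model: str = "ICC(2,1)",
        alpha: float = 0.05) -> ICCReport:
    """Intraclass correlation of two raters' measurements.

    The default, ICC(2,1), is the two-way random-effects, absolute-agreement,
    single-measurement coefficient; ICC(3,1) (consistency) is available for
    sensitivity analysis. CIs use the F-based method of McGraw & Wong.
    """
    y = np.stack([data.series_a, data.series_b], axis=1)
    n, k = y.shape
    msr, msc, mse = _anova_mean_squares(y)
    if y.mean(axis=1).std() == 0:
        raise ValueError("ICC undefined: no between-subject variance")

    if model == "ICC(3,1)":
        val = (msr - mse) / (msr + (k - 1) * mse)
        if mse == 0:
            lo = hi = 1.0
        else:
            f = msr / mse
            fl = f / stats.f.ppf(1 - alpha / 2, n - 1, (n - 1) * (k - 1))
            fu = f * stats.f.ppf(1 - alpha / 2, (n - 1) * (k - 1), n - 1)
            lo = (fl - 1) / (fl + k - 1)
            hi = (fu - 1) / (fu + k - 1)
    elif model == "ICC(2,1)":
        val = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        if mse == 0 and msc == 0:
            lo = hi = 1.0
        else:
            a = k * val / (n * (1 - val)) if val < 1 else np.inf
            b = 1 + k * val * (n - 1) / (n * (1 - val)) if val < 1 else np.inf
            if np.isfinite(a):
                v = (a * msc + b * mse) ** 2 / (
                    (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1)))
            else:
                v = (msc + (n - 1) * mse) ** 2 / (
                    msc ** 2 / (k - 1) + ((n - 1) * mse) ** 2 / ((n - 1) * (k - 1)))
            f_star_l = stats.f.ppf(1 - alpha / 2, n - 1, v)
            f_star_u = stats.f.ppf(1 - alpha / 2, v, n - 1)
            lo = n * (msr - f_star_l * mse) / (
                f_star_l * (k * msc + (k * n - k - n) * mse) + n * msr)
            hi = n * (f_star_u * msr - mse) / (
                k * msc + (k * n - k - n) * mse + n * f_star_u * msr)
    else:
        raise ValueError(f"unsupported ICC model {model!r}")
    return ICCReport(icc=float(val), ci_lower=float(min(lo, val)),
                     ci_upper=float(max(hi, val)), model=model,
                     n_subjects=n, n_raters=k)


def shapiro_wilk(values):
    """Shapiro–Wilk normality test (Royston approximation via scipy).

    Returns ``(W, p)``; requires 3 ≤ n ≤ 5000 and non-constant input.
    """
    x = np.asarray(values, dtype=float).ravel()
    if not 3 <= len(x) <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(x) == 0:
        raise ValueError("Shapiro-Wilk undefined for constant input")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        w, p = stats.shapiro(x)
    return float(w), float(p)


def agreement_suite(results_a: pd.DataFrame, results_b: pd.DataFrame,
                    label_column: str = "subject",
                    parameters=MigrationResult.PARAMETERS):
    """Full per-parameter agreement analysis of two migration result tables.

    Both tables carry one row per subject with the nine migration parameters
    as columns. Returns ``(summary, plot_data)``: a Table-1-shaped summary
    (per-method mean (SD), Bland–Altman fields, ICC with 95% CI) and
    per-parameter Bland–Altman point/line data for plotting.
    """
    a = results_a.set_index(label_column)
    b = results_b.set_index(label_column)
    unpaired = sorted(set(a.index).symmetric_difference(b.index))
    if unpaired:
        raise ValueError(f"subject sets differ between methods: unpaired labels {unpaired}")
    b = b.loc[a.index]

    rows = []
    plot_frames = []
    for param in parameters:
        pm = PairedMeasurements(tuple(a.index), a[param].to_numpy(),
                                b[param].to_numpy(), parameter_name=param)
        ba = bland_altman(pm)
        try:
            ic = icc(pm)
            icc_val, icc_lo, icc_hi = ic.icc, ic.ci_lower, ic.ci_upper
        except ValueError:
            icc_val = icc_lo = icc_hi = float("nan")
        rows.append({
            "parameter": param,
            "mean_a": pm.series_a.mean(), "sd_a": pm.series_a.std(ddof=1),
            "mean_b": pm.series_b.mean(), "sd_b": pm.series_b.std(ddof=1),
            "n": pm.n,
            "mean_diff": ba.mean_diff, "sd_diff": ba.sd_diff,
            "loa_lower": ba.loa_lower, "loa_upper": ba.loa_upper,
            "ci_mean_halfwidth": ba.ci_mean_halfwidth,
            "ci_loa_halfwidth": ba.ci_loa_halfwidth,
            "shapiro_w": ba.shapiro_w, "shapiro_p": ba.shapiro_p,
            "icc": icc_val, "icc_ci_lower": icc_lo, "icc_ci_upper": icc_hi,
            "icc_model": "ICC(2,1)",
        })
        plot_frames.append(pd.DataFrame({
            "parameter": param,
            "subject": list(a.index),
            "mean_pair": (pm.series_a + pm.series_b) / 2.0,
            "difference": pm.differences,
            "line_mean": ba.mean_diff,
            "line_loa_lower": ba.loa_lower,
            "line_loa_upper": ba.loa_upper,
            "ci_mean_halfwidth": ba.ci_mean_halfwidth,
            "ci_loa_halfwidth": ba.ci_loa_halfwidth,
        }))
    summary = pd.DataFrame(rows)
    plot_data = pd.concat(plot_frames, ignore_index=True)
    return summary, plot_data
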