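"""Normality diagnostics for one-way ANOVA residuals.

The ICC estimator assumes normal group and culture effects, so the model
residuals (each observation minus its group mean) are checked with the
Kolmogorov-Smirnov test (Lilliefors-corrected by default, because the
normal parameters are estimated from the same sample), the stricter
D'Agostino-Pearson K^2 omnibus test for groups large enough to estimate
skewness and kurtosis, and a least-squares Gaussian fit to the pooled
residual histogram.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.diagnostic import lilliefors

from .anova import GroupedSample
from .errors import DegenerateDataError, InsufficientDataError

#: Smallest group size accepted by the K^2 test (skewness and kurtosis
#: z-transforms are unstable below this).
K2_MIN_N = 9


@dataclass(frozen=True)
class ResidualSet:
    """Observation-minus-group-mean residuals with their group labels."""

    residuals: np.ndarray
    group_labels: tuple[str, ...]


def residuals_one_way(sample: GroupedSample) -> ResidualSet:
    """Residuals of the one-way model, in stable group-then-observation order."""
    res = []
    labels = []
    for label, values in sample.groups.items():
        res.append(values - values.mean())
        labels.extend([label] * values.size)
    return ResidualSet(np.concatenate(res), tuple(labels))


def ks_normality(
    values, alpha: float = 0.05, lilliefors_correction: bool = True
) -> tuple[float, float, bool]:
    """KS test of normality with parameters estimated from the sample.

    Returns (statistic, p, passed) with passed = (p >= alpha).  By default
    the Lilliefors-corrected p-value is used; the naive KS p (which is
    anti-conservative when mean and s.d. are fitted) is available with
    lilliefors_correction=False.  The Lilliefors tables start at n = 4, so
    n = 3 falls back to the uncorrected p-value.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 3:
        raise InsufficientDataError(f"KS normality test needs n >= 3, got {arr.size}")
    sd = arr.std(ddof=1)
    if sd == 0:
        raise DegenerateDataError("all values equal; normality test undefined")
    if lilliefors_correction and arr.size >= 4:
        stat, p = lilliefors(arr, dist="norm")
    else:
        stat, p = stats.kstest(arr, "norm", args=(arr.mean(), sd))
    return float(stat), float(p), bool(p >= alpha)


def dagostino_k2(values) -> tuple[float, float]:
    """D'Agostino-Pearson K^2 omnibus test (skewness + kurtosis).

    K^2 = Z_skew^2 + Z_kurt^2 is referred to chi-square with 2 df.  Groups
    below n = 9 are rejected outright rather than returning an unreliable
    statistic.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < K2_MIN_N:
        raise InsufficientDataError(
            f"D'Agostino-Pearson K^2 needs n >= {K2_MIN_N}, got {arr.size}"
        )
    if arr.std(ddof=1) == 0:
        raise DegenerateDataError("all values equal; normality test undefined")
    stat, p = stats.normaltest(arr)
    return float(stat), float(p)


@dataclass(frozen=True)
class GaussianHistFit:
    r2: float
    mean: float
    sd: float
    amplitude: float
    excluded_bins: tuple[int, ...]
    bin_centers: np.ndarray
    counts: np.ndarray


def _gauss(x, amp, mu, sd):
    return amp * np.exp(-0.5 * ((x - mu) / sd) ** 2)


def _fit_once(centers: np.ndarray, counts: np.ndarray, keep: np.ndarray):
    x, y = centers[keep], counts[keep]
    w = max(float(np.sum(y)), 1.0)
    mu0 = float(np.sum(x * y) / w)
    sd0 = math.sqrt(max(float(np.sum(y * (x - mu0) ** 2) / w), 1e-12))
    p0 = (float(y.max()), mu0, sd0)
    try:
        with warnings.catch_warnings():
            # a perfect fit has singular parameter covariance; irrelevant here
            warnings.simplefilter("ignore", optimize.OptimizeWarning)
            popt, _ = optimize.curve_fit(_gauss, x, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:  # pragma: no cover - pathological histograms
        raise DegenerateDataError(f"Gaussian fit did not converge: {exc}") from exc
    fitted = _gauss(x, *popt)
    ss_res = float(np.sum((y - fitted) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 and ss_res == 0 else 1.0 - ss_res / ss_tot
    return popt, r2, _gauss(centers, *popt)


def gaussian_hist_fit(
    values, bin_width: float, exclude_outlier_bins: int = 0
) -> GaussianHistFit:
    """Least-squares scaled-Gaussian fit to a fixed-width histogram.

    Up to exclude_outlier_bins bins are removed greedily: after each fit
    the bin with the largest absolute fit residual is dropped and the curve
    refit.  Returns the final r^2, fitted mean and s.d., and which bins
    (by index) were excluded.
    """
    arr = np.asarray(values, dtype=float)
    if bin_width <= 0:
        raise DegenerateDataError(f"bin_width must be > 0, got {bin_width}")
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        raise DegenerateDataError("all values equal; histogram fit undefined")
    edges = np.arange(lo, hi + bin_width, bin_width)
    if edges[-1] < hi:
        edges = np.append(edges, edges[-1] + bin_width)
    counts, edges = np.histogram(arr, bins=edges)
    centers = (edges[:-1] + edges[1:]) / 2.0
    return fit_gaussian_to_counts(centers, counts.astype(float), exclude_outlier_bins)


def fit_gaussian_to_counts(
    bin_centers, counts, exclude_outlier_bins: int = 0
) -> GaussianHistFit:
    """Fit pre-binned counts; used directly by tests with constructed bins."""
    centers = np.asarray(bin_centers, dtype=float)
    counts = np.asarray(counts, dtype=float)
    keep = np.ones(centers.size, dtype=bool)
    excluded: list[int] = []

    def check_enough():
        if int(np.count_nonzero(counts[keep] > 0)) < 5:
            raise InsufficientDataError(
                "fewer than 5 nonempty histogram bins remain for the Gaussian fit"
            )

    check_enough()
    popt, r2, full_fit = _fit_once(centers, counts, keep)
    for _ in range(exclude_outlier_bins):
        resid = np.abs(counts - full_fit)
        resid[~keep] = -np.inf
        worst = int(np.argmax(resid))
        keep[worst] = False
        excluded.append(worst)
        check_enough()
        popt, r2, full_fit = _fit_once(centers, counts, keep)
    amp, mu, sd = popt
    return GaussianHistFit(
        r2=float(r2),
        mean=float(mu),
        sd=float(abs(sd)),
        amplitude=float(amp),
        excluded_bins=tuple(excluded),
        bin_centers=centers,
        counts=counts,
    )


def normality_report(
    sample: GroupedSample,
    alpha: float = 0.05,
    bin_width: float = 0.5,
    exclude_bins: int = 2,
    lilliefors_correction: bool = True,
) -> dict:
    """Per-group and pooled-residual normality summary (JSON-friendly)."""
    res = residuals_one_way(sample)
    report: dict = {"alpha": alpha, "groups": {}, "pooled": {}}
    for label, values in sample.groups.items():
        entry: dict = {"n": int(values.size)}
        if values.size >= 3 and values.std(ddof=1) > 0:
            stat, p, ok = ks_normality(values, alpha, lilliefors_correction)
            entry.update(ks_statistic=stat, ks_p=p, ks_pass=ok)
        if values.size >= K2_MIN_N and values.std(ddof=1) > 0:
            k2, k2p = dagostino_k2(values)
            entry.update(k2_statistic=k2, k2_p=k2p, k2_pass=bool(k2p >= alpha))
        report["groups"][label] = entry
    pooled = res.residuals
    stat, p, ok = ks_normality(pooled, alpha, lilliefors_correction)
    report["pooled"] = {
        "n": int(pooled.size),
        "ks_statistic": stat,
        "ks_p": p,
        "ks_pass": ok,
    }
    if pooled.size >= K2_MIN_N:
        k2, k2p = dagostino_k2(pooled)
        report["pooled"].update(k2_statistic=k2, k2_p=k2p, k2_pass=bool(k2p >= alpha))
    try:
        fit = gaussian_hist_fit(pooled, bin_width, exclude_bins)
        report["pooled"].update(
            gaussian_fit_r2=fit.r2,
            gaussian_fit_mean=fit.mean,
            gaussian_fit_sd=fit.sd,
            excluded_bins=list(fit.excluded_bins),
        )
    except (InsufficientDataError, DegenerateDataError) as exc:
        report["pooled"]["gaussian_fit_error"] = str(exc)
    return report
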