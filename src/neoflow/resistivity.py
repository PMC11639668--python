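"""Population-level resistivity computations.

Artery/vein separation by a two-component Gaussian mixture on the RI
distribution, per-acquisition RI-vs-diameter linear regression (slope and
"RI in small vessels", the fit evaluated at the 0.2 mm resolution limit),
group mean regression with its 95 % confidence band, and ROC/Youden
predictive analysis of the regression biomarkers.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm
from sklearn.mixture import GaussianMixture

__all__ = [
    "RegressionResult",
    "GroupRegression",
    "ROCResult",
    "artery_threshold",
    "select_arteries",
    "fit_ri_vs_diameter",
    "group_mean_regression",
    "roc_analysis",
    "SMALL_VESSEL_DIAMETER_MM",
    "DEFAULT_DIAMETER_GRID",
]

#: Spatial resolution limit of the method; "RI in small vessels" is the
#: regression evaluated at this diameter.
SMALL_VESSEL_DIAMETER_MM = 0.2

DEFAULT_DIAMETER_GRID = np.round(np.arange(0.2, 2.0 + 1e-9, 0.05), 4)


@dataclass
class RegressionResult:
    """Per-acquisition RI-vs-diameter linear model."""

    slope: float          # 1/mm
    intercept: float      # RI units
    ri_small: float       # RI at 0.2 mm (= 0.2 * slope + intercept)
    n_points: int
    residual_sd: float

    def predict(self, d_mm):
        return self.slope * np.asarray(d_mm) + self.intercept


@dataclass
class GroupRegression:
    """Mean regression line of a group with its 95 % confidence band.

    The band is ybar +/- 1.96 sigma_y sqrt(1/n + (x - xbar)^2 / sum(x_i -
    xbar)^2) where sigma_y is the standard deviation of the member lines
    evaluated at xbar (mean of the diameter grid) and n the member count;
    it is symmetric about the mean line and narrowest at xbar.
    """

    mean_slope: float
    mean_intercept: float
    x_grid: np.ndarray
    mean_line: np.ndarray
    sigma_y: float
    n: int
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    meta: dict = field(default_factory=dict)


@dataclass
class ROCResult:
    """Threshold sweep of a binary score with AUC and Youden operating point."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray
    auc: float
    youden_threshold: float
    youden_sensitivity: float
    youden_specificity: float


def _weighted_density_intersection(
    w1: float, mu1: float, sd1: float, w2: float, mu2: float, sd2: float
) -> float | None:
    """Root of w1 N(mu1, sd1) = w2 N(mu2, sd2) between the two means."""

    def g(x):
        return (np.log(w1) + norm.logpdf(x, mu1, sd1)) - (
            np.log(w2) + norm.logpdf(x, mu2, sd2)
        )

    a, b = sorted((mu1, mu2))
    eps = 1e-9 * max(1.0, abs(b - a))
    ga, gb = g(a + eps), g(b - eps)
    if ga == 0:
        return a
    if gb == 0:
        return b
    if np.sign(ga) == np.sign(gb):
        return None
    return float(brentq(g, a + eps, b - eps, xtol=1e-10))


def artery_threshold(
    ri_values: np.ndarray,
    roi_label: str | None = None,
    seed: int = 0,
    min_mean_separation: float = 0.05,
) -> float:
    """Vein/artery RI threshold from a two-component Gaussian mixture.

    Veins are non-pulsatile (low RI) and arteries pulsatile (higher RI), so
    the pooled RI distribution is bimodal; the threshold is the
    intersection of the two weighted component densities between the two
    means (EM fit, k-means initialisation, 20 restarts, seeded).  If the
    fitted means are closer than ``min_mean_separation`` the distribution
    is effectively unimodal: a warning is issued and the midpoint of the
    means is returned.
    """
    x = np.asarray(ri_values, float).ravel()
    if x.size < 100:
        raise ValueError("need at least 100 RI values for a stable mixture fit")
    if x.min() < -0.5 or x.max() > 1.5:
        raise ValueError("RI values outside the plausible range [-0.5, 1.5]")
    gmm = GaussianMixture(
        n_components=2,
        n_init=20,
        init_params="kmeans",
        tol=1e-6,
        random_state=seed,
    ).fit(x[:, None])
    means = gmm.means_.ravel()
    sds = np.sqrt(gmm.covariances_.ravel())
    weights = gmm.weights_.ravel()
    order = np.argsort(means)
    (mu1, mu2), (sd1, sd2), (w1, w2) = means[order], sds[order], weights[order]
    if mu2 - mu1 < min_mean_separation:
        warnings.warn(
            f"unimodal RI distribution (component means {mu1:.3f}, {mu2:.3f}); "
            "returning their midpoint",
            RuntimeWarning,
            stacklevel=2,
        )
        return float((mu1 + mu2) / 2)
    root = _weighted_density_intersection(w1, mu1, sd1, w2, mu2, sd2)
    if root is None:
        warnings.warn(
            "no density intersection between component means; returning midpoint",
            RuntimeWarning,
            stacklevel=2,
        )
        return float((mu1 + mu2) / 2)
    return root


def select_arteries(measurements: pd.DataFrame, threshold: float) -> pd.DataFrame:
    """Retain skeleton records with RI above the artery threshold."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    kept = measurements[measurements["ri"] > threshold]
    if kept.empty:
        raise ValueError("no arterial pixels above the RI threshold")
    return kept.reset_index(drop=True)


def fit_ri_vs_diameter(
    measurements: pd.DataFrame,
    min_points: int = 20,
    min_span_mm: float = 0.3,
) -> RegressionResult:
    """Ordinary least squares of RI on local diameter for one acquisition.

    ``ri_small`` is the prediction at the 0.2 mm resolution limit.
    Degenerate inputs (too few points, diameter span below
    ``min_span_mm``) raise.
    """
    d = np.asarray(measurements["diameter_mm"], float)
    ri = np.asarray(measurements["ri"], float)
    ok = np.isfinite(d) & np.isfinite(ri)
    d, ri = d[ok], ri[ok]
    if d.size < min_points:
        raise ValueError(f"regression needs >= {min_points} points, got {d.size}")
    if d.max() - d.min() < min_span_mm:
        raise ValueError(
            f"diameter span {d.max() - d.min():.3f} mm too narrow (< {min_span_mm} mm)"
        )
    slope, intercept = np.polyfit(d, ri, 1)
    resid = ri - (slope * d + intercept)
    residual_sd = float(np.std(resid, ddof=2)) if d.size > 2 else 0.0
    return RegressionResult(
        slope=float(slope),
        intercept=float(intercept),
        ri_small=float(SMALL_VESSEL_DIAMETER_MM * slope + intercept),
        n_points=int(d.size),
        residual_sd=residual_sd,
    )


def group_mean_regression(
    results: list[RegressionResult],
    x_grid: np.ndarray = DEFAULT_DIAMETER_GRID,
) -> GroupRegression:
    """Mean regression line of a group of per-acquisition fits with 95 % CI.

    The mean line is ybar = mbar x + cbar with mbar, cbar the means of the
    member slopes and intercepts.  sigma_y is the standard deviation
    (ddof 1) of the member lines evaluated at xbar, the mean of the
    diameter grid, and the band half-width is

        1.96 sigma_y sqrt(1/n + (x - xbar)^2 / sum(x_i - xbar)^2)

    with the sum over the grid.  The 1.96 normal quantile and the
    mean-response radical are recorded in the metadata.
    """
    n = len(results)
    if n < 2:
        raise ValueError("group regression needs at least 2 members")
    x = np.asarray(x_grid, float)
    slopes = np.array([r.slope for r in results])
    intercepts = np.array([r.intercept for r in results])
    m_bar, c_bar = float(slopes.mean()), float(intercepts.mean())
    x_bar = float(x.mean())
    member_at_xbar = slopes * x_bar + intercepts
    sigma_y = float(np.std(member_at_xbar, ddof=1))
    mean_line = m_bar * x + c_bar
    ssx = float(np.sum((x - x_bar) ** 2))
    half = 1.96 * sigma_y * np.sqrt(1.0 / n + (x - x_bar) ** 2 / ssx)
    return GroupRegression(
        mean_slope=m_bar,
        mean_intercept=c_bar,
        x_grid=x,
        mean_line=mean_line,
        sigma_y=sigma_y,
        n=n,
        ci_lower=mean_line - half,
        ci_upper=mean_line + half,
        meta={
            "quantile": 1.96,
            "quantile_family": "normal",
            "radical": "sqrt(1/n + (x - xbar)^2 / sum_grid (x_i - xbar)^2)",
            "sigma_y_at": x_bar,
        },
    )


def roc_analysis(scores: np.ndarray, labels: np.ndarray) -> ROCResult:
    """ROC curve, trapezoidal AUC and Youden operating point.

    Positives are predicted where score >= threshold; the sweep runs over
    the unique scores (plus a sentinel above the maximum).  The Youden
    point maximises sensitivity + specificity - 1, ties resolved to the
    lower threshold.
    """
    s = np.asarray(scores, float).ravel()
    y = np.asarray(labels).ravel().astype(bool)
    if s.size != y.size:
        raise ValueError("scores and labels must have equal length")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    thr = np.concatenate(([np.inf], np.unique(s)[::-1]))
    sens = np.empty(thr.size)
    spec = np.empty(thr.size)
    for i, t in enumerate(thr):
        pred = s >= t
        sens[i] = (pred & y).sum() / n_pos
        spec[i] = (~pred & ~y).sum() / n_neg
    fpr = 1.0 - spec
    auc = float(np.trapezoid(sens, fpr))
    youden = sens + spec - 1.0
    best = np.nonzero(youden == youden.max())[0]
    j = int(best[np.argmin(thr[best])])
    return ROCResult(
        thresholds=thr,
        sensitivity=sens,
        specificity=spec,
        auc=auc,
        youden_threshold=float(thr[j]),
        youden_sensitivity=float(sens[j]),
        youden_specificity=float(spec[j]),
    )
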