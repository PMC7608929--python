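"""Observer reliability and cross-system agreement statistics.

Three analyses cover how reproducible and how mutually consistent the two
CT scoring systems are:

* intra-observer reliability of rescored scans via the intraclass
  correlation coefficient (two-way mixed-effects, consistency, single
  measurement — the ICC(3,1) form), with the conventional interpretation
  bands poor / moderate / good / excellent;
* cross-system association via Pearson correlation and simple linear
  regression, optionally after a square-root transform of both score
  vectors (percent scores are right-skewed with variance growing with the
  mean; the square root stabilizes both);
* Bland-Altman limits of agreement on z-standardized scores.  The two
  systems live on different scales (% of lung volume vs % of maximal
  score), so each vector is standardized to mean 0, SD 1 before the
  differences are formed; the bias of standardized pairs is identically 0
  and the limits of agreement quantify the scatter between systems.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import stats

__all__ = [
    "IccResult",
    "CorrelationResult",
    "BlandAltmanResult",
    "icc_two_way",
    "classify_icc",
    "correlate_systems",
    "bland_altman_standardized",
    "bland_altman_plot",
    "scatter_plot",
]

#: Interpretation bands: poor [-1, 0.4), moderate [0.4, 0.6),
#: good [0.6, 0.8], excellent (0.8, 1].  Exactly 0.4 is moderate,
#: exactly 0.6 and exactly 0.8 are good.
ICC_BANDS = ("poor", "moderate", "good", "excellent")


@dataclass(frozen=True)
class IccResult:
    icc: float  # nan when degenerate
    band: str  # one of ICC_BANDS or "undefined"
    n_subjects: int
    n_occasions: int
    degenerate: bool = False
    reason: str = ""


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    p_value: float
    slope: float
    intercept: float
    n: int
    transform_applied: bool


@dataclass(frozen=True)
class BlandAltmanResult:
    points: np.ndarray  # (n, 2) array of (mean, difference) per standardized pair
    bias: float
    loa_low: float
    loa_high: float


def classify_icc(value: float) -> str:
    """Map an ICC in [-1, 1] to its interpretation band.

    Negative values are poor; boundaries follow the documented mapping
    (0.4 -> moderate, 0.6 -> good, 0.8 -> good, above 0.8 -> excellent).
    """
    if not (-1.0 <= value <= 1.0):
        raise ValueError(f"ICC {value} outside [-1, 1]")
    if value < 0.4:
        return "poor"
    if value < 0.6:
        return "moderate"
    if value <= 0.8:
        return "good"
    return "excellent"


def icc_two_way(ratings: np.ndarray) -> IccResult:
    """Two-way mixed-effects, consistency, single-measurement ICC.

    ``ratings`` is a complete subjects x occasions table (n >= 2 subjects,
    k >= 2 occasions, no missing cells).  From the two-way ANOVA mean
    squares, ``ICC = (MS_subjects - MS_error) / (MS_subjects + (k-1) MS_error)``.
    Tables with zero between-subject variance (e.g. all-zero scores, as
    happens for mucus plugging in mild cohorts) are flagged degenerate
    instead of yielding a number.
    """
    x = np.asarray(ratings, dtype=float)
    if x.ndim != 2:
        raise ValueError("ratings must be a 2-D subjects x occasions table")
    n, k = x.shape
    if n < 2 or k < 2:
        raise ValueError("need at least 2 subjects and 2 occasions")
    if np.isnan(x).any():
        raise ValueError("ratings table has missing cells; complete cases required")

    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ms_subjects = k * np.sum((row_means - grand) ** 2) / (n - 1)
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ms_error = np.sum(resid**2) / ((n - 1) * (k - 1))

    if np.ptp(x) == 0:
        return IccResult(math.nan, "undefined", n, k, True, "all ratings identical")
    if ms_subjects <= 1e-12 * max(1.0, float(np.abs(x).max()) ** 2):
        return IccResult(math.nan, "undefined", n, k, True, "zero between-subject variance")

    icc = (ms_subjects - ms_error) / (ms_subjects + (k - 1) * ms_error)
    return IccResult(float(icc), classify_icc(float(icc)), n, k)


def correlate_systems(
    x: np.ndarray, y: np.ndarray, sqrt_transform: bool = False
) -> CorrelationResult:
    """Pearson correlation and simple regression between paired score vectors.

    With ``sqrt_transform`` both vectors (which must be non-negative) are
    square-rooted first.  The two-sided p-value comes from the t
    distribution with n - 2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if sqrt_transform:
        if (x < 0).any() or (y < 0).any():
            raise ValueError("negative value: sqrt transform requires non-negative scores")
        x, y = np.sqrt(x), np.sqrt(y)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance after transform; correlation undefined")
    fit = stats.linregress(x, y)
    return CorrelationResult(
        r=float(fit.rvalue),
        p_value=float(fit.pvalue),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        n=int(x.size),
        transform_applied=bool(sqrt_transform),
    )


def bland_altman_standardized(x: np.ndarray, y: np.ndarray) -> BlandAltmanResult:
    """Bland-Altman analysis of z-standardized paired scores.

    Each vector is standardized over its own subjects (mean 0, SD 1 with
    the n-1 denominator); the result reports per-pair (mean, difference)
    points, the bias (0 by construction, to floating tolerance) and the
    1.96-SD limits of agreement.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    sx = x.std(ddof=1)
    sy = y.std(ddof=1)
    if sx == 0 or sy == 0:
        raise ValueError("zero variance: cannot standardize a constant vector")
    zx = (x - x.mean()) / sx
    zy = (y - y.mean()) / sy
    diff = zx - zy
    mean = (zx + zy) / 2.0
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return BlandAltmanResult(
        points=np.column_stack([mean, diff]),
        bias=bias,
        loa_low=bias - 1.96 * sd,
        loa_high=bias + 1.96 * sd,
    )


def _agg_axes():
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    return plt


def bland_altman_plot(result: BlandAltmanResult, path: str | Path, title: str = "") -> None:
    plt = _agg_axes()
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(result.points[:, 0], result.points[:, 1], s=12, alpha=0.7, color="0.3")
    for y, style in ((result.bias, "-"), (result.loa_low, "--"), (result.loa_high, "--")):
        ax.axhline(y, linestyle=style, color="k", linewidth=1)
    ax.set_xlabel("mean of standardized scores")
    ax.set_ylabel("difference of standardized scores")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def scatter_plot(
    x: np.ndarray, y: np.ndarray, result: CorrelationResult, path: str | Path, title: str = ""
) -> None:
    plt = _agg_axes()
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if result.transform_applied:
        x, y = np.sqrt(x), np.sqrt(y)
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(x, y, s=12, alpha=0.7, color="0.3")
    xs = np.linspace(x.min(), x.max(), 50)
    ax.plot(xs, result.intercept + result.slope * xs, "k-", linewidth=1)
    ax.set_xlabel("system 1")
    ax.set_ylabel("system 2")
    ax.set_title(title or f"r = {result.r:.2f}")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
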