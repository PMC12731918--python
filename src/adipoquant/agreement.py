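"""Method-agreement statistics for paired measurements: Bland-Altman bias
and limits of agreement, intraclass correlation ICC(2,1), and the Wilcoxon
signed-rank test.

Choices pinned here:

* differences are method_b minus method_a (put the prediction in b and the
  manual reference in a to get the usual prediction-minus-manual bias);
* limits of agreement use the fixed 1.96 multiplier and the sample
  (1/(n-1)) standard deviation;
* the ICC variant is ICC(2,1): two-way random effects, absolute agreement,
  single measurement — the appropriate form for method interchangeability;
* Wilcoxon drops zero differences, mid-ranks ties, and uses the exact
  permutation null (all 2^n sign assignments) for n <= 12, a normal
  approximation with tie correction above.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
from scipy import stats

from .errors import InsufficientDataError

__all__ = [
    "PairedSeries",
    "BlandAltmanResult",
    "WilcoxonResult",
    "bland_altman",
    "loa_from_stats",
    "relative_bias_percent",
    "icc_absolute_agreement",
    "wilcoxon_signed_rank",
    "plot_bland_altman",
]

LOA_MULTIPLIER = 1.96
EXACT_WILCOXON_MAX_N = 12


@dataclass
class PairedSeries:
    """Paired measurements of one variable by two methods on the same scans."""

    ids: list[str]
    method_a: np.ndarray
    method_b: np.ndarray
    variable_name: str = ""

    def __post_init__(self) -> None:
        self.method_a = np.asarray(self.method_a, dtype=np.float64)
        self.method_b = np.asarray(self.method_b, dtype=np.float64)
        self.ids = [str(i) for i in self.ids]
        if not (len(self.ids) == self.method_a.size == self.method_b.size):
            raise ValueError("ids, method_a and method_b must have equal length")
        if not (np.all(np.isfinite(self.method_a)) and np.all(np.isfinite(self.method_b))):
            raise ValueError("paired values must be finite")

    @property
    def n(self) -> int:
        return self.method_a.size

    @property
    def differences(self) -> np.ndarray:
        return self.method_b - self.method_a


@dataclass
class BlandAltmanResult:
    mean_bias: float
    sd_bias: float
    loa_lower: float
    loa_upper: float
    n: int
    points: list[tuple[float, float]] = field(default_factory=list)  # (mean, diff)


@dataclass
class WilcoxonResult:
    statistic: float  # sum of ranks of negative differences
    p_value: float
    n_used: int
    method: str  # "exact" or "approx"


def loa_from_stats(
    mean_bias: float, sd_bias: float, multiplier: float = LOA_MULTIPLIER
) -> tuple[float, float]:
    """95% limits of agreement from the bias mean and SD."""
    return mean_bias - multiplier * sd_bias, mean_bias + multiplier * sd_bias


def relative_bias_percent(mean_bias: float, reference_mean: float) -> float:
    """Bias expressed as a percentage of a reference mean value."""
    if reference_mean == 0:
        return math.nan
    return 100.0 * mean_bias / reference_mean


def bland_altman(pairs: PairedSeries, multiplier: float = LOA_MULTIPLIER) -> BlandAltmanResult:
    """Bland-Altman bias, SD and 95% limits of agreement for paired data."""
    if pairs.n < 2:
        raise InsufficientDataError(f"Bland-Altman needs n >= 2, got {pairs.n}")
    d = pairs.differences
    mean_bias = float(d.mean())
    sd_bias = float(d.std(ddof=1))
    lower, upper = loa_from_stats(mean_bias, sd_bias, multiplier)
    means = (pairs.method_a + pairs.method_b) / 2.0
    return BlandAltmanResult(
        mean_bias=mean_bias,
        sd_bias=sd_bias,
        loa_lower=lower,
        loa_upper=upper,
        n=pairs.n,
        points=list(zip(means.tolist(), d.tolist())),
    )


def icc_absolute_agreement(pairs: PairedSeries) -> float:
    """ICC(2,1) from two-way ANOVA mean squares with k = 2 raters.

    Returns NaN when the total variance is zero (the statistic is undefined
    for constant data).
    """
    if pairs.n < 2:
        raise InsufficientDataError(f"ICC needs n >= 2, got {pairs.n}")
    x = np.column_stack([pairs.method_a, pairs.method_b])
    n, k = x.shape
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)

    ss_rows = k * float(((row_means - grand) ** 2).sum())
    ss_cols = n * float(((col_means - grand) ** 2).sum())
    resid = x - row_means[:, None] - col_means[None, :] + grand
    ss_err = float((resid**2).sum())

    if ss_rows + ss_cols + ss_err <= 0:
        return math.nan

    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))

    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom == 0:
        return math.nan
    return (ms_r - ms_e) / denom


def _signed_ranks(d: np.ndarray) -> np.ndarray:
    """Mid-ranks of |d| (d must be nonzero)."""
    return stats.rankdata(np.abs(d))


def _exact_p(ranks: np.ndarray, w_neg: float) -> float:
    """Two-sided p from full enumeration of all 2^n sign assignments."""
    n = ranks.size
    lo = 0
    hi = 0
    total = 2**n
    for signs in product((0, 1), repeat=n):
        w = float(np.dot(signs, ranks))
        if w <= w_neg + 1e-12:
            lo += 1
        if w >= w_neg - 1e-12:
            hi += 1
    return min(1.0, 2.0 * min(lo, hi) / total)


def wilcoxon_signed_rank(pairs: PairedSeries) -> WilcoxonResult:
    """Paired two-sided Wilcoxon signed-rank test on method_b - method_a.

    The statistic is the sum of ranks of negative differences. Zero
    differences are dropped; if all differences are zero, p = 1.0 with a
    warning.
    """
    d = pairs.differences
    d = d[d != 0]
    m = d.size
    if m == 0:
        warnings.warn("all paired differences are zero; Wilcoxon p set to 1.0", stacklevel=2)
        return WilcoxonResult(statistic=0.0, p_value=1.0, n_used=0, method="degenerate")
    ranks = _signed_ranks(d)
    w_neg = float(ranks[d < 0].sum())
    if m <= EXACT_WILCOXON_MAX_N:
        return WilcoxonResult(
            statistic=w_neg, p_value=_exact_p(ranks, w_neg), n_used=m, method="exact"
        )
    # normal approximation with tie correction and continuity correction
    mean_w = m * (m + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / 48.0
    var_w = m * (m + 1) * (2 * m + 1) / 24.0 - tie_term
    if var_w <= 0:
        return WilcoxonResult(statistic=w_neg, p_value=1.0, n_used=m, method="approx")
    dev = w_neg - mean_w
    z = (dev - 0.5 * np.sign(dev)) / math.sqrt(var_w)
    p = min(1.0, 2.0 * float(stats.norm.sf(abs(z))))
    return WilcoxonResult(statistic=w_neg, p_value=p, n_used=m, method="approx")


def plot_bland_altman(result: BlandAltmanResult, title: str = "", path=None):
    """Mean-vs-difference plot with bias and limit lines; saves to ``path``
    if given, otherwise returns the matplotlib figure."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    if result.points:
        means, diffs = zip(*result.points)
        ax.scatter(means, diffs, s=18, alpha=0.8)
    for y, style in ((result.mean_bias, "-"), (result.loa_lower, "--"), (result.loa_upper, "--")):
        ax.axhline(y, linestyle=style, color="gray")
    ax.set_xlabel("mean of methods")
    ax.set_ylabel("difference (b - a)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
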