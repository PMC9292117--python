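"""Statistical layer: rank tests with star codes, correlations, box summaries.

Star codes follow the usual significance ladder on the two-sided p-value:
**** <= 1e-4, *** <= 1e-3, ** <= 0.01, * <= 0.05, ns otherwise (boundary
values inclusive).  Mann-Whitney p-values are exact (full enumeration of the
null rank distribution) when both groups have at most 8 observations and
there are no ties; otherwise the tie-corrected normal approximation with
continuity correction is used, and the mode is recorded in the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

EXACT_MAX_N = 8

STAR_THRESHOLDS = ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (5e-2, "*"))


def star_code(p: float) -> str:
    """Map a two-sided p-value to its significance star code."""
    if not (0.0 <= p <= 1.0):
        raise ValueError("p-value outside [0, 1]")
    for threshold, stars in STAR_THRESHOLDS:
        if p <= threshold:
            return stars
    return "ns"


@dataclass(frozen=True)
class ComparisonResult:
    """Two-group Mann-Whitney-Wilcoxon comparison."""

    label_a: str
    label_b: str
    n_a: int
    n_b: int
    median_a: float
    median_b: float
    u_statistic: float
    p_value: float
    stars: str
    method: str  # "exact" or "asymptotic"

    def as_row(self) -> dict:
        return {
            "group_a": self.label_a, "group_b": self.label_b,
            "n_a": self.n_a, "n_b": self.n_b,
            "median_a": self.median_a, "median_b": self.median_b,
            "U": self.u_statistic, "p": self.p_value, "stars": self.stars,
            "method": self.method,
        }


def mann_whitney(group_a, group_b, label_a: str = "A",
                 label_b: str = "B") -> ComparisonResult:
    """Two-sided Mann-Whitney-Wilcoxon rank-sum test with star coding."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    has_ties = np.unique(np.concatenate([a, b])).size < a.size + b.size
    exact = a.size <= EXACT_MAX_N and b.size <= EXACT_MAX_N and not has_ties
    method = "exact" if exact else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    p = float(min(res.pvalue, 1.0))
    return ComparisonResult(label_a, label_b, a.size, b.size,
                            float(np.median(a)), float(np.median(b)),
                            float(res.statistic), p, star_code(p), method)


def pearson(x, y) -> tuple[float, float]:
    """Sample Pearson correlation with its t-distribution p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y differ in length")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in correlation input")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in correlation input")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


@dataclass(frozen=True)
class BoxSummary:
    """Notched-box summary: median, quartiles, 95% median CI half-width."""

    median: float
    q1: float
    q3: float
    notch: float
    n: int


def box_summary(values) -> BoxSummary:
    """Median, linear-interpolation quartiles, and notch = 1.57*IQR/sqrt(n).

    The notch half-width is the conventional 95% confidence interval for the
    median used by notched box plots.
    """
    v = np.asarray(values, dtype=float)
    if v.size == 0:
        raise ValueError("empty sample")
    q1, med, q3 = np.percentile(v, [25, 50, 75])
    notch = 1.57 * (q3 - q1) / np.sqrt(v.size)
    return BoxSummary(float(med), float(q1), float(q3), float(notch), int(v.size))


@dataclass
class SectorScatter:
    """Per-point quadrant classification of paired log2 ratios.

    Quadrants are labelled by the signs of (x, y); zeros fall on the
    non-negative side and are additionally counted in ``n_on_axis``.
    """

    x: np.ndarray
    y: np.ndarray
    quadrant: np.ndarray  # strings "++", "+-", "-+", "--"
    n_on_axis: int

    def counts(self) -> dict[str, int]:
        labels, counts = np.unique(self.quadrant, return_counts=True)
        out = {q: 0 for q in ("++", "+-", "-+", "--")}
        out.update(dict(zip(labels.tolist(), counts.tolist())))
        return out

    def fraction(self, quadrant: str) -> float:
        return self.counts()[quadrant] / self.x.size


def sector_classify(x, y) -> SectorScatter:
    """Classify (x, y) pairs by quadrant; "-+" is the upper-left sector."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y differ in length")
    xs = np.where(x >= 0, "+", "-")
    ys = np.where(y >= 0, "+", "-")
    quadrant = np.char.add(xs, ys)
    n_on_axis = int(((x == 0) | (y == 0)).sum())
    return SectorScatter(x, y, quadrant, n_on_axis)
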