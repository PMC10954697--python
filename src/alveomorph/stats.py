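"""Distribution descriptors, normality-driven group comparison and
MQ-vs-injury-score regression.

The statistical workflow mirrors common practice in small-animal-cohort
morphometry:

* per-variable distribution summaries — mean, 95 % t-based CI of the mean,
  adjusted Fisher-Pearson skewness, excess kurtosis and a fixed-bin-width
  frequency histogram aligned to zero;
* alveolus-level records are first averaged per animal, and hypothesis tests
  run on the animal-level means only (animals, not alveoli, are the
  independent experimental units);
* two-group comparison with data-driven test selection: Shapiro-Wilk
  normality per group at alpha; if both groups pass, an F-test decides
  between the unpaired Student t-test (equal variances) and Welch's t-test
  (unequal); if either group fails normality — or is degenerate, e.g. all
  ties — the Mann-Whitney U test is used;
* simple (ordinary-least-squares) linear regression of cumulative injury
  score on MQ, reporting slope, intercept, R² and the two-sided slope p.

Significance stars follow the conventional thresholds
(*p<0.05, **p<0.01, ***p<0.001, ****p<0.0001).
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DegenerateFitError, InsufficientDataError
from .geometry import MorphometryRecord

__all__ = [
    "VARIABLES",
    "DEFAULT_BIN_WIDTHS",
    "CohortSummary",
    "ComparisonResult",
    "RegressionResult",
    "significance_stars",
    "summarize_distribution",
    "aggregate_by_animal",
    "compare_groups",
    "regress_mq_on_score",
]

logger = logging.getLogger(__name__)

#: Morphometric variables the pipeline summarises and compares.
VARIABLES = ("wall_thickness_pct", "circularity", "mq")

#: Default frequency-histogram bin widths per variable. The circularity
#: width of 0.4 is deliberately coarse (3 occupied bins on a (0, 1]
#: variable); 0.04 is the natural fine-grained alternative — both are
#: accepted wherever a bin width is taken.
DEFAULT_BIN_WIDTHS = {"wall_thickness_pct": 3.0, "circularity": 0.4, "mq": 0.5}


def significance_stars(p: float) -> str:
    """Star notation: * p<0.05, ** p<0.01, *** p<0.001, **** p<0.0001."""
    if p < 1e-4:
        return "****"
    if p < 1e-3:
        return "***"
    if p < 1e-2:
        return "**"
    if p < 0.05:
        return "*"
    return "ns"


@dataclass(frozen=True)
class CohortSummary:
    """Distribution descriptors of one variable in one cohort."""

    variable: str
    n: int
    mean: float
    ci95_low: float
    ci95_high: float
    sd: float
    skewness: float
    kurtosis: float  # excess
    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]
    degenerate: bool = False  # all values identical; skew/kurtosis undefined

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "n": self.n,
            "mean": self.mean,
            "ci95_low": self.ci95_low,
            "ci95_high": self.ci95_high,
            "sd": self.sd,
            "skewness": self.skewness,
            "kurtosis": self.kurtosis,
            "bin_edges": list(self.bin_edges),
            "counts": list(self.counts),
            "degenerate": self.degenerate,
        }


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of the normality-driven two-group comparison."""

    variable: str
    n_a: int
    n_b: int
    mean_a: float
    mean_b: float
    sd_a: float
    sd_b: float
    test_used: str  # "t" | "welch_t" | "mann_whitney"
    statistic: float
    p_value: float
    stars: str
    normality_p_a: float | None
    normality_p_b: float | None
    variance_equality_p: float | None
    notes: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "variable": self.variable,
            "n_a": self.n_a,
            "n_b": self.n_b,
            "mean_a": self.mean_a,
            "mean_b": self.mean_b,
            "sd_a": self.sd_a,
            "sd_b": self.sd_b,
            "test_used": self.test_used,
            "statistic": self.statistic,
            "p_value": self.p_value,
            "stars": self.stars,
            "normality_p_a": self.normality_p_a,
            "normality_p_b": self.normality_p_b,
            "variance_equality_p": self.variance_equality_p,
            "notes": list(self.notes),
        }


@dataclass(frozen=True)
class RegressionResult:
    """Simple linear regression summary."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    slope_stderr: float

    def slope_ci95(self) -> tuple[float, float]:
        """95 % t-based confidence interval for the slope."""
        tcrit = sps.t.ppf(0.975, self.n - 2)
        return (
            self.slope - tcrit * self.slope_stderr,
            self.slope + tcrit * self.slope_stderr,
        )

    def to_dict(self) -> dict:
        lo, hi = self.slope_ci95()
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "n": self.n,
            "slope_stderr": self.slope_stderr,
            "slope_ci95_low": lo,
            "slope_ci95_high": hi,
        }


def _zero_aligned_edges(values: np.ndarray, bin_width: float) -> np.ndarray:
    """Histogram bin edges of the given width with an edge aligned at 0."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    lo = math.floor(values.min() / bin_width)
    hi = math.floor(values.max() / bin_width) + 1
    return np.arange(lo, hi + 1) * bin_width


def summarize_distribution(
    values: Sequence[float], variable: str = "", bin_width: float | None = None
) -> CohortSummary:
    """Describe a per-alveolus (or per-animal) sample of one variable.

    Mean with 95 % t-distribution CI, sample SD, adjusted Fisher-Pearson
    skewness (small-sample corrected), excess kurtosis, and a frequency
    histogram with ``bin_width``-wide bins aligned to zero. Samples of
    identical values are flagged ``degenerate`` (skewness/kurtosis are
    undefined; the CI collapses to the mean).
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3:
        raise InsufficientDataError(
            f"need >= 3 one-dimensional values, got shape {x.shape}"
        )
    if bin_width is None:
        bin_width = DEFAULT_BIN_WIDTHS.get(variable, 0.5)
    n = int(x.size)
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1))
    degenerate = sd == 0.0
    if degenerate:
        ci_lo = ci_hi = mean
        skew = kurt = float("nan")
        logger.warning(
            "summarize_distribution(%s): all %d values identical; "
            "skewness/kurtosis undefined",
            variable or "<unnamed>",
            n,
        )
    else:
        half = sps.t.ppf(0.975, n - 1) * sd / math.sqrt(n)
        ci_lo, ci_hi = mean - half, mean + half
        skew = float(sps.skew(x, bias=False))
        kurt = float(sps.kurtosis(x, fisher=True, bias=False))
    edges = _zero_aligned_edges(x, bin_width)
    counts, _ = np.histogram(x, bins=edges)
    return CohortSummary(
        variable=variable,
        n=n,
        mean=mean,
        ci95_low=float(ci_lo),
        ci95_high=float(ci_hi),
        sd=sd,
        skewness=skew,
        kurtosis=kurt,
        bin_edges=tuple(float(e) for e in edges),
        counts=tuple(int(c) for c in counts),
        degenerate=degenerate,
    )


def aggregate_by_animal(
    records: Iterable[MorphometryRecord] | pd.DataFrame,
) -> pd.DataFrame:
    """Collapse alveolus-level records to per-animal means.

    Returns a frame indexed by (condition, animal_id) with one mean per
    variable plus the alveolus count. Animals contribute equally downstream
    regardless of how many alveoli were traced for them.
    """
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = pd.DataFrame([r.to_dict() for r in records])
    if frame.empty:
        raise InsufficientDataError("no records to aggregate")
    grouped = frame.groupby(["condition", "animal_id"], observed=True)
    out = grouped[list(VARIABLES)].mean()
    out["n_alveoli"] = grouped.size()
    return out.reset_index()


def _shapiro_p(x: np.ndarray) -> float | None:
    """Shapiro-Wilk p, or None when undefined (constant sample)."""
    if np.ptp(x) == 0:
        return None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return float(sps.shapiro(x).pvalue)


def _f_test_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sided F-test for equality of variances."""
    va, vb = np.var(a, ddof=1), np.var(b, ddof=1)
    if va >= vb:
        f, dfn, dfd = va / vb, len(a) - 1, len(b) - 1
    else:
        f, dfn, dfd = vb / va, len(b) - 1, len(a) - 1
    return float(min(1.0, 2.0 * sps.f.sf(f, dfn, dfd)))


def compare_groups(
    group_a: Sequence[float],
    group_b: Sequence[float],
    variable: str = "",
    alpha: float = 0.05,
) -> ComparisonResult:
    """Two-group comparison with normality-driven test selection.

    Decision rule: Shapiro-Wilk per group at ``alpha``; both normal ->
    F-test for equal variances at ``alpha`` -> Student t (equal) or Welch t
    (unequal); either group non-normal (or degenerate) -> Mann-Whitney U.
    Two-sided p-values throughout. The rule is a pure function of the two
    samples.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise InsufficientDataError(
            f"each group needs >= 3 observations, got {a.size} and {b.size}"
        )
    notes: list[str] = []
    p_sw_a, p_sw_b = _shapiro_p(a), _shapiro_p(b)
    degenerate = p_sw_a is None or p_sw_b is None
    if degenerate:
        notes.append(
            "constant sample: Shapiro-Wilk undefined; falling back to Mann-Whitney"
        )
        logger.warning("compare_groups(%s): %s", variable or "<unnamed>", notes[-1])
    both_normal = (
        not degenerate and p_sw_a >= alpha and p_sw_b >= alpha  # type: ignore[operator]
    )
    p_var: float | None = None
    if both_normal:
        p_var = _f_test_p(a, b)
        if p_var >= alpha:
            test_used = "t"
            stat, p = sps.ttest_ind(a, b, equal_var=True)
        else:
            test_used = "welch_t"
            stat, p = sps.ttest_ind(a, b, equal_var=False)
    else:
        test_used = "mann_whitney"
        try:
            res = sps.mannwhitneyu(a, b, alternative="two-sided")
            stat, p = res.statistic, res.pvalue
        except ValueError:
            # both samples identical and constant: no difference detectable
            stat, p = float("nan"), 1.0
            notes.append("identical constant groups: p set to 1")
    return ComparisonResult(
        variable=variable,
        n_a=int(a.size),
        n_b=int(b.size),
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        sd_a=float(a.std(ddof=1)),
        sd_b=float(b.std(ddof=1)),
        test_used=test_used,
        statistic=float(stat),
        p_value=float(p),
        stars=significance_stars(float(p)),
        normality_p_a=p_sw_a,
        normality_p_b=p_sw_b,
        variance_equality_p=p_var,
        notes=tuple(notes),
    )


def regress_mq_on_score(
    mq: Sequence[float], score: Sequence[float]
) -> RegressionResult:
    """OLS regression of cumulative injury score on per-animal MQ.

    Returns slope, intercept, R² and the two-sided p-value for the slope.
    """
    x = np.asarray(mq, dtype=float)
    y = np.asarray(score, dtype=float)
    if x.size != y.size:
        raise ValueError("mq and score must be paired")
    if x.size < 3:
        raise InsufficientDataError(f"need >= 3 paired observations, got {x.size}")
    if np.ptp(x) == 0:
        raise DegenerateFitError("predictor (MQ) has zero variance")
    fit = sps.linregress(x, y)
    return RegressionResult(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue**2),
        p_value=float(fit.pvalue),
        n=int(x.size),
        slope_stderr=float(fit.stderr),
    )
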