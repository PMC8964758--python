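"""Elementary statistical procedures used throughout the analysis.

Thin, contract-explicit wrappers over :mod:`scipy.stats` returning a uniform
:class:`TestResult` record: two-sample t (Welch by default), paired t,
Mann–Whitney U, Pearson chi-square, McNemar, and the binomial sample-size
formula for a sensitivity estimate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "TestResult",
    "two_sample_t",
    "paired_t",
    "mann_whitney_u",
    "chi_square_2xk",
    "mcnemar",
    "sample_size_sensitivity",
]

_P_FLOOR = float(np.finfo(float).tiny)


@dataclass
class TestResult:
    """A test outcome: statistic, two-sided p, and per-group summaries."""

    test: str
    statistic: float
    pvalue: float
    n: tuple[int, ...]
    summaries: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.pvalue <= 1.0):
            raise ValueError(f"p-value {self.pvalue} outside [0, 1]")

    def to_record(self) -> dict:
        return {
            "test": self.test,
            "statistic": float(self.statistic),
            "pvalue": float(self.pvalue),
            "n": list(self.n),
            **{k: (float(v) if np.isscalar(v) else v) for k, v in self.summaries.items()},
        }


def _mean_sd(x: np.ndarray) -> dict:
    return {"mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1)) if len(x) > 1 else 0.0}


def two_sample_t(x, y, welch: bool = True) -> TestResult:
    """Independent two-sample t test; Welch (unequal variances) by default."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise ValueError("each group needs n >= 2")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values")
    if np.var(x) == 0 and np.var(y) == 0:
        # degenerate: both groups constant
        stat, p = (0.0, 1.0) if np.mean(x) == np.mean(y) else (math.inf * np.sign(np.mean(x) - np.mean(y)), _P_FLOOR)
    else:
        stat, p = stats.ttest_ind(x, y, equal_var=not welch)
    return TestResult(
        test="welch_t" if welch else "pooled_t",
        statistic=float(stat),
        pvalue=float(p),
        n=(len(x), len(y)),
        summaries={"group_x": _mean_sd(x), "group_y": _mean_sd(y)},
    )


def paired_t(pre, post) -> TestResult:
    """Paired t test: one-sample t on post − pre differences."""
    pre, post = np.asarray(pre, dtype=float), np.asarray(post, dtype=float)
    if pre.shape != post.shape:
        raise ValueError("pre and post must have equal length")
    if len(pre) < 2:
        raise ValueError("paired t needs n >= 2 pairs")
    d = post - pre
    if np.std(d, ddof=1) == 0:
        if np.mean(d) == 0:
            stat, p = 0.0, 1.0
        else:  # all differences identical and nonzero: statistic diverges
            stat, p = math.inf * np.sign(np.mean(d)), _P_FLOOR
    else:
        stat, p = stats.ttest_rel(post, pre)
    return TestResult(
        test="paired_t",
        statistic=float(stat),
        pvalue=float(p),
        n=(len(pre),),
        summaries={"pre": _mean_sd(pre), "post": _mean_sd(post), "delta": _mean_sd(d)},
    )


def mann_whitney_u(x, y, method: str = "asymptotic") -> TestResult:
    """Mann–Whitney U with midrank ties.

    The default p-value is the normal approximation with tie correction
    (continuity-corrected); ``method="exact"`` switches to the exact null
    distribution (small samples, no ties)."""
    x, y = np.asarray(x, dtype=float), np.asarray(y, dtype=float)
    if len(x) < 1 or len(y) < 1:
        raise ValueError("each group needs n >= 1")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    p = float(res.pvalue)
    if not np.isfinite(p):  # all values tied: zero-variance normal approximation
        p = 1.0
    med = lambda v: {"median": float(np.median(v)),
                     "iqr": float(np.subtract(*np.percentile(v, [75, 25])))}
    return TestResult(
        test="mann_whitney_u",
        statistic=float(res.statistic),
        pvalue=min(p, 1.0),
        n=(len(x), len(y)),
        summaries={"group_x": med(x), "group_y": med(y)},
    )


def chi_square_2xk(table, correction: bool = False) -> TestResult:
    """Pearson chi-square on an r × k contingency table (no Yates correction
    by default); df = (r−1)(k−1)."""
    table = np.asarray(table)
    if np.any(table < 0) or not np.issubdtype(table.dtype, np.integer):
        table = table.astype(float)
        if np.any(table < 0) or np.any(table != np.round(table)):
            raise ValueError("counts must be nonnegative integers")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("zero row/column sum gives an expected cell of 0")
    stat, p, dof, expected = stats.chi2_contingency(table, correction=correction)
    return TestResult(
        test="pearson_chi2",
        statistic=float(stat),
        pvalue=float(p),
        n=(int(table.sum()),),
        summaries={"df": int(dof)},
    )


def mcnemar(b: int, c: int, exact: bool | None = None) -> TestResult:
    """McNemar test on discordant-pair counts ``b`` and ``c``.

    Continuity-corrected chi-square by default; exact binomial when
    ``exact=True`` or when b + c < 25.
    """
    if b < 0 or c < 0:
        raise ValueError("discordant counts must be nonnegative")
    n_disc = b + c
    if n_disc == 0:
        return TestResult("mcnemar_exact", 0.0, 1.0, (0,), {"b": b, "c": c})
    use_exact = exact if exact is not None else n_disc < 25
    if use_exact:
        p = float(stats.binomtest(min(b, c), n_disc, 0.5, alternative="two-sided").pvalue)
        return TestResult("mcnemar_exact", float(min(b, c)), min(p, 1.0), (n_disc,), {"b": b, "c": c})
    stat = (abs(b - c) - 1) ** 2 / n_disc
    p = float(stats.chi2.sf(stat, df=1))
    return TestResult("mcnemar_cc", float(stat), p, (n_disc,), {"b": b, "c": c})


def sample_size_sensitivity(p_expected: float, margin: float, alpha: float = 0.05) -> int:
    """Cases needed to estimate a sensitivity ``p_expected`` to within
    ``margin`` at confidence 1 − ``alpha``:  ceil(z²·p(1−p)/margin²)."""
    if not 0 < p_expected < 1:
        raise ValueError("p_expected must lie strictly in (0, 1)")
    if margin <= 0 or not 0 < alpha < 1:
        raise ValueError("margin must be > 0 and alpha in (0, 1)")
    z = stats.norm.ppf(1 - alpha / 2)
    return int(math.ceil(z * z * p_expected * (1 - p_expected) / margin**2))
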