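"""Descriptive and inferential statistics for the mask-comparison cohort.

The volume distributions of glioblastoma cohorts are heavily right-skewed,
so the analysis follows the non-parametric route: D'Agostino-Pearson
normality screening, Wilcoxon matched-pairs signed-rank tests for paired
volume comparisons, and tie-aware Spearman rank correlation.

The Wilcoxon test is implemented here rather than delegated: zero
differences are discarded before ranking (Wilcoxon's original method;
Pratt's zero-rank method is available as an option), ties in the absolute
differences receive average ranks, the statistic is W = min(W+, W-), and
the two-tailed p-value is exact — computed from the full null distribution
of W+ over all 2^n sign assignments — whenever there are no ties and the
effective n is small, otherwise a normal approximation with tie and
continuity corrections is used.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .eor import cohort_eor
from .mask_io import CaseRecord

__all__ = [
    "SummaryStats",
    "PairedDiffSummary",
    "TestResult",
    "DegenerateDataError",
    "summarize",
    "paired_differences",
    "wilcoxon_signed_rank",
    "dagostino_pearson",
    "spearman",
    "analyze_cohort",
]


class DegenerateDataError(ValueError):
    """Raised when a statistic is undefined for the given data."""


@dataclass(frozen=True)
class SummaryStats:
    n: int
    mean: float
    sd: float
    median: float
    q25: float
    q75: float
    min: float
    max: float

    def to_dict(self) -> dict:
        return {
            "n": self.n,
            "mean": self.mean,
            "sd": self.sd,
            "median": self.median,
            "q25": self.q25,
            "q75": self.q75,
            "min": self.min,
            "max": self.max,
        }


@dataclass(frozen=True)
class PairedDiffSummary:
    """Per-case differences b - a, their median, and the median magnitude.

    The median of |differences| is reported alongside the median difference
    because positive and negative per-case differences cancel in the latter.
    """

    diffs: tuple
    median_diff: float
    median_abs_diff: float

    @property
    def n(self) -> int:
        return len(self.diffs)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n_effective: int

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic,
            "p_value": self.p_value,
            "method": self.method,
            "n_effective": self.n_effective,
        }


def _clean(values: Sequence) -> np.ndarray:
    arr = np.asarray(
        [v for v in values if v is not None and not (isinstance(v, float) and math.isnan(v))],
        dtype=float,
    )
    return arr


def summarize(values: Sequence[float]) -> SummaryStats:
    """Mean, sample SD (n-1), median and quartiles of the nonmissing values."""
    arr = _clean(values)
    if arr.size == 0:
        raise DegenerateDataError("summarize requires at least one nonmissing value")
    return SummaryStats(
        n=int(arr.size),
        mean=float(arr.mean()),
        sd=float(arr.std(ddof=1)) if arr.size > 1 else float("nan"),
        median=float(np.median(arr)),
        q25=float(np.percentile(arr, 25)),
        q75=float(np.percentile(arr, 75)),
        min=float(arr.min()),
        max=float(arr.max()),
    )


def paired_differences(a: Sequence, b: Sequence) -> PairedDiffSummary:
    """Elementwise differences b - a over pairwise-complete observations."""
    if len(a) != len(b):
        raise ValueError(f"paired inputs differ in length: {len(a)} vs {len(b)}")
    diffs = [
        float(bv) - float(av)
        for av, bv in zip(a, b)
        if av is not None and bv is not None
        and not (isinstance(av, float) and math.isnan(av))
        and not (isinstance(bv, float) and math.isnan(bv))
    ]
    if not diffs:
        raise DegenerateDataError("no complete pairs")
    arr = np.asarray(diffs)
    return PairedDiffSummary(
        diffs=tuple(diffs),
        median_diff=float(np.median(arr)),
        median_abs_diff=float(np.median(np.abs(arr))),
    )


def _signed_rank_null_counts(ranks: np.ndarray) -> np.ndarray:
    """Counts of each achievable W+ value over all 2^n sign assignments.

    Integer ranks only (no ties).  Dynamic programming over the generating
    polynomial prod_r (1 + x^r); equivalent to full enumeration.
    """
    total = int(ranks.sum())
    counts = np.zeros(total + 1, dtype=np.float64)
    counts[0] = 1.0
    for r in ranks.astype(int):
        counts[r:] += counts[:-r] if r > 0 else counts
    return counts


def wilcoxon_signed_rank(
    diffs: Sequence[float],
    zero_method: str = "discard",
    exact_max_n: int = 20,
) -> TestResult:
    """Two-tailed Wilcoxon matched-pairs signed-rank test on paired differences.

    Parameters
    ----------
    diffs : per-pair differences (b - a)
    zero_method : "discard" drops zero differences before ranking (default);
        "pratt" ranks them and then drops their ranks from both sums.
    exact_max_n : largest effective n for which the exact null distribution
        is enumerated (only when there are no ties among |diffs|).
    """
    if zero_method not in ("discard", "pratt"):
        raise ValueError(f"unknown zero_method {zero_method!r}")
    d = _clean(diffs)
    if d.size == 0:
        raise DegenerateDataError("no differences supplied")
    nonzero = d[d != 0]
    if nonzero.size == 0:
        raise DegenerateDataError("all differences are zero; test degenerate")

    if zero_method == "discard":
        d_used = nonzero
        n_zero = 0
    else:
        d_used = d
        n_zero = int(d.size - nonzero.size)

    n = int(d_used.size)
    abs_d = np.abs(d_used)
    ranks = stats.rankdata(abs_d)  # average ranks for ties
    if zero_method == "pratt":
        keep = d_used != 0
        w_plus = float(ranks[keep & (d_used > 0)].sum())
        w_minus = float(ranks[keep & (d_used < 0)].sum())
    else:
        w_plus = float(ranks[d_used > 0].sum())
        w_minus = float(ranks[d_used < 0].sum())
    w = min(w_plus, w_minus)

    has_ties = np.unique(abs_d).size != abs_d.size
    n_eff = n - n_zero

    if zero_method == "discard" and not has_ties and n <= exact_max_n:
        counts = _signed_rank_null_counts(ranks)
        total = counts.sum()
        p = min(1.0, 2.0 * counts[: int(w) + 1].sum() / total)
        method = "exact"
    else:
        if zero_method == "pratt":
            mean_w = (n * (n + 1) - n_zero * (n_zero + 1)) / 4.0
            var_w = (
                n * (n + 1) * (2 * n + 1) - n_zero * (n_zero + 1) * (2 * n_zero + 1)
            ) / 24.0
        else:
            mean_w = n * (n + 1) / 4.0
            var_w = n * (n + 1) * (2 * n + 1) / 24.0
        # tie correction over the ranks actually contributing to W
        ranks_for_ties = ranks[d_used != 0] if zero_method == "pratt" else ranks
        _, tie_counts = np.unique(ranks_for_ties, return_counts=True)
        var_w -= float((tie_counts**3 - tie_counts).sum()) / 48.0
        if var_w <= 0:
            raise DegenerateDataError("zero variance in signed-rank statistic")
        # continuity correction: shift |W - mean| toward the mean by 0.5
        z = (abs(w_plus - mean_w) - 0.5) / math.sqrt(var_w)
        z = max(z, 0.0)
        p = float(min(1.0, 2.0 * stats.norm.sf(z)))
        method = "approximate"
    return TestResult(statistic=w, p_value=p, method=method, n_effective=n_eff)


def dagostino_pearson(values: Sequence[float]) -> TestResult:
    """D'Agostino-Pearson omnibus normality test.

    K^2 = Z(skewness)^2 + Z(kurtosis)^2, referred to chi-square with 2 df.
    Undefined below n = 8 and for constant data.
    """
    arr = _clean(values)
    if arr.size < 8:
        raise DegenerateDataError(
            f"D'Agostino-Pearson requires n >= 8, got n = {arr.size}"
        )
    if np.ptp(arr) == 0:
        raise DegenerateDataError("normality test undefined for constant data")
    k2, p = stats.normaltest(arr)
    return TestResult(
        statistic=float(k2),
        p_value=float(p),
        method="approximate",
        n_effective=int(arr.size),
    )


def _rank_correlation(rx: np.ndarray, ry: np.ndarray) -> float:
    rxc = rx - rx.mean()
    ryc = ry - ry.mean()
    denom = math.sqrt(float((rxc**2).sum() * (ryc**2).sum()))
    if denom == 0:
        raise DegenerateDataError("Spearman undefined for constant input")
    return float((rxc * ryc).sum() / denom)


def spearman(
    x: Sequence[float],
    y: Sequence[float],
    exact: bool = False,
) -> TestResult:
    """Tie-aware Spearman rank correlation with two-tailed p-value.

    rho is the Pearson correlation of the average-rank vectors; p comes from
    the t-distribution approximation, or (``exact=True``, n <= 10 only) from
    full enumeration of the permutation null.
    """
    if len(x) != len(y):
        raise ValueError("x and y differ in length")
    pairs = [
        (float(xv), float(yv))
        for xv, yv in zip(x, y)
        if xv is not None and yv is not None
        and not (isinstance(xv, float) and math.isnan(xv))
        and not (isinstance(yv, float) and math.isnan(yv))
    ]
    if len(pairs) < 3:
        raise DegenerateDataError("Spearman requires at least 3 complete pairs")
    xa = np.array([p[0] for p in pairs])
    ya = np.array([p[1] for p in pairs])
    if np.ptp(xa) == 0 or np.ptp(ya) == 0:
        raise DegenerateDataError("Spearman undefined for constant input")
    n = len(pairs)
    rx = stats.rankdata(xa)
    ry = stats.rankdata(ya)
    rho = _rank_correlation(rx, ry)

    if exact:
        if n > 10:
            raise ValueError("exact permutation p only supported for n <= 10")
        rxc = rx - rx.mean()
        norm = math.sqrt(float((rxc**2).sum() * ((ry - ry.mean()) ** 2).sum()))
        observed = abs(float((rxc * (ry - ry.mean())).sum()))
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            s = abs(float((rxc * (np.asarray(perm) - ry.mean())).sum()))
            if s >= observed - 1e-12 * norm:
                count += 1
            total += 1
        return TestResult(
            statistic=rho, p_value=count / total, method="exact", n_effective=n
        )

    if abs(rho) >= 1.0:
        p = 0.0
    else:
        t = rho * math.sqrt((n - 2) / (1.0 - rho**2))
        p = float(min(1.0, 2.0 * stats.t.sf(abs(t), df=n - 2)))
    return TestResult(statistic=rho, p_value=p, method="approximate", n_effective=n)


# ---------------------------------------------------------------------------
# Cohort-level report


def _col(records, name):
    return [getattr(r, name) for r in records]


def analyze_cohort(
    records: Sequence[CaseRecord],
    gtr_epsilon: float = 0.0,
    wilcoxon_zero_method: str = "discard",
    exact_max_n: int = 20,
) -> dict:
    """Full cohort report: pre-resectional agreement analysis between MRI and
    ultrasound segmentations, and post-resectional extent-of-resection
    analysis.

    Records flagged ``exclude_pre`` contribute to no pre-resectional
    statistic; ``exclude_post`` likewise for the post-resectional block.
    Paired analyses use pairwise-complete observations.
    """
    pre = [r for r in records if not r.exclude_pre]
    report: dict = {
        "config": {
            "gtr_epsilon_cm3": gtr_epsilon,
            "wilcoxon_zero_method": wilcoxon_zero_method,
            "exact_test_max_n": exact_max_n,
        },
        "exclusions": {
            "pre": {
                r.case_id: r.exclude_pre_reason for r in records if r.exclude_pre
            },
            "post": {
                r.case_id: r.exclude_post_reason for r in records if r.exclude_post
            },
        },
    }

    pre_block: dict = {"n_records": len(pre)}
    for key, column in [
        ("volume_mri_cm3", "vol_pre_mri_cm3"),
        ("volume_us_cm3", "vol_pre_us_cm3"),
        ("dice", "dice"),
        ("cog_offset_mm", "cog_offset_mm"),
        ("hausdorff_mm", "hausdorff_mm"),
    ]:
        values = _clean(_col(pre, column))
        pre_block[key] = summarize(values).to_dict() if values.size else None

    mri = _col(pre, "vol_pre_mri_cm3")
    us = _col(pre, "vol_pre_us_cm3")
    try:
        pdiff = paired_differences(mri, us)
        pre_block["paired_volume_diff_cm3"] = {
            "n": pdiff.n,
            "median_diff": pdiff.median_diff,
            "median_abs_diff": pdiff.median_abs_diff,
        }
        pre_block["wilcoxon_volume"] = wilcoxon_signed_rank(
            pdiff.diffs, zero_method=wilcoxon_zero_method, exact_max_n=exact_max_n
        ).to_dict()
    except DegenerateDataError:
        pre_block["paired_volume_diff_cm3"] = None
        pre_block["wilcoxon_volume"] = None

    pre_block["normality"] = {}
    for key, column in [("volume_mri_cm3", "vol_pre_mri_cm3"), ("volume_us_cm3", "vol_pre_us_cm3")]:
        values = _clean(_col(pre, column))
        try:
            pre_block["normality"][key] = dagostino_pearson(values).to_dict()
        except DegenerateDataError:
            pre_block["normality"][key] = None

    for key, column in [
        ("spearman_dice_volume_mri", "vol_pre_mri_cm3"),
        ("spearman_dice_volume_us", "vol_pre_us_cm3"),
    ]:
        try:
            pre_block[key] = spearman(_col(pre, "dice"), _col(pre, column)).to_dict()
        except DegenerateDataError:
            pre_block[key] = None
    report["pre_resectional"] = pre_block

    # ---- post-resectional block
    post = [r for r in records if not r.exclude_post]
    eor_summary = cohort_eor(records, gtr_epsilon=gtr_epsilon)
    post_block: dict = {"n_records": len(post), "eor": eor_summary.to_dict()}

    analyzed_ids = {s.case_id for s in eor_summary.statuses}
    analyzed = [r for r in post if r.case_id in analyzed_ids]
    for key, column in [
        ("volume_post_us_cm3", "vol_post_us_cm3"),
        ("volume_post_mri_cm3", "vol_post_mri_cm3"),
    ]:
        values = _clean(_col(analyzed, column))
        post_block[key] = summarize(values).to_dict() if values.size else None

    str_ids = {s.case_id for s in eor_summary.statuses if s.category == "STR"}
    str_records = [r for r in analyzed if r.case_id in str_ids]
    if str_records:
        sub: dict = {
            "n": len(str_records),
            "residual_us_cm3": summarize(_col(str_records, "vol_post_us_cm3")).to_dict(),
        }
        mri_values = _clean(_col(str_records, "vol_post_mri_cm3"))
        sub["residual_mri_cm3"] = summarize(mri_values).to_dict() if mri_values.size else None
        try:
            pdiff = paired_differences(
                _col(str_records, "vol_post_us_cm3"), _col(str_records, "vol_post_mri_cm3")
            )
            sub["wilcoxon_residual"] = wilcoxon_signed_rank(
                pdiff.diffs, zero_method=wilcoxon_zero_method, exact_max_n=exact_max_n
            ).to_dict()
        except DegenerateDataError:
            sub["wilcoxon_residual"] = None
        post_block["str_subgroup"] = sub
    else:
        post_block["str_subgroup"] = None
    report["post_resectional"] = post_block
    return report
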