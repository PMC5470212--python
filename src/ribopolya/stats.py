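"""Concordance statistics between library types, and inducible-gene sets.

Wraps the standard tests (Pearson/Spearman correlation, Welch's t,
Mann-Whitney U) around scipy, implements Cliff's delta — the dominance-based
effect size used to judge whether the gap between polyA+ and ribo-minus TPM
distributions is negligible — and provides the stimulus-inducible gene-set
rule (detected at both timepoints, log2 fold change above a cutoff) with
Venn-region partitioning for comparing the sets found by each library type.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "EffectSizeResult",
    "SetComparison",
    "correlate",
    "welch_t",
    "mann_whitney",
    "cliffs_delta",
    "log2_fold_change",
    "inducible_set",
    "venn_region_counts",
    "top_fraction_by_abs_difference",
    "paired_log2_values",
]

# dominance-effect magnitude cutoffs: |d| < 0.147 negligible, >= 0.60 large
NEGLIGIBLE_DELTA = 0.147
LARGE_DELTA = 0.60


@dataclass
class EffectSizeResult:
    delta: float
    ci_low: float
    ci_high: float
    magnitude: str  # negligible | intermediate | large

    def __post_init__(self) -> None:
        if not -1.0 <= self.delta <= 1.0:
            raise ValueError("delta out of [-1, 1]")
        if not self.ci_low <= self.delta <= self.ci_high:
            raise ValueError("CI must bracket delta")


def correlate(x: Sequence[float], y: Sequence[float], method: str = "pearson"):
    """Pearson or Spearman correlation with two-sided p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance in input")
    if method == "pearson":
        res = sps.pearsonr(x, y)
    elif method == "spearman":
        res = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(res.statistic), float(res.pvalue)


def welch_t(x: Sequence[float], y: Sequence[float], equal_var: bool = False):
    """Two-sample t-test, unequal-variance (Welch) by default; two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("need >= 2 observations per group")
    if np.ptp(x) == 0 and np.ptp(y) == 0:
        raise ValueError("zero variance in both groups")
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    return float(res.statistic), float(res.pvalue)


def mann_whitney(x: Sequence[float], y: Sequence[float]):
    """Mann-Whitney U (x-side statistic) with two-sided p-value.

    Exact enumeration when both groups have <= 20 tie-free observations;
    otherwise the normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("need >= 1 observation per group")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < pooled.size
    method = "exact" if (x.size <= 20 and y.size <= 20 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)


def cliffs_delta(x: Sequence[float], y: Sequence[float],
                 confidence: float = 0.95) -> EffectSizeResult:
    """Cliff's delta with a 95% confidence interval.

    delta = (#{x_i > y_j} - #{x_i < y_j}) / (n*m): the difference between
    the probability that a value from ``x`` dominates one from ``y`` and the
    reverse; ties contribute 0.  The interval uses Cliff's consistent
    variance estimate with the asymmetric normal-method bounds, clipped to
    [-1, 1].  Magnitudes: |d| < 0.147 negligible, < 0.60 intermediate,
    else large.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n, m = x.size, y.size
    if n < 1 or m < 1:
        raise ValueError("need >= 1 observation per group")

    # dominance matrix in manageable blocks (sign of x_i - y_j)
    block = max(1, int(2e7) // max(m, 1))
    row_means = np.empty(n)
    col_sums = np.zeros(m)
    sq_sum = 0.0
    total = 0.0
    for start in range(0, n, block):
        d = np.sign(x[start : start + block, None] - y[None, :])
        row_means[start : start + block] = d.mean(axis=1)
        col_sums += d.sum(axis=0)
        sq_sum += float((d * d).sum())
        total += float(d.sum())
    delta = total / (n * m)
    col_means = col_sums / n

    if n > 1 and m > 1:
        var_rows = float(((row_means - delta) ** 2).sum())
        var_cols = float(((col_means - delta) ** 2).sum())
        # sum over all entries of (d_ij - delta)^2 = sum d_ij^2 - 2 delta sum d_ij + nm delta^2
        var_all = sq_sum - 2 * delta * total + n * m * delta**2
        sigma2 = (m**2 * var_rows + n**2 * var_cols - var_all) / (n * m * (n - 1) * (m - 1))
        sigma2 = max(sigma2, 0.0)
    else:
        sigma2 = 0.0

    z = sps.norm.ppf(1 - (1 - confidence) / 2)
    denom = 1 - delta**2 + z**2 * sigma2
    if denom <= 0 or (abs(delta) == 1.0 and sigma2 == 0.0):
        lo = hi = delta
    else:
        half = z * math.sqrt(sigma2) * math.sqrt(
            max((1 - delta**2) ** 2 + z**2 * sigma2, 0.0)
        )
        lo = (delta - delta**3 - half) / denom
        hi = (delta - delta**3 + half) / denom
    lo = min(max(lo, -1.0), delta)
    hi = max(min(hi, 1.0), delta)

    mag = ("negligible" if abs(delta) < NEGLIGIBLE_DELTA
           else "large" if abs(delta) >= LARGE_DELTA
           else "intermediate")
    return EffectSizeResult(delta=float(delta), ci_low=float(lo), ci_high=float(hi),
                            magnitude=mag)


def log2_fold_change(post_tpm: float, pre_tpm: float) -> float:
    """log2(post / pre); both inputs must be positive."""
    if post_tpm <= 0 or pre_tpm <= 0:
        raise ValueError("fold change requires positive TPM on both sides")
    return math.log2(post_tpm / pre_tpm)


def inducible_set(
    pre_profile: pd.Series,
    post_profile: pd.Series,
    tpm_threshold: float = 1.0,
    lfc_threshold: float = 2.0,
) -> set[str]:
    """Genes induced by a stimulus: TPM strictly > threshold at BOTH
    timepoints and log2 fold change strictly > ``lfc_threshold``."""
    shared = pre_profile.index.intersection(post_profile.index)
    pre = pre_profile.loc[shared]
    post = post_profile.loc[shared]
    detected = (pre > tpm_threshold) & (post > tpm_threshold)
    out: set[str] = set()
    for g in shared[detected]:
        if log2_fold_change(post[g], pre[g]) > lfc_threshold:
            out.add(g)
    return out


@dataclass
class SetComparison:
    """Disjoint Venn-region counts over 2-4 named sets."""

    set_names: list[str]
    region_counts: dict[frozenset, int]

    @property
    def union_size(self) -> int:
        return sum(self.region_counts.values())


def venn_region_counts(sets: Mapping[str, Iterable]) -> SetComparison:
    """Counts for every non-empty region of the inclusion-exclusion partition.

    Each element of the union is assigned to exactly one region — the subset
    of set names containing it — so the counts are disjoint and sum to the
    union size.
    """
    names = list(sets)
    if not 2 <= len(names) <= 4:
        raise ValueError("need 2-4 sets")
    materialized = {name: set(s) for name, s in sets.items()}
    counts: dict[frozenset, int] = {
        frozenset(combo): 0
        for r in range(1, len(names) + 1)
        for combo in itertools.combinations(names, r)
    }
    union = set().union(*materialized.values())
    for element in union:
        signature = frozenset(n for n in names if element in materialized[n])
        counts[signature] += 1
    return SetComparison(set_names=names, region_counts=counts)


def top_fraction_by_abs_difference(
    profile_a: pd.Series, profile_b: pd.Series, fraction: float = 0.05
) -> set[str]:
    """Genes in the top ``fraction`` of the |profile_a - profile_b| distribution
    (the selection rule feeding enrichment analyses; the enrichment itself is
    out of scope here)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    shared = profile_a.index.intersection(profile_b.index)
    diff = (profile_a.loc[shared] - profile_b.loc[shared]).abs().sort_values(ascending=False)
    k = max(1, int(round(fraction * len(diff))))
    return set(diff.index[:k])


def paired_log2_values(
    profile_a: pd.Series,
    profile_b: pd.Series,
    detect_threshold: float = 1.0,
    log_scale: bool = True,
) -> tuple[np.ndarray, np.ndarray]:
    """Paired per-gene values for distribution comparisons.

    Restricts to genes detected (TPM > threshold) in BOTH profiles and, by
    default, returns log2 values — the scale on which binned TPM
    distributions and their means are coherent.  ``log_scale=False`` returns
    raw TPM.
    """
    shared = profile_a.index.intersection(profile_b.index)
    a = profile_a.loc[shared]
    b = profile_b.loc[shared]
    keep = (a > detect_threshold) & (b > detect_threshold)
    a, b = a[keep].to_numpy(), b[keep].to_numpy()
    if log_scale:
        a, b = np.log2(a), np.log2(b)
    return a, b
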