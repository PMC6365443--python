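"""Resampling inference for typicality scores and ratings.

Covers the rating-side statistics (per-face aggregation, Cronbach's
alpha with raters as items), Kendall rank correlations with
case-resampling bootstrap confidence intervals, a bootstrap test for
the difference between two dependent Kendall correlations sharing one
variable, a two-group permutation test on the distance between mean
shapes, and morphological disparity (Procrustes variance) with a
permutation test on the group difference.

Every resampling routine takes an explicit integer seed and records it
in its result object; identical seeds give bit-identical results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConstantInputError, GroupError
from .superimposition import GPAResult

__all__ = [
    "aggregate_ratings",
    "cronbach_alpha",
    "kendall_tau",
    "BootstrapCI",
    "bootstrap_tau_ci",
    "CorrelationComparison",
    "bootstrap_tau_difference_test",
    "MeanShapeTest",
    "mean_shape_permutation_test",
    "DisparityResult",
    "morphological_disparity",
]


# ---------------------------------------------------------------------------
# Ratings
# ---------------------------------------------------------------------------

def aggregate_ratings(ratings: pd.DataFrame) -> pd.Series:
    """Mean rating per face over the raters who saw it.

    ``ratings`` is raters x faces with NaN for unseen faces (each rater
    typically sees a random subset). Raises if any face has no rating.
    """
    counts = ratings.notna().sum(axis=0)
    empty = list(counts.index[counts == 0])
    if empty:
        raise ValueError(f"faces with zero ratings: {empty}")
    return ratings.mean(axis=0, skipna=True)


def cronbach_alpha(ratings: pd.DataFrame) -> float:
    """Cronbach's alpha with raters as items and faces as cases.

    alpha = k/(k-1) * (1 - sum of rater variances / variance of rater
    sums). Incomplete designs are handled through pairwise-complete
    covariance estimation, with a warning.
    """
    if ratings.shape[0] < 2:
        raise ValueError("Cronbach's alpha needs at least two raters")
    k = ratings.shape[0]
    if ratings.isna().any().any():
        warnings.warn(
            "rating matrix is incomplete; using pairwise-complete covariances"
        )
    cov = ratings.T.cov()  # raters x raters, pairwise-complete
    total_var = float(cov.values.sum())
    item_var = float(np.trace(cov.values))
    if total_var <= 0:
        raise ConstantInputError("zero total variance; alpha undefined")
    return k / (k - 1) * (1.0 - item_var / total_var)


# ---------------------------------------------------------------------------
# Kendall correlations and bootstraps
# ---------------------------------------------------------------------------

def kendall_tau(x, y) -> float:
    """Kendall's tau-b (tie-corrected) rank correlation."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 2:
        raise ValueError("x and y must be equal-length vectors of length >= 2")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ConstantInputError("tau undefined for a constant vector")
    return float(stats.kendalltau(x, y, variant="b").statistic)


@dataclass
class BootstrapCI:
    """Percentile bootstrap interval for Kendall's tau."""

    estimate: float
    lower: float
    upper: float
    B: int
    seed: int
    n_skipped: int = 0


def bootstrap_tau_ci(metric, ratings, B: int = 10_000, seed: int = 0) -> BootstrapCI:
    """Case-resampling percentile CI for tau(metric, ratings).

    Faces are resampled with replacement keeping (metric, rating) pairs
    intact; the interval is the 2.5/97.5 percentile of the replicate
    taus. Degenerate replicates (a constant resampled vector) are
    skipped and counted, with a warning if they exceed 1% of B.
    """
    x = np.asarray(metric, float)
    y = np.asarray(ratings, float)
    if B < 100:
        raise ValueError("B must be at least 100")
    est = kendall_tau(x, y)
    rng = np.random.default_rng(seed)
    n = len(x)
    taus = np.empty(B)
    skipped = 0
    filled = 0
    while filled < B:
        idx = rng.integers(0, n, size=n)
        xb, yb = x[idx], y[idx]
        if np.ptp(xb) == 0 or np.ptp(yb) == 0:
            skipped += 1
            if skipped > B:  # pathological input; give up rather than loop
                raise ConstantInputError("bootstrap resamples persistently degenerate")
            continue
        taus[filled] = stats.kendalltau(xb, yb, variant="b").statistic
        filled += 1
    if skipped > 0.01 * B:
        warnings.warn(f"{skipped} degenerate bootstrap replicates were skipped")
    lo, hi = np.percentile(taus, [2.5, 97.5])
    return BootstrapCI(estimate=est, lower=float(lo), upper=float(hi), B=B, seed=seed, n_skipped=skipped)


@dataclass
class CorrelationComparison:
    """Two dependent Kendall correlations sharing the rating variable."""

    tau_ctdm: float
    tau_dfom: float
    ci_ctdm: BootstrapCI
    ci_dfom: BootstrapCI
    observed_diff: float
    p_diff: float
    B: int
    seed: int
    null_scheme: str


def bootstrap_tau_difference_test(
    ctdm,
    dfom,
    ratings,
    B: int = 10_000,
    seed: int = 0,
    null_scheme: str = "resample",
    compute_cis: bool = True,
    ci_B: int | None = None,
) -> CorrelationComparison:
    """Bootstrap test for tau(ctdm, ratings) - tau(dfom, ratings).

    The two score vectors stay fixed (preserving their mutual
    dependence) while the shared rating vector is resampled i.i.d. with
    replacement under the null (``null_scheme="permute"`` shuffles it
    instead); the two-sided p-value uses the add-one convention
    ``p = (1 + #{|diff*| >= |observed|}) / (B + 1)``. Confidence
    intervals for each tau come from the paired case-resampling
    bootstrap on the same seed stream.
    """
    x = np.asarray(ctdm, float)
    z = np.asarray(dfom, float)
    y = np.asarray(ratings, float)
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(z)) and np.all(np.isfinite(y))):
        raise ValueError("inputs must be finite")
    if B < 1000:
        raise ValueError("B must be at least 1000")
    if null_scheme not in ("resample", "permute"):
        raise ValueError("null_scheme must be 'resample' or 'permute'")
    tau_x = kendall_tau(x, y)
    tau_z = kendall_tau(z, y)
    observed = tau_x - tau_z
    rng = np.random.default_rng(seed)
    n = len(y)
    exceed = 0
    for _ in range(B):
        if null_scheme == "resample":
            ystar = y[rng.integers(0, n, size=n)]
        else:
            ystar = y[rng.permutation(n)]
        if np.ptp(ystar) == 0:
            exceed += 1  # a constant draw carries no evidence against H0
            continue
        d = (
            stats.kendalltau(x, ystar, variant="b").statistic
            - stats.kendalltau(z, ystar, variant="b").statistic
        )
        if abs(d) >= abs(observed) - 1e-15:
            exceed += 1
    p = (1 + exceed) / (B + 1)

    ci_B = ci_B or B
    if compute_cis:
        ci_seed = int(np.random.SeedSequence(seed).generate_state(2)[1] % (2**31))
        ci_x = bootstrap_tau_ci(x, y, B=ci_B, seed=ci_seed)
        ci_z = bootstrap_tau_ci(z, y, B=ci_B, seed=ci_seed)
    else:
        ci_x = BootstrapCI(tau_x, np.nan, np.nan, 0, seed)
        ci_z = BootstrapCI(tau_z, np.nan, np.nan, 0, seed)
    return CorrelationComparison(
        tau_ctdm=tau_x,
        tau_dfom=tau_z,
        ci_ctdm=ci_x,
        ci_dfom=ci_z,
        observed_diff=observed,
        p_diff=p,
        B=B,
        seed=seed,
        null_scheme=null_scheme,
    )


# ---------------------------------------------------------------------------
# Shape-space permutation tests
# ---------------------------------------------------------------------------

@dataclass
class MeanShapeTest:
    """Permutation test on the distance between two group mean shapes."""

    pdm: float
    p: float
    n_perm: int
    seed: int
    groups: tuple[str, str]


def mean_shape_permutation_test(
    result: GPAResult, labels, groups: tuple[str, str], n_perm: int = 999, seed: int = 0
) -> MeanShapeTest:
    """Compare the observed inter-mean distance to label permutations.

    The statistic is the tangent-space Euclidean distance between the
    two group means (PDM); permutations reassign specimens to groups
    preserving group sizes; ``p = (1 + #{PDM* >= PDM}) / (n_perm + 1)``.
    """
    labels = np.asarray(labels, dtype=object)
    a, b = groups
    mask_a = labels == a
    mask_b = labels == b
    if mask_a.sum() < 2 or mask_b.sum() < 2:
        raise GroupError("each group needs at least two members")
    if n_perm < 99:
        warnings.warn("fewer than 99 permutations gives a coarse p-value")
    # canonicalize: smaller label first, rows in original order, so the
    # p-value does not depend on the order the two groups are named in
    first, second = sorted((str(a), str(b)))
    mask_first = labels == (a if str(a) == first else b)
    mask_second = labels == (b if str(a) == first else a)
    n_a = int(mask_first.sum())
    flat = np.concatenate([result.flat[mask_first], result.flat[mask_second]])
    observed = float(np.linalg.norm(flat[:n_a].mean(axis=0) - flat[n_a:].mean(axis=0)))
    rng = np.random.default_rng(seed)
    count = 0
    n_total = flat.shape[0]
    for _ in range(n_perm):
        perm = rng.permutation(n_total)
        pa = flat[perm[:n_a]].mean(axis=0)
        pb = flat[perm[n_a:]].mean(axis=0)
        if np.linalg.norm(pa - pb) >= observed - 1e-15:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return MeanShapeTest(pdm=observed, p=p, n_perm=n_perm, seed=seed, groups=(str(a), str(b)))


@dataclass
class DisparityResult:
    """Procrustes variance per group and a permutation test on the difference."""

    md: dict
    pairwise_diff: float
    p: float
    n_perm: int
    seed: int
    divisor: str


def _disparities(flat: np.ndarray, labels: np.ndarray, divisor: str) -> dict:
    out = {}
    for g in pd.unique(labels):
        grp = flat[labels == g]
        n_g = len(grp)
        dev = grp - grp.mean(axis=0)
        ss = float(np.sum(dev**2))
        out[g] = ss / (n_g if divisor == "n" else n_g - 1)
    return out


def morphological_disparity(
    result: GPAResult,
    labels,
    n_perm: int = 9_999,
    seed: int = 0,
    divisor: str = "n",
) -> DisparityResult:
    """Morphological disparity (Procrustes variance) with a permutation test.

    MD(g) is the summed squared tangent-space deviation of group
    members from their group mean divided by group size (``divisor="n-1"``
    for the unbiased variant); for two groups the test statistic is
    |MD difference| under label permutation.
    """
    labels = np.asarray(labels, dtype=object)
    uniq = list(pd.unique(labels))
    for g in uniq:
        if (labels == g).sum() < 2:
            raise GroupError(f"group {g!r} has fewer than two members")
    if divisor not in ("n", "n-1"):
        raise ValueError("divisor must be 'n' or 'n-1'")
    flat = result.flat
    md = _disparities(flat, labels, divisor)
    if len(uniq) != 2:
        raise GroupError("the permutation test is defined for exactly two groups")
    observed = abs(md[uniq[0]] - md[uniq[1]])
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm_labels = labels[rng.permutation(len(labels))]
        md_star = _disparities(flat, perm_labels, divisor)
        if abs(md_star[uniq[0]] - md_star[uniq[1]]) >= observed - 1e-15:
            count += 1
    p = (1 + count) / (n_perm + 1)
    return DisparityResult(
        md={str(k): float(v) for k, v in md.items()},
        pairwise_diff=float(observed),
        p=p,
        n_perm=n_perm,
        seed=seed,
        divisor=divisor,
    )
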