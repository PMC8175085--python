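"""Curve-comparison inference for grouped activity time series.

Two procedures tailored to population activity curves:

* a two-sample Kolmogorov-Smirnov test with an explicit critical-D
  decision rule: reject when the sup-norm ECDF distance D exceeds
  D_crit(alpha, n1, n2) = c(alpha) * sqrt((n1 + n2) / (n1 * n2)),
  c(alpha) = sqrt(ln(2 / alpha) / 2), the standard large-sample
  critical value;

* a permutation test for a difference between two population mean
  curves, permuting whole-cell curve labels (timepoints within a cell
  are autocorrelated, so the curve is the exchangeable unit), default
  statistic T = mean_t |meanA(t) - meanB(t)|.

Standard omnibus tests (Mann-Whitney, Kruskal-Wallis, ANOVA) are not
re-implemented; use :mod:`scipy.stats`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .metrics import ActivityCurve
from .rng import derived_rng

__all__ = [
    "ECDF",
    "ecdf",
    "KSResult",
    "PermResult",
    "GroupedCurves",
    "ks_two_sample",
    "ks_critical_d",
    "ks_decision",
    "curve_mean",
    "permutation_mean_curve_test",
]


# ---------------------------------------------------------------------------
# ECDF and the KS family


class ECDF:
    """Right-continuous empirical CDF: F(x) = #{points <= x} / n."""

    def __init__(self, sample) -> None:
        sample = np.asarray(sample, dtype=float).ravel()
        if sample.size == 0:
            raise ValueError("empty sample")
        if not np.all(np.isfinite(sample)):
            raise ValueError("sample must be finite")
        self.x = np.sort(sample)
        self.n = sample.size

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.searchsorted(self.x, t, side="right") / self.n
        return float(out) if out.ndim == 0 else out


def ecdf(sample) -> ECDF:
    """Empirical CDF of a finite, nonempty sample."""
    return ECDF(sample)


@dataclass
class KSResult:
    """Two-sample KS outcome with everything needed to reproduce the
    decision. ``critical_D``/``reject`` are filled by :func:`ks_decision`."""

    D: float
    n1: int
    n2: int
    p_asymptotic: float
    alpha: float | None = None
    critical_D: float | None = None
    reject: bool | None = None


def _kolmogorov_sf(lam: float, n_terms: int = 100, tol: float = 1e-10) -> float:
    """Kolmogorov distribution survival function Q(lam) =
    2 * sum_{k>=1} (-1)^{k-1} exp(-2 k^2 lam^2)."""
    if lam <= 0:
        return 1.0
    total = 0.0
    for k in range(1, n_terms + 1):
        term = 2.0 * (-1.0) ** (k - 1) * math.exp(-2.0 * k * k * lam * lam)
        total += term
        if abs(term) < tol:
            break
    return min(1.0, max(0.0, total))


def ks_two_sample(x, y) -> KSResult:
    """Two-sample KS statistic D = sup_t |F_x(t) - F_y(t)| and its
    asymptotic p-value.

    D is evaluated at every jump point of the pooled sample, which
    attains the sup for right-continuous step ECDFs. Symmetric in
    (x, y).
    """
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    fx, fy = ECDF(x), ECDF(y)
    support = np.concatenate([x, y])
    D = float(np.max(np.abs(fx(support) - fy(support))))
    en = math.sqrt(x.size * y.size / (x.size + y.size))
    p = _kolmogorov_sf(en * D)
    return KSResult(D=D, n1=int(x.size), n2=int(y.size), p_asymptotic=max(p, 1e-300))


def ks_critical_d(n1: int, n2: int, alpha: float) -> float:
    """Large-sample critical value of the two-sample KS statistic:
    D_crit = sqrt(ln(2/alpha)/2) * sqrt((n1+n2)/(n1*n2)).

    Strictly decreasing in n1, n2 and alpha; symmetric in (n1, n2).
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must lie in (0, 1)")
    c = math.sqrt(math.log(2.0 / alpha) / 2.0)
    return c * math.sqrt((n1 + n2) / (n1 * n2))


def ks_decision(x, y, alpha: float = 0.001) -> KSResult:
    """KS test with the critical-D rejection rule: reject iff
    D > D_crit(alpha, n1, n2)."""
    res = ks_two_sample(x, y)
    res.alpha = alpha
    res.critical_D = ks_critical_d(res.n1, res.n2, alpha)
    res.reject = bool(res.D > res.critical_D)
    return res


# ---------------------------------------------------------------------------
# grouped curves and the permutation test


@dataclass
class GroupedCurves:
    """A named collection of activity curves on a common time grid."""

    group_name: str
    curves: list[ActivityCurve]

    def __post_init__(self) -> None:
        if not self.curves:
            raise ValueError("a group needs at least one curve")
        grid = self.curves[0].times
        for c in self.curves[1:]:
            if c.times.shape != grid.shape or not np.allclose(c.times, grid):
                raise ValueError("all curves of a group must share the time grid")

    @property
    def n_curves(self) -> int:
        return len(self.curves)

    @property
    def times(self) -> np.ndarray:
        return self.curves[0].times

    @property
    def n_timepoints(self) -> int:
        return self.times.size

    def matrix(self) -> np.ndarray:
        return np.vstack([c.values for c in self.curves])

    def pooled_values(self) -> np.ndarray:
        """All defined values pooled across cells and timepoints — the
        sample formation used for position-vs-control KS comparisons
        (n = cells x timepoints)."""
        vals = self.matrix().ravel()
        return vals[np.isfinite(vals)]


def curve_mean(group: GroupedCurves) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Population mean curve: per-timepoint mean over curves, skipping
    undefined values. Returns (times, mean, n_used); a timepoint with no
    defined value is an error."""
    m = group.matrix()
    n_used = np.isfinite(m).sum(axis=0)
    if np.any(n_used == 0):
        raise ValueError("timepoint with zero defined values")
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(m, axis=0)
    return group.times, mean, n_used


@dataclass
class PermResult:
    """Permutation-test outcome. In sampled mode
    p = (1 + #{T_perm >= T_obs}) / (n_permutations + 1); in exact mode
    (total curves <= 10) p = #{T >= T_obs} / #assignments with the
    observed assignment included in the enumeration."""

    observed_stat: float
    n_permutations: int
    p_value: float
    seed: int
    statistic_name: str
    exact: bool = False


_STATS = {
    "l1": lambda d: float(np.mean(np.abs(d))),
    "l2": lambda d: float(np.sqrt(np.mean(d * d))),
    "sup": lambda d: float(np.max(np.abs(d))),
}


def _group_mean_diff(M: np.ndarray, idx_a: np.ndarray, idx_b: np.ndarray) -> np.ndarray:
    with np.errstate(invalid="ignore"):
        return np.nanmean(M[idx_a], axis=0) - np.nanmean(M[idx_b], axis=0)


def _canonical_rows(M: np.ndarray) -> np.ndarray:
    """Rows sorted lexicographically (NaN high) so the permutation null
    is identical however the two groups were ordered."""
    key = np.where(np.isfinite(M), M, np.inf)
    order = np.lexsort(key.T[::-1])
    return M[order]


def permutation_mean_curve_test(
    group_a: GroupedCurves,
    group_b: GroupedCurves,
    n_permutations: int = 999,
    seed: int = 0,
    statistic: str = "l1",
) -> PermResult:
    """Permutation test for a difference between two population mean curves.

    The exchangeable unit is the whole cell curve. The statistic
    (default L1) summarises |meanA(t) - meanB(t)| over the grid. With at
    most 10 curves in total, all C(n, k) group assignments are
    enumerated exactly; otherwise ``n_permutations`` random assignments
    are sampled (seeded, add-one p-value). The p-value is invariant to
    swapping the two groups.
    """
    if statistic not in _STATS:
        raise ValueError(f"unknown statistic {statistic!r}")
    if n_permutations < 99:
        raise ValueError("n_permutations must be >= 99")
    if group_a.times.shape != group_b.times.shape or not np.allclose(group_a.times, group_b.times):
        raise ValueError("groups must share the time grid")
    if group_a.n_curves < 2 or group_b.n_curves < 2:
        raise ValueError("each group needs >= 2 curves for inference")
    stat = _STATS[statistic]
    Ma, Mb = group_a.matrix(), group_b.matrix()
    t_obs = stat(_group_mean_diff(np.vstack([Ma, Mb]), np.arange(len(Ma)), len(Ma) + np.arange(len(Mb))))

    M = _canonical_rows(np.vstack([Ma, Mb]))
    n = len(M)
    k = min(len(Ma), len(Mb))  # permute the smaller group; the statistic is symmetric
    eps = 1e-12

    if n <= 10:
        count = 0
        total = 0
        all_idx = np.arange(n)
        for comb in combinations(range(n), k):
            idx_a = np.asarray(comb)
            idx_b = np.setdiff1d(all_idx, idx_a, assume_unique=True)
            t_perm = stat(_group_mean_diff(M, idx_a, idx_b))
            count += t_perm >= t_obs - eps
            total += 1
        return PermResult(
            observed_stat=t_obs,
            n_permutations=total,
            p_value=count / total,
            seed=seed,
            statistic_name=statistic,
            exact=True,
        )

    rng = derived_rng(seed, "permutation")
    finite = np.all(np.isfinite(M))
    count = 0
    if finite:
        # vectorized: all permutations at once
        perms = np.argsort(rng.random((n_permutations, n)), axis=1)
        a_idx = perms[:, :k]
        sums_a = M[a_idx].sum(axis=1)  # (P, T)
        total_sum = M.sum(axis=0)
        mean_a = sums_a / k
        mean_b = (total_sum - sums_a) / (n - k)
        diffs = mean_a - mean_b
        if statistic == "l1":
            t_perms = np.mean(np.abs(diffs), axis=1)
        elif statistic == "l2":
            t_perms = np.sqrt(np.mean(diffs * diffs, axis=1))
        else:
            t_perms = np.max(np.abs(diffs), axis=1)
        count = int(np.sum(t_perms >= t_obs - eps))
    else:
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            t_perm = stat(_group_mean_diff(M, perm[:k], perm[k:]))
            count += t_perm >= t_obs - eps
    return PermResult(
        observed_stat=t_obs,
        n_permutations=n_permutations,
        p_value=(1 + count) / (n_permutations + 1),
        seed=seed,
        statistic_name=statistic,
        exact=False,
    )
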