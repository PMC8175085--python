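"""Monte-Carlo calibration harnesses for the curve-comparison tests.

Used to verify, on the synthetic activity generator, that the KS
critical-D rule and the permutation test hold their nominal type-I
error under the null (both groups drawn from the control generator)
and that their power is monotone in the simulated effect amplitude.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .rng import derived_rng
from .stats import GroupedCurves, ks_critical_d, permutation_mean_curve_test
from .synth import CONTROL, TrajectoryParams, simulate_activity_curves

__all__ = [
    "ks_null_rejection_rate",
    "perm_null_rejection_rate",
    "ks_power",
    "perm_power",
    "binomial_ci",
]

DEFAULT_TIMES = np.arange(2.0, 23.0)  # the 21-frame early post-wound window


def binomial_ci(p: float, n: int, z: float = 1.96) -> tuple[float, float]:
    """Normal-approximation CI for an empirical rate of a true proportion p."""
    half = z * np.sqrt(p * (1.0 - p) / n)
    return p - half, p + half


def _two_group_values(
    rep: int, seed: int, n_per_group: int, times: np.ndarray, params_b: TrajectoryParams
) -> tuple[np.ndarray, np.ndarray]:
    """Pooled (cells x timepoints) samples for two groups, group A always
    from the control generator."""
    curves = simulate_activity_curves(
        {"a": (n_per_group, CONTROL), "b": (n_per_group, params_b)},
        times,
        seed=int(derived_rng(seed, "rep", rep).integers(2**31)),
    )
    a = np.vstack([c.values for c in curves if c.group_label == "a"])
    b = np.vstack([c.values for c in curves if c.group_label == "b"])
    return a, b


def _ks_rejects(a: np.ndarray, b: np.ndarray, alpha: float) -> bool:
    """Critical-D decision on the pooled per-group samples, computed with
    the sorted-sample sup formula (vectorised for the Monte-Carlo loop)."""
    x, y = np.sort(a.ravel()), np.sort(b.ravel())
    support = np.concatenate([x, y])
    fx = np.searchsorted(x, support, side="right") / x.size
    fy = np.searchsorted(y, support, side="right") / y.size
    d = np.max(np.abs(fx - fy))
    return bool(d > ks_critical_d(x.size, y.size, alpha))


def ks_rejection_rate(
    n_reps: int = 500,
    n_per_group: int = 10,
    times: np.ndarray = DEFAULT_TIMES,
    alpha: float = 0.05,
    seed: int = 0,
    params_b: TrajectoryParams = CONTROL,
) -> float:
    """Fraction of replicates where the KS critical-D rule rejects."""
    hits = 0
    for rep in range(n_reps):
        a, b = _two_group_values(rep, seed, n_per_group, times, params_b)
        hits += _ks_rejects(a, b, alpha)
    return hits / n_reps


def perm_rejection_rate(
    n_reps: int = 500,
    n_per_group: int = 10,
    times: np.ndarray = DEFAULT_TIMES,
    alpha: float = 0.05,
    n_permutations: int = 499,
    seed: int = 0,
    params_b: TrajectoryParams = CONTROL,
) -> float:
    """Fraction of replicates where the permutation mean-curve test
    rejects at ``alpha``."""
    hits = 0
    for rep in range(n_reps):
        curves = simulate_activity_curves(
            {"a": (n_per_group, CONTROL), "b": (n_per_group, params_b)},
            times,
            seed=int(derived_rng(seed, "prep", rep).integers(2**31)),
        )
        ga = GroupedCurves("a", [c for c in curves if c.group_label == "a"])
        gb = GroupedCurves("b", [c for c in curves if c.group_label == "b"])
        res = permutation_mean_curve_test(
            ga, gb, n_permutations=n_permutations, seed=rep
        )
        hits += res.p_value <= alpha
    return hits / n_reps


def ks_null_rejection_rate(n_reps: int = 500, n_per_group: int = 10, alpha: float = 0.05, seed: int = 0) -> float:
    return ks_rejection_rate(n_reps, n_per_group, alpha=alpha, seed=seed, params_b=CONTROL)


def perm_null_rejection_rate(
    n_reps: int = 500, n_per_group: int = 10, alpha: float = 0.05, seed: int = 0, n_permutations: int = 499
) -> float:
    return perm_rejection_rate(
        n_reps, n_per_group, alpha=alpha, seed=seed, n_permutations=n_permutations, params_b=CONTROL
    )


def _effect(amplitude: float) -> TrajectoryParams:
    return replace(CONTROL, amplitude=amplitude, tau_decay_min=np.inf)


def ks_power(amplitudes, n_reps: int = 200, n_per_group: int = 10, alpha: float = 0.05, seed: int = 0) -> list[float]:
    """KS rejection rate at each effect amplitude (0 = the null)."""
    return [
        ks_rejection_rate(n_reps, n_per_group, alpha=alpha, seed=seed, params_b=_effect(a))
        for a in amplitudes
    ]


def perm_power(
    amplitudes,
    n_reps: int = 150,
    n_per_group: int = 10,
    alpha: float = 0.05,
    seed: int = 0,
    n_permutations: int = 299,
) -> list[float]:
    """Permutation-test rejection rate at each effect amplitude."""
    return [
        perm_rejection_rate(
            n_reps, n_per_group, alpha=alpha, seed=seed, n_permutations=n_permutations, params_b=_effect(a)
        )
        for a in amplitudes
    ]
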