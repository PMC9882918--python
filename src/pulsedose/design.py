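"""Cycle-map analysis and closed-form pulse-regimen design.

Over one pulse period the population state is advanced by the cycle matrix

    M = exp(A_off * t_off) @ exp(A_on * t_on)

whose eigenvalues (Floquet-type multipliers) lambda_1, lambda_2 govern the
per-cycle peaks: c(t_2l) = p1*lambda_1^l + p2*lambda_2^l.  Peaks decline iff
both multipliers lie inside the unit disk, which for realistic parameters
reduces to a condition on the duration ratio x = t_off/t_on alone:

    x < x_c = -K_n,on / K_n,off        (critical ratio)

The geometric-mean peak-to-peak decline rate

    k(x) = sqrt((K_n,on + K_n,off*x) * (K_p,on + K_p,off*x)) / (1 + x)

is maximised at

    x_opt = (2*R_n*R_p - R_n - R_p) / (2 - R_n - R_p),
    R_n = K_n,on/K_n,off,  R_p = K_p,on/K_p,off

which for tolerant persisters (R_p ~ 0) reduces to R_n/(R_n - 2),
equivalently x_c/(x_c + 2).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .model import (
    InitialCondition,
    Trajectory,
    TwoStateModel,
    phase_propagator,
)
from .regimen import PulseRegimen

__all__ = [
    "PeakSeries",
    "DeclineRates",
    "DesignResult",
    "cycle_matrix",
    "peak_series",
    "critical_ratio",
    "decline_rate",
    "optimal_ratio",
    "dominant_rate_surface",
    "design_regimen",
    "eradication_time",
]

# relative eigenvalue-gap threshold below which the cycle matrix is treated
# as defective and mode coefficients are not reported
_DEFECTIVE_RTOL = 1e-10


def cycle_matrix(model: TwoStateModel, t_on: float, t_off: float) -> np.ndarray:
    """One-period propagator M = exp(A_off*t_off) @ exp(A_on*t_on)."""
    if t_on < 0 or t_off < 0:
        raise ValueError(f"durations must be nonnegative (t_on={t_on}, t_off={t_off})")
    return phase_propagator(model.off, t_off) @ phase_propagator(model.on, t_on)


def _ordered_eig(M: np.ndarray) -> Tuple[np.ndarray, np.ndarray]:
    """Eigenvalues/vectors ordered by descending modulus, ties by real part.

    M is a product of entrywise-nonnegative matrices (matrix exponentials of
    Metzler matrices), so its eigenvalues are real.
    """
    lam, V = np.linalg.eig(M)
    lam, V = lam.real, V.real
    order = np.lexsort((-lam, -np.abs(lam)))
    return lam[order], V[:, order]


@dataclass(frozen=True)
class PeakSeries:
    """Per-cycle peak prediction c(t_2l) = p1*lambda1^l + p2*lambda2^l.

    ``p1``/``p2`` are None when the cycle matrix is (near-)defective; the
    peak values are then computed by explicit matrix powers and remain exact.
    """

    lambda1: float
    lambda2: float
    p1: Optional[float]
    p2: Optional[float]
    times: np.ndarray
    peaks: np.ndarray
    defective: bool = False

    @property
    def eradicating(self) -> bool:
        """Peaks decline iff the dominant multiplier is inside the unit disk."""
        return max(abs(self.lambda1), abs(self.lambda2)) < 1.0


def peak_series(
    model: TwoStateModel,
    t_on: float,
    t_off: float,
    ic: InitialCondition,
    L: int,
) -> PeakSeries:
    """Eigen-decomposition of the cycle map and predicted peaks for l = 0..L.

    The mode coefficients project the initial state onto the dual
    (left-eigenvector) basis and weight each right eigenvector by the
    observable (component sum), so that p1 + p2 = c(0).
    """
    if L < 1:
        raise ValueError(f"L must be >= 1, got {L}")
    M = cycle_matrix(model, t_on, t_off)
    lam, V = _ordered_eig(M)
    x0 = ic.state().vector
    period = t_on + t_off
    times = np.arange(L + 1) * period

    gap = abs(lam[0] - lam[1])
    defective = gap <= _DEFECTIVE_RTOL * max(1.0, abs(lam[0]))
    if defective:
        # fall back to explicit matrix powers; still exact
        peaks = np.empty(L + 1)
        x = x0.copy()
        for l in range(L + 1):
            peaks[l] = x.sum()
            x = M @ x
        return PeakSeries(
            lambda1=float(lam[0]),
            lambda2=float(lam[1]),
            p1=None,
            p2=None,
            times=times,
            peaks=peaks,
            defective=True,
        )

    W = np.linalg.inv(V)  # rows are the dual basis
    p = (V.sum(axis=0)) * (W @ x0)
    powers = lam[None, :] ** np.arange(L + 1)[:, None]
    peaks = powers @ p
    return PeakSeries(
        lambda1=float(lam[0]),
        lambda2=float(lam[1]),
        p1=float(p[0]),
        p2=float(p[1]),
        times=times,
        peaks=peaks,
    )


def critical_ratio(K_n_on: float, K_n_off: float) -> float:
    """Critical duration ratio x_c = -K_n_on / K_n_off.

    Requires a bactericidal on-phase (K_n_on < 0) and net regrowth in the
    off-phase (K_n_off > 0); the pulse-design condition is meaningless
    otherwise.
    """
    if not K_n_on < 0:
        raise ValueError(
            f"K_n_on must be negative (antibiotic kills normal cells); got {K_n_on}"
        )
    if not K_n_off > 0:
        raise ValueError(
            f"K_n_off must be positive (regrowth without antibiotic); got {K_n_off}"
        )
    return -K_n_on / K_n_off


@dataclass(frozen=True)
class DeclineRates:
    """Peak-to-peak decline rates at duration ratio x = t_off/t_on.

    ``k`` is the geometric-mean rate from the closed form; ``k1``/``k2`` are
    the individual mode rates -ln(lambda_i)/(t_on+t_off) from the cycle
    matrix; ``k_dominant`` (the smaller) controls the long-time decline.
    ``eradicating`` is False outside the decline domain, where k is NaN.
    """

    x: float
    k: float
    k1: float
    k2: float
    eradicating: bool

    @property
    def k_dominant(self) -> float:
        return min(self.k1, self.k2)

    @property
    def tau(self) -> float:
        """Time constant 1/k (h)."""
        return 1.0 / self.k


def decline_rate(x: float, model: TwoStateModel, t_on: float = 1.0) -> DeclineRates:
    """Evaluate the peak-to-peak decline rates at ratio x = t_off/t_on.

    The closed form depends on x only; the mode rates k1, k2 are evaluated
    through the cycle matrix at the supplied t_on (they too depend only on x
    when no normal->persister switching occurs during either phase).
    """
    if x < 0:
        raise ValueError(f"x must be nonnegative, got {x}")
    f1 = model.on.K_n + model.off.K_n * x
    f2 = model.on.K_p + model.off.K_p * x

    t_off = x * t_on
    period = t_on + t_off
    lam, _ = _ordered_eig(cycle_matrix(model, t_on, t_off))
    with np.errstate(divide="ignore", invalid="ignore"):
        k1 = -np.log(np.abs(lam[0])) / period
        k2 = -np.log(np.abs(lam[1])) / period

    if f1 < 0 and f2 < 0:
        k = math.sqrt(f1 * f2) / (1.0 + x)
        return DeclineRates(x=x, k=k, k1=float(k1), k2=float(k2), eradicating=True)
    return DeclineRates(
        x=x, k=float("nan"), k1=float(k1), k2=float(k2), eradicating=False
    )


@dataclass(frozen=True)
class OptimalRatio:
    x_opt_full: float
    x_opt_approx: float
    R_n: float
    R_p: Optional[float]
    x_c: float
    warnings: Tuple[str, ...] = ()


def optimal_ratio(R_n: float, R_p: Optional[float] = None) -> OptimalRatio:
    """Optimal duration ratio maximising the peak-to-peak decline rate.

    Full form: (2*R_n*R_p - R_n - R_p) / (2 - R_n - R_p); this is the
    stationary point of the closed-form rate k(x).  Approximate form
    (persisters fully tolerant, R_p -> 0): R_n/(R_n - 2) = x_c/(x_c + 2).
    When R_p is omitted the full form equals the approximation.
    """
    if not R_n < 0:
        raise ValueError(
            f"R_n = K_n_on/K_n_off must be negative for a workable design; got {R_n}"
        )
    x_c = -R_n
    x_opt_approx = R_n / (R_n - 2.0)
    if R_p is None:
        x_opt_full = x_opt_approx
        R_p_out = None
    else:
        denom = 2.0 - R_n - R_p
        if denom == 0:
            raise ZeroDivisionError("optimal-ratio formula degenerate: R_n + R_p = 2")
        x_opt_full = (2.0 * R_n * R_p - R_n - R_p) / denom
        R_p_out = R_p
    warns = []
    if not (0.0 < x_opt_full < x_c):
        warns.append(
            f"x_opt_full={x_opt_full:.4g} outside (0, x_c={x_c:.4g}); "
            "formula extrapolated outside its derivation domain"
        )
    return OptimalRatio(
        x_opt_full=x_opt_full,
        x_opt_approx=x_opt_approx,
        R_n=R_n,
        R_p=R_p_out,
        x_c=x_c,
        warnings=tuple(warns),
    )


@dataclass(frozen=True)
class RateSurface:
    """k_dominant over a (t_on, t_off) grid plus the crease locus k1 = k2."""

    t_on: np.ndarray
    t_off: np.ndarray
    k_dominant: np.ndarray  # shape (len(t_off), len(t_on))
    k1: np.ndarray
    k2: np.ndarray
    crease_t_on: np.ndarray
    crease_t_off: np.ndarray
    crease_ratio: Optional[float]  # analytic x where k1 = k2 (a = 0 case)


def _crease_ratio_analytic(model: TwoStateModel) -> Optional[float]:
    # with no on-switching in either phase the multipliers are the two
    # diagonal exponentials; they cross where the exponents are equal
    if model.on.a != 0 or model.off.a != 0:
        return None
    num = model.on.K_p - model.on.K_n
    den = model.off.K_n - model.off.K_p
    if den == 0:
        return None
    return num / den


def dominant_rate_surface(
    model: TwoStateModel,
    t_on_grid: Sequence[float],
    t_off_grid: Sequence[float],
) -> RateSurface:
    """Long-time (dominant-mode) decline rate over a duration grid.

    ``k_dominant[i, j]`` is the slower of the two mode rates at
    (t_off_grid[i], t_on_grid[j]).  The crease, where the two mode-rate
    surfaces intersect, is the locus of the fastest achievable long-time
    decline; when neither phase switches normal cells into persistence it
    is the straight line t_off/t_on = (K_p_on - K_n_on)/(K_n_off - K_p_off),
    otherwise it is located numerically as the minimum eigenvalue gap.
    """
    t_on_grid = np.asarray(t_on_grid, dtype=float)
    t_off_grid = np.asarray(t_off_grid, dtype=float)
    if (t_on_grid <= 0).any() or (t_off_grid <= 0).any():
        raise ValueError("grid durations must be positive")

    k1 = np.empty((len(t_off_grid), len(t_on_grid)))
    k2 = np.empty_like(k1)
    for i, t_off in enumerate(t_off_grid):
        for j, t_on in enumerate(t_on_grid):
            lam, _ = _ordered_eig(cycle_matrix(model, t_on, t_off))
            period = t_on + t_off
            with np.errstate(divide="ignore"):
                k1[i, j] = -np.log(abs(lam[0])) / period
                k2[i, j] = -np.log(abs(lam[1])) / period
    k_dom = np.minimum(k1, k2)

    ratio = _crease_ratio_analytic(model)
    if ratio is not None and ratio > 0:
        crease_t_on = t_on_grid.copy()
        crease_t_off = ratio * t_on_grid
    else:
        # numeric crease: per t_on, the t_off minimising the eigenvalue gap
        from scipy.optimize import minimize_scalar

        lo, hi = float(t_off_grid.min()), float(t_off_grid.max())
        ons, offs = [], []
        for t_on in t_on_grid:
            res = minimize_scalar(
                lambda t_off, t_on=t_on: float(
                    np.diff(_ordered_eig(cycle_matrix(model, t_on, t_off))[0])[0] ** 2
                ),
                bounds=(lo, hi),
                method="bounded",
            )
            ons.append(float(t_on))
            offs.append(float(res.x))
        crease_t_on = np.array(ons)
        crease_t_off = np.array(offs)

    return RateSurface(
        t_on=t_on_grid,
        t_off=t_off_grid,
        k_dominant=k_dom,
        k1=k1,
        k2=k2,
        crease_t_on=crease_t_on,
        crease_t_off=crease_t_off,
        crease_ratio=ratio,
    )


def _round_duration(t: float, rule: str) -> float:
    if rule == "none":
        return t
    if rule == "half_hour":
        return round(t * 2.0) / 2.0
    raise ValueError(f"unknown rounding rule {rule!r} (use 'none' or 'half_hour')")


@dataclass(frozen=True)
class DesignResult:
    """Recommended pulse-dosing design.

    All ratios are t_off/t_on.  ``t_on_h``/``t_off_h`` are populated only
    when an on-duration policy was supplied.
    """

    x_c: float
    x_opt_full: float
    x_opt_approx: float
    R_n: float
    R_p: Optional[float]
    t_on_h: Optional[float] = None
    t_off_h: Optional[float] = None
    k_at_opt_per_h: Optional[float] = None
    tau_at_opt_h: Optional[float] = None
    warnings: Tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "x_c": self.x_c,
            "x_opt_full": self.x_opt_full,
            "x_opt_approx": self.x_opt_approx,
            "R_n": self.R_n,
            "R_p": self.R_p,
            "t_on_h": self.t_on_h,
            "t_off_h": self.t_off_h,
            "k_at_opt_per_h": self.k_at_opt_per_h,
            "tau_at_opt_h": self.tau_at_opt_h,
            "warnings": list(self.warnings),
        }


def design_regimen(
    K_n_on: float,
    K_n_off: float,
    R_p: Optional[float] = None,
    t_on: Optional[float] = None,
    K_p_on: Optional[float] = None,
    K_p_off: Optional[float] = None,
    rounding: str = "half_hour",
) -> DesignResult:
    """Full design workflow: critical ratio, optimal ratio, durations.

    ``K_n_on``/``K_n_off`` come from short-term time-kill / time-growth
    slopes (natural-log units, 1/h).  Persister rates enter only through
    ``R_p`` (or ``K_p_on``/``K_p_off``, which additionally enable the
    decline rate at the optimum).  With a ``t_on`` policy the off-duration
    t_off = x_opt * t_on is rounded per ``rounding`` ('half_hour' rounds to
    the nearest 0.5 h; 'none' disables).
    """
    x_c = critical_ratio(K_n_on, K_n_off)
    R_n = K_n_on / K_n_off
    if R_p is None and K_p_on is not None and K_p_off is not None:
        R_p = K_p_on / K_p_off
    opt = optimal_ratio(R_n, R_p)

    t_off = k_at_opt = tau_at_opt = None
    if t_on is not None:
        if t_on <= 0:
            raise ValueError(f"t_on must be positive, got {t_on}")
        t_off = _round_duration(opt.x_opt_full * t_on, rounding)
    if K_p_on is not None and K_p_off is not None:
        from .model import PhaseRates

        probe = TwoStateModel(
            on=PhaseRates(K_n=K_n_on, K_p=K_p_on),
            off=PhaseRates(K_n=K_n_off, K_p=K_p_off),
            cap_log10=None,
        )
        dr = decline_rate(opt.x_opt_full, probe)
        if dr.eradicating:
            k_at_opt = dr.k
            tau_at_opt = dr.tau

    return DesignResult(
        x_c=x_c,
        x_opt_full=opt.x_opt_full,
        x_opt_approx=opt.x_opt_approx,
        R_n=R_n,
        R_p=opt.R_p,
        t_on_h=t_on,
        t_off_h=t_off,
        k_at_opt_per_h=k_at_opt,
        tau_at_opt_h=tau_at_opt,
        warnings=opt.warnings,
    )


def eradication_time(
    traj: Trajectory, threshold_log10: float = 0.0
) -> Optional[float]:
    """First time log10 c(t) falls below the threshold and stays below.

    The crossing is refined by linear interpolation of log10 c between the
    bracketing samples.  Returns None if the trajectory never settles below
    the threshold (the default, 0 log10, is 1 CFU/mL).
    """
    log_c = traj.log10_c
    below = log_c < threshold_log10
    if not below.any():
        return None
    # last index that is NOT below; everything after must be below
    above_idx = np.nonzero(~below)[0]
    if len(above_idx) == 0:
        return float(traj.t[0])
    i = above_idx[-1]
    if i == len(log_c) - 1:
        return None  # ends above the threshold
    t0, t1 = traj.t[i], traj.t[i + 1]
    y0, y1 = log_c[i], log_c[i + 1]
    if not np.isfinite(y1):  # population hit exact zero within the step
        return float(t1)
    if y1 == y0:
        return float(t1)
    return float(t0 + (threshold_log10 - y0) * (t1 - t0) / (y1 - y0))
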