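"""Parameter estimation from CFU time-series.

Two routes, ordered by effort:

1. ``fit_log_slope`` / ``quick_design_estimates``: ordinary least squares on
   log10 counts over an early time window of a time-growth and a time-kill
   experiment.  The two slopes give K_n_off and K_n_on, which are all the
   pulse-design formulas need.
2. ``fit_two_state``: bounded nonlinear least squares of the full two-state
   model (eight phase rates plus the initial persister fraction f0 and
   log10 c0) against one or more datasets, with biology-motivated equality
   constraints to tame the identifiability problem: the observable c(t) is
   a sum of two exponential modes, so the four rates of a single phase are
   not separately well determined from one curve.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares

from .model import InitialCondition, PhaseRates, TwoStateModel
from .regimen import PulseRegimen
from .synth import CFUDataset, predict_log10

__all__ = [
    "SlopeFit",
    "fit_log_slope",
    "quick_design_estimates",
    "ConstraintProfile",
    "PROFILES",
    "FitResult",
    "fit_two_state",
]

LN10 = math.log(10.0)


@dataclass(frozen=True)
class SlopeFit:
    """OLS slope of log10 counts vs time on a window.

    ``K = slope_log10 * ln(10)`` converts the plotted slope to the model's
    natural-log rate.  ``curvature_p`` is the p-value of a quadratic term
    refit on the same window — small values flag a biphasic bend inside the
    window, i.e. the window reaches past the initial exponential segment.
    """

    slope_log10: float
    se: float
    intercept: float
    window: Tuple[float, float]
    n_points: int
    curvature_p: Optional[float] = None

    @property
    def K(self) -> float:
        return self.slope_log10 * LN10

    @property
    def K_se(self) -> float:
        return self.se * LN10

    @property
    def bend_detected(self) -> bool:
        return self.curvature_p is not None and self.curvature_p < 0.05


def fit_log_slope(
    data: CFUDataset,
    window: Tuple[float, float],
    cap_log10: Optional[float] = None,
) -> SlopeFit:
    """Fit a straight line to log10 counts vs time on [t0, t1].

    Censored observations are excluded; with ``cap_log10`` set, points within
    0.05 log10 of the ceiling are also dropped (saturated culture carries no
    slope information).  Requires >= 3 usable points.
    """
    import statsmodels.api as sm

    t0, t1 = window
    tab = data.table
    mask = (tab["censored"] == 0) & (tab["t_h"] >= t0) & (tab["t_h"] <= t1)
    t = tab.loc[mask, "t_h"].to_numpy(dtype=float)
    y = data.log10_values()[mask.to_numpy()]
    if cap_log10 is not None:
        keep = y < cap_log10 - 0.05
        t, y = t[keep], y[keep]
    if len(t) < 3:
        raise ValueError(
            f"need >= 3 uncensored points in window {window}, found {len(t)}"
        )
    if np.ptp(t) == 0:
        raise ValueError("all observations at a single time; slope undefined")

    X = sm.add_constant(t)
    fit = sm.OLS(y, X).fit()
    slope = float(fit.params[1])
    se = float(fit.bse[1]) if len(t) > 2 else float("nan")

    curvature_p = None
    if len(t) >= 4 and len(np.unique(t)) >= 3:
        Xq = sm.add_constant(np.column_stack([t, t * t]))
        qfit = sm.OLS(y, Xq).fit()
        curvature_p = float(qfit.pvalues[2])

    return SlopeFit(
        slope_log10=slope,
        se=se,
        intercept=float(fit.params[0]),
        window=(float(t0), float(t1)),
        n_points=len(t),
        curvature_p=curvature_p,
    )


def quick_design_estimates(
    growth: CFUDataset,
    kill: CFUDataset,
    growth_window: Tuple[float, float] = (0.0, 3.0),
    kill_window: Tuple[float, float] = (0.0, 3.0),
    cap_log10: Optional[float] = 9.0,
) -> Tuple[SlopeFit, SlopeFit]:
    """Short-term slope estimates (K_n_off, K_n_on) from growth/kill curves.

    Returns the two slope fits; their ``.K`` attributes feed directly into
    :func:`pulsedose.design.design_regimen`.  Raises if the slopes have the
    wrong sign (growth must grow, kill must kill).
    """
    g = fit_log_slope(growth, growth_window, cap_log10=cap_log10)
    k = fit_log_slope(kill, kill_window, cap_log10=None)
    if g.slope_log10 <= 0:
        raise ValueError(
            f"time-growth slope must be positive, got {g.slope_log10:.3g} log10/h"
        )
    if k.slope_log10 >= 0:
        raise ValueError(
            f"time-kill slope must be negative, got {k.slope_log10:.3g} log10/h"
        )
    return g, k


# ---------------------------------------------------------------------------
# full nine-parameter fit

_PARAMS = [
    "K_n_on", "K_p_on", "a_on", "b_on",
    "K_n_off", "K_p_off", "a_off", "b_off",
    "log10_f0", "log10_c0",
]

# sign structure: antibiotic kills (K_on <= 0), culture regrows (K_n_off >= 0)
_BOUNDS = {
    "K_n_on": (-50.0, 0.0),
    "K_p_on": (-50.0, 0.0),
    "a_on": (0.0, 10.0),
    "b_on": (0.0, 10.0),
    "K_n_off": (0.0, 50.0),
    "K_p_off": (-50.0, 50.0),
    "a_off": (0.0, 10.0),
    "b_off": (0.0, 10.0),
    "log10_f0": (-12.0, 0.0),
    "log10_c0": (0.0, 12.0),
}


@dataclass(frozen=True)
class ConstraintProfile:
    """Named equality constraints reducing the free-parameter count.

    ``fixed`` pins parameters to constants; ``tied`` sets a parameter to a
    scalar multiple of another free parameter (e.g. persister decay in the
    off-phase equal to the resuscitation rate, K_p_off = -b_off: dormant
    cells neither grow nor die, they only leave by switching back).
    """

    name: str
    fixed: Dict[str, float] = field(default_factory=dict)
    tied: Dict[str, Tuple[str, float]] = field(default_factory=dict)

    def free_params(self) -> List[str]:
        return [p for p in _PARAMS if p not in self.fixed and p not in self.tied]

    def expand(self, free_values: Dict[str, float]) -> Dict[str, float]:
        out = dict(free_values)
        out.update(self.fixed)
        for target, (source, factor) in self.tied.items():
            out[target] = factor * out[source]
        return out


PROFILES: Dict[str, ConstraintProfile] = {
    # dormancy arguments: no resuscitation under antibiotic (b_on = 0), no
    # switching into dormancy during early exponential growth or under brief
    # antibiotic stress (a_off = a_on = 0)
    "standard": ConstraintProfile(
        name="standard", fixed={"a_on": 0.0, "a_off": 0.0, "b_on": 0.0}
    ),
    # additionally: off-phase persisters neither grow nor die, so their net
    # rate is pure outflow, K_p_off = -b_off
    "standard_tied": ConstraintProfile(
        name="standard_tied",
        fixed={"a_on": 0.0, "a_off": 0.0, "b_on": 0.0},
        tied={"K_p_off": ("b_off", -1.0)},
    ),
    "free": ConstraintProfile(name="free"),
}


@dataclass
class FitResult:
    """Outcome of the full two-state fit.

    ``estimates``/``se`` cover the eight phase rates plus f0 and log10_c0;
    fixed parameters carry their pinned value with SE 0, tied parameters
    propagate the SE of their source.  ``rank_deficient`` echoes a
    near-singular Jacobian at the optimum — the classic symptom of trying
    to resolve all four rates of a phase from a two-mode observable.
    """

    estimates: Dict[str, float]
    se: Dict[str, float]
    profile: str
    residual_rms: float
    n_obs: int
    n_free: int
    cost: float
    success: bool
    rank_deficient: bool
    message: str = ""

    @property
    def model(self) -> TwoStateModel:
        e = self.estimates
        return TwoStateModel(
            on=PhaseRates(K_n=e["K_n_on"], K_p=e["K_p_on"], a=e["a_on"], b=e["b_on"]),
            off=PhaseRates(
                K_n=e["K_n_off"], K_p=e["K_p_off"], a=e["a_off"], b=e["b_off"]
            ),
            cap_log10=None,
        )

    @property
    def ic(self) -> InitialCondition:
        return InitialCondition(
            log10_c0=self.estimates["log10_c0"], f0=self.estimates["f0"]
        )

    def to_dict(self) -> dict:
        return {
            "estimates": self.estimates,
            "se": self.se,
            "profile": self.profile,
            "residual_rms_log10": self.residual_rms,
            "n_obs": self.n_obs,
            "n_free": self.n_free,
            "success": self.success,
            "rank_deficient": self.rank_deficient,
            "message": self.message,
        }


def _default_start(datasets) -> Dict[str, float]:
    # crude data-driven anchors: earliest observation sets log10_c0
    first = min(
        (d.log10_values()[d.table["t_h"].to_numpy().argmin()] for d, _ in datasets),
        key=lambda v: -v,
    )
    return {
        "K_n_on": -3.0,
        "K_p_on": -0.3,
        "a_on": 0.0,
        "b_on": 0.0,
        "K_n_off": 1.0,
        "K_p_off": -1.0,
        "a_off": 0.0,
        "b_off": 1.0,
        "log10_f0": -6.0,
        "log10_c0": float(np.clip(first, 1.0, 11.0)),
    }


def fit_two_state(
    datasets: Sequence[Tuple[CFUDataset, PulseRegimen]],
    profile: ConstraintProfile | str = "standard",
    starts: int = 10,
    seed: Optional[int] = None,
    censored_mode: str = "exclude",
    init: Optional[Dict[str, float]] = None,
) -> FitResult:
    """Fit the two-state model jointly to several dosing experiments.

    Residuals are (predicted - observed) log10 CFU/mL at the uncensored
    observation times, unweighted; parameters are shared across datasets.
    ``censored_mode``: 'exclude' drops censored points; 'penalty' adds a
    one-sided residual max(0, prediction - log10 LOD) at censored times.
    Multi-start (``starts`` seeded jittered initialisations) guards against
    local minima; the best final cost wins.
    """
    if isinstance(profile, str):
        profile = PROFILES[profile]
    if not datasets:
        raise ValueError("at least one (dataset, regimen) pair required")
    if censored_mode not in ("exclude", "penalty"):
        raise ValueError(f"unknown censored_mode {censored_mode!r}")

    free = profile.free_params()
    lo = np.array([_BOUNDS[p][0] for p in free])
    hi = np.array([_BOUNDS[p][1] for p in free])

    obs: List[Tuple[np.ndarray, np.ndarray, np.ndarray, PulseRegimen, float]] = []
    n_obs = 0
    for ds, reg in datasets:
        tab = ds.table
        t = tab["t_h"].to_numpy(dtype=float)
        y = ds.log10_values()
        cens = tab["censored"].to_numpy() == 1
        obs.append((t, y, cens, reg, math.log10(ds.lod)))
        n_obs += int((~cens).sum())
        if censored_mode == "penalty":
            n_obs += int(cens.sum())

    def build(theta: np.ndarray):
        full = profile.expand(dict(zip(free, theta)))
        model = TwoStateModel(
            on=PhaseRates(
                K_n=full["K_n_on"], K_p=full["K_p_on"],
                a=full["a_on"], b=full["b_on"],
            ),
            off=PhaseRates(
                K_n=full["K_n_off"], K_p=full["K_p_off"],
                a=full["a_off"], b=full["b_off"],
            ),
            cap_log10=None,
        )
        ic = InitialCondition(
            log10_c0=full["log10_c0"], f0=10.0 ** full["log10_f0"]
        )
        return model, ic, full

    def residuals(theta: np.ndarray) -> np.ndarray:
        model, ic, _ = build(theta)
        res = []
        for t, y, cens, reg, log_lod in obs:
            pred = predict_log10(model, reg, ic, t, apply_cap=False)
            pred = np.maximum(pred, -30.0)  # guard log of exact zero
            res.append(pred[~cens] - y[~cens])
            if censored_mode == "penalty":
                res.append(np.maximum(0.0, pred[cens] - log_lod))
        return np.concatenate(res)

    base = _default_start(datasets)
    if init:
        base.update(init)
    rng = np.random.default_rng(seed)

    best = None
    for s in range(max(1, starts)):
        x0 = np.array([base[p] for p in free])
        if s > 0:
            jitter = rng.normal(0.0, 0.3, size=len(free))
            x0 = x0 * (1.0 + jitter)
            if "log10_f0" in free:
                x0[free.index("log10_f0")] = rng.uniform(-8.0, -3.0)
        x0 = np.clip(x0, lo + 1e-9, hi - 1e-9)
        try:
            sol = least_squares(
                residuals, x0, bounds=(lo, hi),
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=4000,
            )
        except Exception:
            continue
        if best is None or sol.cost < best.cost:
            best = sol

    if best is None:
        raise RuntimeError("no optimisation start converged")

    model, ic, full = build(best.x)

    # covariance from the Jacobian at the optimum
    J = best.jac
    dof = max(1, n_obs - len(free))
    sigma2 = 2.0 * best.cost / dof
    u, sv, vt = np.linalg.svd(J, full_matrices=False)
    rank_deficient = bool(sv.size and sv[-1] < 1e-8 * sv[0])
    sv_inv = np.where(sv > 1e-12 * sv[0], 1.0 / sv, 0.0)
    cov = (vt.T * sv_inv**2) @ vt * sigma2
    se_free = dict(zip(free, np.sqrt(np.maximum(np.diag(cov), 0.0))))

    se: Dict[str, float] = {}
    for p in _PARAMS:
        if p in profile.fixed:
            se[p] = 0.0
        elif p in profile.tied:
            src, factor = profile.tied[p]
            se[p] = abs(factor) * se_free.get(src, float("nan"))
        else:
            se[p] = se_free[p]

    estimates = {p: full[p] for p in _PARAMS}
    f0 = 10.0 ** full["log10_f0"]
    estimates["f0"] = f0
    se["f0"] = f0 * LN10 * se["log10_f0"]  # delta method

    rms = math.sqrt(2.0 * best.cost / max(1, n_obs))
    return FitResult(
        estimates=estimates,
        se=se,
        profile=profile.name,
        residual_rms=rms,
        n_obs=n_obs,
        n_free=len(free),
        cost=float(best.cost),
        success=bool(best.success),
        rank_deficient=rank_deficient,
        message=str(best.message),
    )
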