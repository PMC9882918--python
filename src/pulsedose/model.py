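"""Two-state (normal/persister) linear population model.

The population is split into normal cells ``n(t)`` that grow and are killed
by the antibiotic, and persister cells ``p(t)`` that are largely dormant and
tolerant.  Within a phase of constant antibiotic level the dynamics are
linear::

    dn/dt = K_n * n + b * p
    dp/dt = a * n + K_p * p

where ``a`` is the normal->persister switch rate, ``b`` the
persister->normal switch rate, and ``K_n``, ``K_p`` the net per-capita
rates (growth minus kill minus outgoing switch).  All rates are in natural
log units (1/h); slopes of log10 plots convert by a factor ln(10).

A pulse-dosing experiment alternates two such phases ("on" and "off"), each
with its own rate matrix.  Propagation through a phase is the exact matrix
exponential of the 2x2 rate matrix, computed in closed form.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .regimen import PulseRegimen

__all__ = [
    "PhaseRates",
    "TwoStateModel",
    "PopulationState",
    "InitialCondition",
    "ModeDecomposition",
    "Trajectory",
    "phase_matrix",
    "phase_propagator",
    "propagate",
    "analytic_modes",
    "simulate",
]

LN10 = math.log(10.0)

# below this the eigenvalue gap is treated as degenerate and the
# sinh(q*t)/q factor switches to its series expansion
_DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class PhaseRates:
    """Kinetic parameters of one antibiotic phase (on or off).

    Parameters
    ----------
    K_n, K_p : float
        Net per-capita rates of normal and persister cells (1/h).
    a, b : float
        Switch rates normal->persister and persister->normal (1/h);
        must be nonnegative.
    mu_n, mu_p, k_n, k_p : float, optional
        Optional decomposition into growth (mu) and kill (k) rates such
        that ``K_n = mu_n - k_n - a`` and ``K_p = mu_p - k_p - b``.
    """

    K_n: float
    K_p: float
    a: float = 0.0
    b: float = 0.0
    mu_n: Optional[float] = None
    mu_p: Optional[float] = None
    k_n: Optional[float] = None
    k_p: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("K_n", "K_p", "a", "b"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.a < 0 or self.b < 0:
            raise ValueError(
                f"switch rates must be nonnegative (a={self.a}, b={self.b})"
            )
        decomposed = [v is not None for v in (self.mu_n, self.mu_p, self.k_n, self.k_p)]
        if any(decomposed):
            if not all(decomposed):
                raise ValueError("mu_n, mu_p, k_n, k_p must be given together")
            if abs(self.K_n - (self.mu_n - self.k_n - self.a)) > 1e-12:
                raise ValueError("K_n != mu_n - k_n - a")
            if abs(self.K_p - (self.mu_p - self.k_p - self.b)) > 1e-12:
                raise ValueError("K_p != mu_p - k_p - b")


@dataclass(frozen=True)
class TwoStateModel:
    """Paired on/off phase rates plus an optional saturation ceiling.

    ``cap_log10`` is the carrying-capacity ceiling in log10(CFU/mL);
    simulated totals are clipped to it when requested.
    """

    on: PhaseRates
    off: PhaseRates
    cap_log10: Optional[float] = 9.0

    def __post_init__(self) -> None:
        if self.cap_log10 is not None and not self.cap_log10 > 0:
            raise ValueError(f"cap_log10 must be > 0, got {self.cap_log10}")

    def rates(self, phase: str) -> PhaseRates:
        if phase == "on":
            return self.on
        if phase == "off":
            return self.off
        raise ValueError(f"unknown phase {phase!r}")


@dataclass(frozen=True)
class PopulationState:
    """Counts of normal (n) and persister (p) cells, CFU/mL, at time t (h)."""

    n: float
    p: float
    t: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 0 or self.p < 0:
            raise ValueError(f"counts must be nonnegative (n={self.n}, p={self.p})")

    @property
    def c(self) -> float:
        """Total observable count n + p."""
        return self.n + self.p

    @property
    def vector(self) -> np.ndarray:
        return np.array([self.n, self.p], dtype=float)


@dataclass(frozen=True)
class InitialCondition:
    """Initial total count (log10 CFU/mL) and persister fraction f0."""

    log10_c0: float
    f0: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.f0 <= 1.0:
            raise ValueError(f"f0 must lie in [0, 1], got {self.f0}")

    def state(self, t: float = 0.0) -> PopulationState:
        c0 = 10.0 ** self.log10_c0
        return PopulationState(n=(1.0 - self.f0) * c0, p=self.f0 * c0, t=t)


@dataclass(frozen=True)
class ModeDecomposition:
    """Exponents and coefficients of the two solution modes of c(t).

    For a non-defective phase matrix ``c(t) = q1*exp(rho1*t) +
    q2*exp(rho2*t)`` with ``rho1 >= rho2``.  When the two exponents
    coincide (``defective`` is set) the solution degenerates to
    ``c(t) = (q1 + q2*t) * exp(rho1*t)``.
    """

    rho1: float
    rho2: float
    q1: float
    q2: float
    defective: bool = False

    def c(self, t):
        t = np.asarray(t, dtype=float)
        if self.defective:
            return (self.q1 + self.q2 * t) * np.exp(self.rho1 * t)
        return self.q1 * np.exp(self.rho1 * t) + self.q2 * np.exp(self.rho2 * t)


@dataclass
class Trajectory:
    """Time-ordered samples of the simulated population.

    Attributes are parallel arrays; ``phase`` labels each sample with the
    antibiotic phase it belongs to (phase-boundary samples carry the label
    of the ending phase).
    """

    t: np.ndarray
    n: np.ndarray
    p: np.ndarray
    phase: list
    regimen: PulseRegimen = field(repr=False, default=None)
    capped: bool = False

    @property
    def c(self) -> np.ndarray:
        return self.n + self.p

    @property
    def log10_c(self) -> np.ndarray:
        with np.errstate(divide="ignore"):
            return np.log10(self.c)

    def to_frame(self):
        import pandas as pd

        c = self.c
        with np.errstate(divide="ignore"):
            log10_c = np.log10(c)
        return pd.DataFrame(
            {
                "t_h": self.t,
                "n_cfu_per_ml": self.n,
                "p_cfu_per_ml": self.p,
                "c_cfu_per_ml": c,
                "log10_c": log10_c,
                "phase": self.phase,
            }
        )


def phase_matrix(r: PhaseRates) -> np.ndarray:
    """2x2 rate matrix A = [[K_n, b], [a, K_p]], row order (normal, persister)."""
    return np.array([[r.K_n, r.b], [r.a, r.K_p]], dtype=float)


def _expm_params(r: PhaseRates):
    """Mean rate m, half-gap q (both real: a*b >= 0 keeps the discriminant >= 0)."""
    m = 0.5 * (r.K_n + r.K_p)
    q = math.sqrt(r.a * r.b + 0.25 * (r.K_n - r.K_p) ** 2)
    return m, q


def phase_propagator(r: PhaseRates, dt: float) -> np.ndarray:
    """Exact matrix exponential exp(A*dt) of the phase rate matrix.

    Closed form for a 2x2 matrix with real eigenvalues m +- q:
    ``exp(A t) = e^{mt} [cosh(qt) I + sinh(qt)/q (A - mI)]``,
    with the ``sinh(qt)/q -> t`` series limit at a degenerate spectrum.
    """
    if dt < 0:
        raise ValueError(f"dt must be nonnegative, got {dt}")
    A = phase_matrix(r)
    m, q = _expm_params(r)
    qt = q * dt
    if qt < _DEGENERATE_TOL:
        # sinh(qt)/q = dt * (1 + (qt)^2/6 + ...); qt ~ 0 so dt suffices
        s = dt * (1.0 + qt * qt / 6.0)
        ch = 1.0 + 0.5 * qt * qt
    else:
        s = math.sinh(qt) / q
        ch = math.cosh(qt)
    return math.exp(m * dt) * (ch * np.eye(2) + s * (A - m * np.eye(2)))


def propagate(state: PopulationState, r: PhaseRates, dt: float) -> PopulationState:
    """Propagate a population state exactly through one phase for dt hours."""
    if dt < 0:
        raise ValueError(f"dt must be nonnegative, got {dt}")
    if dt == 0:
        return state
    x = phase_propagator(r, dt) @ state.vector
    # exact propagation of a nonnegative state under a Metzler matrix stays
    # nonnegative; clip pure floating-point undershoot
    x = np.maximum(x, 0.0)
    return PopulationState(n=float(x[0]), p=float(x[1]), t=state.t + dt)


def analytic_modes(r: PhaseRates, ic: InitialCondition) -> ModeDecomposition:
    """Decompose the observable c(t) into its two exponential modes.

    The mode exponents are the eigenvalues of the phase matrix,
    ``rho_{1,2} = (K_n + K_p)/2 +- sqrt(a*b + ((K_n - K_p)/2)^2)``, and the
    coefficients are fixed by the initial state so that
    ``c(t) = q1 exp(rho1 t) + q2 exp(rho2 t)`` with ``q1 + q2 = c(0)``.
    """
    m, q = _expm_params(r)
    x0 = ic.state().vector
    c0 = float(x0.sum())
    # column sums of (A - mI) applied to x0: the "slope" part of c(t)
    s0 = (0.5 * (r.K_n - r.K_p) + r.a) * x0[0] + (r.b - 0.5 * (r.K_n - r.K_p)) * x0[1]
    if q < _DEGENERATE_TOL:
        # defective (or diagonal-degenerate) spectrum: c(t) = (c0 + s0 t) e^{mt}
        return ModeDecomposition(rho1=m, rho2=m, q1=c0, q2=s0, defective=True)
    q1 = 0.5 * (c0 + s0 / q)
    q2 = 0.5 * (c0 - s0 / q)
    return ModeDecomposition(rho1=m + q, rho2=m - q, q1=q1, q2=q2)


def _cap_state(state: PopulationState, cap_log10: Optional[float]) -> PopulationState:
    if cap_log10 is None:
        return state
    cap = 10.0 ** cap_log10
    c = state.c
    if c > cap:
        scale = cap / c
        return replace(state, n=state.n * scale, p=state.p * scale)
    return state


def simulate(
    model: TwoStateModel,
    regimen: PulseRegimen,
    ic: InitialCondition,
    sample_dt: float = 0.1,
    apply_cap: bool = True,
) -> Trajectory:
    """Piecewise-exact simulation of the model through a pulse regimen.

    Samples are taken on a uniform grid of spacing ``sample_dt`` merged with
    every phase boundary, so per-cycle peaks and dips are always present in
    the output.  With ``apply_cap`` the total count is clipped so that
    ``log10(c) <= model.cap_log10`` (n and p scaled proportionally); the
    clipped state is what propagates forward, making the cap an absorbing
    ceiling at sample resolution.
    """
    if sample_dt <= 0:
        raise ValueError(f"sample_dt must be positive, got {sample_dt}")
    if len(regimen) == 0:
        raise ValueError("regimen is empty")

    cap = model.cap_log10 if apply_cap else None
    state = _cap_state(ic.state(), cap)

    times = [0.0]
    ns = [state.n]
    ps = [state.p]
    phases = [regimen.segments[0].phase]

    t_start = 0.0
    for seg in regimen.segments:
        r = model.rates(seg.phase)
        t_end = t_start + seg.duration_h
        # uniform global grid points strictly inside this segment
        k0 = math.floor(t_start / sample_dt) + 1
        grid = [k * sample_dt for k in range(k0, math.ceil(t_end / sample_dt) + 1)]
        seg_times = [t for t in grid if t_start < t < t_end - 1e-12]
        seg_times.append(t_end)
        for t_next in seg_times:
            state = propagate(state, r, t_next - state.t)
            state = _cap_state(state, cap)
            times.append(t_next)
            ns.append(state.n)
            ps.append(state.p)
            phases.append(seg.phase)
        t_start = t_end

    return Trajectory(
        t=np.array(times),
        n=np.array(ns),
        p=np.array(ps),
        phase=phases,
        regimen=regimen,
        capped=apply_cap,
    )
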