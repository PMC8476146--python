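"""Deterministic chemostat dynamics under static and fluctuating nutrient feeds.

A chemostat holds a microbial culture at constant volume: fresh medium flows in
and culture flows out at dilution rate ``D`` (culture volumes per hour).  Growth
is limited by one or two nutrients (here ammonium sulfate and glucose) through a
dual-substrate Monod law,

    u(S_as, S_g) = u_max / (1 + K_as/S_as + K_g/S_g),

which reduces to the classical Monod form ``u_max * S / (S + K)`` when the other
substrate is saturating.  The state ``(S_as, S_g, X)`` — vessel nutrient
concentrations (uM) and cell density (cells/ml) — evolves as

    dS_as/dt = D * (R_as(t) - S_as) - (X / Y_as) * u
    dS_g/dt  = D * (R_g(t)  - S_g)  - (X / Y_g)  * u
    dX/dt    = (u - D) * X

where ``R(t)`` are the reservoir (feed) concentrations.  Fluctuating
environments are encoded in the feed schedule: a *switch* schedule alternates
the two media as a square wave (instantaneous change every half period), while
a *pulse* schedule keeps a static feed and injects a small nutrient bolus
directly into the vessel at fixed intervals.  Discontinuities are handled by
segmenting the integration at the exact event times, never by smoothing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

__all__ = [
    "ChemostatParams",
    "FeedSchedule",
    "ChemostatState",
    "SimulationResult",
    "growth_rate",
    "simulate",
    "steady_state",
]

#: Default integration tolerances.  The absolute tolerance is in uM for the
#: substrate components; undershoots beyond ``10 * atol`` trigger a warning.
RTOL = 1e-8
ATOL = 1e-10


@dataclass(frozen=True)
class ChemostatParams:
    """Physical parameters of the vessel and the strain.

    Parameters
    ----------
    dilution_rate
        D, culture volumes per hour.  The study design uses 0.12 /h.
    max_growth_rate
        u_max, maximal per-cell growth rate constant (1/h).
    yield_as, yield_g
        Cells produced per ml per uM of ammonium sulfate / glucose consumed.
    half_sat_as, half_sat_g
        Monod half-saturation constants (uM).
    """

    dilution_rate: float = 0.12
    max_growth_rate: float = 0.4
    yield_as: float = 7.5e4
    yield_g: float = 7.5e4
    half_sat_as: float = 5.0
    half_sat_g: float = 5.0

    def __post_init__(self) -> None:
        if self.dilution_rate <= 0:
            raise ValueError("dilution_rate must be positive")
        for name in ("yield_as", "yield_g", "half_sat_as", "half_sat_g"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.max_growth_rate <= 0:
            raise ValueError("max_growth_rate must be positive")

    @property
    def washout(self) -> bool:
        """True when u_max <= D, so no positive-density steady state exists."""
        return self.max_growth_rate <= self.dilution_rate


@dataclass(frozen=True)
class FeedSchedule:
    """Time-varying reservoir concentrations.

    ``kind`` is one of ``static``, ``switch`` or ``pulse``:

    * static — constant feed ``(reservoir_as, reservoir_g)``.
    * switch — square wave alternating between ``(reservoir_as, reservoir_g)``
      (first phase) and ``(alt_reservoir_as, alt_reservoir_g)`` every
      ``switch_half_period`` hours; the feed change is instantaneous.
    * pulse — static feed plus an instantaneous bolus of ``pulse_bolus_as`` /
      ``pulse_bolus_g`` (uM added to the *vessel* concentration) every
      ``pulse_interval`` hours.
    """

    kind: str = "static"
    reservoir_as: float = 400.0
    reservoir_g: float = 1.111e5
    alt_reservoir_as: float = 3.7e4
    alt_reservoir_g: float = 444.4
    switch_half_period: float = 30.0
    pulse_interval: float = 3.0
    pulse_bolus_as: float = 40.0
    pulse_bolus_g: float = 0.0

    def __post_init__(self) -> None:
        if self.kind not in ("static", "switch", "pulse"):
            raise ValueError(f"unknown schedule kind {self.kind!r}")
        if self.kind == "switch" and self.switch_half_period <= 0:
            raise ValueError("switch_half_period must be positive")
        if self.kind == "pulse" and self.pulse_interval <= 0:
            raise ValueError("pulse_interval must be positive")

    def reservoirs(self, t: float) -> tuple[float, float]:
        """Feed concentrations (R_as, R_g) in uM at time ``t`` (hours)."""
        if self.kind == "switch":
            phase = int(np.floor(t / self.switch_half_period)) % 2
            if phase == 1:
                return self.alt_reservoir_as, self.alt_reservoir_g
        return self.reservoir_as, self.reservoir_g

    def event_times(self, t0: float, t_end: float) -> np.ndarray:
        """Discontinuity times (switches or pulses) strictly inside (t0, t_end)."""
        if self.kind == "static":
            return np.empty(0)
        step = self.switch_half_period if self.kind == "switch" else self.pulse_interval
        first = np.floor(t0 / step) + 1
        times = np.arange(first, np.ceil(t_end / step) + 1) * step
        return times[(times > t0 + 1e-12) & (times < t_end - 1e-12)]


@dataclass(frozen=True)
class ChemostatState:
    """Instantaneous vessel state: nutrients (uM) and cell density (cells/ml)."""

    s_as: float
    s_g: float
    x: float = 0.0
    time: float = 0.0

    def __post_init__(self) -> None:
        if self.s_as < 0 or self.s_g < 0 or self.x < 0:
            raise ValueError("state components must be non-negative")


@dataclass
class SimulationResult:
    """Trajectory of a chemostat integration on a strictly increasing grid."""

    time: np.ndarray
    s_as: np.ndarray
    s_g: np.ndarray
    x: np.ndarray
    params: ChemostatParams | None = None
    schedule: FeedSchedule | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.time) <= 0):
            raise ValueError("time grid must be strictly increasing")
        for arr in (self.s_as, self.s_g, self.x):
            if len(arr) != len(self.time):
                raise ValueError("trajectory length must equal grid length")

    def to_frame(self):
        """Tidy long table (time, variable, value) of the bulk trajectory."""
        import pandas as pd

        frames = []
        for name, arr in (("s_as", self.s_as), ("s_g", self.s_g), ("x", self.x)):
            frames.append(
                pd.DataFrame(
                    {"time": self.time, "variable": name, "genotype_id": "bulk", "value": arr}
                )
            )
        return pd.concat(frames, ignore_index=True)


def growth_rate(s_as, s_g, params: ChemostatParams):
    """Per-cell growth rate (1/h) under dual-substrate Monod limitation.

    ``u = u_max / (1 + K_as/S_as + K_g/S_g)``.  Either substrate at exactly 0
    gives the limit value 0; ``np.inf`` marks a saturating substrate.  Accepts
    scalars or arrays (broadcast).
    """
    s_as = np.asarray(s_as, dtype=float)
    s_g = np.asarray(s_g, dtype=float)
    if np.any(s_as < 0) or np.any(s_g < 0):
        raise ValueError("substrate concentrations must be non-negative")
    with np.errstate(divide="ignore"):
        denom = 1.0 + params.half_sat_as / s_as + params.half_sat_g / s_g
    u = np.where(np.isinf(denom), 0.0, params.max_growth_rate / denom)
    return float(u) if u.ndim == 0 else u


def _rhs(t, y, params: ChemostatParams, schedule: FeedSchedule):
    s_as, s_g, x = y
    r_as, r_g = schedule.reservoirs(t)
    u = growth_rate(max(s_as, 0.0), max(s_g, 0.0), params)
    d = params.dilution_rate
    return [
        d * (r_as - s_as) - (x / params.yield_as) * u,
        d * (r_g - s_g) - (x / params.yield_g) * u,
        (u - d) * x,
    ]


def _integrate_segments(rhs, y0, t0, t_end, events, t_eval, jumps=None,
                        rtol=RTOL, atol=ATOL, method="LSODA"):
    """Integrate ``rhs`` restarting at each event time.

    ``jumps(t, y)``, if given, is applied to the state at each event (pulse
    boluses).  Returns (times, states) sampled at ``t_eval`` (which must
    contain t0 and t_end).
    """
    boundaries = np.concatenate([[t0], events, [t_end]])
    ts: list[np.ndarray] = []
    ys: list[np.ndarray] = []
    y = np.asarray(y0, dtype=float)
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        mask = (t_eval >= a - 1e-12) & (t_eval <= b + 1e-12)
        seg_eval = np.unique(np.concatenate([[a], t_eval[mask], [b]]))
        sol = solve_ivp(rhs, (a, b), y, t_eval=seg_eval, rtol=rtol, atol=atol,
                        method=method)
        if not sol.success:
            raise RuntimeError(f"integration failed on [{a}, {b}]: {sol.message}")
        ts.append(sol.t)
        ys.append(sol.y)
        y = sol.y[:, -1].copy()
        if jumps is not None and b < t_end - 1e-12:
            y = jumps(b, y)
    t = np.concatenate(ts)
    y_all = np.concatenate(ys, axis=1)
    # keep the first value at duplicated segment boundaries (pre-jump state is
    # recorded at the boundary; the post-jump state shapes the next segment)
    t, idx = np.unique(t, return_index=True)
    return t, y_all[:, idx]


def _check_negative(y, atol, label):
    undershoot = -np.minimum(y, 0.0).min()
    if undershoot > 10 * atol:
        warnings.warn(
            f"{label}: state undershoot {undershoot:.3g} exceeds tolerance; clipping",
            RuntimeWarning,
        )
    return np.clip(y, 0.0, None)


def simulate(
    params: ChemostatParams,
    schedule: FeedSchedule,
    initial: ChemostatState,
    t_end: float,
    n_points: int = 601,
    rtol: float = RTOL,
    atol: float = ATOL,
) -> SimulationResult:
    """Integrate the bulk (single-population) chemostat model to ``t_end`` hours.

    Feed switches and pulse boluses are exact events: the integrator is
    restarted at each discontinuity.  With ``initial.x == 0`` the system is
    linear and the solution relaxes exponentially toward each reservoir value —
    a closed-form oracle used in the tests.  Washout (u_max <= D) is valid
    input; the population then decays toward zero.
    """
    if t_end <= initial.time:
        raise ValueError("t_end must exceed the initial time")
    t_eval = np.linspace(initial.time, t_end, n_points)
    events = schedule.event_times(initial.time, t_end)

    def jumps(t, y):
        if schedule.kind != "pulse":
            return y
        y = y.copy()
        y[0] += schedule.pulse_bolus_as
        y[1] += schedule.pulse_bolus_g
        return y

    t, y = _integrate_segments(
        lambda t, y: _rhs(t, y, params, schedule),
        [initial.s_as, initial.s_g, initial.x],
        initial.time,
        t_end,
        events,
        t_eval,
        jumps=jumps,
        rtol=rtol,
        atol=atol,
    )
    y = _check_negative(y, atol, "simulate")
    return SimulationResult(
        time=t, s_as=y[0], s_g=y[1], x=y[2], params=params, schedule=schedule,
        meta={"events": events, "t_end": t_end},
    )


def steady_state(
    params: ChemostatParams, reservoirs: tuple[float, float]
) -> tuple[float, float, float, bool]:
    """Fixed point (S*_as, S*_g, X*, washout_flag) of the static-feed model.

    At a positive-density steady state the growth rate equals the dilution
    rate, ``u(S*_as, S*_g) = D``, and the yield relations tie cell density to
    nutrient draw-down the same way for both substrates:

        X* = Y_as (R_as - S*_as) = Y_g (R_g - S*_g).

    A saturating substrate may be passed as ``np.inf``; the fixed point then
    reduces to the single-substrate Monod result ``S* = K D / (u_max - D)``,
    ``X* = Y (R - S*)``.  When no steady state with positive density exists
    (washout, or feed too dilute) the cell-free state (R_as, R_g, 0) is
    returned with the flag set.
    """
    r_as, r_g = reservoirs
    d = params.dilution_rate
    if params.washout or growth_rate(r_as, r_g, params) <= d:
        return r_as, r_g, 0.0, True

    def residual(s_as: float) -> float:
        # S_g follows from the shared draw-down X = Y_as (R_as - S_as)
        if np.isinf(s_as):
            return np.inf
        s_g = r_g - params.yield_as * (r_as - s_as) / params.yield_g
        if s_g <= 0:
            return -d  # glucose exhausted: growth must fall below D
        return growth_rate(s_as, s_g, params) - d

    if np.isinf(r_as) or np.isinf(r_g):
        # single-substrate limit: the finite substrate sets the fixed point
        if np.isinf(r_as) and np.isinf(r_g):
            raise ValueError("at least one reservoir must be finite")
        k = params.half_sat_g if np.isinf(r_as) else params.half_sat_as
        y = params.yield_g if np.isinf(r_as) else params.yield_as
        r = r_g if np.isinf(r_as) else r_as
        # other substrate saturating: u = u_max/(1 + K/S)  =>  S* = K D/(u_max-D)
        s_star = k * d / (params.max_growth_rate - d)
        if s_star >= r:
            return r_as, r_g, 0.0, True
        x_star = y * (r - s_star)
        if np.isinf(r_as):
            return np.inf, s_star, x_star, False
        return s_star, np.inf, x_star, False

    lo = 1e-12
    hi = r_as
    if residual(hi) < 0:  # should be caught by the washout check above
        return r_as, r_g, 0.0, True
    s_as = brentq(residual, lo, hi, xtol=1e-14, rtol=1e-14)
    s_g = r_g - params.yield_as * (r_as - s_as) / params.yield_g
    x_star = params.yield_as * (r_as - s_as)
    return s_as, s_g, x_star, False


def no_cell_solution(
    schedule: FeedSchedule, s0: tuple[float, float], d: float, times: np.ndarray
) -> np.ndarray:
    """Closed-form cell-free solution S(t) = R + (S(t_k) - R) exp(-D (t - t_k)).

    With X = 0 the substrate equations are linear first-order relaxations
    toward the current reservoir value, restarted at every feed switch.  Used
    as the analytic oracle for :func:`simulate`.  Returns an array of shape
    (2, len(times)) for (S_as, S_g).  Pulse boluses are applied as jumps.
    """
    times = np.asarray(times, dtype=float)
    out = np.empty((2, len(times)))
    events = schedule.event_times(times[0], times[-1])
    boundaries = np.concatenate([[times[0]], events, [times[-1]]])
    s = np.asarray(s0, dtype=float)
    for a, b in zip(boundaries[:-1], boundaries[1:]):
        r = np.asarray(schedule.reservoirs(a + 1e-9))
        mask = (times >= a - 1e-12) & (times <= b + 1e-12)
        dt = times[mask] - a
        out[:, mask] = r[:, None] + (s - r)[:, None] * np.exp(-d * dt)[None, :]
        s = r + (s - r) * np.exp(-d * (b - a))
        if schedule.kind == "pulse" and b < times[-1] - 1e-12:
            s = s + np.array([schedule.pulse_bolus_as, schedule.pulse_bolus_g])
    return out
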