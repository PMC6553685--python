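"""Coupled socio-climate simulation.

The full state is [x, C_at, C_veg, C_so, C_oc, T].  Simulations run in two
phases: a historical *spin-up* (default 1800-2014) with the social component
frozen and the full historical emission rate forcing the carbon cycle, then
the coupled phase in which behaviour dynamics start from x0 and the
replicator equation feeds back on emissions.  The single discrete delay —
the projected temperature needs T(t - tp) — is handled by the method of
steps: the coupled phase is integrated in chunks of length tp, with the
delayed temperature served from the dense solution already accumulated
(the spin-up provides the initial history function).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import minimize_scalar

from .earth import ClimateParams, ClimateState, carbon_rhs, temperature_rhs
from .forcing import EmissionSchedule, emission_rate
from .social import InsufficientHistoryError, SocialParams, social_rhs

__all__ = [
    "ScenarioConfig",
    "SocioClimateTrajectory",
    "MissingForcingError",
    "spin_up",
    "run_coupled",
    "fixed_behaviour_run",
    "peak_anomaly",
]

STATE_COLUMNS = ("x", "C_at", "C_veg", "C_so", "C_oc", "T")


class MissingForcingError(ValueError):
    """Emission schedule does not cover the requested simulation window."""


@dataclass(frozen=True)
class ScenarioConfig:
    """Everything needed to run one scenario deterministically."""

    social: SocialParams
    climate: ClimateParams
    schedule: EmissionSchedule
    start_year: float = 1800.0
    behaviour_start_year: float = 2014.0
    horizon_end: float = 2200.0
    rtol: float = 1e-8
    atol: float = 1e-10
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.start_year < self.behaviour_start_year < self.horizon_end:
            raise ValueError("require start_year < behaviour_start_year < horizon_end")

    def replace(self, **changes) -> "ScenarioConfig":
        return replace(self, **changes)


class SocioClimateTrajectory:
    """Dense, interpolation-capable record of one simulation.

    Stores the solver's dense-output segments plus the accepted step nodes;
    callable at arbitrary times within range.  Columns follow
    :data:`STATE_COLUMNS`.
    """

    def __init__(self, config: ScenarioConfig):
        self.config = config
        self._starts: list[float] = []
        self._segments: list = []      # (t0, t1, OdeSolution)
        self._node_t: list[np.ndarray] = []
        self._node_y: list[np.ndarray] = []

    # -- construction ------------------------------------------------------
    def _append(self, sol) -> None:
        t0, t1 = float(sol.t[0]), float(sol.t[-1])
        if self._segments and not np.isclose(t0, self._segments[-1][1]):
            raise ValueError("non-contiguous trajectory segment")
        self._starts.append(t0)
        self._segments.append((t0, t1, sol.sol))
        self._node_t.append(sol.t)
        self._node_y.append(sol.y)

    # -- access ------------------------------------------------------------
    @property
    def t_min(self) -> float:
        return self._segments[0][0]

    @property
    def t_max(self) -> float:
        return self._segments[-1][1]

    @property
    def nodes(self) -> tuple[np.ndarray, np.ndarray]:
        """Accepted solver steps: (times, states with shape (6, n))."""
        return np.concatenate(self._node_t), np.concatenate(self._node_y, axis=1)

    def _eval_scalar(self, t: float) -> np.ndarray:
        if t < self.t_min - 1e-9 or t > self.t_max + 1e-9:
            raise InsufficientHistoryError(
                f"t={t} outside trajectory range [{self.t_min}, {self.t_max}]"
            )
        i = bisect.bisect_right(self._starts, t) - 1
        i = max(i, 0)
        t0, t1, interp = self._segments[i]
        y = interp(np.clip(t, t0, t1))
        y[0] = min(max(y[0], 0.0), 1.0)
        return y

    def __call__(self, t):
        t_arr = np.asarray(t, dtype=float)
        if t_arr.ndim == 0:
            return self._eval_scalar(float(t_arr))
        return np.stack([self._eval_scalar(float(ti)) for ti in t_arr], axis=1)

    def x(self, t):
        out = self(t)
        return out[0]

    def T(self, t):
        out = self(t)
        return out[5] if out.ndim == 1 else out[5, :]

    def state(self, t: float) -> ClimateState:
        return ClimateState.from_array(self(t)[1:])

    def to_frame(self, step: float = 1.0) -> pd.DataFrame:
        """Annual (or finer) table with emission rate and effective emissions."""
        years = np.arange(self.t_min, self.t_max + 0.5 * step, step)
        years = np.clip(years, self.t_min, self.t_max)
        vals = self(years)
        df = pd.DataFrame(dict(zip(STATE_COLUMNS, vals)), index=np.round(years, 6))
        df.index.name = "year"
        eps = np.array([emission_rate(self.config.schedule, ti) for ti in years])
        df["emission_rate"] = eps
        df["effective_emissions"] = eps * (1.0 - df["x"].to_numpy())
        return df

    def summary(self, window: Optional[tuple[float, float]] = None) -> dict:
        peak, peak_year = peak_anomaly(self, window, return_year=True)
        out = {"peak_anomaly": peak, "peak_year": peak_year}
        for probe in (2060.0, 2100.0):
            if self.t_min <= probe <= self.t_max:
                out[f"x_{int(probe)}"] = float(self.x(probe))
                out[f"T_{int(probe)}"] = float(self.T(probe))
        return out


def _rhs_factory(config: ScenarioConfig, social_on: bool, history=None):
    soc, clim, sched = config.social, config.climate, config.schedule
    ratio = soc.tf / soc.tp

    def rhs(t, y):
        x = min(max(y[0], 0.0), 1.0)
        state = ClimateState(y[1], y[2], y[3], y[4], y[5])
        eps = emission_rate(sched, t)
        dydt = np.empty(6)
        if social_on:
            T_past = history(t - soc.tp)
            Tf = y[5] + ratio * (y[5] - T_past)
            dydt[0] = social_rhs(x, Tf, soc)
        else:
            dydt[0] = 0.0
        dydt[1:5] = carbon_rhs(state, eps, x, clim)
        dydt[5] = temperature_rhs(state, clim)
        return dydt

    return rhs


def _solve_chunk(traj: SocioClimateTrajectory, rhs, t0: float, t1: float, y0):
    sol = solve_ivp(
        rhs,
        (t0, t1),
        y0,
        method="LSODA",
        dense_output=True,
        rtol=traj.config.rtol,
        atol=traj.config.atol,
    )
    if not sol.success:
        raise RuntimeError(f"integration failed on [{t0}, {t1}]: {sol.message}")
    traj._append(sol)
    y_end = sol.y[:, -1].copy()
    y_end[0] = min(max(y_end[0], 0.0), 1.0)  # clamp replicator boundary drift
    return y_end


def spin_up(config: ScenarioConfig) -> SocioClimateTrajectory:
    """Historical phase: climate starts from zero deviation, behaviour frozen.

    The anthropogenic term enters un-scaled (x = 0) so the full historical
    emission record forces the carbon cycle; the resulting trajectory also
    provides the delay history for the coupled phase.
    """
    sched = config.schedule
    if sched.years[0] > config.start_year:
        raise MissingForcingError(
            f"emission schedule starts {sched.years[0]:.0f}, after "
            f"simulation start {config.start_year:.0f}"
        )
    traj = SocioClimateTrajectory(config)
    y0 = np.zeros(6)
    rhs = _rhs_factory(config, social_on=False)
    _solve_chunk(traj, rhs, config.start_year, config.behaviour_start_year, y0)
    return traj


def run_coupled(
    config: ScenarioConfig, spin: Optional[SocioClimateTrajectory] = None
) -> SocioClimateTrajectory:
    """Full simulation over [start_year, horizon_end].

    Behaviour dynamics start at ``behaviour_start_year`` from x0 (a state
    reset from the frozen spin-up value); the delayed temperature T(t - tp)
    is served by the method of steps from the trajectory's own dense output.
    """
    soc = config.social
    if spin is None:
        spin = spin_up(config)
    if spin.t_min > config.behaviour_start_year - soc.tp:
        raise InsufficientHistoryError(
            f"spin-up must cover [{config.behaviour_start_year - soc.tp}, "
            f"{config.behaviour_start_year}]"
        )
    traj = SocioClimateTrajectory(config)
    for seg in zip(spin._starts, spin._segments, spin._node_t, spin._node_y):
        traj._starts.append(seg[0])
        traj._segments.append(seg[1])
        traj._node_t.append(seg[2])
        traj._node_y.append(seg[3])

    y0 = traj(config.behaviour_start_year)
    y0[0] = soc.x0
    history_T = lambda s: traj._eval_scalar(s)[5]
    rhs = _rhs_factory(config, social_on=True, history=history_T)
    t = config.behaviour_start_year
    while t < config.horizon_end - 1e-9:
        t_next = min(t + soc.tp, config.horizon_end)
        y0 = _solve_chunk(traj, rhs, t, t_next, y0)
        t = t_next
    return traj


def fixed_behaviour_run(config: ScenarioConfig, x_const: float) -> SocioClimateTrajectory:
    """Null model: mitigator fraction pinned at ``x_const`` after 2014."""
    if not 0.0 <= x_const <= 1.0:
        raise ValueError(f"x_const must lie in [0, 1], got {x_const}")
    traj = spin_up(config)
    y0 = traj(config.behaviour_start_year)
    y0[0] = x_const
    rhs = _rhs_factory(config, social_on=False)
    _solve_chunk(traj, rhs, config.behaviour_start_year, config.horizon_end, y0)
    return traj


def peak_anomaly(
    traj: SocioClimateTrajectory,
    window: Optional[tuple[float, float]] = None,
    return_year: bool = False,
):
    """Maximum temperature anomaly over a window (default the full run).

    A coarse scan of the dense output locates the bracketing interval; a
    bounded scalar optimisation then refines the maximum.
    """
    lo, hi = window if window is not None else (traj.t_min, traj.t_max)
    if not (traj.t_min - 1e-9 <= lo < hi <= traj.t_max + 1e-9):
        raise ValueError(f"window [{lo}, {hi}] outside trajectory range or empty")
    lo, hi = max(lo, traj.t_min), min(hi, traj.t_max)
    grid = np.linspace(lo, hi, max(int(4 * (hi - lo)), 16) + 1)
    Tg = np.array([traj._eval_scalar(g)[5] for g in grid])
    i = int(np.argmax(Tg))
    a = grid[max(i - 1, 0)]
    b = grid[min(i + 1, len(grid) - 1)]
    if b - a < 1e-9:
        best_t, best_T = grid[i], Tg[i]
    else:
        res = minimize_scalar(
            lambda s: -traj._eval_scalar(s)[5], bounds=(a, b), method="bounded",
            options={"xatol": 1e-6},
        )
        best_t, best_T = float(res.x), float(-res.fun)
        if Tg[i] > best_T:  # guard against optimizer missing the node
            best_t, best_T = float(grid[i]), float(Tg[i])
    if return_year:
        return best_T, best_t
    return best_T
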