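"""Numerical experiments on the coupled socio-climate model.

Covers the study designs behind the headline analyses: Monte-Carlo
ensembles with triangular parameter uncertainty (median and pointwise 95%
percentile bands), one-at-a-time tornado sensitivity of the peak
temperature anomaly, the forecast-horizon sweep, the (beta, kappa) peak-
anomaly contour grid with steepest-descent intervention pathways, and the
printed worst-/best-case parameter presets.  Every experiment is a pure
function of (config, distributions, master seed): realisation seeds are
spawned from the master seed so results are independent of execution order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.interpolate import RectBivariateSpline

from .config import (
    CLIMATE_FIELDS,
    FORCING_FIELDS,
    SOCIAL_FIELDS,
    ParameterDistribution,
    apply_overrides,
)

_KNOWN_PARAMS = SOCIAL_FIELDS | CLIMATE_FIELDS | FORCING_FIELDS
from .simulate import ScenarioConfig, peak_anomaly, run_coupled

__all__ = [
    "EnsembleResult",
    "sample_triangular",
    "sample_parameters",
    "run_ensemble",
    "tornado",
    "contour_grid",
    "steepest_descent_path",
    "horizon_sweep",
    "scenario_presets",
]

log = logging.getLogger("socioclim")

PRESETS = {
    # bounds that most favour non-mitigative behaviour
    "worst": {"kappa": 0.02, "beta": 1.5, "delta": 1.5, "fmax": 4.0, "x0": 0.01},
    # bounds that least favour non-mitigative behaviour
    "best": {"kappa": 0.2, "beta": 0.5, "delta": 0.5, "fmax": 6.0, "tf": 50.0},
}


def scenario_presets(name: str) -> dict[str, float]:
    """Printed worst-/best-case parameter override sets."""
    try:
        return dict(PRESETS[name])
    except KeyError:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}") from None


def sample_triangular(dist: ParameterDistribution, rng: np.random.Generator) -> float:
    """One triangular draw in [lower, upper] peaking at the mode."""
    return dist.sample(rng)


def sample_parameters(
    distributions: Mapping[str, ParameterDistribution],
    rng: np.random.Generator,
    overrides: Optional[Mapping[str, float]] = None,
) -> dict[str, float]:
    """Draw one parameter set; overridden names bypass sampling entirely.

    Iteration order is sorted by name so draws are reproducible regardless
    of the mapping's insertion order.
    """
    overrides = dict(overrides or {})
    out = {}
    for name in sorted(distributions):
        if name in overrides:
            continue
        out[name] = distributions[name].sample(rng)
    out.update(overrides)
    return out


@dataclass
class EnsembleResult:
    """Ensemble summaries: pointwise median and 95% percentile band.

    ``values`` maps variable name ("T", "x", ...) to an (n, n_years) array;
    peak anomalies are per-realisation scalars over the default window.
    """

    years: np.ndarray
    values: dict[str, np.ndarray]
    peak_anomalies: np.ndarray
    parameters: pd.DataFrame
    master_seed: int
    n: int

    def median(self, var: str) -> np.ndarray:
        return np.median(self.values[var], axis=0)

    def band(self, var: str, level: float = 95.0) -> tuple[np.ndarray, np.ndarray]:
        half = (100.0 - level) / 2.0
        arr = self.values[var]
        return (
            np.percentile(arr, half, axis=0),
            np.percentile(arr, 100.0 - half, axis=0),
        )

    def to_frame(self, var: str = "T") -> pd.DataFrame:
        lo, hi = self.band(var)
        return pd.DataFrame(
            {
                "year": self.years,
                f"{var}_median": self.median(var),
                f"{var}_lo95": lo,
                f"{var}_hi95": hi,
            }
        )


def _run_once(config: ScenarioConfig, params: Mapping[str, float]) -> "SocioClimateTrajectory":
    from .simulate import SocioClimateTrajectory  # for type only

    cfg = apply_overrides(config, params)
    return run_coupled(cfg)


def run_ensemble(
    config: ScenarioConfig,
    distributions: Mapping[str, ParameterDistribution],
    overrides: Optional[Mapping[str, float]] = None,
    n: int = 100,
    master_seed: int = 0,
    variables: Sequence[str] = ("x", "T", "C_at"),
    window: Optional[tuple[float, float]] = None,
) -> EnsembleResult:
    """Monte-Carlo ensemble with triangular parameter uncertainty.

    Each realisation draws every distributed parameter (except overridden
    ones, which stay fixed at the given values), reruns the full simulation
    including the historical spin-up, and is recorded on an annual grid.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    for name in overrides or {}:
        if name not in _KNOWN_PARAMS:
            raise KeyError(f"unknown parameter name {name!r} in overrides")
    children = np.random.SeedSequence(master_seed).spawn(n)
    years = np.arange(config.start_year, config.horizon_end + 0.5)
    col_index = {"x": 0, "C_at": 1, "C_veg": 2, "C_so": 3, "C_oc": 4, "T": 5}
    store = {v: np.empty((n, years.size)) for v in variables}
    peaks = np.empty(n)
    rows = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        params = sample_parameters(distributions, rng, overrides)
        log.info("ensemble realisation %d/%d: %s", i + 1, n, params)
        traj = _run_once(config, params)
        vals = traj(years)
        for v in variables:
            store[v][i] = vals[col_index[v]]
        peaks[i] = peak_anomaly(traj, window)
        rows.append(params)
    return EnsembleResult(
        years=years,
        values=store,
        peak_anomalies=peaks,
        parameters=pd.DataFrame(rows),
        master_seed=master_seed,
        n=n,
    )


def tornado(
    config: ScenarioConfig,
    distributions: Mapping[str, ParameterDistribution],
    window: Optional[tuple[float, float]] = None,
) -> pd.DataFrame:
    """One-at-a-time sensitivity of peak anomaly to each parameter's bounds.

    Each parameter is set in turn to its lower and its upper bound with all
    others at baseline; deviations are reported separately per bound
    (asymmetry is preserved), ordered by maximum absolute impact.
    """
    base_peak = peak_anomaly(run_coupled(config), window)
    rows = []
    for name in sorted(distributions):
        dist = distributions[name]
        devs = {}
        for bound_name, value in (("lower", dist.lower), ("upper", dist.upper)):
            if value == dist.mode:
                devs[bound_name] = 0.0
                continue
            try:
                traj = _run_once(config, {name: value})
                devs[bound_name] = peak_anomaly(traj, window) - base_peak
            except Exception as exc:  # propagate with context per spec contract
                raise RuntimeError(
                    f"tornado run failed for {name}={value} ({bound_name} bound)"
                ) from exc
        rows.append(
            {
                "parameter": name,
                "dev_lower": devs["lower"],
                "dev_upper": devs["upper"],
                "baseline_peak": base_peak,
            }
        )
    df = pd.DataFrame(rows)
    df["max_abs"] = df[["dev_lower", "dev_upper"]].abs().max(axis=1)
    return (
        df.sort_values("max_abs", ascending=False)
        .drop(columns="max_abs")
        .reset_index(drop=True)
    )


def contour_grid(
    config: ScenarioConfig,
    beta_grid: Sequence[float],
    kappa_grid: Sequence[float],
    window: Optional[tuple[float, float]] = None,
) -> np.ndarray:
    """Peak-anomaly matrix over a (kappa, beta) grid, all else at baseline.

    Indexed [i, j] = (kappa_grid[i], beta_grid[j]); failed nodes are
    recorded as NaN and logged rather than aborting the scan.
    """
    beta_grid = np.asarray(beta_grid, float)
    kappa_grid = np.asarray(kappa_grid, float)
    if beta_grid.size == 0 or kappa_grid.size == 0:
        raise ValueError("grids must be non-empty")
    out = np.full((kappa_grid.size, beta_grid.size), np.nan)
    for i, kap in enumerate(kappa_grid):
        for j, bet in enumerate(beta_grid):
            try:
                traj = _run_once(config, {"kappa": float(kap), "beta": float(bet)})
                out[i, j] = peak_anomaly(traj, window)
            except Exception:
                log.exception("contour node failed at kappa=%g beta=%g", kap, bet)
    return out


def steepest_descent_path(
    grid: np.ndarray,
    beta_grid: Sequence[float],
    kappa_grid: Sequence[float],
    start: tuple[float, float],
    step: float = 0.02,
    grad_tol: float = 1e-4,
    max_steps: int = 2000,
) -> np.ndarray:
    """Steepest-descent pathway across the peak-anomaly surface.

    The grid is interpolated with a smooth bivariate spline over axes
    rescaled to [0, 1] (so "steepest" compares the two parameters on a
    common footing — the metric choice is a documented convention); the
    path follows the negative gradient with unit-normalised steps of size
    ``step`` in the rescaled space and stops at the grid boundary or when
    the gradient norm drops below ``grad_tol``.

    Parameters use (beta, kappa) ordering in ``start`` and in the returned
    (n_points, 2) array.
    """
    beta_grid = np.asarray(beta_grid, float)
    kappa_grid = np.asarray(kappa_grid, float)
    b0, b1 = beta_grid[0], beta_grid[-1]
    k0, k1 = kappa_grid[0], kappa_grid[-1]
    beta, kappa = start
    if not (b0 <= beta <= b1 and k0 <= kappa <= k1):
        raise ValueError(f"start {start} outside the grid hull")
    u = (beta_grid - b0) / (b1 - b0)
    v = (kappa_grid - k0) / (k1 - k0)
    kx = min(3, len(u) - 1)
    ky = min(3, len(v) - 1)
    spline = RectBivariateSpline(u, v, grid.T, kx=kx, ky=ky, s=0)

    pu = (beta - b0) / (b1 - b0)
    pv = (kappa - k0) / (k1 - k0)
    path = [(beta, kappa)]
    for _ in range(max_steps):
        gu = spline(pu, pv, dx=1, dy=0).item()
        gv = spline(pu, pv, dx=0, dy=1).item()
        norm = np.hypot(gu, gv)
        if norm < grad_tol:
            break
        pu_n = pu - step * gu / norm
        pv_n = pv - step * gv / norm
        if not (0.0 <= pu_n <= 1.0 and 0.0 <= pv_n <= 1.0):
            pu_n = min(max(pu_n, 0.0), 1.0)
            pv_n = min(max(pv_n, 0.0), 1.0)
            path.append((b0 + pu_n * (b1 - b0), k0 + pv_n * (k1 - k0)))
            break
        pu, pv = pu_n, pv_n
        path.append((b0 + pu * (b1 - b0), k0 + pv * (k1 - k0)))
    return np.asarray(path)


def horizon_sweep(
    config: ScenarioConfig,
    distributions: Mapping[str, ParameterDistribution],
    tf_values: Sequence[float],
    n: int = 100,
    master_seed: int = 0,
    window: Optional[tuple[float, float]] = None,
) -> pd.DataFrame:
    """Peak-anomaly samples per forecast horizon tf (box-plot raw data).

    For each tf (tf = 0, decisions on the current anomaly only, is legal)
    an ensemble is run with tf fixed and all other parameters sampled.
    Returns tidy rows (tf, realisation, peak_anomaly).
    """
    frames = []
    for tf in tf_values:
        res = run_ensemble(
            config,
            distributions,
            overrides={"tf": float(tf)},
            n=n,
            master_seed=master_seed,
            variables=("T",),
            window=window,
        )
        frames.append(
            pd.DataFrame(
                {
                    "tf": float(tf),
                    "realisation": np.arange(n),
                    "peak_anomaly": res.peak_anomalies,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)
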