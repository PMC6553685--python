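"""Anthropogenic CO2 emission forcing.

The baseline emission rate eps(t), in GtC/yr, is the rate the world would
emit with no behavioural change: linear interpolation of an annual
historical series up to 2014, then an increasing-but-saturating branch

    eps(t) = eps_2014 + (t - 2014) * eps_max / ((t - 2014) + s)

mirroring saturating global population and energy demand.  The module also
provides CSV input for CDIAC-style annual series (fossil + land-use, with
linear extrapolation of a land-use column that ends early) and synthetic
series generators so the package runs without any download.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

__all__ = [
    "EmissionSchedule",
    "EmissionRangeError",
    "EmissionFileError",
    "emission_rate",
    "load_historical_emissions",
    "synth_historical_emissions",
    "stylised_historical_emissions",
    "make_schedule",
    "rcp_like_emissions",
]

PIVOT_YEAR = 2014


class EmissionRangeError(ValueError):
    """Emission rate requested before the first historical data year."""


class EmissionFileError(ValueError):
    """Malformed emission CSV (bad rows reported with their row number)."""


@dataclass(frozen=True)
class EmissionSchedule:
    """Piecewise emission forcing: historical interpolation then saturation.

    Attributes
    ----------
    years, rates : annual historical grid (strictly increasing years, GtC/yr).
    eps_max : saturating post-pivot increment, GtC/yr.
    s : half-saturation constant, yr.
    """

    years: np.ndarray
    rates: np.ndarray
    eps_max: float
    s: float
    pivot_year: float = field(default=PIVOT_YEAR)

    def __post_init__(self) -> None:
        years = np.asarray(self.years, dtype=float)
        rates = np.asarray(self.rates, dtype=float)
        object.__setattr__(self, "years", years)
        object.__setattr__(self, "rates", rates)
        if years.ndim != 1 or years.shape != rates.shape or years.size < 2:
            raise ValueError("historical series needs matching 1-d year/rate arrays")
        if not np.all(np.diff(years) > 0):
            raise ValueError("historical years must be strictly increasing")
        if np.any(rates < 0):
            raise ValueError("emission rates must be non-negative")
        if self.eps_max < 0 or self.s <= 0:
            raise ValueError("require eps_max >= 0 and s > 0")
        if years[-1] != self.pivot_year:
            raise ValueError(
                f"historical series must end at {self.pivot_year}, ends {years[-1]}"
            )

    @property
    def eps_2014(self) -> float:
        """Emission rate at the pivot year (continuity anchor), GtC/yr."""
        return float(self.rates[-1])

    def __call__(self, t):
        return emission_rate(self, t)

    def replace(self, **changes) -> "EmissionSchedule":
        return replace(self, **changes)


def emission_rate(schedule: EmissionSchedule, t):
    """Baseline emission rate eps(t) in GtC/yr (scalar or array t).

    Continuous at the pivot year; monotone and bounded by
    eps_2014 + eps_max on the saturating branch.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < schedule.years[0]):
        raise EmissionRangeError(
            f"emission rate undefined before first data year {schedule.years[0]:.0f}"
        )
    hist = np.interp(t_arr, schedule.years, schedule.rates)
    dt = t_arr - schedule.pivot_year
    denom = np.where(dt > 0, dt + schedule.s, 1.0)
    sat = schedule.eps_2014 + np.where(dt > 0, dt * schedule.eps_max / denom, 0.0)
    out = np.where(t_arr <= schedule.pivot_year, hist, sat)
    return float(out) if out.ndim == 0 else out


def load_historical_emissions(path, fit_window: int = 20) -> pd.Series:
    """Read an annual emission CSV and return a (year-indexed) GtC/yr series.

    Two layouts are accepted: a single total column ``year,emissions_gtc``,
    or CDIAC-style ``year,fossil_gtc,landuse_gtc`` where the land-use column
    may end early (it is then linearly extrapolated by a least-squares fit
    over its last ``fit_window`` available years before summation).
    """
    df = pd.read_csv(path)
    cols = list(df.columns)
    if "year" not in cols:
        raise EmissionFileError(f"{path}: missing 'year' column (found {cols})")
    for name in cols:
        bad = df.index[pd.to_numeric(df[name], errors="coerce").isna() & df[name].notna()]
        if len(bad):
            raise EmissionFileError(
                f"{path}: non-numeric value in column '{name}' at data row {bad[0] + 2}"
            )
        df[name] = pd.to_numeric(df[name], errors="coerce")
    if df["year"].isna().any():
        row = int(df.index[df["year"].isna()][0]) + 2
        raise EmissionFileError(f"{path}: missing year at data row {row}")
    dup = df["year"][df["year"].duplicated()]
    if len(dup):
        raise EmissionFileError(f"{path}: duplicated year {int(dup.iloc[0])}")
    df = df.sort_values("year").set_index(df["year"].astype(int).values)

    if "emissions_gtc" in cols:
        total = df["emissions_gtc"]
        if total.isna().any():
            row = int(np.where(total.isna())[0][0]) + 2
            raise EmissionFileError(f"{path}: missing emission value at data row {row}")
    elif "fossil_gtc" in cols and "landuse_gtc" in cols:
        fossil = df["fossil_gtc"]
        if fossil.isna().any():
            raise EmissionFileError(f"{path}: fossil_gtc column has gaps")
        landuse = df["landuse_gtc"].copy()
        missing = landuse.isna()
        if missing.any():
            if missing.iloc[0] or not missing.iloc[-1]:
                raise EmissionFileError(
                    f"{path}: landuse_gtc gaps are only supported at the series tail"
                )
            have = landuse.dropna()
            tail = have.iloc[-min(fit_window, len(have)):]
            slope, intercept = np.polyfit(tail.index.values, tail.values, 1)
            yrs = landuse.index[missing].values
            landuse.loc[missing] = np.clip(slope * yrs + intercept, 0.0, None)
        total = fossil + landuse
    else:
        raise EmissionFileError(
            f"{path}: expected columns year,emissions_gtc or year,fossil_gtc,landuse_gtc"
        )
    total = total.astype(float)
    total.name = "emissions_gtc"
    total.index.name = "year"
    return total


def synth_historical_emissions(
    end_rate: float,
    start_year: int = 1800,
    end_year: int = PIVOT_YEAR,
    start_rate: float = 0.03,
    wiggle: float = 0.05,
    seed: int | None = None,
) -> pd.Series:
    """Generate a smooth, monotone synthetic annual emission history.

    Exponential growth from ``start_rate`` to exactly ``end_rate`` at
    ``end_year``, modulated by a few seeded smooth positive bumps of relative
    amplitude ``wiggle``; monotonicity and the endpoint are enforced.
    Deterministic for a given seed.
    """
    if end_year <= start_year:
        raise ValueError("end_year must exceed start_year")
    if end_rate <= 0:
        raise ValueError("end_rate must be positive")
    years = np.arange(start_year, end_year + 1, dtype=float)
    g = np.log(end_rate / start_rate) / (end_year - start_year)
    base = start_rate * np.exp(g * (years - start_year))
    if wiggle > 0:
        rng = np.random.default_rng(seed)
        centres = rng.uniform(start_year, end_year, size=4)
        widths = rng.uniform(15.0, 40.0, size=4)
        amps = rng.uniform(0.0, wiggle, size=4)
        mod = np.ones_like(years)
        for c0, w, a in zip(centres, widths, amps):
            mod += a * np.exp(-0.5 * ((years - c0) / w) ** 2)
        base = base * mod
    base = np.maximum.accumulate(base)          # enforce monotone
    base *= end_rate / base[-1]                 # pin the endpoint
    return pd.Series(base, index=years.astype(int), name="emissions_gtc")


# Decadal anchor values (GtC/yr) for global fossil-fuel + land-use emissions.
# Stylised/synthetic stand-in for the CDIAC annual record: round numbers
# consistent with the broad shape of the published global totals
# (cumulative 1800-2014 ~ 580 GtC).
_STYLISED_ANCHORS = (
    (1800, 0.35), (1850, 0.70), (1875, 0.95), (1900, 1.40), (1925, 2.10),
    (1950, 2.80), (1960, 4.00), (1970, 5.80), (1980, 6.90), (1990, 7.60),
    (2000, 8.50), (2005, 9.50), (2010, 10.40), (2014, 10.80),
)


def stylised_historical_emissions() -> pd.Series:
    """Stylised (synthetic) annual global emission history, 1800-2014.

    Monotone-cubic interpolation through decadal anchor values; used as the
    default forcing so the model runs without the CDIAC download.
    """
    yrs, vals = zip(*_STYLISED_ANCHORS)
    interp = PchipInterpolator(np.array(yrs, float), np.array(vals, float))
    years = np.arange(1800, PIVOT_YEAR + 1)
    return pd.Series(interp(years.astype(float)), index=years, name="emissions_gtc")


def make_schedule(historical, eps_max: float, s: float) -> EmissionSchedule:
    """Assemble an :class:`EmissionSchedule` from an annual historical series.

    ``historical`` is a year-indexed pandas Series (or (years, rates) pair)
    that must end at 2014; eps_2014 is read off its endpoint.
    """
    if isinstance(historical, pd.Series):
        years = historical.index.to_numpy(dtype=float)
        rates = historical.to_numpy(dtype=float)
    else:
        years, rates = (np.asarray(a, dtype=float) for a in historical)
    if years[-1] != PIVOT_YEAR:
        raise ValueError(f"historical series must end at {PIVOT_YEAR}, ends {years[-1]:.0f}")
    return EmissionSchedule(years=years, rates=rates, eps_max=eps_max, s=s)


# Approximate total-emission trajectories of the four RCP scenario families,
# GtC/yr at decadal nodes 2000-2100, for qualitative validation of the
# climate core (end-of-century anomaly ordering). Values are stylised
# round numbers following the published scenario shapes.
_RCP_NODES = {
    "rcp26": [8.0, 9.0, 9.5, 8.0, 5.5, 3.5, 2.0, 1.0, 0.5, 0.2, 0.0],
    "rcp45": [8.0, 9.5, 10.5, 11.0, 11.0, 10.5, 9.0, 7.0, 5.5, 4.5, 4.2],
    "rcp60": [8.0, 9.0, 10.0, 11.0, 12.5, 14.0, 15.5, 17.0, 17.5, 15.0, 13.5],
    "rcp85": [8.0, 10.0, 12.0, 14.5, 17.5, 20.5, 23.0, 25.5, 27.0, 28.0, 28.5],
}


def rcp_like_emissions(name: str, history: pd.Series | None = None) -> pd.Series:
    """Annual emission series 1800-2100 following an RCP-style pathway.

    Historical values up to 2000 come from ``history`` (default the stylised
    record); 2000-2100 follows monotone-cubic interpolation of decadal nodes
    shaped like the named RCP family (stylised values, for qualitative
    scenario-ordering checks only).
    """
    key = name.lower().replace(".", "").replace("-", "")
    if key not in _RCP_NODES:
        raise ValueError(f"unknown scenario {name!r}; choose from {sorted(_RCP_NODES)}")
    if history is None:
        history = stylised_historical_emissions()
    hist = history[history.index < 2000]
    nodes_y = np.arange(2000, 2101, 10, dtype=float)
    interp = PchipInterpolator(nodes_y, np.array(_RCP_NODES[key], float))
    years = np.arange(2000, 2101)
    fut = pd.Series(np.clip(interp(years.astype(float)), 0.0, None), index=years)
    out = pd.concat([hist.astype(float), fut])
    out.name = "emissions_gtc"
    out.index.name = "year"
    return out
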