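"""Imitation dynamics of climate-mitigation behaviour.

A well-mixed population holds one of two strategies, *mitigator* or
*non-mitigator*; ``x`` is the mitigator fraction.  Individuals sample others
at a social-learning rate ``kappa`` and copy strategies with probability
proportional to the utility difference, giving replicator dynamics

    dx/dt = kappa * x * (1 - x) * [ -beta + f(T_f) + delta * (2x - 1) ]

where ``beta`` is the net cost of mitigating (cost of mitigation minus the
cost, e.g. a carbon tax, of not mitigating), ``delta`` the strength of the
social norm rewarding majority behaviour, and ``f`` a sigmoidal perceived
cost of climate change evaluated at a projected temperature anomaly ``T_f``
obtained by linear extrapolation of the recent temperature trend.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Optional

import numpy as np
from scipy.special import expit

__all__ = [
    "SocialParams",
    "InsufficientHistoryError",
    "perceived_cost",
    "raw_cost",
    "mitigator_utility",
    "nonmitigator_utility",
    "switch_rates",
    "projected_temperature",
    "social_rhs",
]


class InsufficientHistoryError(ValueError):
    """Temperature history does not extend far enough back for the delay."""


@dataclass(frozen=True)
class SocialParams:
    """Behavioural parameters, stored in reduced form.

    The reduced form uses the net mitigation cost ``beta = alpha - gamma``
    and the scaled cost ceiling ``fmax = (c + 1) * ftilde_max``; the raw
    parameters (``alpha``, ``gamma``, ``c``, ``ftilde_max``) are optional and
    only needed to evaluate the individual utilities.

    Parameters
    ----------
    kappa : social learning (sampling) rate, 1/yr.
    beta : net cost to mitigate, utility units.
    delta : strength of social norms, utility units.
    fmax : ceiling of the scaled perceived-cost sigmoid, utility units.
    omega : steepness of the cost sigmoid, 1/degC.
    Tc : critical temperature anomaly at the sigmoid midpoint, degC.
    tf : forward extrapolation horizon of the temperature projection, yr.
    tp : backward window the projection is based on, yr.
    x0 : initial mitigator fraction when behaviour dynamics start.
    """

    kappa: float
    beta: float
    delta: float
    fmax: float
    omega: float
    Tc: float
    tf: float
    tp: float
    x0: float = 0.05
    alpha: Optional[float] = None
    gamma: Optional[float] = None
    c: Optional[float] = None
    ftilde_max: Optional[float] = None

    def __post_init__(self) -> None:
        if not self.kappa >= 0:
            raise ValueError(f"kappa must be >= 0, got {self.kappa}")
        if not self.omega > 0:
            raise ValueError(f"omega must be > 0, got {self.omega}")
        if not self.fmax > 0:
            raise ValueError(f"fmax must be > 0, got {self.fmax}")
        if not self.tp > 0:
            raise ValueError(f"tp must be > 0, got {self.tp}")
        if not self.tf >= 0:
            raise ValueError(f"tf must be >= 0, got {self.tf}")
        if not 0.0 <= self.x0 <= 1.0:
            raise ValueError(f"x0 must lie in [0, 1], got {self.x0}")
        # consistency of the two representations when both are populated
        if self.alpha is not None and self.gamma is not None:
            if abs(self.beta - (self.alpha - self.gamma)) > 1e-9:
                raise ValueError("beta inconsistent with alpha - gamma")
        if self.c is not None and self.ftilde_max is not None:
            if abs(self.fmax - (self.c + 1.0) * self.ftilde_max) > 1e-9:
                raise ValueError("fmax inconsistent with (c + 1) * ftilde_max")

    @classmethod
    def from_raw(
        cls,
        *,
        alpha: float,
        gamma: float,
        c: float,
        ftilde_max: float,
        kappa: float,
        delta: float,
        omega: float,
        Tc: float,
        tf: float,
        tp: float,
        x0: float = 0.05,
    ) -> "SocialParams":
        """Construct from the raw utility parameters, enforcing the reduction
        beta = alpha - gamma and fmax = (c + 1) * ftilde_max."""
        return cls(
            kappa=kappa,
            beta=alpha - gamma,
            delta=delta,
            fmax=(c + 1.0) * ftilde_max,
            omega=omega,
            Tc=Tc,
            tf=tf,
            tp=tp,
            x0=x0,
            alpha=alpha,
            gamma=gamma,
            c=c,
            ftilde_max=ftilde_max,
        )

    def with_(self, **changes) -> "SocialParams":
        """Return a copy with fields replaced (raw fields dropped if a
        reduced-form field they constrain is changed)."""
        if ("beta" in changes or "fmax" in changes) and self.alpha is not None:
            changes.setdefault("alpha", None)
            changes.setdefault("gamma", None)
            changes.setdefault("c", None)
            changes.setdefault("ftilde_max", None)
        return replace(self, **changes)


def perceived_cost(T, params: SocialParams):
    """Scaled perceived cost of climate change f(T) = fmax / (1 + e^{-omega (T - Tc)}).

    Strictly increasing in T, with range (0, fmax) and midpoint fmax/2 at Tc.
    """
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T)):
        raise ValueError("temperature anomaly must be finite")
    out = params.fmax * expit(params.omega * (T - params.Tc))
    return out if out.ndim else float(out)


def raw_cost(T, params: SocialParams):
    """Unscaled cost ftilde(T) = ftilde_max / (1 + e^{-omega (T - Tc)}).

    Requires the raw parameterisation (``ftilde_max``) to be populated.
    """
    if params.ftilde_max is None:
        raise ValueError("raw_cost requires ftilde_max (use SocialParams.from_raw)")
    T = np.asarray(T, dtype=float)
    if not np.all(np.isfinite(T)):
        raise ValueError("temperature anomaly must be finite")
    out = params.ftilde_max * expit(params.omega * (T - params.Tc))
    return out if out.ndim else float(out)


def _require_raw(params: SocialParams) -> None:
    if params.alpha is None or params.gamma is None or params.c is None:
        raise ValueError(
            "utilities require the raw parameters alpha/gamma/c "
            "(construct with SocialParams.from_raw)"
        )


def mitigator_utility(x: float, Tf: float, params: SocialParams) -> float:
    """Utility of the mitigator strategy: e_M = -alpha + c*ftilde(T_f) + delta*x."""
    _require_raw(params)
    return -params.alpha + params.c * raw_cost(Tf, params) + params.delta * x


def nonmitigator_utility(x: float, Tf: float, params: SocialParams) -> float:
    """Utility of the non-mitigator strategy: e_N = -gamma - ftilde(T_f) + delta*(1 - x)."""
    _require_raw(params)
    return -params.gamma - raw_cost(Tf, params) + params.delta * (1.0 - x)


def switch_rates(x: float, eM: float, eN: float, kappa: float) -> tuple[float, float]:
    """Strategy-switching rates (non-mitigator->mitigator, mitigator->non-mitigator).

    Each is kappa * x * (1 - x) * max(payoff gain, 0); at most one is nonzero,
    and both vanish at the boundary states x = 0 and x = 1.
    """
    if not 0.0 <= x <= 1.0:
        raise ValueError(f"x must lie in [0, 1], got {x}")
    prefac = kappa * x * (1.0 - x)
    return prefac * max(eM - eN, 0.0), prefac * max(eN - eM, 0.0)


def projected_temperature(
    history: Callable[[float], float], t: float, params: SocialParams
) -> float:
    """Linearly extrapolated anomaly T_f(t) = T(t) + (tf/tp) * (T(t) - T(t - tp)).

    ``history`` must be evaluable at ``t`` and ``t - tp``; with ``tf = 0``
    the projection reduces to the current anomaly. Exact for linear trends.
    """
    T_now = history(t)
    T_past = history(t - params.tp)
    return T_now + (params.tf / params.tp) * (T_now - T_past)


def social_rhs(x: float, Tf: float, params: SocialParams) -> float:
    """Replicator right-hand side dx/dt for the mitigator fraction.

    Equals the net switching rate r_{N->M} - r_{M->N} built from the raw
    utilities; zero at the boundary equilibria x = 0 and x = 1.
    """
    return (
        params.kappa
        * x
        * (1.0 - x)
        * (-params.beta + perceived_cost(Tf, params) + params.delta * (2.0 * x - 1.0))
    )
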