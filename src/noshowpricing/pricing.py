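"""Zero-loss penalty-fee pricing for appointment no-shows.

The model: a clinic books ``nt`` patients at fee ``Pf`` per visit, pays a
material cost ``cm`` per patient actually seen and a fixed personnel cost
``cp`` per period.  ``ns`` patients show up; the ``nn = nt - ns`` vacated
slots are partially refilled.  With ``beta`` the classifier's show-up rate
(positive predictive value of predicted show-ups), the expected refill of the
``nn`` empty slots is

* ``nnr = nn * (1 - beta) * beta`` — prior no-shows who rebook and attend;
  they pay the penalty fee ``phi`` instead of ``Pf``;
* ``nsn = nn * beta**2`` — new patients who book the vacated slot and attend;
  they pay the standard fee,

so ``nnr + nsn = nn * beta <= nn`` and the revised revenue is

    Rr = ns*(Pf - cm) + beta^2*nn*(Pf - cm) + (beta - beta^2)*nn*(phi - cm) - cp.

A non-profit clinic wants neither profit nor loss, so ``phi`` is the unique
solution of ``Rr = 0``:

    phi = cm + [cp - (ns + beta^2*nn)*(Pf - cm)] / [beta*(1 - beta)*nn].

``phi`` may fall below ``cm`` (subsidy regime: attendance already covers the
period) or above ``Pf`` (super-fee regime: the shortfall exceeds what a
full-fee rebooking would recover); both are reported unclamped with flags.
The horizon simulation draws daily demand and no-show fractions, prices each
day with at least one unfilled no-show, and averages the daily penalty rate
``100 * phi / Pf``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import binom

from noshowpricing.metrics import RatesMatrix

__all__ = [
    "PricingParams",
    "SlotFill",
    "RevenueReport",
    "PenaltySeries",
    "DemandConfig",
    "CostConfig",
    "UndefinedPenaltyError",
    "no_show_count",
    "slot_fill",
    "expected_revenue",
    "revised_revenue",
    "revised_revenue_from_slot_fill",
    "penalty_cost",
    "penalty_rate",
    "pricing_report",
    "escalated_penalty",
    "simulate_horizon",
]


class UndefinedPenaltyError(ValueError):
    """The zero-loss fee has no solution (no reappointments carry the penalty)."""


@dataclass(frozen=True)
class PricingParams:
    """All symbols of the pricing model for one period.

    pf: standard treatment/examination fee per patient (currency units).
    cm: material cost per patient actually seen (currency units).
    cp: fixed personnel cost per period (currency units).
    nt: appointed patients; ns: patients who showed up.
    beta: classifier show-up rate in (0, 1) (a float or a RatesMatrix).
    """

    pf: float
    cm: float
    cp: float
    nt: float
    ns: float
    beta: float

    def __post_init__(self) -> None:
        if isinstance(self.beta, RatesMatrix):
            object.__setattr__(self, "beta", self.beta.beta)
        if not self.pf > self.cm:
            raise ValueError(f"need pf > cm, got pf={self.pf}, cm={self.cm}")
        if self.cm < 0 or self.cp < 0:
            raise ValueError("costs must be non-negative")
        if not 0 <= self.ns <= self.nt:
            raise ValueError(f"need 0 <= ns <= nt, got ns={self.ns}, nt={self.nt}")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError(f"beta must lie in [0, 1], got {self.beta}")

    @property
    def nn(self) -> float:
        return self.nt - self.ns


@dataclass(frozen=True)
class SlotFill:
    """Expected refill of the vacated slots (counts may be fractional)."""

    nn: float
    nnr: float  # reappointed prior no-shows who attend (penalty payers)
    nsn: float  # new patients filling vacated slots (standard fee)

    def __post_init__(self) -> None:
        if self.nnr < 0 or self.nsn < 0:
            raise ValueError("refill counts must be non-negative")
        if self.nnr + self.nsn > self.nn + 1e-12:
            raise ValueError("refill cannot exceed the number of vacated slots")


@dataclass(frozen=True)
class RevenueReport:
    """Break-even summary for one period at the zero-loss fee."""

    expected_revenue: float
    revised_revenue_at_phi: float
    phi: float
    penalty_rate_pct: float
    below_material_cost: bool  # phi < cm: subsidy regime
    above_full_fee: bool  # phi > pf: super-fee regime


def no_show_count(nt: float, ns: float):
    """Number of patients who did not show up, nn = nt - ns."""
    nt, ns = np.asarray(nt), np.asarray(ns)
    if np.any(ns > nt) or np.any(ns < 0):
        raise ValueError("need 0 <= ns <= nt")
    out = nt - ns
    return out.item() if out.ndim == 0 else out


def slot_fill(nn: float, beta: float) -> SlotFill:
    """Expected slot refill: nnr = nn(1-beta)beta reappointments, nsn = nn beta^2 new."""
    if nn < 0:
        raise ValueError("nn must be non-negative")
    if not 0.0 <= beta <= 1.0:
        raise ValueError("beta must lie in [0, 1]")
    return SlotFill(nn=nn, nnr=nn * (1.0 - beta) * beta, nsn=nn * beta * beta)


def expected_revenue(params: PricingParams) -> float:
    """Revenue if every appointed patient attended: nt*(Pf - cm) - cp."""
    return params.nt * (params.pf - params.cm) - params.cp


def revised_revenue(params: PricingParams, phi: float):
    """Revenue with no-shows, expected slot refill and penalty fee *phi*."""
    p = params
    margin = p.pf - p.cm
    b = p.beta
    return (
        p.ns * margin
        + b * b * p.nn * margin
        + (b - b * b) * p.nn * (phi - p.cm)
        - p.cp
    )


def revised_revenue_from_slot_fill(params: PricingParams, phi: float) -> float:
    """Same revenue written over the slot-fill counts: (ns+nsn)(Pf-cm) + nnr(phi-cm) - cp."""
    fill = slot_fill(params.nn, params.beta)
    return (params.ns + fill.nsn) * (params.pf - params.cm) + fill.nnr * (
        phi - params.cm
    ) - params.cp


def penalty_cost(params: PricingParams):
    """The zero-loss penalty fee: the unique phi with revised_revenue(params, phi) = 0.

    Requires at least one no-show (nt > ns) and beta strictly inside (0, 1);
    otherwise no reappointed patient carries the penalty and the fee is
    undefined.  The returned fee is not clamped to [cm, Pf].
    """
    p = params
    if p.beta <= 0.0 or p.beta >= 1.0 or p.nn == 0:
        raise UndefinedPenaltyError(
            f"zero-loss fee undefined for beta={p.beta}, nn={p.nn} "
            "(no penalty-paying reappointments)"
        )
    return float(_phi_closed_form(p.pf, p.cm, p.cp, p.nt, p.ns, p.beta))


def _phi_closed_form(pf, cm, cp, nt, ns, beta):
    """Vectorised zero-loss fee; callers must guard beta in (0, 1) and nt > ns."""
    nn = np.asarray(nt, dtype=float) - np.asarray(ns, dtype=float)
    margin = np.asarray(pf, dtype=float) - np.asarray(cm, dtype=float)
    beta = np.asarray(beta, dtype=float)
    shortfall = np.asarray(cp, dtype=float) - (ns + beta**2 * nn) * margin
    return cm + shortfall / (beta * (1.0 - beta) * nn)


def penalty_rate(phi: float, pf: float):
    """The penalty fee as a percentage of the standard fee, 100*phi/Pf."""
    pf_arr = np.asarray(pf, dtype=float)
    if np.any(pf_arr <= 0):
        raise ValueError("pf must be positive")
    out = 100.0 * np.asarray(phi, dtype=float) / pf_arr
    return out.item() if out.ndim == 0 else out


def pricing_report(params: PricingParams) -> RevenueReport:
    """Solve the period and flag subsidy / super-fee regimes."""
    phi = penalty_cost(params)
    return RevenueReport(
        expected_revenue=expected_revenue(params),
        revised_revenue_at_phi=revised_revenue(params, phi),
        phi=phi,
        penalty_rate_pct=penalty_rate(phi, params.pf),
        below_material_cost=phi < params.cm,
        above_full_fee=phi > params.pf,
    )


def escalated_penalty(
    phi: float, n_offenses: int, multipliers: Sequence[float] = (1.0, 1.5, 2.0)
) -> float:
    """Penalty for a repeat offender: phi times the n-th escalation multiplier.

    Offense counts beyond the configured sequence stay at the last multiplier.
    """
    if n_offenses < 1:
        raise ValueError("n_offenses must be >= 1")
    if not multipliers:
        raise ValueError("multipliers must be non-empty")
    return phi * multipliers[min(n_offenses, len(multipliers)) - 1]


@dataclass(frozen=True)
class DemandConfig:
    """Daily appointment demand: nt ~ Poisson(mean_daily_patients)."""

    mean_daily_patients: float = 10.73  # 1073 patients over a 100-day horizon

    def __post_init__(self) -> None:
        if self.mean_daily_patients <= 0:
            raise ValueError("mean_daily_patients must be positive")


@dataclass(frozen=True)
class CostConfig:
    """Fee and cost parameters held fixed over the horizon.

    ``cp`` defaults to mean-demand break-even, cp = E[nt]*(pf - cm), so a day
    with full attendance at average demand yields exactly zero revenue.
    """

    pf: float = 100.0
    cm: float = 20.0
    cp: float | None = None

    def resolved_cp(self, demand: DemandConfig) -> float:
        if self.cp is not None:
            return self.cp
        return demand.mean_daily_patients * (self.pf - self.cm)


@dataclass(frozen=True)
class PenaltySeries:
    """Daily pricing results over a simulated horizon for one algorithm.

    ``days`` has one row per day: nt, ns, phi and the penalty rate (NaN on
    days with no unfilled no-show — nothing to price); ``average_rate`` is the
    arithmetic mean rate over the contributing days.
    """

    algorithm: str
    beta: float
    days: pd.DataFrame = field(repr=False)
    average_rate: float

    @property
    def n_contributing(self) -> int:
        return int(self.days["rate"].notna().sum())


def simulate_horizon(
    horizon_days: int = 100,
    demand: DemandConfig = DemandConfig(),
    costs: CostConfig = CostConfig(),
    rates: Mapping[str, float | RatesMatrix] | None = None,
    seed: int = 0,
) -> dict[str, PenaltySeries]:
    """Simulate daily penalty pricing over a horizon per classifier.

    Each day draws a demand ``nt ~ Poisson`` and a no-show fraction uniform on
    ``(0, 1 - beta]`` — the classifier's no-show ceiling; each of the day's
    patients then no-shows independently with that fraction, so the no-show
    count is Binomial(nt, fraction) (drawn by inverse CDF).  Days with at
    least one no-show are priced at the zero-loss fee.  Demand, the fraction
    draws and the binomial quantile draws are shared across algorithms
    (common random numbers), so differences between series reflect only the
    show-up rates ``beta``.
    """
    if horizon_days < 1:
        raise ValueError("horizon_days must be >= 1")
    if rates is None:
        rates = {"RF": 0.975, "GB": 0.975, "AB": 0.950}
    betas = {
        alg: (r.beta if isinstance(r, RatesMatrix) else float(r)) for alg, r in rates.items()
    }
    for alg, b in betas.items():
        if not 0.0 < b < 1.0:
            raise ValueError(f"beta for {alg} must lie strictly in (0, 1), got {b}")

    rng = np.random.default_rng(seed)
    nt_days = rng.poisson(demand.mean_daily_patients, size=horizon_days)
    u_days = 1.0 - rng.random(horizon_days)  # uniform on (0, 1]
    v_days = rng.random(horizon_days)  # shared binomial quantile draws
    cp = costs.resolved_cp(demand)

    out: dict[str, PenaltySeries] = {}
    for alg, beta in betas.items():
        frac = (1.0 - beta) * u_days  # no-show fraction on (0, 1 - beta]
        nn_days = binom.ppf(v_days, nt_days, frac).astype(int)
        ns_days = nt_days - nn_days
        phi = np.full(horizon_days, np.nan)
        contributing = nn_days > 0
        if not contributing.any():
            raise UndefinedPenaltyError(
                f"no contributing day over the horizon for {alg} "
                "(every slot was kept or refilled)"
            )
        phi[contributing] = _phi_closed_form(
            costs.pf,
            costs.cm,
            cp,
            nt_days[contributing].astype(float),
            ns_days[contributing].astype(float),
            beta,
        )
        rate = np.where(np.isnan(phi), np.nan, 100.0 * phi / costs.pf)
        days = pd.DataFrame(
            {
                "day": np.arange(1, horizon_days + 1),
                "nt": nt_days,
                "ns": ns_days,
                "phi": phi,
                "rate": rate,
            }
        )
        out[alg] = PenaltySeries(
            algorithm=alg,
            beta=beta,
            days=days,
            average_rate=float(np.nanmean(rate)),
        )
    return out
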