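"""Discounting, trace accumulation into totals, ICER, threshold pricing.

Accumulation uses the half-cycle convention throughout: state person-time
for the interval ``[t, t+1)`` is the arithmetic mean of the boundary
occupancies, and the discount factor is evaluated at the interval midpoint.
Costs are attached to person-time by state; progressed-disease person-time
is split into an "on subsequent therapy" part and a "best supportive care"
part by aging each progression cohort through the per-patient
subsequent-therapy cap (using the trace's PD inflow and PD death
fractions).  Adverse-event management costs/disutilities and the PD-L1
immunohistochemistry screen are one-time items at cycle 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Optional

import numpy as np

from .config import DAYS_PER_YEAR, CYCLE_DAYS
from .costs import (IHC_KEY, StrategySpec, ae_burden, cycle_cost,
                    pd_post_cap_cost)
from .engines import CohortTrace

__all__ = ["discount_factor", "StrategyOutcome", "CEResult", "accumulate",
           "icer", "threshold_price"]


def discount_factor(cycle, annual_rate: float,
                    cycle_len_days: float = CYCLE_DAYS):
    """Discount factor ``(1 + r)^(-t_years)`` at ``t = cycle`` cycles.

    Accepts fractional (e.g. mid-interval) and array-valued cycle indices.
    """
    if annual_rate < 0:
        raise ValueError("annual_rate must be >= 0")
    t_years = np.asarray(cycle, dtype=float) * cycle_len_days / DAYS_PER_YEAR
    out = (1.0 + annual_rate) ** (-t_years)
    return float(out) if np.ndim(cycle) == 0 else out


@dataclass(frozen=True)
class StrategyOutcome:
    """Discounted totals for one arm."""

    arm: str
    total_cost: float
    total_ly: float
    total_qaly: float


@dataclass(frozen=True)
class CEResult:
    """Pairwise comparison of two arms (a vs b, i.e. intervention vs comparator)."""

    a: StrategyOutcome
    b: StrategyOutcome
    delta_cost: float
    delta_qaly: float
    icer: Optional[float]
    dominance: Optional[str]   # None | "dominant" | "dominated" | "undefined"

    def to_dict(self) -> dict:
        return {
            "strategies": {
                o.arm: {"total_cost": o.total_cost, "total_ly": o.total_ly,
                        "total_qaly": o.total_qaly}
                for o in (self.a, self.b)
            },
            "delta_cost": self.delta_cost,
            "delta_qaly": self.delta_qaly,
            "icer": self.icer,
            "dominance": self.dominance,
        }


def _active_pd_boundaries(trace: CohortTrace, cap: Optional[int]) -> np.ndarray:
    """PD occupancy still within the subsequent-therapy cap, per boundary.

    Each progression cohort is aged cycle by cycle, shrinking by the trace's
    pooled PD death fraction (time-in-state-independent mortality within
    PD); after ``cap`` cycles in PD a cohort drops out of the active set.
    """
    n = trace.n_cycles
    if cap is None:
        return trace.pd.copy()
    if cap <= 0:
        return np.zeros(n + 1)
    ages = np.zeros(cap)   # mass by completed PD cycles, oldest last
    active = np.zeros(n + 1)
    for i in range(n):
        surv = 1.0 - trace.pd_death_frac[i]
        ages[1:] = ages[:-1] * surv
        ages[0] = trace.pd_inflow[i] * surv
        active[i + 1] = ages.sum()
    return np.minimum(active, trace.pd + 1e-15)


def accumulate(trace: CohortTrace, spec: StrategySpec,
               values: Mapping[str, float], discount_rate: float = 0.05,
               cycle_len_days: float = CYCLE_DAYS,
               discount_lys: bool = True) -> StrategyOutcome:
    """Fold a cohort trace and a strategy's cost model into totals.

    Also fills the trace's discounted per-cycle increment arrays.
    """
    for key in ("utility.PFS", "utility.PD"):
        if key not in values:
            raise KeyError(f"missing utility value {key!r}")
    n = trace.n_cycles
    cyl_years = cycle_len_days / DAYS_PER_YEAR
    mid = np.arange(n) + 0.5
    disc = discount_factor(mid, discount_rate, cycle_len_days)
    disc_ly = disc if discount_lys else np.ones(n)

    pfs_mid = 0.5 * (trace.pfs[:-1] + trace.pfs[1:])
    pd_mid = 0.5 * (trace.pd[:-1] + trace.pd[1:])
    active = _active_pd_boundaries(trace, spec.subsequent_cap)
    active_mid = np.minimum(0.5 * (active[:-1] + active[1:]), pd_mid)
    bsc_mid = pd_mid - active_mid

    pfs_cost = np.array([cycle_cost(spec, "PFS", i, values) for i in range(n)])
    pd_cost = cycle_cost(spec, "PD", 0, values)   # cycle-independent rate
    bsc_cost = pd_post_cap_cost(spec, values)

    cost_inc = disc * (pfs_mid * pfs_cost + active_mid * pd_cost + bsc_mid * bsc_cost)
    ly_inc = disc_ly * (pfs_mid + pd_mid) * cyl_years
    qaly_inc = disc * (pfs_mid * values["utility.PFS"]
                       + pd_mid * values["utility.PD"]) * cyl_years

    ae_cost, ae_qaly_loss = ae_burden(spec, values, cyl_years)
    one_time = values.get(IHC_KEY, 0.0) + ae_cost

    trace.cost_inc, trace.ly_inc, trace.qaly_inc = cost_inc, ly_inc, qaly_inc
    return StrategyOutcome(
        arm=spec.arm,
        total_cost=float(one_time + cost_inc.sum()),
        total_ly=float(ly_inc.sum()),
        total_qaly=float(qaly_inc.sum() - ae_qaly_loss),
    )


def icer(a: StrategyOutcome, b: StrategyOutcome) -> CEResult:
    """Incremental cost-effectiveness of ``a`` over ``b``.

    Sign disagreements are reported as dominance flags instead of a
    misleading ratio; a zero QALY difference is flagged "undefined".
    """
    d_cost = a.total_cost - b.total_cost
    d_qaly = a.total_qaly - b.total_qaly
    if d_qaly == 0.0:
        return CEResult(a, b, d_cost, d_qaly, None,
                        "undefined" if d_cost != 0.0 else "dominant")
    if d_qaly > 0 and d_cost <= 0:
        return CEResult(a, b, d_cost, d_qaly, None, "dominant")
    if d_qaly < 0 and d_cost >= 0:
        return CEResult(a, b, d_cost, d_qaly, None, "dominated")
    return CEResult(a, b, d_cost, d_qaly, d_cost / d_qaly, None)


def threshold_price(model_runner: Callable[[float], float], wtp: float,
                    price_hi: float, price_lo: float = 0.0,
                    rel_tol: float = 1e-6,
                    interval_tol: float = 0.01) -> tuple[float, str]:
    """Bisection for the drug price at which the ICER equals ``wtp``.

    ``model_runner(price)`` must return the ICER at that price and be
    monotone non-decreasing in price (costs are linear in price, QALYs
    unaffected).  Returns ``(price, status)`` where status is ``"converged"``
    or ``"already_cost_effective"`` (ICER at ``price_hi`` does not exceed
    ``wtp``).
    """
    if wtp <= 0:
        raise ValueError("wtp must be > 0")
    if price_hi <= price_lo:
        raise ValueError("price_hi must exceed price_lo")
    if model_runner(price_hi) <= wtp:
        return price_hi, "already_cost_effective"
    lo, hi = price_lo, price_hi
    while hi - lo > interval_tol:
        mid = 0.5 * (lo + hi)
        ic = model_runner(mid)
        if abs(ic - wtp) <= rel_tol * wtp:
            return mid, "converged"
        if ic > wtp:
            hi = mid
        else:
            lo = mid
    return 0.5 * (lo + hi), "converged"
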