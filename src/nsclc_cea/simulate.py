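"""Synthetic survival-data generation.

Emulates the individual patient data that curve digitization + pseudo-IPD
reconstruction would yield from published Kaplan-Meier figures: event times
drawn by inverse-CDF from a parametric survival model, administratively
censored at a cutoff, plus digitized-curve fixtures (coordinates on an even
time grid with at-risk counts).  Everything is deterministic for a fixed
seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .survival import KMCurve, ParametricSurvival, ipd_frame, km_estimate

__all__ = ["SimSpec", "simulate_ipd", "make_km_fixture"]


@dataclass(frozen=True)
class SimSpec:
    """One simulation scenario: model, cohort size, censoring, seed."""

    model: ParametricSurvival
    n: int
    censor_time: float
    seed: int

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be > 0")
        if self.censor_time <= 0:
            raise ValueError("censor_time must be > 0 (no observable time otherwise)")


def simulate_ipd(spec: SimSpec) -> pd.DataFrame:
    """Draw right-censored survival data from a parametric model.

    Event times come from the model's quantile function applied to uniform
    draws; times beyond ``censor_time`` are recorded as censored there.
    """
    rng = np.random.default_rng(spec.seed)
    u = rng.random(spec.n)
    t = np.maximum(spec.model.ppf(u), 1e-12)   # guard u == 0.0
    event = t <= spec.censor_time
    time = np.where(event, t, spec.censor_time)
    return ipd_frame(time, event.astype(int))


def make_km_fixture(model: ParametricSurvival, n_points: int, n_patients: int,
                    seed: int, censor_time: float = 120.0,
                    ) -> tuple[KMCurve, pd.DataFrame]:
    """Simulate IPD and return digitized-style KM coordinates + the IPD.

    The Kaplan-Meier estimate of the simulated cohort is sampled at
    ``n_points`` evenly spaced times from 0 to ``censor_time`` (step
    interpolation, so coordinates are guaranteed monotone), with the number
    at risk just before each grid time attached — the shape a graph
    digitization step would produce.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    ipd = simulate_ipd(SimSpec(model=model, n=n_patients,
                               censor_time=censor_time, seed=seed))
    km = km_estimate(ipd)
    grid = np.linspace(0.0, censor_time, n_points)
    surv = km.step_interp(grid)
    times = ipd["time_months"].to_numpy()
    at_risk = np.array([(times >= g - 1e-12).sum() for g in grid], dtype=float)
    return KMCurve(times=grid, surv=surv, at_risk=at_risk), ipd
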