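"""Deterministic and probabilistic sensitivity analysis, and scenarios.

One-way analysis re-runs the model once per parameter bound (tornado);
probabilistic analysis draws every uncertain item jointly — gamma for
costs, beta for utilities/probabilities, method-of-moments with the printed
range read as a 95 % interval (sd = (high - low)/3.92) — and summarises the
draws as a cost-effectiveness acceptability curve (CEAC).
"""

from __future__ import annotations

import logging
from typing import Callable, Mapping, Optional

import numpy as np
import pandas as pd

from .costs import DISCOUNT_KEY, PRICE_ONLY_REDUCED, ParamItem

logger = logging.getLogger(__name__)

__all__ = ["osa_ranges", "one_way", "draw_params", "psa", "ceac",
           "DEFAULT_WTP_GRID"]

#: CEAC grid: 0 to 150,000 USD/QALY in 1,000-USD steps.
DEFAULT_WTP_GRID = np.arange(0.0, 150_001.0, 1_000.0)

_RANGE_SD_DIVISOR = 3.92   # printed ranges treated as 95 % intervals


def osa_ranges(table: Mapping[str, ParamItem]) -> dict[str, tuple[float, float]]:
    """(low, high) per parameter for the tornado.

    Checkpoint-inhibitor prices can only fall (0.8x baseline to baseline);
    every other item uses its printed range, including the discount rate.
    """
    ranges: dict[str, tuple[float, float]] = {}
    for key, item in table.items():
        if key in PRICE_ONLY_REDUCED:
            ranges[key] = (0.8 * item.baseline, item.baseline)
        else:
            ranges[key] = (item.low, item.high)
    return ranges


def one_way(evaluate: Callable[[Mapping[str, float]], float],
            base_values: Mapping[str, float],
            ranges: Mapping[str, tuple[float, float]]) -> pd.DataFrame:
    """Tornado table: ICER at each parameter's bounds, sorted by swing.

    ``evaluate`` maps a full parameter-value mapping (which includes the
    discount rate under its table key) to an ICER; all other items are held
    at baseline while one moves.
    """
    rows = []
    for key, (lo, hi) in ranges.items():
        if lo > hi:
            raise ValueError(f"{key}: low bound exceeds high bound")
        icers = []
        for bound in (lo, hi):
            vals = dict(base_values)
            vals[key] = bound
            icers.append(evaluate(vals))
        rows.append({"parameter": key, "low": lo, "high": hi,
                     "icer_at_low": icers[0], "icer_at_high": icers[1],
                     "swing": abs(icers[1] - icers[0])})
    out = pd.DataFrame(rows).sort_values("swing", ascending=False,
                                         kind="stable").reset_index(drop=True)
    return out


def _gamma_draw(rng: np.random.Generator, mean: float, sd: float) -> float:
    if sd <= 0 or mean <= 0:
        return mean
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return float(rng.gamma(shape, scale))


def _beta_draw(rng: np.random.Generator, mean: float, sd: float,
               name: str) -> float:
    if sd <= 0:
        return mean
    if not 0.0 < mean < 1.0 or sd * sd >= mean * (1.0 - mean):
        logger.warning("%s: sd incompatible with beta support; using baseline", name)
        return mean
    nu = mean * (1.0 - mean) / (sd * sd) - 1.0
    return float(rng.beta(mean * nu, (1.0 - mean) * nu))


def draw_params(table: Mapping[str, ParamItem],
                rng: np.random.Generator) -> dict[str, float]:
    """One Monte-Carlo draw of every uncertain parameter.

    Disutilities are drawn as beta on their magnitude and re-negated;
    ``dist: fixed`` items (the discount rate) stay at baseline.
    """
    values: dict[str, float] = {}
    for key, item in table.items():
        sd = (item.high - item.low) / _RANGE_SD_DIVISOR
        if item.dist == "fixed":
            values[key] = item.baseline
        elif item.dist == "gamma":
            values[key] = _gamma_draw(rng, item.baseline, sd)
        elif item.kind == "disutility":
            values[key] = -_beta_draw(rng, abs(item.baseline), sd, key)
        else:
            values[key] = _beta_draw(rng, item.baseline, sd, key)
    return values


def ceac(samples: pd.DataFrame,
         wtp_grid: np.ndarray = DEFAULT_WTP_GRID) -> pd.DataFrame:
    """P(intervention cost-effective) over a WTP grid.

    A draw favours the intervention when its net monetary benefit is
    positive: ``wtp * delta_qaly - delta_cost > 0``.
    """
    dq = samples["delta_qaly"].to_numpy()
    dc = samples["delta_cost"].to_numpy()
    prob = [(w * dq - dc > 0).mean() for w in wtp_grid]
    return pd.DataFrame({"wtp": wtp_grid, "prob_cost_effective": prob})


def psa(evaluate_pair: Callable[[Mapping[str, float]], tuple[float, float]],
        table: Mapping[str, ParamItem], n_iter: int = 1000, seed: int = 12345,
        wtp_grid: Optional[np.ndarray] = None,
        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Monte-Carlo PSA: returns (samples, CEAC).

    ``evaluate_pair(values)`` runs both arms under one parameter draw and
    returns ``(delta_cost, delta_qaly)``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(seed)
    rows = []
    for it in range(n_iter):
        values = draw_params(table, rng)
        d_cost, d_qaly = evaluate_pair(values)
        rows.append({"iteration": it, "delta_cost": d_cost, "delta_qaly": d_qaly})
    samples = pd.DataFrame(rows)
    grid = DEFAULT_WTP_GRID if wtp_grid is None else np.asarray(wtp_grid, float)
    return samples, ceac(samples, grid)
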