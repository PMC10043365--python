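"""Orchestration: strategies + engine(s) -> totals, ICERs, scenarios, PSA.

The central object is :class:`PairModel`, which freezes the cohort traces
for both arms under one engine (occupancy depends only on the fitted curves
and the cycle grid, not on costs, utilities or the discount rate) and then
re-prices them cheaply for base case, tornado bounds, PSA draws, PAP and
threshold-price searches.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .config import RunConfig, TABLE1_CURVES, WTP_TABLE
from .costs import (DISCOUNT_KEY, StrategySpec, atezolizumab_strategy,
                    baseline_values, chemotherapy_strategy, load_table)
from .econ import CEResult, accumulate, icer, threshold_price
from .engines import CohortTrace, markov_trace, partsa_trace
from .sensitivity import one_way, osa_ranges, psa

__all__ = ["PairModel", "base_case", "tornado", "run_psa", "threshold_prices",
           "run_scenario", "run"]

ATEZO_PRICE_KEY = "drug.Atezolizumab"


class PairModel:
    """Both arms of the comparison under one engine and one configuration."""

    def __init__(self, config: RunConfig, engine: str,
                 table_path=None) -> None:
        if engine not in ("partsa", "markov"):
            raise ValueError(f"engine must be 'partsa' or 'markov', got {engine!r}")
        config.validate()
        self.config = config
        self.engine = engine
        self.table = load_table(table_path)
        self.base_values = baseline_values(self.table, config.value_overrides)
        # the config's discount rate is authoritative over the table row
        self.base_values[DISCOUNT_KEY] = config.discount_rate
        self.traces: dict[str, CohortTrace] = {}
        for arm, curves in TABLE1_CURVES.items():
            if engine == "partsa":
                self.traces[arm] = partsa_trace(
                    curves["pfs"], curves["os"], config.horizon_cycles,
                    config.cycle_len_months)
            else:
                self.traces[arm] = markov_trace(
                    curves["pfs"], curves["os"], config.horizon_cycles,
                    config.cycle_len_months, p_nat=config.p_nat)

    # -- strategy builders ---------------------------------------------------
    def _strategies(self, pap: bool) -> tuple[StrategySpec, StrategySpec]:
        cfg = self.config
        atezo = atezolizumab_strategy(
            pap=pap, pap_share=cfg.pap_share, pap_paid_cycles=cfg.pap_paid_cycles,
            subsequent_cap=cfg.subsequent_cap_atezo_arm,
            squamous=cfg.squamous_proportion)
        chemo = chemotherapy_strategy(
            subsequent_cap=cfg.subsequent_cap_chemo_arm,
            squamous=cfg.squamous_proportion)
        return atezo, chemo

    # -- evaluation ----------------------------------------------------------
    def result(self, values: Optional[Mapping[str, float]] = None,
               pap: bool = False,
               atezo_price: Optional[float] = None) -> CEResult:
        """Price the frozen traces under one parameter set."""
        vals = dict(self.base_values)
        if values is not None:
            vals.update(values)
        if atezo_price is not None:
            vals[ATEZO_PRICE_KEY] = atezo_price
        rate = vals[DISCOUNT_KEY]
        atezo, chemo = self._strategies(pap)
        cfg = self.config
        out_a = accumulate(self.traces["atezolizumab"], atezo, vals, rate,
                           cfg.cycle_len_days, cfg.discount_lys)
        out_c = accumulate(self.traces["chemotherapy"], chemo, vals, rate,
                           cfg.cycle_len_days, cfg.discount_lys)
        return icer(out_a, out_c)

    def icer_at_price(self, price: float, pap: bool = False) -> float:
        """ICER as a function of the atezolizumab per-cycle price.

        Dominant results map to ``-inf`` so threshold bisection can treat
        them as 'below any willingness-to-pay'.
        """
        res = self.result(pap=pap, atezo_price=price)
        if res.icer is None:
            return float("-inf") if res.dominance == "dominant" else float("inf")
        return res.icer


def _engines(config: RunConfig) -> list[str]:
    return ["partsa", "markov"] if config.engine == "both" else [config.engine]


def base_case(config: RunConfig) -> dict[str, CEResult]:
    """Base-case totals and pairwise ICER per requested engine."""
    return {eng: PairModel(config, eng).result() for eng in _engines(config)}


def tornado(config: RunConfig, engine: str = "partsa",
            pap: bool = False) -> pd.DataFrame:
    """One-way sensitivity of the ICER, sorted by swing (descending)."""
    model = PairModel(config, engine)

    def evaluate(vals: Mapping[str, float]) -> float:
        res = model.result(values=vals, pap=pap)
        return res.icer if res.icer is not None else float("nan")

    return one_way(evaluate, model.base_values, osa_ranges(model.table))


def run_psa(config: RunConfig, engine: str = "partsa",
            ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Probabilistic sensitivity analysis; returns (samples, CEAC)."""
    model = PairModel(config, engine)

    def evaluate_pair(vals: Mapping[str, float]) -> tuple[float, float]:
        res = model.result(values=vals)
        return res.delta_cost, res.delta_qaly

    return psa(evaluate_pair, model.table, n_iter=config.psa_iters,
               seed=config.seed)


def threshold_prices(config: RunConfig, engine: str = "partsa",
                     pap: bool = False,
                     regions: Optional[list[str]] = None) -> pd.DataFrame:
    """Cost-effectiveness price of atezolizumab per region and WTP basis."""
    model = PairModel(config, engine)
    baseline_price = model.base_values[ATEZO_PRICE_KEY]
    regions = regions or list(WTP_TABLE)
    rows = []
    for region in regions:
        if region not in WTP_TABLE:
            raise ValueError(f"unknown region {region!r}; expected one of "
                             f"{sorted(WTP_TABLE)}")
        for basis, wtp in WTP_TABLE[region].items():
            price, status = threshold_price(
                lambda p: model.icer_at_price(p, pap=pap), wtp, baseline_price)
            rows.append({"region": region, "wtp_basis": basis, "wtp": wtp,
                         "price": price, "status": status, "pap": pap})
    return pd.DataFrame(rows)


def run_scenario(config: RunConfig, scenario: str = "base",
                 region: Optional[str] = None, engine: str = "partsa") -> dict:
    """Evaluate a named scenario.

    ``base`` is the unmodified comparison; ``pap`` applies the patient
    assistance program to the atezolizumab arm; ``region`` re-evaluates the
    threshold prices against a region's 1x and 3x per-capita-GDP
    willingness-to-pay.
    """
    model = PairModel(config, engine)
    if scenario == "base":
        return {"scenario": "base", "result": model.result().to_dict()}
    if scenario == "pap":
        res = model.result(pap=True)
        return {"scenario": "pap", "result": res.to_dict()}
    if scenario == "region":
        if region is None:
            raise ValueError("region scenario requires a region label")
        prices = threshold_prices(config, engine, regions=[region])
        return {"scenario": f"region:{region}",
                "result": model.result().to_dict(),
                "threshold_prices": prices.to_dict(orient="records")}
    raise ValueError(f"unknown scenario {scenario!r}")


def run(config: RunConfig, out_dir: Optional[str] = None) -> dict:
    """Base case (plus configured scenario) for every requested engine.

    Returns a JSON-serialisable bundle with a provenance block; optionally
    writes ``results.json`` and per-arm trace CSVs under ``out_dir``.
    """
    bundle: dict = {"provenance": config.provenance(), "engines": {}}
    for eng in _engines(config):
        model = PairModel(config, eng)
        entry: dict = {"base": model.result().to_dict()}
        if config.scenario == "pap":
            entry["pap"] = model.result(pap=True).to_dict()
        elif config.scenario == "region":
            entry["region"] = run_scenario(config, "region", config.region, eng)
        bundle["engines"][eng] = entry
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / "results.json", "w") as fh:
            json.dump(bundle, fh, indent=2, sort_keys=True)
        for eng in _engines(config):
            model = PairModel(config, eng)
            model.result()   # fill increment arrays at base case
            for arm, trace in model.traces.items():
                trace.write_csv(out / f"trace_{eng}_{arm}.csv")
    return bundle
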