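"""One-way and probabilistic sensitivity analysis machinery."""

import dataclasses

import numpy as np
import pandas as pd
import pytest

from nsclc_cea import (PairModel, RunConfig, ceac, draw_params, one_way,
                       osa_ranges, psa)
from nsclc_cea.costs import DISCOUNT_KEY, PRICE_ONLY_REDUCED


def _degenerate(table):
    return {k: dataclasses.replace(item, low=item.baseline, high=item.baseline)
            for k, item in table.items()}


class TestDrawParams:
    def test_sample_means_recover_baselines(self, table, rng):
        draws = pd.DataFrame([draw_params(table, rng) for _ in range(10_000)])
        assert draws["drug.Atezolizumab"].mean() == pytest.approx(4716.03, rel=0.01)
        assert draws["utility.PFS"].mean() == pytest.approx(0.856, rel=0.01)
        assert draws["incidence.Anemia(Chemotherapy)"].mean() == pytest.approx(
            0.190, rel=0.02)

    def test_supports_respected(self, table, rng):
        for _ in range(200):
            vals = draw_params(table, rng)
            assert vals["drug.Atezolizumab"] > 0
            assert 0.0 < vals["utility.PFS"] < 1.0
            assert 0.0 < vals["incidence.Neutropenia(Chemotherapy)"] < 1.0
            assert -1.0 < vals["disutility.Neutropenia"] < 0.0

    def test_seeded_draws_reproducible(self, table):
        a = draw_params(table, np.random.default_rng(99))
        b = draw_params(table, np.random.default_rng(99))
        assert a == b

    def test_fixed_items_stay_at_baseline(self, table, rng):
        assert draw_params(table, rng)[DISCOUNT_KEY] == 0.05

    def test_degenerate_ranges_return_baselines(self, table, rng):
        vals = draw_params(_degenerate(table), rng)
        assert all(vals[k] == pytest.approx(item.baseline)
                   for k, item in table.items())


class TestOneWay:
    def test_zero_width_range_gives_zero_swing(self):
        evaluate = lambda vals: vals["x"] * 2.0
        out = one_way(evaluate, {"x": 5.0}, {"x": (5.0, 5.0)})
        assert out.loc[0, "swing"] == 0.0

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            one_way(lambda v: 0.0, {"x": 1.0}, {"x": (2.0, 1.0)})

    def test_entries_sorted_by_swing(self):
        evaluate = lambda vals: vals["a"] + 10 * vals["b"]
        out = one_way(evaluate, {"a": 1.0, "b": 1.0},
                      {"a": (0.0, 2.0), "b": (0.0, 2.0)})
        assert list(out["parameter"]) == ["b", "a"]

    def test_ici_prices_can_only_fall(self, table):
        ranges = osa_ranges(table)
        for key in PRICE_ONLY_REDUCED:
            lo, hi = ranges[key]
            assert hi == table[key].baseline
            assert lo == pytest.approx(0.8 * table[key].baseline)

    def test_absent_parameter_has_zero_swing(self, config, table):
        """Items outside the model path (atezolizumab AE incidences do not
        touch the chemotherapy arm and vice versa) still evaluate cleanly;
        a no-op parameter produces zero swing."""
        model = PairModel(config, "partsa")
        evaluate = lambda vals: model.result(values=vals).icer
        out = one_way(evaluate, model.base_values,
                      {"followup.Register": (2.01, 2.01)})
        assert out.loc[0, "swing"] == 0.0

    def test_lower_atezolizumab_price_lowers_icer(self, config):
        model = PairModel(config, "partsa")
        base = model.result().icer
        cheaper = model.result(values={"drug.Atezolizumab": 4000.0}).icer
        assert cheaper < base


class TestPSA:
    def test_degenerate_distributions_reproduce_base_case(self, config, table):
        model = PairModel(config, "partsa")
        base = model.result()
        evaluate = lambda vals: (model.result(values=vals).delta_cost,
                                 model.result(values=vals).delta_qaly)
        samples, _ = psa(evaluate, _degenerate(table), n_iter=5, seed=1)
        assert np.allclose(samples["delta_cost"], base.delta_cost)
        assert np.allclose(samples["delta_qaly"], base.delta_qaly)

    def test_single_iteration_ceac_is_binary(self):
        samples = pd.DataFrame({"delta_cost": [50.0], "delta_qaly": [0.01]})
        curve = ceac(samples, np.array([0.0, 10_000.0]))
        assert set(curve["prob_cost_effective"]).issubset({0.0, 1.0})

    def test_ceac_monotone_when_all_draws_gain_qalys(self):
        rng = np.random.default_rng(4)
        samples = pd.DataFrame({"delta_cost": rng.normal(1000, 300, 500),
                                "delta_qaly": rng.uniform(0.1, 0.5, 500)})
        curve = ceac(samples, np.arange(0.0, 20_000.0, 500.0))
        assert (curve["prob_cost_effective"].diff().dropna() >= 0).all()

    def test_same_seed_identical_samples(self, config, table):
        model = PairModel(config, "partsa")
        evaluate = lambda vals: (model.result(values=vals).delta_cost,
                                 model.result(values=vals).delta_qaly)
        s1, _ = psa(evaluate, table, n_iter=3, seed=77)
        s2, _ = psa(evaluate, table, n_iter=3, seed=77)
        pd.testing.assert_frame_equal(s1, s2)


class TestPAPScenario:
    def test_pap_changes_costs_never_outcomes(self, config):
        model = PairModel(config, "partsa")
        base = model.result()
        pap = model.result(pap=True)
        assert pap.a.total_cost < base.a.total_cost
        assert pap.a.total_qaly == base.a.total_qaly
        assert pap.a.total_ly == base.a.total_ly
        assert pap.delta_qaly == base.delta_qaly

    def test_base_scenario_is_identity(self, config):
        from nsclc_cea import run_scenario
        direct = PairModel(config, "partsa").result().to_dict()
        wrapped = run_scenario(config, "base")["result"]
        assert wrapped == direct

    def test_unknown_region_rejected(self, config):
        from nsclc_cea import run_scenario
        with pytest.raises(ValueError):
            run_scenario(config, "region", region="Atlantis")
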