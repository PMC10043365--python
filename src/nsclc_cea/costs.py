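"""Cost/utility parameter table and per-cycle strategy costing.

The parameter table ships as YAML (``data/table2.yaml``) whose row names
mirror the published table; every item carries a baseline, an uncertainty
range and a sampling family (gamma for costs, beta for probabilities and
utilities).  Items are addressed by qualified names such as
``drug.Atezolizumab`` or ``incidence.Anemia(Chemotherapy)``.

Strategy arms
-------------
* atezolizumab: 1,200 mg every 3 weeks until progression; on progression a
  salvage-chemotherapy mix (docetaxel / paclitaxel) until death.
* chemotherapy: platinum doublet for 5 induction cycles (cisplatin or
  carboplatin with equal probability; partner drug pemetrexed for
  non-squamous, gemcitabine twice per cycle for squamous), then pemetrexed
  maintenance (non-squamous) or best supportive care (squamous); on
  progression a second-line immunotherapy mix (nivolumab 1.5 doses per
  3-week cycle / pembrolizumab) for a capped number of cycles, then best
  supportive care.

A six-item follow-up bundle is charged every cycle in both alive states, and
PD-L1 immunohistochemistry screening once per patient in both arms.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, replace
from typing import Mapping, Optional

import yaml

__all__ = [
    "ParamItem",
    "load_table",
    "baseline_values",
    "StrategySpec",
    "atezolizumab_strategy",
    "chemotherapy_strategy",
    "followup_cost",
    "cycle_cost",
    "pd_post_cap_cost",
    "ae_burden",
    "apply_pap",
]

_SECTION_PREFIX = {
    "drug_cost_per_cycle": "drug",
    "ae_cost": "ae_cost",
    "follow_up_cost_per_cycle": "followup",
    "utility": "utility",
    "ae_disutility": "disutility",
    "ae_incidence": "incidence",
    "other": "other",
}

_KIND = {
    "drug": "cost", "ae_cost": "cost", "followup": "cost", "other": "cost",
    "utility": "utility", "disutility": "disutility", "incidence": "probability",
}

IHC_KEY = "other.Immunohistochemistry(IHC) cost"
DISCOUNT_KEY = "other.Discount rate"
BSC_KEY = "drug.Best supportive care"

#: drugs whose price can only fall in one-way sensitivity analysis
PRICE_ONLY_REDUCED = (
    "drug.Atezolizumab", "drug.Pembrolizumab", "drug.Nivolumab(14days)",
)


@dataclass(frozen=True)
class ParamItem:
    """One uncertain model input: baseline, range, sampling family."""

    name: str
    baseline: float
    low: float
    high: float
    dist: str      # gamma | beta | fixed
    kind: str      # cost | utility | disutility | probability

    def __post_init__(self) -> None:
        if not self.low <= self.baseline <= self.high:
            raise ValueError(f"{self.name}: need low <= baseline <= high, "
                             f"got {self.low}, {self.baseline}, {self.high}")
        if self.kind == "cost" and self.baseline < 0:
            raise ValueError(f"{self.name}: costs must be >= 0")
        if self.kind == "utility" and not 0.0 <= self.baseline <= 1.0:
            raise ValueError(f"{self.name}: utilities must lie in [0, 1]")
        if self.kind == "disutility" and not -1.0 <= self.baseline <= 0.0:
            raise ValueError(f"{self.name}: disutilities must lie in [-1, 0]")
        if self.kind == "probability" and not 0.0 <= self.baseline <= 1.0:
            raise ValueError(f"{self.name}: probabilities must lie in [0, 1]")
        if self.dist not in ("gamma", "beta", "fixed"):
            raise ValueError(f"{self.name}: unknown distribution {self.dist!r}")


def load_table(path=None) -> dict[str, ParamItem]:
    """Load the parameter table (package default or a user YAML override)."""
    if path is None:
        ref = importlib.resources.files("nsclc_cea") / "data" / "table2.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    table: dict[str, ParamItem] = {}
    for section, prefix in _SECTION_PREFIX.items():
        for name, row in raw.get(section, {}).items():
            lo, hi = sorted((float(row["low"]), float(row["high"])))
            key = f"{prefix}.{name}"
            table[key] = ParamItem(name=key, baseline=float(row["baseline"]),
                                   low=lo, high=hi, dist=row["dist"],
                                   kind=_KIND[prefix])
    return table


def baseline_values(table: Mapping[str, ParamItem],
                    overrides: Optional[Mapping[str, float]] = None) -> dict[str, float]:
    values = {k: item.baseline for k, item in table.items()}
    if overrides:
        unknown = set(overrides) - set(values)
        if unknown:
            raise KeyError(f"unknown parameter overrides: {sorted(unknown)}")
        values.update(overrides)
    return values


# ---------------------------------------------------------------------------
# Strategies
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrategySpec:
    """An arm's treatment schedule and cost structure.

    ``subsequent`` lists (drug key, mix weight, doses per cycle) triples for
    post-progression therapy; ``subsequent_cap`` is the per-patient maximum
    number of cycles of that therapy (None = until death), after which only
    best supportive care is charged.
    """

    arm: str
    induction_cycles: int = 0
    squamous: float = 0.697
    subsequent: tuple = ()
    subsequent_cap: Optional[int] = None
    pap: bool = False
    pap_share: float = 0.5
    pap_paid_cycles: int = 16
    ae: tuple = ()   # (incidence key, cost key, disutility key) triples

    def __post_init__(self) -> None:
        if self.arm not in ("atezolizumab", "chemotherapy"):
            raise ValueError(f"unknown arm {self.arm!r}")
        if self.induction_cycles < 0:
            raise ValueError("induction_cycles must be >= 0")
        if not 0.0 <= self.squamous <= 1.0:
            raise ValueError("squamous proportion must lie in [0, 1]")
        total = self.squamous + self.non_squamous
        if abs(total - 1.0) > 1e-12:
            raise ValueError("histology proportions must sum to 1")

    @property
    def non_squamous(self) -> float:
        return 1.0 - self.squamous


_AE_ATEZO = (
    ("incidence.Anemia(Atezolizumab)", "ae_cost.Anemia", "disutility.Anemia"),
    ("incidence.Neutropenia(Atezolizumab)", "ae_cost.Neutropenia", "disutility.Neutropenia"),
    ("incidence.Thrombocytopenia(Atezolizumab)", "ae_cost.Thrombocytopenia",
     "disutility.Thrombocytopenia"),
)
_AE_CHEMO = (
    ("incidence.Anemia(Chemotherapy)", "ae_cost.Anemia", "disutility.Anemia"),
    ("incidence.Neutropenia(Chemotherapy)", "ae_cost.Neutropenia", "disutility.Neutropenia"),
    ("incidence.Thrombocytopenia(Chemotherapy)", "ae_cost.Thrombocytopenia",
     "disutility.Thrombocytopenia"),
)


def atezolizumab_strategy(pap: bool = False, pap_share: float = 0.5,
                          pap_paid_cycles: int = 16,
                          subsequent_cap: Optional[int] = None,
                          squamous: float = 0.697) -> StrategySpec:
    return StrategySpec(
        arm="atezolizumab", induction_cycles=0, squamous=squamous,
        subsequent=(("drug.Docetaxel", 0.5, 1.0), ("drug.Taxol", 0.5, 1.0)),
        subsequent_cap=subsequent_cap, pap=pap, pap_share=pap_share,
        pap_paid_cycles=pap_paid_cycles, ae=_AE_ATEZO)


def chemotherapy_strategy(subsequent_cap: Optional[int] = 24,
                          squamous: float = 0.697) -> StrategySpec:
    return StrategySpec(
        arm="chemotherapy", induction_cycles=5, squamous=squamous,
        subsequent=(("drug.Nivolumab(14days)", 0.5, 1.5),
                    ("drug.Pembrolizumab", 0.5, 1.0)),
        subsequent_cap=subsequent_cap, ae=_AE_CHEMO)


# ---------------------------------------------------------------------------
# Per-cycle costing
# ---------------------------------------------------------------------------

_FOLLOWUP_KEYS = (
    "followup.Register", "followup.Injection", "followup.CT",
    "followup.Blood routine tests", "followup.Biochemical test",
    "followup.Blood coagulation",
)


def followup_cost(values: Mapping[str, float]) -> float:
    """Per-cycle follow-up bundle (registration, injection, CT, labs)."""
    return sum(values[k] for k in _FOLLOWUP_KEYS)


def _pap_weight(spec: StrategySpec, cycle: int) -> float:
    """Fraction of the list price actually paid at a given cycle.

    Under the patient assistance program, ``pap_share`` of patients receive
    the drug free of charge once they have paid for ``pap_paid_cycles``
    cycles; the remainder pay list price throughout.
    """
    if not spec.pap:
        return 1.0
    paying = 1.0 - spec.pap_share
    return paying + spec.pap_share * (1.0 if cycle < spec.pap_paid_cycles else 0.0)


def _subsequent_drug_cost(spec: StrategySpec, values: Mapping[str, float]) -> float:
    return sum(w * doses * values[key] for key, w, doses in spec.subsequent)


def cycle_cost(spec: StrategySpec, state: str, cycle: int,
               values: Mapping[str, float]) -> float:
    """Undiscounted cost of one full cycle spent in ``state``.

    For PD this is the on-subsequent-therapy rate; patients beyond the
    subsequent-therapy cap are costed with :func:`pd_post_cap_cost` instead
    (the engines' accumulation step tracks who is beyond the cap).
    """
    if cycle < 0:
        raise ValueError("cycle must be >= 0")
    fu = followup_cost(values)
    if state == "PFS":
        if spec.arm == "atezolizumab":
            return values["drug.Atezolizumab"] * _pap_weight(spec, cycle) + fu
        if cycle < spec.induction_cycles:
            platinum = 0.5 * (values["drug.Cisplatin"]
                              + values["drug.Carboplatin(Weighted average)"])
            partner = (spec.non_squamous * values["drug.Pemetrexed"]
                       + spec.squamous * 2.0 * values["drug.Gemcitabine(Weighted average)"])
            return platinum + partner + fu
        maintenance = (spec.non_squamous * values["drug.Pemetrexed"]
                       + spec.squamous * values[BSC_KEY])
        return maintenance + fu
    if state == "PD":
        return _subsequent_drug_cost(spec, values) + fu
    raise ValueError(f"unknown state {state!r}; expected 'PFS' or 'PD'")


def pd_post_cap_cost(spec: StrategySpec, values: Mapping[str, float]) -> float:
    """Per-cycle PD cost once subsequent therapy is exhausted (BSC + follow-up)."""
    return values[BSC_KEY] + followup_cost(values)


def ae_burden(spec: StrategySpec, values: Mapping[str, float],
              cycle_len_years: float) -> tuple[float, float]:
    """One-time adverse-event cost and QALY loss, applied at cycle 0.

    QALY loss assumes each event's disutility lasts one treatment cycle.
    """
    cost = sum(values[inc] * values[c] for inc, c, _ in spec.ae)
    qaly_loss = sum(values[inc] * abs(values[d]) for inc, _, d in spec.ae) * cycle_len_years
    return cost, qaly_loss


def apply_pap(spec: StrategySpec) -> StrategySpec:
    """Turn on the patient assistance program for a PAP-eligible arm.

    Idempotent; the chemotherapy arm (no PAP-eligible drug) is returned
    unchanged.
    """
    if spec.arm != "atezolizumab" or spec.pap:
        return spec
    return replace(spec, pap=True)
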