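# nsclc-cea

Cost-effectiveness models for **first-line atezolizumab monotherapy versus
platinum-based chemotherapy** in PD-L1-high (TC ≥ 50 %), EGFR/ALK wild-type
advanced non-small-cell lung cancer, from the perspective of the Chinese
healthcare system.

Immune-checkpoint inhibitors extend survival in this population but at a
price far above chemotherapy. This package implements the full
decision-analytic workflow a health-economics analyst needs to quantify that
trade-off: parametric survival modelling of trial curves, two independent
cohort engines, a structured cost/utility model, deterministic and
probabilistic sensitivity analysis, and threshold ("fair price") search. It
is aimed at HTA analysts and methods researchers who want a scriptable,
tested alternative to spreadsheet/TreeAge implementations.

## The model

Three health states — progression-free (PFS), progressed disease (PD), death
— over a 10-year horizon of 170 three-week cycles, discounted at 5 %/year.

**Survival.** Trial OS and PFS are represented by parametric curves; the
package supports the exponential, Weibull, loglogistic

S(t) = 1 / (1 + λ t^γ)

and lognormal

S(t) = 1 − Φ((ln t − μ)/σ)

families (t in months), fits them to right-censored individual patient data
by maximum likelihood, and selects among them by AIC/BIC. Pseudo-IPD can be
reconstructed from digitized Kaplan–Meier coordinates so published figures
become fittable data.

**Engines.** The *partitioned survival* engine reads state occupancy off the
curves directly: `pfs = min(S_PFS, S_OS)`, `dead = 1 − S_OS`, PD the area in
between. The *Markov* engine converts the same curves into time-dependent
transition probabilities (PFS exit from the conditional PFS survival ratio,
a constant background-mortality PFS→Death, and a residual PD→Death that
keeps cohort deaths on the OS curve) with a half-cycle correction. With
background mortality switched off the two engines coincide exactly, which
is used as a cross-engine oracle in the tests.

**Economics.** Per-cycle drug, follow-up, best-supportive-care and
subsequent-therapy costs, one-time adverse-event and PD-L1
immunohistochemistry costs, EQ-5D state utilities and AE disutilities
combine into discounted totals per arm, and

ICER = ΔCost / ΔQALY

is judged against willingness-to-pay thresholds of 1× and 3× per-capita GDP
(national and regional). One-way sensitivity produces a tornado table;
probabilistic sensitivity draws every uncertain parameter (gamma for costs,
beta for utilities/probabilities) and summarises 1,000 Monte-Carlo runs as a
cost-effectiveness acceptability curve. A bisection search returns the
atezolizumab price at which the ICER equals any threshold, with and without
the patient assistance program (PAP).

## Worked example

```bash
$ nsclc-cea --quiet base-case --engine both --out-dir results
partsa: ICER = 107747.95 USD/QALY (dCost 77952, dQALY 0.723)
markov: ICER = 107969.84 USD/QALY (dCost 78113, dQALY 0.723)
```

Atezolizumab adds 0.723 QALYs over chemotherapy at an extra discounted cost
of about $78k, i.e. roughly $108k per QALY gained under either engine —
about three times the national 3×-GDP willingness-to-pay threshold of
$34,928.54/QALY, so first-line atezolizumab is not cost-effective at list
price. The price at which it would become cost-effective:

```bash
$ nsclc-cea --quiet threshold --engine partsa --region China --out-dir results
region wtp_basis          wtp       price    status   pap
 China    1x_gdp 11642.846667 2271.450526 converged False
 China    3x_gdp 34928.540000 2863.756254 converged False
```

i.e. the per-cycle price would have to fall from $4,716.03 to about $2,864
(3× GDP) or $2,271 (1× GDP). Python API equivalent:

```python
from nsclc_cea import RunConfig, PairModel

model = PairModel(RunConfig(), "partsa")
print(model.result().icer)          # ~107748 USD/QALY
print(model.result(pap=True).icer)  # ~48546 USD/QALY under the PAP
```

Other subcommands: `tornado` (one-way sensitivity), `psa` (Monte-Carlo PSA +
CEAC), `scenario` (PAP / regional thresholds), `simulate` and `fit`
(synthetic IPD and survival fitting).

## Layout

| module | contents |
| --- | --- |
| `nsclc_cea.survival` | parametric curves, MLE fitting, AIC/BIC selection, KM, pseudo-IPD reconstruction |
| `nsclc_cea.costs` | parameter table (YAML), strategy specs, per-cycle costing, AE burden, PAP |
| `nsclc_cea.engines` | partitioned-survival and Markov cohort traces |
| `nsclc_cea.econ` | discounting, accumulation, ICER, threshold-price bisection |
| `nsclc_cea.sensitivity` | tornado, parameter draws, PSA, CEAC |
| `nsclc_cea.simulate` | synthetic IPD and digitized-curve fixtures |
| `nsclc_cea.config` / `pipeline` / `cli` | run configuration, orchestration, command line |

See `docs/methods.md` for modelling assumptions, parameter provenance and
known limitations.
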