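# Methods

This note records the modelling choices behind `nsclc_cea`, the reasoning
where a choice was genuinely open, and what the synthetic-data tests do and
do not establish.

## Population, comparator and time frame

The modelled cohort is PD-L1-high (tumour cells ≥ 50 %), EGFR/ALK wild-type
stage IV NSCLC starting first-line therapy: 1,200 mg atezolizumab every 3
weeks until progression versus platinum doublet chemotherapy (cisplatin or
carboplatin with equal probability; pemetrexed partner for non-squamous
histology, gemcitabine twice per cycle for squamous; 5 induction cycles,
then pemetrexed maintenance for non-squamous or best supportive care for
squamous). The histology mix is 69.7 % squamous / 30.3 % non-squamous. The
cycle length is 21 days (= 21/30.4375 months), the horizon 170 cycles
(≈ 9.8 years), and all costs, QALYs and (by default) life-years are
discounted at 5 %/year with the factor (1 + r)^(−t), t in years at the
interval midpoint.

Time is months throughout the survival mathematics. This is the only scale
consistent with the fitted parameters: the lognormal OS location μ = 3.0758
implies a median of exp(μ) ≈ 21.7 months, matching the ~20-month median OS
reported for this population, and the loglogistic PFS median
(1/λ)^(1/γ) ≈ 5.14 matches a first-line chemotherapy PFS. A weeks scale
would put these medians at implausible values. The cycle-length conversion
(21/30.4375 months) is config-exposed should a different convention be
needed.

## Survival model

OS and PFS per arm are parametric curves (defaults in
`config.TABLE1_CURVES`): lognormal for atezolizumab OS/PFS and chemotherapy
OS, loglogistic for chemotherapy PFS. The fitting stage supports four
families (exponential, Weibull, loglogistic, lognormal), maximising the
right-censored log-likelihood via lifelines' fitters, with AIC selection
(BIC, then the fixed family order, as tie-breaks). The Weibull is
parameterized as S(t) = exp(−(t/scale)^shape). Non-convergence raises an
explicit error rather than returning silent garbage.

Pseudo-IPD reconstruction from digitized curve coordinates uses a
simplified interval-allocation scheme: the number of events in each
interval follows from successive survival ratios at the digitized
coordinates (events placed at interval midpoints to avoid a systematic
right shift of the time scale), censoring is administrative at the stated
cutoff unless at-risk counts are supplied, in which case interval
censorings are allocated to honour them. The scheme's contract — the KM
estimate of the output reproduces the input coordinates — is what the
downstream fitting needs; the full published reconstruction algorithm
(event/censoring interleaving within intervals guided by at-risk tables)
is intentionally out of scope.

## Engines

Both engines share one half-cycle convention: person-time and costs for a
cycle use the arithmetic mean of the start- and end-of-cycle occupancies,
and the discount factor at the interval midpoint. Applying the correction
in the partitioned-survival engine as well (a point on which practice
varies) makes the two engines exactly comparable; it is equivalent to
trapezoid integration of the survival curves on the cycle grid.

**Partitioned survival.** Occupancy read directly off the curves, with the
standard clamp `pfs = min(S_PFS, S_OS)` for independently fitted curves
that cross (logged when it happens).

**Markov.** Time-dependent transitions derived from the same curves:

* PFS exit: 1 − S_PFS(t+Δ)/S_PFS(t);
* PFS→Death: a constant per-cycle background-mortality probability
  `p_nat`, derived from 1.2 %/year all-cause mortality (≈ life-table
  mortality at the cohort's median age, ~64 years), ≈ 6.9 × 10⁻⁴ per
  21-day cycle; progression takes the remainder of the exits;
* PD→Death: residual, chosen so cumulative deaths track 1 − S_OS. The
  residual death probability applies to the post-progression pool
  *including* the cycle's new progressors, and targets the cumulative
  (not per-cycle) death total, so discretisation errors self-correct.
  Clamping to [0, 1] is logged.

Two consequences are worth stating. First, with `p_nat = 0` the Markov
occupancies equal the partitioned-survival occupancies exactly — this is
enforced as a cross-engine oracle test. Second, because the residual
calibration keeps Markov deaths on the OS curve, the two engines produce
nearly identical life-years and ICERs here; implementations whose PD→Death
is modelled independently of OS can show a larger engine gap.

## Costs and utilities

All monetary inputs (2021–2022 USD) live in `data/table2.yaml`, one row per
published parameter with baseline, range and sampling family; any row can
be overridden from a user config. Key conventions:

* Drug rows are **per-cycle arm-level costs** with dose/body-surface-area
  arithmetic and vial wastage already folded in; no dose computation is
  re-implemented.
* The six-item follow-up bundle ($208.34/cycle) is charged in both alive
  states every cycle.
* PD-L1 immunohistochemistry ($115.03) is charged once, to both arms (the
  test defines the population), so it cancels in the ICER — asserted in a
  test.
* Adverse events (grade ≥ 3 anaemia, neutropenia, thrombocytopenia) enter
  as one-time expected costs and one-time QALY losses at cycle 0, with the
  disutility lasting one cycle (no duration is published; one treatment
  cycle is the natural unit).

**Subsequent therapy.** The exact composition and duration of post-
progression treatment is not published; the defaults are deliberate,
config-exposed calibration knobs chosen once against the published total
costs and then frozen. Progressors in the atezolizumab arm receive a 50/50
docetaxel/paclitaxel mix until death (palliative chemotherapy has no
natural stopping rule). Progressors in the chemotherapy arm receive a
50/50 mix of nivolumab (1.5 doses per 3-week cycle, reflecting its 2-week
schedule) and pembrolizumab for at most 24 cycles (≈ 17 months, in the
range of real-world second-line immunotherapy durations), then best
supportive care ($446.45/cycle). The per-patient cap is implemented by
aging each progression cohort through the trace (time-in-state-independent
PD mortality), not by tunnel states in the engine itself.

**Patient assistance program.** The scenario assumes half of patients meet
PAP requirements. A flat "qualifying half pays half forever" rule is
inconsistent with the joint pattern of the published with-PAP totals and
threshold prices, which instead pin down "qualifying patients stop paying
after roughly one year of therapy". PAP is therefore modelled as the
qualifying half receiving the drug free after 16 paid cycles (≈ 11
months), matching how such programs are actually structured
(pay-N-cycles-then-free). Both the share and the paid-cycle count are
config fields. PAP touches only drug payments: QALYs and LYs are
bit-identical with and without it (tested).

## Sensitivity analysis

* **One-way:** each parameter moves to its printed bounds holding the rest
  at baseline; checkpoint-inhibitor prices (atezolizumab, pembrolizumab,
  nivolumab) can only fall, so their range is (0.8 × baseline, baseline);
  the discount rate varies over 0–8 %. Entries are sorted by ICER swing.
* **Probabilistic:** gamma draws for costs, beta for
  utilities/probabilities (disutilities drawn as beta on the magnitude),
  method-of-moments with mean = baseline and sd = (high − low)/3.92 — the
  printed ranges are read as 95 % intervals, since the published mix of
  "±20 %" and "95 % CI" ranges states no sd rule. Draws incompatible with
  the beta support fall back to baseline with a warning. Parameters are
  drawn independently (no correlation information is published). The CEAC
  grid is $0–150,000/QALY in $1,000 steps. Survival-curve parameters are
  not varied (no covariance matrix is published), so the cohort traces are
  frozen per engine and only re-priced, which keeps a 1,000-iteration PSA
  under a second.
* **Threshold prices:** bisection on the atezolizumab per-cycle price to
  $0.01 / 10⁻⁶ relative ICER tolerance; valid because arm costs are linear
  and QALYs constant in the price, making the ICER monotone. "Already
  cost-effective at baseline price" is returned as a flag.

Regional thresholds: the published regional figures ($79,358.73 Beijing,
$17,704.96 Gansu) are numerically 3×-GDP thresholds and are labelled as
such in `config.WTP_TABLE`, with the 1× values derived by division.

## Synthetic data

`simulate.py` draws right-censored IPD by inverse-CDF sampling (closed-form
quantiles exist for all four families) with administrative censoring, and
builds digitized-curve fixtures (KM coordinates on an even grid plus
at-risk counts) so the fitting and reconstruction stages are testable
without any trial data. The generator emulates administrative censoring
only — no dropout, no interval censoring, no covariates, and no
patient-level PFS/OS correlation (the engines consume marginal curves
only). Passing the recovery tests therefore shows the estimators are
correct under the assumed data-generating process, not that the published
curves were themselves fitted without error.

## Numerical conventions and degenerate inputs

* Occupancy conservation enforced to 10⁻⁹ per cycle; transition rows to
  10⁻¹²; violations raise.
* S_PFS(t) = 0 in the Markov engine: the PFS row is treated as fully
  transitioned (exit probability 1).
* Empty PD pool: PD→Death set to 0 for that cycle.
* ICER sign disagreements are reported as dominance flags, never as
  negative ratios; ΔQALY = 0 is flagged undefined.
* Model selection ties: AIC, then BIC, then the fixed family order
  (exponential, Weibull, loglogistic, lognormal).
* Reconstruction rounds interval event counts to integers; with small
  cohorts this quantises the curve at ~1/n resolution.

## Problem sizes used in tests

Parameter-recovery tests use n = 10,000 simulated patients per curve with
~30 % administrative censoring (censoring at the 70th percentile);
fixture round-trips use n = 1,000; large-sample KM/KS checks use
n = 50,000; the PSA check uses the full 1,000 iterations. These sizes make
the statistical tolerances (5 %, 10 %, ±0.01) comfortably attainable while
keeping the whole suite fast.

## Known limitations

* The three-state structure ignores treatment beyond second line and any
  state beyond progression granularity.
* Subsequent-therapy composition, duration cap and the PAP payment
  schedule are calibrated assumptions (see above), not published facts;
  conclusions that hinge on absolute cost totals inherit that uncertainty,
  which is why those totals carry wide acceptance tolerances while
  survival-driven quantities are tight.
* Background mortality is constant, not age-updating; over a 10-year
  horizon in a cohort with ~2-year median survival the difference is
  negligible, but the constant is config-exposed.
* Utilities come from a single published EQ-5D study of advanced NSCLC in
  China; no treatment-specific utility decrement is applied in PFS.
* Only direct medical costs are modelled (healthcare-system perspective);
  no societal costs, no real-world dose-intensity adjustment, no
  vial-sharing optimisation.
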