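# Model parameters: baseline values, ranges and sampling distributions.
# Row names mirror the published parameter table for the Chinese-setting
# evaluation of first-line atezolizumab vs platinum chemotherapy in
# PD-L1-high advanced NSCLC (costs in 2021-2022 USD, $1 = RMB 6.955).
# Any item may be overridden by a user config.
version: 1

drug_cost_per_cycle:   # USD per 3-week cycle, dose/BSA arithmetic already folded in
  Atezolizumab: {baseline: 4716.03, low: 3772.83, high: 4716.03, dist: gamma}
  Pembrolizumab: {baseline: 5152.55, low: 4122.04, high: 5152.55, dist: gamma}
  Nivolumab(14days): {baseline: 2644.75, low: 2127.97, high: 2644.75, dist: gamma}
  Cisplatin: {baseline: 18.86, low: 15.09, high: 22.63, dist: gamma}
  Carboplatin(Weighted average): {baseline: 33.59, low: 26.87, high: 40.30, dist: gamma}
  Pemetrexed: {baseline: 786.72, low: 629.38, high: 944.07, dist: gamma}
  Gemcitabine(Weighted average): {baseline: 126.89, low: 101.51, high: 152.26, dist: gamma}
  Taxol: {baseline: 96.68, low: 77.34, high: 116.01, dist: gamma}
  Docetaxel: {baseline: 256.36, low: 205.09, high: 307.63, dist: gamma}
  Best supportive care: {baseline: 446.45, low: 357.16, high: 535.74, dist: gamma}

ae_cost:               # one-off management cost per event, USD
  Anemia: {baseline: 444.70, low: 355.76, high: 533.64, dist: gamma}
  Neutropenia: {baseline: 647.70, low: 518.16, high: 777.25, dist: gamma}
  Thrombocytopenia: {baseline: 1665.00, low: 1332.00, high: 1998.00, dist: gamma}

follow_up_cost_per_cycle:   # USD per cycle, charged in every alive state
  Register: {baseline: 2.01, low: 1.61, high: 2.42, dist: gamma}
  Injection: {baseline: 0.86, low: 0.69, high: 1.04, dist: gamma}
  CT: {baseline: 158.16, low: 126.53, high: 189.79, dist: gamma}
  Blood routine tests: {baseline: 2.16, low: 1.73, high: 2.59, dist: gamma}
  Biochemical test: {baseline: 38.82, low: 31.06, high: 46.59, dist: gamma}
  Blood coagulation: {baseline: 6.33, low: 5.06, high: 7.59, dist: gamma}

utility:               # EQ-5D health-state utilities
  PFS: {baseline: 0.856, low: 0.8132, high: 0.8988, dist: beta}
  PD: {baseline: 0.768, low: 0.7296, high: 0.8064, dist: beta}

ae_disutility:         # per-event utility decrement (applied for one cycle)
  Anemia: {baseline: -0.073, low: -0.088, high: -0.058, dist: beta}
  Neutropenia: {baseline: -0.650, low: -0.780, high: -0.520, dist: beta}
  Thrombocytopenia: {baseline: -0.460, low: -0.552, high: -0.368, dist: beta}

ae_incidence:          # grade >=3 incidence per arm
  Anemia(Atezolizumab): {baseline: 0.017, low: 0.0153, high: 0.0187, dist: beta}
  Neutropenia(Atezolizumab): {baseline: 0.007, low: 0.0063, high: 0.0077, dist: beta}
  Thrombocytopenia(Atezolizumab): {baseline: 0.003, low: 0.0027, high: 0.0033, dist: beta}
  Anemia(Chemotherapy): {baseline: 0.190, low: 0.1710, high: 0.2090, dist: beta}
  Neutropenia(Chemotherapy): {baseline: 0.175, low: 0.1575, high: 0.1925, dist: beta}
  Thrombocytopenia(Chemotherapy): {baseline: 0.076, low: 0.0684, high: 0.0836, dist: beta}

other:
  Immunohistochemistry(IHC) cost: {baseline: 115.03, low: 92.02, high: 138.03, dist: gamma}
  Discount rate: {baseline: 0.05, low: 0.00, high: 0.08, dist: fixed}
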