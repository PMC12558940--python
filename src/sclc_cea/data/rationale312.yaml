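# Base-case model inputs for first-line tislelizumab + chemotherapy vs
# placebo + chemotherapy in ES-SCLC (China healthcare-system perspective).
# Costs in 2023 CNY; survival scales in months; dist: gamma | beta | fixed.
settings:
  cycle_length_days: 21
  horizon_years: 10
  discount_annual: 0.05
  wtp: 268074

conventions:
  platinum: carboplatin          # carboplatin | cisplatin | mix
  carboplatin_share: 0.5         # only used when platinum: mix
  n_sub_cycles: 4                # cycles per subsequent-chemotherapy course
  ae_disutility_years: 0.057534246575342465   # one 21-day cycle
  cycle_timing: end              # end | start | half
  followup_states: [pfs, pd]
  bsc_states: [pd]
  psa_sample_survival: true
  psa_ipd_n_per_arm: 228
  psa_admin_censor_months: 40.0
  psa_random_censor_rate: 0.005

arms:
  - name: placebo
    survival:
      os:  {family: loglogistic, scale: os_scale_placebo,  shape: os_shape_placebo}
      pfs: {family: loglogistic, scale: pfs_scale_placebo, shape: pfs_shape_placebo}
    induction_cycles: 4
    maintenance_drug: null
    subsequent_proportion: subsq_placebo
    adverse_events:
      - {incidence: ae_inc_placebo_neutropenia,     cost: ae_cost_neutropenia,     disutility: du_neutropenia}
      - {incidence: ae_inc_placebo_wbc_decreased,   cost: ae_cost_wbc_decreased,   disutility: du_wbc_decreased}
      - {incidence: ae_inc_placebo_thrombocytopenia, cost: ae_cost_thrombocytopenia, disutility: du_thrombocytopenia}
      - {incidence: ae_inc_placebo_anemia,          cost: ae_cost_anemia,          disutility: du_anemia}

  - name: tislelizumab
    survival:
      os:  {family: loglogistic, scale: os_scale_tislelizumab,  shape: os_shape_tislelizumab}
      pfs: {family: loglogistic, scale: pfs_scale_tislelizumab, shape: pfs_shape_tislelizumab}
    induction_cycles: 4
    maintenance_drug: tislelizumab_cost
    subsequent_proportion: subsq_tislelizumab
    adverse_events:
      - {incidence: ae_inc_tislelizumab_neutropenia,     cost: ae_cost_neutropenia,     disutility: du_neutropenia}
      - {incidence: ae_inc_tislelizumab_wbc_decreased,   cost: ae_cost_wbc_decreased,   disutility: du_wbc_decreased}
      - {incidence: ae_inc_tislelizumab_thrombocytopenia, cost: ae_cost_thrombocytopenia, disutility: du_thrombocytopenia}
      - {incidence: ae_inc_tislelizumab_anemia,          cost: ae_cost_anemia,          disutility: du_anemia}

parameters:
  # fitted log-logistic survival parameters (no range / fixed in PSA draws
  # of scalar parameters; parameter uncertainty handled via psa_sample_survival)
  - {name: os_scale_tislelizumab,  base: 16.50756, dist: fixed}
  - {name: os_shape_tislelizumab,  base: 1.70402,  dist: fixed}
  - {name: pfs_scale_tislelizumab, base: 5.6371,   dist: fixed}
  - {name: pfs_shape_tislelizumab, base: 1.81906,  dist: fixed}
  - {name: os_scale_placebo,       base: 14.9796,  dist: fixed}
  - {name: os_shape_placebo,       base: 1.9698,   dist: fixed}
  - {name: pfs_scale_placebo,      base: 4.94181,  dist: fixed}
  - {name: pfs_shape_placebo,      base: 2.51144,  dist: fixed}

  # per-cycle costs (CNY)
  - {name: tislelizumab_cost, base: 2507.06, low: 2507.06, high: 2755.00, dist: gamma}
  - {name: cisplatin_cost,    base: 102.81,  low: 82.22,   high: 641.13,  dist: gamma}
  - {name: carboplatin_cost,  base: 521.03,  low: 132.30,  high: 1420.00, dist: gamma}
  - {name: etoposide_cost,    base: 1630.56, low: 40.20,   high: 3250.16, dist: gamma}
  - {name: bsc_cost,          base: 2467.00, low: 1973.65, high: 2960.47, dist: gamma}
  - {name: followup_cost,     base: 600.58,  low: 480.46,  high: 720.70,  dist: gamma}

  # adverse-event unit costs (CNY, grade >= 3, one-off at model entry)
  - {name: ae_cost_neutropenia,      base: 607.45,  low: 485.92,  high: 728.91,  dist: gamma}
  - {name: ae_cost_wbc_decreased,    base: 3361.50, low: 2689.19, high: 4033.79, dist: gamma}
  - {name: ae_cost_thrombocytopenia, base: 7603.00, low: 6082.42, high: 9123.64, dist: gamma}
  - {name: ae_cost_anemia,           base: 3665.90, low: 2932.73, high: 4399.07, dist: gamma}

  # adverse-event incidences
  - {name: ae_inc_tislelizumab_neutropenia,      base: 0.5595, low: 0.504, high: 0.615, dist: beta}
  - {name: ae_inc_tislelizumab_wbc_decreased,    base: 0.2379, low: 0.214, high: 0.262, dist: beta}
  - {name: ae_inc_tislelizumab_thrombocytopenia, base: 0.1938, low: 0.174, high: 0.213, dist: beta}
  - {name: ae_inc_tislelizumab_anemia,           base: 0.1630, low: 0.147, high: 0.179, dist: beta}
  - {name: ae_inc_placebo_neutropenia,           base: 0.5459, low: 0.491, high: 0.600, dist: beta}
  - {name: ae_inc_placebo_wbc_decreased,         base: 0.2751, low: 0.248, high: 0.303, dist: beta}
  - {name: ae_inc_placebo_thrombocytopenia,      base: 0.2533, low: 0.228, high: 0.279, dist: beta}
  - {name: ae_inc_placebo_anemia,                base: 0.1659, low: 0.149, high: 0.182, dist: beta}

  # proportion receiving subsequent chemotherapy after progression
  - {name: subsq_tislelizumab, base: 0.55, low: 0.495, high: 0.605, dist: beta}
  - {name: subsq_placebo,      base: 0.67, low: 0.603, high: 0.737, dist: beta}

  # health-state utilities and adverse-event disutility decrements
  - {name: u_pfs,               base: 0.804, low: 0.724, high: 0.884, dist: beta}
  - {name: u_pd,                base: 0.321, low: 0.289, high: 0.353, dist: beta}
  - {name: du_neutropenia,      base: 0.200, low: 0.180, high: 0.220, dist: beta}
  - {name: du_wbc_decreased,    base: 0.200, low: 0.180, high: 0.220, dist: beta}
  - {name: du_thrombocytopenia, base: 0.190, low: 0.171, high: 0.209, dist: beta}
  - {name: du_anemia,           base: 0.078, low: 0.070, high: 0.086, dist: beta}

  # annual discount rate (varied in one-way analysis, fixed in PSA)
  - {name: discount_rate, base: 0.05, low: 0.0, high: 0.08, dist: fixed}
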