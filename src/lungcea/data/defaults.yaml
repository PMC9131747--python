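# Default model inputs for the lung-cancer screening cost-effectiveness model.
#
# Values tagged [published] reproduce the published input table verbatim
# (rates per 100,000/year, probabilities per year, costs in 2018 CNY).
# Values tagged [fixture] are inputs the analysis needs but the source
# never printed; they are clearly-labelled defaults and fully overridable.
schema_version: 1

# [published] annual lung-cancer incidence per 100,000 general population
incidence_per_100k:
  50-54: {female: 89.6626, male: 81.0559}
  55-59: {female: 112.4574, male: 162.0833}
  60-64: {female: 154.6871, male: 256.0943}
  65-69: {female: 190.2521, male: 373.6808}
  70-74: {female: 242.6310, male: 498.0681}

# [published] incidence relative risk by minimum cumulative smoking exposure
rr_20py: 2.84
rr_30py: 3.87

# [published] stage distribution of screen-detected cancers, by tool
detect_stage_ldct: {CIS: 0.0370, StageI: 0.6852, StageII: 0.0370, StageIII: 0.1852, StageIV: 0.0556}
detect_stage_ldct_msc: {CIS: 0.0, StageI: 0.5441, StageII: 0.0570, StageIII: 0.1195, StageIV: 0.2794}

# [published] screening test operating characteristics (joint values for the
# conjunctive low-dose CT + biomarker pathway)
sens_ldct: 0.79
spec_ldct: 0.81
sens_msc_conj: 0.69
spec_msc_conj: 0.96

# [published] annual all-cause mortality probability for smokers, by age
allcause_mort:
  50-54: 0.0045
  55-59: 0.0065
  60-64: 0.0108
  65-69: 0.0188
  70-74: 0.0336
  75-79: 0.0540

# [published] annual lung-cancer deaths per 100,000 general population
lc_mort_per_100k:
  50-54: 28.81
  55-59: 52.86
  60-64: 101.93
  65-69: 153.34
  70-74: 248.57

# [published] annual stage-to-stage progression probabilities
stage_prog:
  CIS: {StageI: 0.0980}
  StageI: {StageII: 0.3682, StageIII: 0.0328, StageIV: 0.0745}
  StageII: {StageIII: 0.2260, StageIV: 0.1510}
  StageIII: {StageIV: 0.1455}
  StageIV: {}

# [published] annual within-stage death probabilities
stage_death: {CIS: 0.0, StageI: 0.1739, StageII: 0.2842, StageIII: 0.4626, StageIV: 0.5880}

# [published] health-state utilities
utility: {CIS: 0.87, StageI: 0.84, StageII: 0.84, StageIII: 0.87, StageIV: 0.75}
# [fixture] healthy-state and death utilities (standard convention; indeterminate
# screening results carry no disutility)
utility_normal: 1.0
utility_death: 0.0

# [published] unit costs, 2018 CNY
cost_ldct: 245.86
cost_msc: 400.00
cost_prediag: 628.36
cost_biopsy: 1232.44
cost_treat: {CIS: 47341.85, StageI: 53344.51, StageII: 83365.95, StageIII: 90643.18, StageIV: 116471.34}

# [published] annual maintenance cost as a fraction of stage treatment cost
maintenance_fraction: 0.10

# [published] discounting and horizon settings
discount_rate: 0.05
discount_effects: true
cycle_length: 1.0
max_age: 79
stop_screen_age: 74

# [published] willingness-to-pay anchor: per-capita GDP, CNY/QALY
wtp_gdp: 70892.0
price_year: 2018
# [fixture] consumer-price-index rate, used only to re-base user-supplied
# costs onto the 2018 price level; shipped costs are already 2018-based
cpi_rate: 0.02

# [fixture] fraction of each strategy's simulated cohort meeting the
# strategy's smoking eligibility threshold.  The default of 1.0 runs every
# strategy on its fully-eligible cohort (the threshold's relative risk
# applied to everyone, everyone screened), which is the only reading
# consistent with the published base-case table, where the 30 pack-year
# annual strategy is always the most costly with the fewest life-years.
# Set fractions below 1 to mix in an unscreened background-risk stratum.
eligible_fraction_20py: 1.0
eligible_fraction_30py: 1.0

# [fixture] stage distribution at clinical presentation for cancers not
# detected by screening: the screen-detected distribution shifted one stage
# later, stage IV keeping its own mass plus the inflow
clinical_stage_dist: {CIS: 0.0, StageI: 0.0370, StageII: 0.6852, StageIII: 0.0370, StageIV: 0.2408}

# [fixture] sex mix of simulated cohorts
male_fraction: 0.5

# --- structural switches (defaults documented in the module ledger) ---
# rate -> probability conversion: "linear" (rate/100000) or "exponential"
rate_conversion: linear
# annual probability of relapse from a maintenance state to its partner stage
maintenance_recurrence: 0.0
# charge biopsy (in addition to prediagnosis workup) to false positives
fp_workup_biopsy: false
# charge the biomarker assay to every screenee rather than only CT-positives
msc_cost_all_screened: false
# subtract banded lung-cancer mortality from all-cause background mortality
subtract_lc_mortality: false
# apply a half-cycle correction to state payoffs
half_cycle_correction: false
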