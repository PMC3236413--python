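# Default run configuration: the published single-institution 2009
# endometrial-cancer hysterectomy cohort and cost parameters.
#
# Provenance classes used below:
#   cohort-observed        — published per-method cohort statistic
#   derived                — arithmetic consequence of published statistics
#                            (cohort SDs recovered from the published 95% CIs;
#                             nonoperative charge = encounter - operative charge)
#   published-literature   — published external estimate (return-to-work days,
#                            median weekly earnings)
#   placeholder            — value the analysis needs but no source prints
#                            (robotic conversion probability; added OR times)

seed: 0
output_dir: results
log_level: INFO

cohort:
  seed: 0
  # hemorrhage is drawn as a Bernoulli event at the observed rate; "ebl" mode
  # instead derives it from the sampled blood loss (>= 1000 mL).
  hemorrhage_mode: rate
  methods:
    TAH:                              # open abdominal hysterectomy, n = 73
      n: 73
      continuous:                     # mean / cohort sd / truncation bounds
        age:            {mean: 61.9,   sd: 9.2,    lower: 43,   upper: 87}
        bmi:            {mean: 35.7,   sd: 10.1,   lower: 16.7, upper: 69.4}
        uterine_weight: {mean: 243.5,  sd: 330.12, lower: 25,   upper: 2170}
        or_time:        {mean: 192.28, sd: 48.824, lower: 30,   upper: 600}  # sd derived
        ebl:            {mean: 255.94, sd: 175.242, lower: 0}                # sd derived
        los:            {mean: 3.84,   sd: 1.635,  lower: 0}                 # sd derived
      rates:                          # cohort-observed proportions
        prior_laparotomy: 0.464
        prior_laparoscopy: 0.197
        adhesions: 0.329
        lnd: 0.740
        conversion: 0.0               # structural: laparotomy cannot convert
        organ_injury: 0.0137
        postop_complication: 0.110
        hemorrhage: 0.0145
    TLH:                              # laparoscopic hysterectomy, n = 118
      n: 118
      continuous:
        age:            {mean: 59.9,   sd: 10.4,   lower: 34,   upper: 91}
        bmi:            {mean: 29.8,   sd: 7.5,    lower: 19.7, upper: 59.2}
        uterine_weight: {mean: 134.4,  sd: 101.4,  lower: 34,   upper: 704}
        or_time:        {mean: 186.80, sd: 48.809, lower: 30,   upper: 600}
        ebl:            {mean: 105.23, sd: 176.717, lower: 0}
        los:            {mean: 1.44,   sd: 1.552,  lower: 0}
      rates:
        prior_laparotomy: 0.315
        prior_laparoscopy: 0.105
        adhesions: 0.144
        lnd: 0.385
        conversion: 0.051
        organ_injury: 0.0085
        postop_complication: 0.068
        hemorrhage: 0.0091
    TRH:                              # robot-assisted hysterectomy, n = 43
      n: 43
      continuous:
        age:            {mean: 58.2,   sd: 7.57,   lower: 43,   upper: 74}
        bmi:            {mean: 40.5,   sd: 11.0,   lower: 18.6, upper: 61.4}
        uterine_weight: {mean: 176.3,  sd: 153.34, lower: 45.5, upper: 905}
        or_time:        {mean: 252.6,  sd: 48.814, lower: 30,   upper: 600}
        ebl:            {mean: 41.22,  sd: 183.679, lower: 0}
        los:            {mean: 1.30,   sd: 1.572,  lower: 0}
      rates:
        prior_laparotomy: 0.463
        prior_laparoscopy: 0.238
        adhesions: 0.395
        lnd: 0.379
        conversion: 0.0               # no robotic conversions observed
        organ_injury: 0.0
        postop_complication: 0.070
        hemorrhage: 0.0

cost:
  # The per-increment rate and robot flat fee are not published; they are
  # identified from the per-method mean OR times and mean operative charges
  # under the observed 190:1 time-to-equipment charge policy.
  calibration:
    increment_length: 15.0            # OR billing increment (minutes)
    time_to_equipment_ratio: 190.0    # cohort-observed charge ratio
    or_time_means:                    # cohort-observed (minutes)
      TAH: 192.28
      TLH: 186.80
      TRH: 252.6
    operative_charge_means:           # cohort-observed (USD-2009)
      TAH: 33756
      TLH: 33706
      TRH: 44698
  # derived: mean encounter charge minus mean operative charge
  nonoperative_charges:
    TAH: 20354.0
    TLH: 5661.0
    TRH: 6854.0
  wages:
    median_weekly_earnings: 657.0     # published median weekly wage (USD-2009)
    days_per_week_convention: calendar
    employment_adjustment: 1.0        # employment-rate scaling, 1.0 = none
    point_estimate_rule: midpoint
    return_to_work_days:              # published-literature absence intervals
      TAH: [38, 41]
      TLH: [19, 24]
      TRH: [19, 24]                   # assumed equal to TLH
  cost_to_charge_ratio: null          # optional 0.5-0.7 charge-to-cost multiplier

model:
  # "cohort": estimate branch probabilities and OR times from the generated
  # cohort (the pipeline's default); "config": use the point estimates below.
  source: cohort
  parameters:                         # cohort-observed point estimates
    TAH: {p_lnd: 0.740, p_conversion: 0.0,   p_hemorrhage: 0.0145,
          or_time_mean: 192.28, or_time_sd: 48.824, n: 73}
    TLH: {p_lnd: 0.385, p_conversion: 0.051, p_hemorrhage: 0.0091,
          or_time_mean: 186.80, or_time_sd: 48.809, n: 118}
    TRH: {p_lnd: 0.379, p_conversion: 0.03,  p_hemorrhage: 0.0,   # conversion: placeholder
          or_time_mean: 252.6,  or_time_sd: 48.814, n: 43}
  overrides:
    TRH:
      p_conversion: 0.03              # placeholder for the unobserved robotic rate
  literature_required:
    - [TRH, p_conversion]
  added_times:                        # placeholder whole-increment event times (min)
    lnd: 30.0
    conversion: 60.0
    hemorrhage: 30.0

sensitivity:
  step: 1.0                           # sweep/threshold grid (minutes)
  threshold_range: [15, 900]
  sweep_percentiles: [25, 75]         # cohort OR-time interquartile range
  threshold_pairs:
    - [TRH, TAH]

psa:
  n_iterations: 10000
  seed: 0
  use_common_random_numbers: true
  overrides:
    TRH:
      p_conversion:                   # placeholder distribution (unobserved)
        {mean: 0.03, sd: 0.015, lower: 0.0, upper: 1.0, source: placeholder}
      p_hemorrhage:                   # observed zero: held degenerate at 0
        {mean: 0.0, sd: 0.0, lower: 0.0, upper: 1.0, source: cohort-degenerate}
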