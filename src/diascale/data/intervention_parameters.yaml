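# Intervention effectiveness, affected fractions, age ranges and scenario
# coverage targets for the ten diarrhea prevention/treatment interventions.
#
# effectiveness: proportional reduction in diarrheal deaths among children the
#   intervention reaches and can affect (E).
# affected_fraction: share of diarrheal deaths the intervention can act on (A).
#   ORS acts on non-dysentery deaths (95%), antibiotics on dysentery deaths
#   (5%), rotavirus vaccine on rotavirus deaths (39%); these are shares of
#   deaths, not of episodes.
# age ranges in months: ORS 0-59, vitamin A 6-59, all others 1-59.
# targets in percent coverage by 2015.

interventions:
  ors:
    effectiveness: 0.93
    affected_fraction: 0.95
    age_min_months: 0
    age_max_months: 59
    is_wash: false
    is_treatment: true
    targets: {ambitious: 75, universal: 90}
  zinc:
    effectiveness: 0.23
    affected_fraction: 1.0
    age_min_months: 1
    age_max_months: 59
    is_wash: false
    is_treatment: true
    targets: {ambitious: 50, universal: 90}
  antibiotics_dysentery:
    effectiveness: 0.99
    affected_fraction: 0.05
    age_min_months: 1
    age_max_months: 59
    is_wash: false
    is_treatment: true
    targets: {ambitious: 75, universal: 90}
  rotavirus:
    effectiveness: 0.74
    affected_fraction: 0.39
    age_min_months: 1
    age_max_months: 59
    is_wash: false
    is_treatment: false
    targets: {ambitious: 50, universal: 90}
  vitamin_a:
    effectiveness: 0.32
    affected_fraction: 1.0
    age_min_months: 6
    age_max_months: 59
    is_wash: false
    is_treatment: false
    targets: {ambitious: 90, universal: 90}
  handwashing:
    effectiveness: 0.48
    affected_fraction: 1.0
    age_min_months: 1
    age_max_months: 59
    is_wash: true
    is_treatment: false
    targets: {ambitious: 35, universal: 55}
  improved_sanitation:
    effectiveness: 0.69
    affected_fraction: 1.0
    age_min_months: 1
    age_max_months: 59
    is_wash: true
    is_treatment: false
    targets: {ambitious: 67, universal: 75}
  improved_water:
    effectiveness: 0.17
    affected_fraction: 1.0
    age_min_months: 1
    age_max_months: 59
    is_wash: true
    is_treatment: false
    # Ambitious safe-water targets are region-specific; countries outside
    # Africa/Asia follow the Asia value.
    targets: {universal: 99}
    regional_targets:
      ambitious: {Africa: 75, Asia: 86, Other: 86}
  treated_water:
    effectiveness: 0.21
    affected_fraction: 1.0
    age_min_months: 1
    age_max_months: 59
    is_wash: true
    is_treatment: false
    targets: {ambitious: 30, universal: 70}

# Relative risk of diarrhea mortality by breastfeeding practice category.
# Reference is exclusive breastfeeding at 0-5 mo and any breastfeeding at
# 6-23 mo; no RRs apply beyond 23 mo.
breastfeeding_rr:
  0-5mo: {exclusive: 1.0, predominant: 2.28, partial: 4.62, none: 10.53}
  6-11mo: {exclusive: 1.0, predominant: 1.0, partial: 1.0, none: 2.28}
  12-23mo: {exclusive: 1.0, predominant: 1.0, partial: 1.0, none: 2.28}

# Breastfeeding practice targets by 2015 (percent prevalence per age band).
# The "none" category is the residual and is never listed as a target.
breastfeeding_targets:
  ambitious:
    0-5mo: {exclusive: 70, predominant: 10, partial: 10}
    6-11mo: {exclusive: 0, predominant: 0, partial: 90}
    12-23mo: {exclusive: 0, predominant: 0, partial: 75}
  universal:
    0-5mo: {exclusive: 90, predominant: 5, partial: 0}
    6-11mo: {exclusive: 0, predominant: 0, partial: 95}
    12-23mo: {exclusive: 0, predominant: 0, partial: 85}
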