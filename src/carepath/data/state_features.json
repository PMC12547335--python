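{
 "version": "1",
 "features": [
  "age_std",
  "female",
  "male",
  "gender_other",
  "race_asian",
  "race_black",
  "race_hispanic",
  "race_white",
  "race_other_multiple",
  "hypertension",
  "depression",
  "diabetes",
  "substance_use_disorder",
  "copd",
  "chf",
  "housing_instability",
  "food_insecurity",
  "transportation_barriers",
  "utility_needs",
  "child_in_household",
  "sud_screen_positive",
  "dme_flag",
  "ed_visits_1m",
  "ed_visits_3m",
  "ed_visits_6m",
  "hosp_1m",
  "hosp_3m",
  "hosp_6m",
  "baseline_ed_flag",
  "baseline_hosp_flag",
  "cum_events",
  "months_since_event",
  "month_index",
  "risk_score",
  "hx_substance_use_support",
  "hx_mental_health_support",
  "hx_chronic_condition_support",
  "hx_food_assistance",
  "hx_housing_assistance",
  "hx_transportation_assistance",
  "hx_utility_assistance",
  "hx_childcare_assistance",
  "hx_watchful_waiting",
  "steps_since_last_intervention",
  "need_medical",
  "need_behavioral",
  "need_social"
 ],
 "actions": [
  "substance_use_support",
  "mental_health_support",
  "chronic_condition_support",
  "food_assistance",
  "housing_assistance",
  "transportation_assistance",
  "utility_assistance",
  "childcare_assistance",
  "watchful_waiting"
 ]
}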