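# Clinical constraint rules behind the action mask.
#
# Each entry permits an action only when at least one listed predicate over
# named state features holds; otherwise the action is masked out at that
# decision point.  Watchful waiting is never maskable and so never appears
# here.  Edit this file to adapt the mask to local service availability.
- action: childcare_assistance
  requires_any:
    - {feature: child_in_household, op: ge, value: 1}
- action: substance_use_support
  requires_any:
    - {feature: substance_use_disorder, op: ge, value: 1}
    - {feature: sud_screen_positive, op: ge, value: 1}
- action: housing_assistance
  requires_any:
    - {feature: housing_instability, op: ge, value: 1}
- action: food_assistance
  requires_any:
    - {feature: food_insecurity, op: ge, value: 1}
- action: transportation_assistance
  requires_any:
    - {feature: transportation_barriers, op: ge, value: 1}
- action: utility_assistance
  requires_any:
    - {feature: utility_needs, op: ge, value: 1}
    - {feature: dme_flag, op: ge, value: 1}
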