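meta:
  name: reference-calibrated
  currency: CAD
  price_year: 2014
  note: Costs are taken as already converted to 2014 CAD; foreign-currency conversion
    and the 2.05% inflation adjustment are upstream of this model. Transition probabilities,
    state costs and program costs are calibrated against the published 30-year summary
    results (see glaucoma_cea.calibrate).
  limitations:
  - no background mortality / death state
  - single treatment pathway; treatment variation not modelled
horizon:
  value: 30
  source: reported
discount_rate:
  value: 0.03
  source: reported
wtp:
  value: 40000.0
  source: reported
prevalence:
  value: 0.48011813917489987
  source: calibrated
confirmatory_exam_cost:
  value: 146.91345705823986
  source: calibrated
reward_timing: start
utilities:
  at_risk:
    value: 1.0
    source: assumption
  mild:
    value: 0.87
    source: reported
  moderate:
    value: 0.79
    source: reported
  severe:
    value: 0.64
    source: reported
  blind:
    value: 0.5
    source: reported
state_costs:
  at_risk:
    value: 14.533425839950707
    source: calibrated
  mild:
    value: 40.9600658542803
    source: calibrated
  moderate:
    value: 50.40313889999708
    source: calibrated
  severe:
    value: 77.16828680597274
    source: calibrated
  blind:
    value: 73.32377727588252
    source: calibrated
reference_strategy: teleglaucoma
comparator_strategy: in_person
strategies:
  teleglaucoma:
    entry_state: at_risk
    annual_service_cost:
      value: 8.74036221266563
      source: calibrated
    treated_transitions:
      kind: progression
      probs:
        at_risk_to_mild:
          value: 0.28728088495392595
          source: calibrated
        mild_to_moderate:
          value: 0.06959935455138941
          source: calibrated
        moderate_to_severe:
          value: 0.16726125203278677
          source: calibrated
        severe_to_blind:
          value: 0.2407691481096121
          source: calibrated
    untreated_transitions:
      kind: progression
      probs:
        at_risk_to_mild:
          value: 0.28728088495392595
          source: assumption
        mild_to_moderate:
          value: 0.45
          source: assumption
        moderate_to_severe:
          value: 0.5
          source: assumption
        severe_to_blind:
          value: 0.55
          source: assumption
    test:
      sensitivity:
        value: 0.865
        source: reported
      specificity:
        value: 0.786
        source: reported
      cost_per_screen:
        value: 35.04366450102009
        source: calibrated
      fixed_program_cost:
        value: 10513.099350306027
        source: derived
      capacity:
        value: 300
        source: reported
  in_person:
    entry_state: at_risk
    annual_service_cost:
      value: 153.25902653147202
      source: calibrated
    treated_transitions:
      kind: progression
      probs:
        at_risk_to_mild:
          value: 0.0955342383818864
          source: calibrated
        mild_to_moderate:
          value: 0.17473510009607407
          source: calibrated
        moderate_to_severe:
          value: 0.30569686798122303
          source: calibrated
        severe_to_blind:
          value: 0.9499934911367143
          source: calibrated
    untreated_transitions:
      kind: progression
      probs:
        at_risk_to_mild:
          value: 0.28728088495392595
          source: assumption
        mild_to_moderate:
          value: 0.45
          source: assumption
        moderate_to_severe:
          value: 0.5
          source: assumption
        severe_to_blind:
          value: 0.55
          source: assumption
    test:
      sensitivity:
        value: 0.7579999425435022
        source: calibrated
      specificity:
        value: 0.9
        source: assumption
      cost_per_screen:
        value: 659.138552226136
        source: calibrated
      fixed_program_cost:
        value: 908952.0635198415
        source: derived
      capacity:
        value: 1379
        source: reported
dsa:
  relative_range: 0.2
  parameters:
  - prevalence
  - cost.blind
  - teleglaucoma.treated.at_risk_to_mild
  - teleglaucoma.treated.severe_to_blind
  - natural_history.at_risk_to_mild
  - natural_history.severe_to_blind
psa:
  n_samples: 1000
  seed: 20150918
  distributions:
  - name: prevalence
    kind: beta
    se: 0.1
  - name: teleglaucoma.sensitivity
    kind: beta
    se: 0.03
  - name: teleglaucoma.specificity
    kind: beta
    se: 0.03
  - name: in_person.sensitivity
    kind: beta
    se: 0.05
  - name: in_person.specificity
    kind: beta
    se: 0.03
  - name: utility.mild
    kind: beta
    se: 0.03
  - name: utility.moderate
    kind: beta
    se: 0.03
  - name: utility.severe
    kind: beta
    se: 0.03
  - name: utility.blind
    kind: beta
    se: 0.03
  - name: cost.at_risk
    kind: gamma
    se: 2.906685
  - name: cost.mild
    kind: gamma
    se: 8.192013
  - name: cost.moderate
    kind: gamma
    se: 10.080628
  - name: cost.severe
    kind: gamma
    se: 15.433657
  - name: cost.blind
    kind: gamma
    se: 14.664755
  - name: teleglaucoma.annual_service_cost
    kind: gamma
    se: 1.748072
  - name: in_person.annual_service_cost
    kind: gamma
    se: 45.977708
  - name: teleglaucoma.cost_per_screen
    kind: gamma
    se: 7.008733
  - name: in_person.cost_per_screen
    kind: gamma
    se: 263.655421
  - name: confirmatory_exam_cost
    kind: gamma
    se: 29.382691
  - name: teleglaucoma.treated.at_risk_to_mild
    kind: beta
    se: 0.014364
  - name: teleglaucoma.treated.mild_to_moderate
    kind: beta
    se: 0.00348
  - name: teleglaucoma.treated.moderate_to_severe
    kind: beta
    se: 0.008363
  - name: teleglaucoma.treated.severe_to_blind
    kind: beta
    se: 0.012038
  - name: natural_history.at_risk_to_mild
    kind: beta
    se: 0.014364
  - name: natural_history.mild_to_moderate
    kind: beta
    se: 0.0225
  - name: natural_history.moderate_to_severe
    kind: beta
    se: 0.025
  - name: natural_history.severe_to_blind
    kind: beta
    se: 0.0275
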