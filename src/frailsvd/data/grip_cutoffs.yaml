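# Hand-grip weakness cutoffs (kg) by sex and BMI stratum, after the
# cardiovascular-health-study frailty phenotype.  Grip at or below the
# cutoff for the subject's stratum scores the weakness component.
# Each entry: [bmi_upper_bound_inclusive, cutoff_kg]; .inf closes the table.
male:
  - [24.0, 29.0]
  - [26.0, 30.0]
  - [28.0, 30.0]
  - [.inf, 32.0]
female:
  - [23.0, 17.0]
  - [26.0, 17.3]
  - [29.0, 18.0]
  - [.inf, 21.0]
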