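# Illustrative alert rules for the daily-batch engine.
- rule_id: respiratory_admission
  concepts: [resp_admission]
- rule_id: ocs_2_in_30d
  concepts: [ocs]
  count_min: 2
  window_days: 30
- rule_id: low_fev1_pct
  concepts: [fev1_pct_pred]
  value_op: "<"
  value_threshold: 30
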