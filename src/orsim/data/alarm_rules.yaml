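# Adult-patient alarm thresholds (editable).  Alarm IDs are symbolic
# IEC 60601-1-8 category/priority names; "cardmed" is the medium-priority
# cardiac alarm.  Conditions are strict: low fires when value < threshold,
# high when value > threshold.
latching: false
rules:
  - {parameter: HR,       direction: low,  threshold: 60,  priority: medium, alarm_id: cardmed}
  - {parameter: HR,       direction: high, threshold: 100, priority: medium, alarm_id: cardmed}
  - {parameter: SpO2,     direction: low,  threshold: 90,  priority: high,   alarm_id: oxyhigh}
  - {parameter: NIBP_sys, direction: low,  threshold: 90,  priority: medium, alarm_id: bpmed}
  - {parameter: NIBP_sys, direction: high, threshold: 160, priority: medium, alarm_id: bpmed}
  - {parameter: EtCO2,    direction: low,  threshold: 25,  priority: medium, alarm_id: co2med}
  - {parameter: EtCO2,    direction: high, threshold: 60,  priority: medium, alarm_id: co2med}
  - {parameter: PIP,      direction: high, threshold: 40,  priority: medium, alarm_id: airwaymed}
  - {parameter: TV,       direction: low,  threshold: 200, priority: high,   alarm_id: airwayhigh}
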