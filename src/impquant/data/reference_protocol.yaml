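components:
- id: PE
  label: participatory ergonomics
- id: PT
  label: physical training
- id: CBT
  label: cognitive behavioural training
sessions:
- session_id: pe_kickoff
  component_id: PE
  duration: 1.0
  receipt_mode: individual
  criteria_ids:
  - pe_kickoff_c1
  - pe_kickoff_c2
  - pe_kickoff_c3
  - pe_kickoff_c4
  has_intensity: false
- session_id: pe_ws1
  component_id: PE
  duration: 3.0
  receipt_mode: team
  criteria_ids:
  - pe_ws1_c1
  - pe_ws1_c2
  - pe_ws1_c3
  - pe_ws1_c4
  has_intensity: false
- session_id: pe_ws2
  component_id: PE
  duration: 3.0
  receipt_mode: team
  criteria_ids:
  - pe_ws2_c1
  - pe_ws2_c2
  - pe_ws2_c3
  - pe_ws2_c4
  has_intensity: false
- session_id: pe_ev1
  component_id: PE
  duration: 1.0
  receipt_mode: team
  criteria_ids:
  - pe_ev1_c1
  - pe_ev1_c2
  - pe_ev1_c3
  has_intensity: false
- session_id: pe_ev2
  component_id: PE
  duration: 1.0
  receipt_mode: team
  criteria_ids:
  - pe_ev2_c1
  - pe_ev2_c2
  - pe_ev2_c3
  has_intensity: false
- session_id: pt_01
  component_id: PT
  duration: 1.0
  receipt_mode: individual
  criteria_ids:
  - pt_01_c1
  - pt_01_c2
  has_intensity: true
- session_id: pt_02
  component_id: PT
  duration: 1.0
  receipt_mode: individual
  criteria_ids:
  - pt_02_c1
  - pt_02_c2
  has_intensity: true
- session_id: pt_03
  component_id: PT
  duration: 1.0
  receipt_mode: individual
  criteria_ids:
  - pt_03_c1
  - pt_03_c2
  has_intensity: true
- session_id: pt_04
  component_id: PT
  duration: 1.0
  receipt_mode: individual
  criteria_ids:
  - pt_04_c1
  - pt_04_c2
  has_intensity: true
- session_id: pt_05
  component_id: PT
  duration: 1.0
  receipt_mode: individual
  criteria_ids:
  - pt_05_c1
  - pt_05_c2
  has_intensity: true
- session_id: pt_06
  component_id: PT
  duration: 1.0
  receipt_mode: individual
  criteria_ids:
  - pt_06_c1
  - pt_06_c2
  has_intensity: true
- session_id: pt_07
  component_id: PT
  duration: 1.0
  receipt_mode: individual
  criteria_ids:
  - pt_07_c1
  - pt_07_c2
  has_intensity: true
- session_id: pt_08
  component_id: PT
  duration: 1.0
  receipt_mode: individual
  criteria_ids:
  - pt_08_c1
  - pt_08_c2
  has_intensity: true
- session_id: pt_09
  component_id: PT
  duration: 1.0
  receipt_mode: individual
  criteria_ids:
  - pt_09_c1
  - pt_09_c2
  has_intensity: true
- session_id: pt_10
  component_id: PT
  duration: 1.0
  receipt_mode: individual
  criteria_ids:
  - pt_10_c1
  - pt_10_c2
  has_intensity: true
- session_id: pt_11
  component_id: PT
  duration: 1.0
  receipt_mode: individual
  criteria_ids:
  - pt_11_c1
  - pt_11_c2
  has_intensity: true
- session_id: pt_12
  component_id: PT
  duration: 1.0
  receipt_mode: individual
  criteria_ids:
  - pt_12_c1
  - pt_12_c2
  has_intensity: true
- session_id: cbt_1
  component_id: CBT
  duration: 3.0
  receipt_mode: individual
  criteria_ids:
  - cbt_1_c1
  - cbt_1_c2
  - cbt_1_c3
  - cbt_1_c4
  - cbt_1_c5
  - cbt_1_c6
  has_intensity: false
- session_id: cbt_2
  component_id: CBT
  duration: 3.0
  receipt_mode: individual
  criteria_ids:
  - cbt_2_c1
  - cbt_2_c2
  - cbt_2_c3
  - cbt_2_c4
  - cbt_2_c5
  - cbt_2_c6
  - cbt_2_c7
  has_intensity: false
total_hours: 27.0
representation_schedule:
- min_size: 1
  max_size: 4
  required: 2
- min_size: 5
  max_size: 9
  required: 3
- min_size: 10
  max_size: 14
  required: 4
- min_size: 15
  max_size: 19
  required: 5
- min_size: 20
  max_size: null
  required: 6
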