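seed: 0
step_sizes:
- 126
- 146
- 158
- 164
workplace_sizes:
- 172
- 194
- 57
- 171
n_teams: 58
pe_working_groups: 39
pt_groups: 42
cbt_groups: 40
pt_trimmed_sessions: 3
n_deliverers: 6
canceled_sessions:
  PE: 1
  PT: 37
  CBT: 2
cancellation_probability: null
behavior:
  PE:
    content: 0.95
    quality: 0.92
    motivation: 0.91
    attendance: 0.0
  PT:
    content: 0.86
    quality: 0.93
    motivation: 0.96
    attendance: 0.38
  CBT:
    content: 0.96
    quality: 0.92
    motivation: 0.93
    attendance: 0.48
kickoff_attendance: 0.66
rep_attendance: 0.835
nonrep_attendance: 0.02
satisfaction: 0.83
support: 0.93
questionnaire_response: participation
step_fidelity_shift: []
workplace_fidelity_shift: []
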