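# Free-text search configuration for sudden-cardiac-death case finding.
#
# triggers:        case-insensitive substrings; a note matches if any single
#                  trigger occurs.
# trigger_pairs:   conjunctive pairs — both substrings must occur in the note.
# exclusion_phrases: if any of these occurs in the +-500 character context
#                  window around a trigger hit, the verdict is not_scd
#                  (the note "clearly specifies another cause of death").
#                  Editable: the source protocol used expert review; this list
#                  is the rule-based stand-in.

triggers:
  - dropped dead
  - died unexpectedly
  - sudden cardiac death
  - acute cardiac death
  - mors subita
  - death instanta
  - died instanta
  - sudden death
  - died suddenly

trigger_pairs:
  - [death, cause unknown]
  - [unexpected, death]

exclusion_phrases:
  - motor vehicle accident
  - road traffic accident
  - overdose
  - suicide
  - hanging
  - drowning
  - terminal cancer
  - terminal malignancy
  - palliative care
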