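# Outcome and exclusion code sets.
#
# ICD-10 entries are matched by hierarchy prefix: an entry "I46" matches
# "I46", "I46.1", ...; an entry "I47.2" matches only that subcode.
# Primary-care (Read-like) records use the internal 1:1 mapping
# "Ry<ICD code without dot>" (e.g. I46 -> RyI46); compact stand-in codes,
# not real Read dictionaries.
#
# Editorial note: the broad sudden-cardiac-death set is defined to be a
# superset of the narrow set (R96 rather than its R96.1 subcode), keeping
# the advertised narrow-within-broad nesting of the tiered definitions.

outcomes:
  cardiac_mortality:
    icd: [I10, I11.9, I20, I21, I22, I23, I24, I25, I42.8, I42.9, I46, I47,
          I49.0, I49.8, I49.9, I51.6, I51.9, I70.9, R09.2, R96, R98]
    sources: [death_certificate]
  scd_primary:
    icd: [I46, I47.2, I49.0, R09.2, R96]
    sources: [death_certificate, free_text, primary_care]
    hospital_rule: exclude_within_30d_post_discharge
  scd_secondary:
    icd: [I10, I11.9, I20, I21, I22, I23, I24, I25, I42.8, I42.9, I46, I47,
          I49.0, I49.8, I49.9, I51.6, I51.9, I70.9, R09.2, R96, R98]
    sources: [death_certificate, free_text, primary_care]
    hospital_rule: exclude_any_hospitalised
  scd_tertiary:
    # broad set restricted to primary-care records and free text only
    icd: [I10, I11.9, I20, I21, I22, I23, I24, I25, I42.8, I42.9, I46, I47,
          I49.0, I49.8, I49.9, I51.6, I51.9, I70.9, R09.2, R96, R98]
    sources: [free_text, primary_care]
  chd:
    # acute myocardial infarction or cardiac procedures
    icd: [I21, I22]
    sources: [hospital, primary_care]
  ventricular_arrhythmia:
    icd: [I49.0]
    sources: [hospital, primary_care]

# deaths from intentional self-harm, removed from all-cause mortality
suicide:
  icd: [X60, X61, X62, X63, X64, X65, X66, X67, X68, X69,
        X70, X71, X72, X73, X74, X75, X76, X77, X78, X79,
        X80, X81, X82, X83, X84]

# cohort exclusion rules (compact internal Read-like codes)
exclusions:
  any_time:          # congenital conduction disorder / advanced cardiomyopathy
    read: [EXCL.CONGCOND, EXCL.CARDIOMYO]
  pre_registration_and_pre_index:   # life-threatening VT, cardioversion,
    read: [EXCL.VTACHY, EXCL.CARDIOVERT, EXCL.ARREST, EXCL.DEFIB]
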