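# Infection code catalog shipped with the package.
#
# The LRTI (non-pneumonia lower respiratory tract infection) entry is the
# published diagnosis-code catalog for that infection type. All other
# infection types carry small SYNTHETIC toy code sets (codes starting with
# an uppercase letter followed by "9" are invented) so the multi-type
# machinery is exercisable without the full expert catalogs, which are
# user-supplied input. Device procedure codes are invented placeholders.
lrti:
  group: nondevice
  icd9:
    - "466.0"
    - "466.1"
    - "466.11"
    - "466.19"
    - "466.2"
    - "510"
    - "510.0"
    - "510.9"
    - "511.1"
    - "513.0"
    - "513.1"
    - "031.0"
    - "464.10"
    - "464.11"
    - "464.2"
    - "464.21"
  icd10:
    - "J20.0"
    - "J20.1"
    - "J20.2"
    - "J20.3"
    - "J20.4"
    - "J20.5"
    - "J20.6"
    - "J20.7"
    - "J20.8"
    - "J20.9"
    - "J21.0"
    - "J21.1"
    - "J21.8"
    - "J21.9"
    - "J86.0"
    - "J86.9"
    - "J90"
    - "J94.2"
    - "J85.0"
    - "J85.1"
    - "J85.2"
    - "J85.3"
    - "A31.0"
    - "J04.10"
    - "J04.11"
    - "J05.0"
uti:
  group: device
  icd9: ["U91.0", "U91.1"]
  icd10: ["U99.0", "U99.1"]
pneumonia:
  group: device
  icd9: ["P91.0", "P91.1"]
  icd10: ["P99.0", "P99.1"]
bsi:
  group: device
  icd9: ["B91.0"]
  icd10: ["B99.0"]
devices:
  catheter_procedure_codes: ["CATH01"]
  ventilation_procedure_codes: ["VENT01"]
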