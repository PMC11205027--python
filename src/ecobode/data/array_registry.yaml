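# Electrode-array geometry registry.
#
# array_length_mm is the basal-most to apical-most CONTACT distance (active
# span).  default_apical_depth_mm and default_aid_deg are population-average
# insertion values used only to build standardized axes when postoperative
# imaging is unavailable.
#
# PROVENANCE: numeric values below are nominal figures assembled for a
# working default and are NOT vendor-certified; verify every value against
# the manufacturer's current datasheet (or your clinic's imaging study)
# before clinical interpretation.  Entries with null averages are
# placeholders that require user-supplied geometry.

- name: HiFocus MidScala
  manufacturer: Advanced Bionics
  n_contacts: 16
  array_length_mm: 15.0
  default_apical_depth_mm: 18.5
  default_aid_deg: 390.0
  source: nominal; verify against the manufacturer's specification

- name: HiFocus SlimJ
  manufacturer: Advanced Bionics
  n_contacts: 16
  array_length_mm: 20.0
  default_apical_depth_mm: 23.0
  default_aid_deg: 420.0
  source: nominal; verify against the manufacturer's specification

- name: CI622
  manufacturer: Cochlear
  n_contacts: 22
  array_length_mm: 19.1
  default_apical_depth_mm: 21.0
  default_aid_deg: 400.0
  source: nominal; verify against the manufacturer's specification

- name: CI612
  manufacturer: Cochlear
  n_contacts: 22
  array_length_mm: 14.0
  default_apical_depth_mm: 17.0
  default_aid_deg: 400.0
  source: nominal; verify against the manufacturer's specification

- name: FLEX28
  manufacturer: MED-EL
  n_contacts: 12
  array_length_mm: 23.1
  default_apical_depth_mm: 26.0
  default_aid_deg: 540.0
  source: nominal; verify against the manufacturer's specification

- name: FLEX24
  manufacturer: MED-EL
  n_contacts: 12
  array_length_mm: 20.9
  default_apical_depth_mm: null
  default_aid_deg: null
  source: placeholder; supply average insertion geometry before use
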