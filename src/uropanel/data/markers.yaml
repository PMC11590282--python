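# Default marker specification: the five urinary biomarkers with the
# positivity cutoffs fixed in the identification studies.
- name: ALOX5
  level: methylation
  threshold: 0.435
- name: TRPS1
  level: methylation
  threshold: 0.465
- name: Chr16
  level: methylation
  threshold: 0.555
- name: CXCL16
  level: protein
  threshold: 648.52
- name: TGFBI
  level: protein
  threshold: 1345.97
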