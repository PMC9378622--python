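# Reference domain architecture of bovine rhodopsin (RHO, 348 aa).
#
# Editable config asset. Boundaries follow the standard bovine rhodopsin
# (UniProt P02699) transmembrane topology annotation, converted to this
# package's 0-based half-open convention. Replace this file to anchor the
# projection on a different reference or on different boundary choices; the
# only requirements are the complete 15-segment architecture in canonical
# order and segments that tile the full sequence.
protein_id: RHO
source: bovine rhodopsin topology per UniProt P02699
length: 348
segments:
  - {label: N-term, start: 0, end: 36}
  - {label: TM1, start: 36, end: 61}
  - {label: ICL1, start: 61, end: 73}
  - {label: TM2, start: 73, end: 96}
  - {label: ECL1, start: 96, end: 110}
  - {label: TM3, start: 110, end: 133}
  - {label: ICL2, start: 133, end: 152}
  - {label: TM4, start: 152, end: 173}
  - {label: ECL2, start: 173, end: 202}
  - {label: TM5, start: 202, end: 224}
  - {label: ICL3, start: 224, end: 252}
  - {label: TM6, start: 252, end: 274}
  - {label: ECL3, start: 274, end: 286}
  - {label: TM7, start: 286, end: 308}
  - {label: C-term, start: 308, end: 348}
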