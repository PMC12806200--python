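# Adverse-event term sets (MedDRA-preferred-term style, matched case-insensitively).
# tma_core: the six thrombotic-microangiopathy-spectrum terms analysed together.
tma_core:
  - thrombotic microangiopathy
  - thrombotic thrombocytopenic purpura
  - haemolytic uraemic syndrome
  - atypical haemolytic uraemic syndrome
  - microangiopathic haemolytic anaemia
  - renal thrombotic microangiopathy
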