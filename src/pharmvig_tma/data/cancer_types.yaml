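# Indication-text -> cancer-type code lookup (13 TCGA-style codes).
# Matching is case-insensitive on the exact indication string; unmapped
# indications fall into "other".
UCEC:
  - endometrial cancer
  - uterine corpus endometrial carcinoma
  - endometrial carcinoma
OV:
  - ovarian cancer
  - ovarian carcinoma
STAD:
  - gastric cancer
  - gastric adenocarcinoma
  - stomach cancer
GBM:
  - glioblastoma
  - glioblastoma multiforme
BRCA:
  - breast cancer
  - invasive breast carcinoma
KIRC:
  - renal cell carcinoma
  - renal clear cell carcinoma
  - kidney cancer
COAD:
  - colon cancer
  - colon adenocarcinoma
  - colorectal cancer
READ:
  - rectal cancer
  - rectal adenocarcinoma
LIHC:
  - hepatocellular carcinoma
  - liver cancer
LUSC:
  - lung squamous cell carcinoma
LUAD:
  - lung adenocarcinoma
  - non-small cell lung cancer
SARC:
  - soft tissue sarcoma
  - sarcoma
THCA:
  - thyroid cancer
  - thyroid carcinoma
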