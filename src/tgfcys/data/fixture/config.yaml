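cutoff: 0.2
known_interactions:
- - TGFB1
  - TGFB1
- - INHA
  - INHBB
- - TGFB1
  - LTBP1
- - TGFB1
  - LTBP3
- - TGFB1
  - LTBP4
- - TGFB1
  - LRC32
- - TGFB1
  - LRC33
n_family: 33
partners:
- LTBP1
- LTBP2
- LTBP3
- LTBP4
- FBN1
- FBN2
- FBN3
- LRC32
- LRC33
- SELE
reference_pairs:
  FBN2_EGF22_mutated:
  - 1378
  - 1406
  FBN2_TB6_mutated:
  - 1579
  - 1608
  LRC32_TGFB1_binding:
  - 211
  - 350
  LTBP1_TB1_mutated:
  - 559
  - 594
  LTBP1_TB3_TGFB1_binding:
  - 1359
  - 1384
similarity_scheme:
- FYW
- ILVM
- RK
- DE
- ST
- NQ
- A
- G
- P
- C
- H
spacing_tolerance: 5
synonyms:
  colon adenocarcinomas: colon adenocarcinoma
  endometrial adenocarcinomas: endometrial adenocarcinoma
  endometrial adenomas: endometrial adenocarcinoma
  plasma cell tumor: plasma cell tumors
threshold: 0.2
windows:
  assn:
  - 70
  - 73
  b8:
  - 305
  - 308
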