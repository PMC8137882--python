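# Code prefixes and drug names driving the rule-based phenotypes.
# Prefix matching: a diagnosis code matches a rule when the code string
# starts with any listed prefix (dots ignored on both sides).
dhf:
  diabetes_any:        # any diabetes diagnosis (inclusion screen)
    - "250"            # ICD-9 diabetes mellitus
    - "E08"
    - "E09"
    - "E10"
    - "E11"
    - "E13"
    - "6488"           # ICD-9 gestational (648.8)
    - "O24"
    - "2538"           # diabetes insipidus family (253.5 is central DI)
    - "2535"
    - "E232"
    - "N251"
    - "7751"           # neonatal DM (775.1)
    - "P702"
  type2_dm:
    - "2500"           # 250.x0 / 250.x2 are type II in ICD-9; prefix kept simple
    - "E11"
  type1_dm:
    - "E10"
    - "2501"           # simplified type-I marker
  gestational_dm:
    - "6488"
    - "O24"
  secondary_dm:
    - "E08"
    - "E09"
    - "2491"
    - "249"
  neonatal_dm:
    - "7751"
    - "P702"
  diabetes_insipidus:
    - "2535"
    - "E232"
    - "N251"
  heart_failure:
    - "428"
    - "40403"
    - "40413"
    - "40211"
    - "40411"
    - "40201"
    - "40401"
    - "40291"
    - "39891"
    - "40493"
    - "40491"
    - "I50"
    - "I110"
    - "I0981"
    - "I132"
    - "I9713"
    - "I130"
  antidiabetic_agents:
    - metformin
    - chlorpropamide
    - glimepiride
    - glyburide
    - glipizide
    - tolbutamide
    - tolazamide
    - pioglitazone
    - rosiglitazone
    - sitagliptin
    - saxagliptin
    - alogliptin
    - linagliptin
    - repaglinide
    - nateglinide
    - miglitol
    - acarbose
    - insulin
paca:
  pancreatic_cancer:
    - "157"
    - "C25"
  other_cancer:       # any other malignancy prior to the first PaCa code
    - "14"
    - "15"
    - "16"
    - "17"
    - "18"
    - "19"
    - "20"
    - "C"
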