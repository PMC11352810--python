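# Default study-drug dictionary: CDK4/6 inhibitors by ingredient and brand
# name variants. Patterns are matched as substrings after normalization
# (uppercase, punctuation stripped).
palbociclib:
  ingredient:
    - PALBOCICLIB
  brand:
    - IBRANCE
ribociclib:
  ingredient:
    - RIBOCICLIB
  brand:
    - KISQALI
    - KRYXANA
abemaciclib:
  ingredient:
    - ABEMACICLIB
  brand:
    - VERZENIO
    - VERZENIOS
    - RAMIVEN
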