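# Synthetic test vocabulary — not MedDRA content. A SOC-style umbrella
# query: union of the toy SMQ terms plus SOC-only terms.
name: Toy cardiac disorders
code: "90000100"
scope: narrow
pts:
  - Toy QT prolonged
  - Toy torsade event
  - Toy ventricular tachyarrhythmia
  - Toy cardiac failure
  - Toy cardiac decompensation
  - Toy ejection fraction decreased
  - Toy blood pressure increased
  - Toy hypertensive event
  - Toy myocardial infarction
  - Toy atrial fibrillation
  - Toy palpitations
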