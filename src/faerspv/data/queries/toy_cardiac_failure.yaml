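# Synthetic test vocabulary — not MedDRA content.
name: Toy cardiac failure
code: "90000002"
scope: narrow
pts:
  - Toy cardiac failure
  - Toy cardiac decompensation
  - Toy ejection fraction decreased
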