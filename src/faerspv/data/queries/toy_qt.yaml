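# Synthetic test vocabulary — not MedDRA content.
name: Toy torsade/QT prolongation
code: "90000001"
scope: narrow
pts:
  - Toy QT prolonged
  - Toy torsade event
  - Toy ventricular tachyarrhythmia
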