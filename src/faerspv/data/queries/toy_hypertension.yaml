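# Synthetic test vocabulary — not MedDRA content.
name: Toy hypertension
code: "90000003"
scope: narrow
pts:
  - Toy blood pressure increased
  - Toy hypertensive event
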