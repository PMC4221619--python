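# Default organ-at-risk acceptability rules (6 OAR classes).
# Each rule has a primary branch and, where clinical practice allows it, a
# list of fallback branches that rescue the rule when the primary dose limit
# cannot be achieved ("met via fallback").  Doses in Gy, volumes in percent
# of the structure volume unless given as volume_cc.
rules:
  - name: brain stem
    structures: [brain_stem]
    kind: MaxDoseOrDVH
    dose_gy: 54.0
    fallback:
      - {kind: MaxDVH, dose_gy: 60.0, volume_pct: 1.0}
  - name: spinal cord
    structures: [spinal_cord]
    kind: MaxDoseOrDVH
    dose_gy: 45.0
    fallback:
      - {kind: MaxDVH, dose_gy: 50.0, volume_pct: 1.0}
      - {kind: MaxDVH, dose_gy: 50.0, volume_cc: 1.0}
  - name: optic nerves/chiasm
    structures: [optic_nerve, optic_chiasma]
    kind: MaxDoseOrDVH
    dose_gy: 54.0
    fallback:
      - {kind: MaxDVH, dose_gy: 60.0, volume_pct: 1.0}
  - name: parotid glands
    structures: [parotid]
    kind: MeanDoseOrDVH
    dose_gy: 26.0
    fallback:
      - {kind: MaxDVH, dose_gy: 30.0, volume_pct: 50.0, strict: true}
  - name: eyes
    structures: [eye_retina]
    kind: MaxDoseOrDVH
    dose_gy: 45.0
    fallback:
      - {kind: MeanDose, dose_gy: 35.0, strict: true}
  - name: lens
    structures: [lens]
    kind: MaxDoseOrDVH
    dose_gy: 6.0
    fallback:
      - {kind: MaxDVH, dose_gy: 10.0, volume_pct: 1.0}
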