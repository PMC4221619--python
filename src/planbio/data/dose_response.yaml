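# Poisson-LQ dose-response parameter library for nasopharyngeal-carcinoma
# plan evaluation.  TCP rows are selected by disease stage; NTCP rows use the
# relative-seriality model (s ~ organ architecture).  D50/gamma in the
# Kallman sigmoid P(D) = 2^(-exp(e*gamma*(1 - D/D50))); alpha_beta in Gy for
# the EQD2 conversion of DVH bin doses.
tcp:
  early:
    d50: 57.40
    gamma: 6.3
    alpha_beta: 10.0
    endpoint: local control (stage I/II)
  t3:
    d50: 60.20
    gamma: 4.2
    alpha_beta: 10.0
    endpoint: local control (T3)
  stage4:
    d50: 67.00
    gamma: 3.0
    alpha_beta: 10.0
    endpoint: local control (stage 4)
ntcp:
  brain_stem:
    d50: 65.10
    gamma: 2.4
    alpha_beta: 3.0
    seriality: 1.0
    endpoint: necrosis/infarction
  spinal_cord:
    d50: 68.60
    gamma: 1.9
    alpha_beta: 3.0
    seriality: 4.0
    endpoint: myelitis necrosis
  optic_chiasma:
    d50: 65.00
    gamma: 2.3
    alpha_beta: 3.0
    seriality: 1.0
    endpoint: blindness
  optic_nerve:
    d50: 65.00
    gamma: 2.3
    alpha_beta: 3.0
    seriality: 1.0
    endpoint: blindness
  eye_retina:
    d50: 65.00
    gamma: 1.8
    alpha_beta: 3.0
    seriality: 1.0
    endpoint: blindness
  lens:
    d50: 18.00
    gamma: 1.2
    alpha_beta: 3.0
    seriality: 1.0
    endpoint: cataract
  parotid:
    d50: 46.00
    gamma: 1.8
    alpha_beta: 3.0
    seriality: 1.0
    endpoint: xerostomia
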