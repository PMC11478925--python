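# Class-conditional mean metabolite concentrations (mM) for the three
# major childhood cerebellar tumour types, emulating their qualitative
# short-echo 1.5 T spectral patterns:
#   MB: high total choline (GPC+PCh), taurine present, low myo-inositol
#   EP: high myo-inositol and creatine, intermediate choline
#   PA: low creatine, prominent NAA-region signal, lactate present
# Concentrations are per-proton-normalised model units; cv is the
# per-component coefficient of variation (diagonal covariance).
classes:
  PA:
    cv: 0.22
    mean_mM:
      Ala: 0.3
      Asp: 0.8
      Cr: 2.2
      GPC: 0.9
      PCh: 0.9
      Glc: 1.2
      Gln: 3.5
      Glu: 3.0
      Gua: 0.5
      Gly: 0.6
      Ins: 4.0
      Lac: 2.5
      NAA: 2.4
      NAAG: 0.4
      Scyllo: 0.25
      Tau: 0.0
      MM09: 1.0
      MM12: 0.6
      MM14: 0.5
      MM17: 0.6
      MM20: 1.0
      Lip09: 0.6
      Lip13a: 0.8
      Lip13b: 0.6
      Lip20: 0.5
      -CrCH2: 0.4
  EP:
    cv: 0.22
    mean_mM:
      Ala: 0.6
      Asp: 0.8
      Cr: 5.0
      GPC: 1.5
      PCh: 1.3
      Glc: 1.0
      Gln: 2.5
      Glu: 3.5
      Gua: 0.5
      Gly: 1.4
      Ins: 8.0
      Lac: 1.5
      NAA: 1.4
      NAAG: 0.3
      Scyllo: 0.4
      Tau: 0.5
      MM09: 1.4
      MM12: 0.8
      MM14: 0.7
      MM17: 0.7
      MM20: 1.3
      Lip09: 1.0
      Lip13a: 1.2
      Lip13b: 0.9
      Lip20: 0.8
      -CrCH2: 0.8
  MB:
    cv: 0.22
    mean_mM:
      Ala: 0.4
      Asp: 1.0
      Cr: 4.0
      GPC: 2.6
      PCh: 3.2
      Glc: 0.8
      Gln: 2.0
      Glu: 3.0
      Gua: 0.6
      Gly: 2.2
      Ins: 1.5
      Lac: 2.0
      NAA: 1.3
      NAAG: 0.3
      Scyllo: 0.3
      Tau: 3.8
      MM09: 1.2
      MM12: 0.7
      MM14: 0.6
      MM17: 0.7
      MM20: 1.2
      Lip09: 0.9
      Lip13a: 1.1
      Lip13b: 0.8
      Lip20: 0.7
      -CrCH2: 0.7
# Acquisition-artifact ranges (uniform draws per subject) and the
# time-domain complex noise SD (per real/imaginary component, in the
# same per-mM units as the signal model).
artifacts:
  phi0_deg: [-30.0, 30.0]
  phi1_deg_per_ppm: [-5.0, 5.0]
  eddy_amp_rad: [0.0, 0.8]
  eddy_decay_ms: [20.0, 80.0]
  noise_sd: 0.5
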