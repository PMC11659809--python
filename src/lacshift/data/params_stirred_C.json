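{
  "reactor_type": "stirred",
  "mu_max1": 0.282,
  "kd1": 0.0449,
  "K_glc": 14.1,
  "K_gln": 0.693,
  "K_lac": 6.36,
  "KI_lac1": 2.70,
  "KI_lac2": 1.16,
  "KD_lac1": 9.61,
  "KD_amm": 6.03,
  "KDI_glc": 0.806,
  "Y_Xv_glc": 4.83e8,
  "m_glc": 0.0,
  "k_gln11": 1.60e-12,
  "k_gln12": 0.0,
  "k_gln13": 2.03,
  "k_gln14": -4.56e-12,
  "k_gln21": -3.07e-13,
  "k_lac11": 2.83e-11,
  "k_lac12": 0.0461,
  "k_lac13": 1.38,
  "k_lac14": -5.73e-11,
  "k_lac21": 3.50e-12,
  "k_amm1": 2.01,
  "k_amm2": 7.35e-13,
  "q_p": 6.07e-11,
  "K_ldcell": 7.46e7,
  "r_dcell": 1.36e6,
  "r_hcp": 0.0,
  "r_dna": 0.0,
  "K_dhcp": 0.0,
  "K_ddna": 0.0,
  "Y_hcp_Xd": 9.67e-6,
  "Y_dna_Xd": 1.04e-7,
  "standard_errors": {
    "mu_max1": 1.29e-2,
    "kd1": 7.60e-3,
    "K_glc": 1.50,
    "K_gln": 0.200,
    "K_lac": 2.61,
    "KI_lac1": 0.234,
    "KI_lac2": 0.153,
    "KD_lac1": 2.69,
    "KD_amm": 1.62,
    "KDI_glc": 0.158,
    "Y_Xv_glc": 2.22e7,
    "k_gln11": 1.51e-18,
    "k_gln13": 1.50e-2,
    "k_gln14": 3.89e-22,
    "k_gln21": 2.91e-17,
    "k_lac11": 1.17e-14,
    "k_lac12": 2.55e-3,
    "k_lac13": 1.16e-2,
    "k_lac14": 5.10e-14,
    "k_lac21": 2.44e-15,
    "k_amm1": 8.66e-2,
    "k_amm2": 1.03e-16,
    "q_p": 2.75e-13,
    "K_ldcell": 6.26e7,
    "r_dcell": 1.92e5,
    "Y_hcp_Xd": 1.76e-6,
    "Y_dna_Xd": 1.93e-8
  }
}
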