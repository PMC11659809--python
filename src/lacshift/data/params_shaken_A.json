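{
  "reactor_type": "shaken",
  "mu_max1": 0.271,
  "mu_max2": 0.296,
  "kd1": 0.0515,
  "kd2": 0.0315,
  "K_glc": 36.7,
  "K_gln": 0.631,
  "K_lac": 6.46,
  "KI_lac1": 3.87,
  "KI_lac2": 1.15,
  "KD_lac1": 12.6,
  "KD_lac2": 0.0,
  "KD_amm": 6.96,
  "KDI_glc": 0.582,
  "Y_Xv_glc": 4.89e8,
  "m_glc": 0.0,
  "k_gln11": 1.21e-12,
  "k_gln12": 0.0,
  "k_gln13": 1.67,
  "k_gln14": -4.88e-12,
  "k_gln21": 1.57e-14,
  "k_lac11": 2.63e-11,
  "k_lac12": 0.065,
  "k_lac13": 1.19,
  "k_lac14": -6.41e-11,
  "k_lac21": 8.85e-14,
  "k_amm1": 1.83,
  "k_amm2": 2.49e-12,
  "q_p": 4.71e-11,
  "K_ldcell": 1.29e8,
  "r_dcell": 1.91e6,
  "r_hcp": 0.0,
  "r_dna": 0.0,
  "K_dhcp": 0.0,
  "K_ddna": 0.0,
  "Y_hcp_Xd": 9.09e-6,
  "Y_dna_Xd": 1.42e-7,
  "standard_errors": {
    "mu_max1": 1.16e-2,
    "mu_max2": 6.72e-2,
    "kd1": 1.33e-2,
    "kd2": 9.40e-3,
    "K_glc": 2.38,
    "K_gln": 0.182,
    "K_lac": 1.61,
    "KI_lac1": 0.503,
    "KI_lac2": 0.469,
    "KD_lac1": 5.29,
    "KD_amm": 2.22,
    "KDI_glc": 0.103,
    "Y_Xv_glc": 2.37e7,
    "k_gln11": 4.13e-19,
    "k_gln13": 6.70e-3,
    "k_gln14": 6.93e-22,
    "k_gln21": 6.19e-17,
    "k_lac11": 4.08e-15,
    "k_lac12": 1.43e-3,
    "k_lac13": 5.25e-3,
    "k_lac14": 2.28e-14,
    "k_lac21": 6.50e-16,
    "k_amm1": 0.125,
    "k_amm2": 1.00e-15,
    "q_p": 1.82e-13,
    "K_ldcell": 2.91e7,
    "r_dcell": 9.88e4,
    "Y_hcp_Xd": 1.93e-6,
    "Y_dna_Xd": 7.46e-9
  }
}
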