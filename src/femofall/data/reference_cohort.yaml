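# Published group distributions (mean, sd) of DXA/3D-DXA densitometry and
# FE-based mechanical descriptors in a retrospective case-control cohort of
# post-menopausal women (64 incident hip fractures, 64 matched controls).
# These parameterize the synthetic cohort generators; the reference_auroc
# block holds the corresponding published leave-one-out cross-validated
# AUROC values used as qualitative/quantitative calibration references.
schema: femofall-reference-cohort-v1
units:
  aBMD_gcm2: g/cm^2
  vBMD_int_mgcm3: mg/cm^3
  vBMD_trab_mgcm3: mg/cm^3
  sBMD_cort_mgcm2: mg/cm^2   # cortical vBMD x cortical thickness
  F0_N: N
  D0_mm: mm
  E_nl_Nmm: N.mm
  F1_N: N
  D1_mm: mm
  E_lin_Nmm: N.mm
  D2_mm: mm
  D3_mm: mm
  E_dis_Nmm: N.mm
  E_res_Nmm: N.mm
groups:
  control:
    n: 64
    aBMD_gcm2: {mean: 0.85, sd: 0.12}
    vBMD_int_mgcm3: {mean: 290.17, sd: 47.92}
    vBMD_trab_mgcm3: {mean: 140.39, sd: 34.94}
    sBMD_cort_mgcm2: {mean: 144.13, sd: 18.90}
    F0_N: {mean: 3407.70, sd: 568.3}
    D0_mm: {mean: 2.67, sd: 0.28}
    E_nl_Nmm: {mean: 6588.48, sd: 1197.23}
    F1_N: {mean: 2707.66, sd: 469.18}
    D1_mm: {mean: 0.92, sd: 0.06}
    E_lin_Nmm: {mean: 1250.07, sd: 216.58}
    D2_mm: {mean: 1.75, sd: 0.23}
    D3_mm: {mean: 1.50, sd: 0.21}
    E_dis_Nmm: {mean: 4579.60, sd: 875.13}
    E_res_Nmm: {mean: 1983.11, sd: 335.87}
  fracture:
    n: 64
    aBMD_gcm2: {mean: 0.76, sd: 0.11}
    vBMD_int_mgcm3: {mean: 252.23, sd: 41.22}
    vBMD_trab_mgcm3: {mean: 112.2, sd: 28.54}
    sBMD_cort_mgcm2: {mean: 131.30, sd: 18.21}
    F0_N: {mean: 2984.82, sd: 552.81}
    D0_mm: {mean: 2.98, sd: 0.31}
    E_nl_Nmm: {mean: 6504.74, sd: 1248.04}
    F1_N: {mean: 2351.17, sd: 446.46}
    D1_mm: {mean: 0.97, sd: 0.06}
    E_lin_Nmm: {mean: 1139.39, sd: 211.78}
    D2_mm: {mean: 2.01, sd: 0.28}
    D3_mm: {mean: 1.74, sd: 0.23}
    E_dis_Nmm: {mean: 4621.86, sd: 885.90}
    E_res_Nmm: {mean: 1839.58, sd: 342.28}
reference_auroc:
  aBMD_gcm2: 0.69
  vBMD_int_mgcm3: 0.71
  vBMD_trab_mgcm3: 0.72
  sBMD_cort_mgcm2: 0.66
  F0_N: 0.72
  D0_mm: 0.78
  E_nl_Nmm: 0.52
  F1_N: 0.72
  D1_mm: 0.72
  E_lin_Nmm: 0.65
  D2_mm: 0.79
  D3_mm: 0.79
  E_dis_Nmm: 0.51
  E_res_Nmm: 0.63
reference_auroc_combinations:
  F0_N+D0_mm: 0.79
  F0_N+E_nl_Nmm: 0.79
  F0_N+D2_mm: 0.79
  F0_N+D3_mm: 0.80
  F0_N+E_dis_Nmm: 0.79
  F0_N+E_res_Nmm: 0.73
  F1_N+D1_mm: 0.74
  F1_N+E_lin_Nmm: 0.74
  F1_N+D2_mm: 0.78
  F1_N+D3_mm: 0.79
  F1_N+E_dis_Nmm: 0.77
  F1_N+E_res_Nmm: 0.71
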