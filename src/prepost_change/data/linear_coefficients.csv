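# Linear link-function coefficients percentage = b0 + b1 * abc, by design,
# marginal shape (skewness, excess kurtosis) and pre-post correlation rho.
# Estimated from 13 effect sizes x 500 simulated samples of n = 25 per
# condition; abc is d (single_group) or interaction omega-squared
# (control_group); classical OLS standard errors. Version 1.
design,skewness,excess_kurtosis,rho,b0,b0_se,b1,b1_se
single_group,-3,18,0.5,-0.01,0.24,30.08,0.11
single_group,-3,18,0.7,0.48,0.25,29.89,0.12
single_group,-3,18,0.9,1.30,0.27,29.69,0.12
single_group,-2,9,0.5,1.11,0.20,29.43,0.09
single_group,-2,9,0.7,1.09,0.21,29.51,0.10
single_group,-2,9,0.9,1.57,0.22,29.33,0.10
single_group,-1,2,0.5,1.65,0.18,29.07,0.08
single_group,-1,2,0.7,1.76,0.18,29.05,0.08
single_group,-1,2,0.9,2.15,0.18,28.92,0.09
single_group,0,0,0.5,1.88,0.15,28.82,0.07
single_group,0,0,0.7,1.89,0.15,28.83,0.07
single_group,0,0,0.9,1.84,0.15,28.89,0.07
single_group,1,2,0.5,0.42,0.17,29.43,0.08
single_group,1,2,0.7,0.44,0.16,29.46,0.08
single_group,1,2,0.9,0.30,0.17,29.49,0.08
single_group,2,9,0.5,-0.49,0.19,29.93,0.09
single_group,2,9,0.7,-1.02,0.19,30.11,0.09
single_group,2,9,0.9,-1.12,0.20,30.12,0.09
single_group,3,18,0.5,-1.69,0.22,30.52,0.11
single_group,3,18,0.7,-2.45,0.23,30.78,0.11
single_group,3,18,0.9,-2.34,0.24,30.68,0.12
control_group,-3,18,0.5,3.51,0.29,162.9,0.82
control_group,-3,18,0.7,4.18,0.29,164.7,0.83
control_group,-3,18,0.9,5.92,0.31,164.9,0.89
control_group,-2,9,0.5,3.02,0.24,160.3,0.69
control_group,-2,9,0.7,3.95,0.25,162.0,0.70
control_group,-2,9,0.9,5.18,0.25,162.5,0.72
control_group,-1,2,0.5,3.49,0.21,156.7,0.59
control_group,-1,2,0.7,3.74,0.21,157.5,0.59
control_group,-1,2,0.9,4.50,0.21,158.2,0.59
control_group,0,0,0.5,2.35,0.19,152.2,0.53
control_group,0,0,0.7,2.56,0.19,151.7,0.53
control_group,0,0,0.9,2.54,0.19,151.8,0.54
control_group,1,2,0.5,1.07,0.21,149.8,0.60
control_group,1,2,0.7,0.86,0.22,147.6,0.61
control_group,1,2,0.9,0.37,0.22,146.6,0.61
control_group,2,9,0.5,0.96,0.26,148.8,0.73
control_group,2,9,0.7,0.33,0.26,146.2,0.72
control_group,2,9,0.9,-0.03,0.28,143.4,0.77
control_group,3,18,0.5,0.95,0.30,147.6,0.84
control_group,3,18,0.7,0.63,0.31,144.1,0.85
control_group,3,18,0.9,0.43,0.33,139.7,0.91
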