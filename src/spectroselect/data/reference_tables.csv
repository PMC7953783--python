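# Reference genetic-parameter estimates for nine beef-quality traits measured in
# the laboratory (lab) and predicted at the abattoir from Vis-NIR (vis) and
# Micro-NIR (micro) spectra, as published for a population of 1,327 Piemontese
# young bulls.  mean/sd/r2_ext: descriptive statistics and external-validation
# R^2 of the calibrations; phen_var: model-based phenotypic variance in squared
# trait units times var_scale (pH variances are printed x 10^2, hence
# var_scale = 0.01); ratio_*: variance components as fractions of phenotypic
# variance; h2: intra-herd heritability sigma2_a/(sigma2_a+sigma2_e); r_a/r_e:
# additive-genetic and residual correlations of each prediction with its
# laboratory measurement (standard errors alongside).
trait,source,n,mean,sd,r2_ext,phen_var,var_scale,ratio_additive,ratio_batch,ratio_herd,ratio_residual,h2,h2_se,r_a,r_a_se,r_e,r_e_se
L*,lab,1129,39.86,3.46,,11.64,1.0,0.23,0.18,0.06,0.54,0.3,0.09,,,,
a*,lab,1133,28.59,1.74,,3.12,1.0,0.09,0.25,0.11,0.55,0.14,0.07,,,,
b*,lab,1134,9.65,1.66,,2.79,1.0,0.1,0.23,0.08,0.59,0.14,0.07,,,,
C*,lab,1133,30.19,2.15,,4.71,1.0,0.09,0.25,0.1,0.56,0.14,0.07,,,,
h*,lab,1131,18.53,2.04,,4.17,1.0,0.1,0.21,0.06,0.62,0.14,0.07,,,,
pH,lab,1127,5.55,0.05,,0.3,0.01,0.08,0.61,0.06,0.25,0.25,0.09,,,,
PL,lab,1128,4.5,1.19,,1.39,1.0,0.1,0.14,0.05,0.71,0.13,0.07,,,,
CL,lab,1134,16.76,3.45,,11.78,1.0,0.1,0.42,0.04,0.44,0.19,0.08,,,,
WBSF,lab,1117,40.96,10.43,,113.14,1.0,0.16,0.42,0.06,0.37,0.31,0.1,,,,
L*,vis,1129,39.87,3.17,0.84,9.96,1.0,0.32,0.15,0.06,0.46,0.41,0.1,1.0,0.001,0.871,0.016
a*,vis,1133,28.6,1.34,0.55,1.83,1.0,0.04,0.31,0.11,0.53,0.08,0.07,0.958,0.173,0.671,0.029
b*,vis,1134,9.63,1.38,0.63,1.88,1.0,0.02,0.26,0.08,0.64,0.04,0.04,1.0,0.001,0.761,0.021
C*,vis,1133,30.18,1.73,0.58,3.01,1.0,0.03,0.3,0.1,0.58,0.04,0.05,1.0,0.001,0.703,0.024
h*,vis,1131,18.5,1.68,0.64,2.81,1.0,0.03,0.24,0.06,0.67,0.05,0.06,1.0,0.001,0.763,0.057
pH,vis,1127,5.56,0.04,0.3,0.13,0.01,0.08,0.48,0.07,0.37,0.18,0.08,0.701,0.164,0.358,0.056
PL,vis,1128,4.47,0.6,0.31,0.36,1.0,0.17,0.21,0.04,0.58,0.22,0.1,0.979,0.085,0.385,0.054
CL,vis,1134,16.8,1.43,0.16,2.07,1.0,0.03,0.54,0.04,0.4,0.07,0.06,0.703,0.168,0.12,0.059
WBSF,vis,1117,40.89,4.79,0.16,23.33,1.0,0.0,0.53,0.07,0.41,0.0,0.04,0.805,0.187,0.202,0.055
L*,micro,1129,39.89,3.12,0.8,9.74,1.0,0.28,0.15,0.05,0.52,0.35,0.11,1.0,0.001,0.831,0.022
a*,micro,1133,28.62,1.22,0.52,1.52,1.0,0.04,0.22,0.1,0.64,0.07,0.05,0.783,0.225,0.646,0.031
b*,micro,1134,9.7,1.29,0.61,1.67,1.0,0.04,0.16,0.07,0.73,0.05,0.06,0.93,0.189,0.598,0.025
C*,micro,1133,30.22,1.56,0.55,2.46,1.0,0.03,0.21,0.1,0.65,0.05,0.05,0.771,0.228,0.687,0.027
h*,micro,1131,18.56,1.61,0.63,2.59,1.0,0.09,0.18,0.07,0.67,0.11,0.08,0.858,0.134,0.756,0.026
pH,micro,1127,5.55,0.02,0.22,0.06,0.01,0.06,0.49,0.05,0.4,0.13,0.09,0.448,0.256,0.262,0.028
PL,micro,1128,4.5,0.53,0.27,0.28,1.0,0.1,0.16,0.15,0.69,0.13,0.07,0.879,0.162,0.378,0.045
CL,micro,1134,16.67,0.75,0.19,0.57,1.0,0.01,0.13,0.03,0.83,0.01,0.04,0.248,0.271,0.265,0.058
WBSF,micro,1117,40.89,3.84,0.19,15.41,1.0,0.05,0.4,0.07,0.48,0.1,0.07,0.418,0.316,0.271,0.07
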