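# Default trait parameterization for the synthetic beef-quality population.
# Means are population means in trait units; phen_var is the model-based
# phenotypic variance (squared trait units; pH on the natural scale, i.e.
# 0.0030 rather than the x-100 convention used in printed summary tables).
# Variance fractions are the published laboratory-trait partitions rounded to
# two decimals; they are renormalized to sum exactly to one when loaded.
# spectral_info is the fraction of latent-trait variance recoverable from
# noise-free replicate-averaged spectra by the best linear predictor; the
# defaults follow the external-validation R^2 ladder of the Vis-NIR
# instrument (~0.8 for lightness down to ~0.16 for shear force).
traits:
  "L*":
    mean: 39.86
    phen_var: 11.64
    fractions: {additive: 0.23, batch: 0.18, herd: 0.06, residual: 0.54}
    spectral_info: 0.84
  "a*":
    mean: 28.59
    phen_var: 3.12
    fractions: {additive: 0.09, batch: 0.25, herd: 0.11, residual: 0.55}
    spectral_info: 0.55
  "b*":
    mean: 9.65
    phen_var: 2.79
    fractions: {additive: 0.10, batch: 0.23, herd: 0.08, residual: 0.59}
    spectral_info: 0.63
  "C*":
    mean: 30.19
    phen_var: 4.71
    fractions: {additive: 0.09, batch: 0.25, herd: 0.10, residual: 0.56}
    spectral_info: 0.58
  "h*":
    mean: 18.53
    phen_var: 4.17
    fractions: {additive: 0.10, batch: 0.21, herd: 0.06, residual: 0.62}
    spectral_info: 0.64
  "pH":
    mean: 5.55
    phen_var: 0.0030
    fractions: {additive: 0.08, batch: 0.61, herd: 0.06, residual: 0.25}
    spectral_info: 0.30
  "PL":
    mean: 4.50
    phen_var: 1.39
    fractions: {additive: 0.10, batch: 0.14, herd: 0.05, residual: 0.71}
    spectral_info: 0.31
  "CL":
    mean: 16.76
    phen_var: 11.78
    fractions: {additive: 0.10, batch: 0.42, herd: 0.04, residual: 0.44}
    spectral_info: 0.16
  "WBSF":
    mean: 40.96
    phen_var: 113.14
    fractions: {additive: 0.16, batch: 0.42, herd: 0.06, residual: 0.37}
    spectral_info: 0.16
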