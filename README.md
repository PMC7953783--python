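# spectroselect

Genetic evaluation of at-line NIR predictions of beef-quality traits.

Meat quality (CIELAB color L\*, a\*, b\*, C\*, h\*; ultimate pH; purge and
cooking losses; Warner-Bratzler shear force) is expensive to phenotype: it
requires sampling carcasses and days of laboratory work, which rules out the
routine recording a breeding program needs.  Portable spectrometers applied
to the intact muscle surface at the abattoir offer a cheap proxy.  The open
question is quantitative-genetic: are the spectra-based *predictions* of
these traits heritable, and how strongly are they genetically correlated
with the laboratory measurements they stand in for?  If the genetic
correlation r<sub>a</sub> is high, the prediction can serve as an indicator
trait for indirect selection even when its phenotypic accuracy is modest.

`spectroselect` implements the full two-stage inference pipeline for this
question, for researchers in animal breeding and chemometrics:

1. **Calibration.**  Each trait is regressed on standardized absorbance
   spectra under the **Bayes B** mixture prior (an effect is exactly zero
   with probability π, otherwise scaled-t), sampled by Gibbs.  External
   validation is **leave-one-batch-out**: all animals slaughtered on the
   same day are held out together, the model is refit on the remaining
   batches, and predictions accumulate across batches.  R²<sub>EXT</sub> is
   the squared correlation of accumulated predictions with measurements —
   by construction no batch or animal information leaks into its own
   prediction, so the predictions can enter a genetic analysis without
   inflating estimates.
2. **Genetic analysis.**  Each (measured, predicted) pair is analysed with
   a bivariate animal model

   y = Xβ + W₁c + W₂q + Zu + e,

   with random herd c ~ N(0, C⊗I), slaughter-batch q ~ N(0, Q⊗I), additive
   genetic u ~ N(0, G⊗A) (A = pedigree numerator relationship matrix) and
   residual e ~ N(0, R⊗I), fitted by average-information REML on sparse
   mixed-model equations.  Reported parameters: intra-herd heritability
   h² = σ²ₐ/(σ²ₐ+σ²ₑ), variance ratios, genetic and residual correlations
   with delta-method standard errors, variance-loss statistics
   Δσ²ₚ = 1 − σ²ₚ(pred)/σ²ₚ(meas) (and the additive-genetic analogue), and
   relative indirect-selection efficiency r<sub>a</sub>·h_indicator/h_target.

Because the motivating dataset (1,327 Piemontese young bulls, two portable
spectrometers, ~13k-animal pedigree) is not publicly deposited, the package
ships a first-class **synthetic-data module** that emulates the study design
— many-sire pedigrees, herd/batch structure, the published variance
partitions for all nine traits, and replicate spectra whose information
content per trait is tunable — plus the published summary tables as a
fixture, so every stage is testable end to end.

## Worked example

```python
from spectroselect import (
    SimulationConfig, InstrumentGrid, default_trait_catalog,
    simulate_dataset, leave_one_batch_out, BayesBSettings,
    build_design, reml_bivariate, correlations, variance_ratios,
)

catalog = {t.name: t for t in default_trait_catalog()}
cfg = SimulationConfig(
    n_sires=25, n_dams=200, n_progeny=400, n_herds=12, n_batches=20,
    traits=[catalog["L*"]], instruments=(InstrumentGrid("micro", 905, 1649, 6),),
    seed=11,
)
ds = simulate_dataset(cfg)

# stage 1: QC + Bayes B with leave-one-batch-out validation
res = leave_one_batch_out(ds.spectra["micro"], ds.phenotypes, "L*",
                          BayesBSettings(iterations=2000, burn_in=500, seed=1))
print(f"R2_EXT = {res.r2_ext:.2f}")

# stage 2: bivariate animal model on (measured, predicted)
merged = ds.phenotypes.merge(
    res.predictions[["animal", "predicted"]].rename(columns={"predicted": "L*:micro"}),
    on="animal", how="left")
spec = build_design(merged, ds.pedigree, ["L*", "L*:micro"])
comp = reml_bivariate(spec)
print(f"h2(measured)  = {variance_ratios(comp, 0)['h2']:.2f}")
print(f"h2(predicted) = {variance_ratios(comp, 1)['h2']:.2f}")
corr = correlations(comp)
print(f"r_a = {corr['r_a']:.2f} (SE {corr['r_a_se']:.2f})")
```

Output of this exact script:

```
R2_EXT = 0.78
h2(measured)  = 0.28
h2(predicted) = 0.18
r_a = 0.99 (SE 0.06)
```

Read: on a small synthetic population the lightness calibration validates
externally at R² ≈ 0.78; the prediction is somewhat less heritable than the
measurement (shrinkage removes part of the signal), but the two are
genetically nearly the same trait (r_a ≈ 1), i.e. a usable indicator for
indirect selection.

The same flow is available from the shell:

```bash
spectroselect run --config run.yaml       # simulate -> qc -> calibrate -> genparams -> evaluate
spectroselect verify-paper                # check bundled reference tables
spectroselect calibrate --spectra S.csv --phenotypes P.csv --trait "L*" --out preds.csv
```

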