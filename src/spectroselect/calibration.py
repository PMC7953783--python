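"""Bayes B chemometric calibration with leave-one-batch-out validation.

Each trait is regressed on standardized spectral covariates under the Bayes B
mixture prior: every wavelength effect is exactly zero with probability π,
otherwise normal with its own variance drawn from a scaled inverse-χ²
(marginally a scaled-t effect).  A single-site Gibbs sampler draws the
indicator and effect jointly (the effect integrated out of the indicator
step), per-effect variances, the intercept, and the residual variance.

External validation mirrors at-line deployment: all animals slaughtered on
the same day (one *batch*) are held out together, the standardization and the
sampler are refit on the remaining batches, and the held-out batch is
predicted.  Predictions accumulate over batches and ``R²_EXT`` is the squared
Pearson correlation between accumulated predictions and measurements.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .spectral import (
    SpectraSet,
    average_replicates,
    apply_standardization,
    fit_standardization,
    flag_outliers_mahalanobis,
)

logger = logging.getLogger(__name__)

__all__ = [
    "BayesBSettings",
    "CalibrationModel",
    "ValidationResult",
    "fit_bayesb",
    "predict",
    "leave_one_batch_out",
]

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        def wrap(f):
            return f

        return wrap if not (args and callable(args[0])) else args[0]


@dataclass
class BayesBSettings:
    """Gibbs-chain and prior settings.

    ``pi`` is the prior null probability of each wavelength effect.  The
    effect-variance scale follows the expected-R² rule: the prior mode of the
    total genomic variance, ``(1 − π) · Σ_j var(x_j) · mode(σ²_β)``, equals
    ``expected_r2 · var(y)``; the residual scale puts its prior mode at
    ``(1 − expected_r2) · var(y)``.
    """

    iterations: int = 12_000
    burn_in: int = 2_000
    thin: int = 5
    pi: float = 0.95
    df_effect: float = 5.0
    df_residual: float = 5.0
    expected_r2: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.pi < 1.0:
            raise ValueError("pi must be in (0, 1)")
        if self.burn_in >= self.iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")
        if self.df_effect <= 2 or self.df_residual <= 0:
            raise ValueError("prior degrees of freedom too small")


@dataclass
class CalibrationModel:
    """Posterior summaries of a fitted Bayes B regression."""

    intercept: float
    effects: np.ndarray  # posterior mean per covariate (zeros included)
    inclusion_prob: np.ndarray
    residual_variance: float
    pi: float
    settings: BayesBSettings
    columns: np.ndarray | None = None  # covariate labels (wavelengths)
    standardization: object | None = None  # params used on the training set

    def __post_init__(self) -> None:
        if np.any((self.inclusion_prob < 0) | (self.inclusion_prob > 1)):
            raise ValueError("inclusion probabilities must lie in [0, 1]")


@njit(cache=True)
def _gibbs_bayesb(XT, y, pi, df_b, scale_b, df_e, scale_e, n_iter, burn, thin, seed):
    np.random.seed(seed)
    p, n = XT.shape
    xtx = np.empty(p)
    for j in range(p):
        acc = 0.0
        for i in range(n):
            acc += XT[j, i] * XT[j, i]
        xtx[j] = acc
    b = np.zeros(p)
    s2 = np.full(p, scale_b)
    mu = 0.0
    for i in range(n):
        mu += y[i]
    mu /= n
    e = y - mu
    s2e = scale_e if scale_e > 0.0 else 1.0
    log_prior_odds = np.log((1.0 - pi) / pi)

    mu_sum = 0.0
    b_sum = np.zeros(p)
    incl_sum = np.zeros(p)
    s2e_sum = 0.0
    n_kept = 0
    for it in range(n_iter):
        # intercept
        ebar = 0.0
        for i in range(n):
            ebar += e[i]
        ebar /= n
        new_mu = mu + ebar + np.random.standard_normal() * np.sqrt(s2e / n)
        delta_mu = new_mu - mu
        for i in range(n):
            e[i] -= delta_mu
        mu = new_mu
        for j in range(p):
            bj = b[j]
            if bj != 0.0:
                for i in range(n):
                    e[i] += XT[j, i] * bj
            r = 0.0
            for i in range(n):
                r += XT[j, i] * e[i]
            v0 = xtx[j] * s2e
            v1 = xtx[j] * xtx[j] * s2[j] + v0
            if v0 <= 0.0:
                b[j] = 0.0
                continue
            log_odds = (
                log_prior_odds
                - 0.5 * (np.log(v1) - np.log(v0))
                + 0.5 * r * r * (1.0 / v0 - 1.0 / v1)
            )
            prob1 = 1.0 / (1.0 + np.exp(-log_odds))
            if np.random.random() < prob1:
                cj = xtx[j] + s2e / s2[j]
                mean = r / cj
                bj = mean + np.random.standard_normal() * np.sqrt(s2e / cj)
                for i in range(n):
                    e[i] -= XT[j, i] * bj
                b[j] = bj
            else:
                b[j] = 0.0
            # per-effect variance (from prior when the effect is null)
            if b[j] != 0.0:
                s2[j] = (scale_b * df_b + b[j] * b[j]) / np.random.chisquare(df_b + 1.0)
            else:
                s2[j] = scale_b * df_b / np.random.chisquare(df_b)
        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        s2e = (sse + df_e * scale_e) / np.random.chisquare(n + df_e)
        if s2e < 1e-300:
            s2e = 1e-300
        if it >= burn and (it - burn) % thin == 0:
            n_kept += 1
            mu_sum += mu
            s2e_sum += s2e
            for j in range(p):
                b_sum[j] += b[j]
                if b[j] != 0.0:
                    incl_sum[j] += 1.0
    return mu_sum / n_kept, b_sum / n_kept, incl_sum / n_kept, s2e_sum / n_kept


def fit_bayesb(
    X: np.ndarray, y: np.ndarray, settings: BayesBSettings | None = None, columns=None
) -> CalibrationModel:
    """Fit the Bayes B regression of ``y`` on standardized covariates ``X``."""
    settings = settings or BayesBSettings()
    settings.validate()
    X = np.ascontiguousarray(np.asarray(X, dtype=float))
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise ValueError("X rows must match y")
    bad_rows = np.flatnonzero(~np.isfinite(X).all(axis=1) | ~np.isfinite(y))
    if bad_rows.size:
        raise ValueError(f"non-finite covariates/responses at rows {bad_rows[:10].tolist()}")
    n, p = X.shape
    vy = float(np.var(y))
    if vy < 1e-12 or p == 0:
        # degenerate response: the posterior collapses on the zero model
        return CalibrationModel(
            intercept=float(np.mean(y)),
            effects=np.zeros(p),
            inclusion_prob=np.zeros(p),
            residual_variance=0.0,
            pi=settings.pi,
            settings=settings,
            columns=None if columns is None else np.asarray(columns),
        )
    msx = float(np.sum(np.var(X, axis=0)))
    msx = msx if msx > 0 else 1.0
    scale_b = (
        settings.expected_r2
        * vy
        * (settings.df_effect + 2.0)
        / (settings.df_effect * (1.0 - settings.pi) * msx)
    )
    scale_e = (1.0 - settings.expected_r2) * vy * (settings.df_residual + 2.0) / settings.df_residual
    mu, b, incl, s2e = _gibbs_bayesb(
        np.ascontiguousarray(X.T),
        y,
        settings.pi,
        settings.df_effect,
        scale_b,
        settings.df_residual,
        scale_e,
        settings.iterations,
        settings.burn_in,
        settings.thin,
        settings.seed % (2**31),
    )
    return CalibrationModel(
        intercept=float(mu),
        effects=np.asarray(b),
        inclusion_prob=np.asarray(incl),
        residual_variance=float(s2e),
        pi=settings.pi,
        settings=settings,
        columns=None if columns is None else np.asarray(columns),
    )


def predict(model: CalibrationModel, X_new: np.ndarray, columns=None) -> np.ndarray:
    """Posterior-mean prediction: intercept + X_new · E[β | y].

    ``X_new`` must be standardized with the model's training-set parameters.
    If both the model and the call carry column labels they must agree.
    """
    X_new = np.asarray(X_new, dtype=float)
    if X_new.ndim != 2 or X_new.shape[1] != model.effects.shape[0]:
        got = 0 if X_new.ndim != 2 else X_new.shape[1]
        msg = f"covariate count mismatch: model has {model.effects.shape[0]}, input has {got}"
        if model.columns is not None and columns is not None:
            missing = sorted(set(map(str, model.columns)) - set(map(str, columns)))
            extra = sorted(set(map(str, columns)) - set(map(str, model.columns)))
            msg += f"; missing {missing[:5]}, unexpected {extra[:5]}"
        raise ValueError(msg)
    if model.columns is not None and columns is not None:
        if list(map(str, columns)) != list(map(str, model.columns)):
            missing = sorted(set(map(str, model.columns)) - set(map(str, columns)))
            extra = sorted(set(map(str, columns)) - set(map(str, model.columns)))
            raise ValueError(f"wavelength mismatch; missing {missing[:5]}, unexpected {extra[:5]}")
    return model.intercept + X_new @ model.effects


@dataclass
class ValidationResult:
    """Accumulated leave-one-batch-out predictions for one trait."""

    trait: str
    instrument: str
    predictions: pd.DataFrame  # animal, batch, measured, predicted
    r2_ext: float
    batch_sizes: dict = field(default_factory=dict)

    @property
    def measured_sd(self) -> float:
        return float(self.predictions["measured"].std(ddof=1))

    @property
    def predicted_sd(self) -> float:
        return float(self.predictions["predicted"].std(ddof=1))


def leave_one_batch_out(
    spectra: SpectraSet,
    phenotypes: pd.DataFrame,
    trait: str,
    settings: BayesBSettings | None = None,
    qc: bool = True,
    qc_threshold: float = 3.0,
) -> ValidationResult:
    """External validation of one trait by leave-one-batch-out.

    ``phenotypes`` needs columns ``animal``, ``batch`` and the trait.  When
    ``qc`` is true the replicate spectra are first screened for Mahalanobis
    outliers; surviving replicates are always averaged to one spectrum per
    animal.  For each batch, standardization and the Bayes B model are refit
    on all other batches (no leakage) and the held-out batch is predicted;
    the per-fold chain seed is derived from ``settings.seed`` and the fold
    index.
    """
    settings = settings or BayesBSettings()
    if trait not in phenotypes.columns:
        raise KeyError(f"trait {trait!r} not found in phenotype table")
    if qc:
        spectra = flag_outliers_mahalanobis(spectra, threshold=qc_threshold)
    spectra = average_replicates(spectra)
    pheno = phenotypes.dropna(subset=[trait]).set_index("animal")
    common = [a for a in spectra.animal if a in pheno.index]
    if not common:
        raise ValueError("no animals shared between spectra and phenotypes")
    order = {a: i for i, a in enumerate(spectra.animal)}
    rows = np.array([order[a] for a in common])
    spectra = spectra.subset(rows)
    y = pheno.loc[list(common), trait].to_numpy(dtype=float)
    batch = pheno.loc[list(common), "batch"].to_numpy()
    batches = pd.unique(batch)
    if len(batches) < 2:
        raise ValueError("external validation needs at least 2 batches")
    pred = np.full(len(y), np.nan)
    for k, b in enumerate(batches):
        test = batch == b
        train = ~test
        params = fit_standardization(spectra.subset(train))
        X_train = apply_standardization(params, spectra.subset(train))
        X_test = apply_standardization(params, spectra.subset(test))
        fold_settings = replace(settings, seed=(settings.seed * 100_003 + k) % (2**31))
        model = fit_bayesb(X_train, y[train], fold_settings, columns=params.wavelengths)
        pred[test] = predict(model, X_test, columns=params.wavelengths)
    r = np.corrcoef(pred, y)[0, 1] if np.std(pred) > 0 and np.std(y) > 0 else 0.0
    result = ValidationResult(
        trait=trait,
        instrument=spectra.instrument,
        predictions=pd.DataFrame(
            {"animal": list(common), "batch": batch, "measured": y, "predicted": pred}
        ),
        r2_ext=float(r**2),
        batch_sizes={b: int((batch == b).sum()) for b in batches},
    )
    logger.info(
        "%s/%s: R2_EXT=%.3f over %d batches (n=%d)",
        spectra.instrument, trait, result.r2_ext, len(batches), len(y),
    )
    return result
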