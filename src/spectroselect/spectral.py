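"""Spectral QC and pretreatment: outlier screening, replicate averaging,
centering/standardization.

The editing pipeline runs in a fixed order — flag Mahalanobis outliers,
average the surviving replicates per animal, then center and standardize the
covariates using training-set parameters only.  The Mahalanobis screen works
in a principal-component subspace because the covariance of >1,000
wavelengths is singular at typical sample sizes; the standardized distance
``GH = D²/k`` (k = retained components) is compared against a conventional
chemometric cutoff of 3.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SpectraSet",
    "StandardizationParams",
    "flag_outliers_mahalanobis",
    "average_replicates",
    "fit_standardization",
    "apply_standardization",
    "read_spectra_csv",
    "write_spectra_csv",
    "qc_report",
]


@dataclass
class SpectraSet:
    """Per-(animal, replicate) absorbance vectors on one instrument grid."""

    instrument: str
    wavelengths: np.ndarray  # (p,), nm, strictly increasing
    animal: np.ndarray  # (m,) ids
    replicate: np.ndarray  # (m,) int
    values: np.ndarray  # (m, p) absorbance
    flags: np.ndarray | None = None  # True = discarded by QC
    gh: np.ndarray | None = None  # standardized Mahalanobis distance

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.wavelengths) <= 0):
            raise ValueError("wavelength grid must be strictly increasing")
        if self.values.shape != (len(self.animal), len(self.wavelengths)):
            raise ValueError("values shape does not match animals x wavelengths")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("spectra contain missing or non-finite absorbances")

    def __len__(self) -> int:
        return len(self.animal)

    @property
    def n_flagged(self) -> int:
        return 0 if self.flags is None else int(self.flags.sum())

    def subset(self, mask: np.ndarray) -> "SpectraSet":
        return SpectraSet(
            instrument=self.instrument,
            wavelengths=self.wavelengths,
            animal=self.animal[mask],
            replicate=self.replicate[mask],
            values=self.values[mask],
            flags=None if self.flags is None else self.flags[mask],
            gh=None if self.gh is None else self.gh[mask],
        )


def flag_outliers_mahalanobis(
    spectra: SpectraSet, threshold: float = 3.0, variance_kept: float = 0.99, max_components: int = 20
) -> SpectraSet:
    """Flag gross outlier spectra by standardized Mahalanobis distance.

    Distances are computed in the principal-component subspace retaining
    ``variance_kept`` of the total variance (capped at ``max_components``);
    ``GH = D²/k`` and spectra with ``GH > threshold`` are flagged.  Under
    multivariate normality GH is approximately χ²_k/k distributed.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    m = len(spectra)
    if m < 10:
        raise ValueError(f"need at least 10 spectra for outlier screening, got {m}")
    X = spectra.values
    mu = X.mean(axis=0)
    Xc = X - mu
    # principal components via SVD of the centered matrix
    U, s, Vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2 / (m - 1)
    keep = var > max(var.max(), 1.0) * 1e-12
    var, U, s = var[keep], U[:, keep], s[keep]
    cum = np.cumsum(var) / var.sum()
    k = int(np.searchsorted(cum, variance_kept) + 1)
    k = min(k, max_components, len(var))
    if k > m - 1:
        logger.warning(
            "fewer spectra (%d) than requested components; falling back to %d", m, m - 1
        )
        k = m - 1
    scores = U[:, :k] * s[:k]  # (m, k)
    d2 = np.sum(scores**2 / var[:k], axis=1)
    gh = d2 / k
    flags = gh > threshold
    if flags.any():
        logger.info(
            "%s: flagged %d of %d spectra (GH > %g, k=%d components)",
            spectra.instrument, int(flags.sum()), m, threshold, k,
        )
    return replace(spectra, flags=flags, gh=gh)


def average_replicates(spectra: SpectraSet) -> SpectraSet:
    """Arithmetic mean over unflagged replicates, one spectrum per animal.

    Animals whose replicates were all flagged are dropped (logged).  Output
    order follows first appearance of each animal.
    """
    flags = spectra.flags if spectra.flags is not None else np.zeros(len(spectra), bool)
    animals = pd.unique(spectra.animal)
    keep_rows = []
    means = []
    dropped = []
    for a in animals:
        mask = (spectra.animal == a) & ~flags
        if not mask.any():
            dropped.append(a)
            continue
        keep_rows.append(a)
        means.append(spectra.values[mask].mean(axis=0))
    if dropped:
        logger.info(
            "%s: dropped %d animals with no surviving replicate: %s",
            spectra.instrument, len(dropped), dropped[:10],
        )
    return SpectraSet(
        instrument=spectra.instrument,
        wavelengths=spectra.wavelengths,
        animal=np.asarray(keep_rows, dtype=object),
        replicate=np.zeros(len(keep_rows), dtype=int),
        values=np.asarray(means) if means else np.empty((0, len(spectra.wavelengths))),
    )


@dataclass
class StandardizationParams:
    """Per-wavelength centering/scaling learned from a training set."""

    wavelengths: np.ndarray  # retained (non-constant) wavelengths
    mean: np.ndarray
    sd: np.ndarray
    dropped_wavelengths: np.ndarray = field(default_factory=lambda: np.array([]))


def fit_standardization(training: SpectraSet) -> StandardizationParams:
    """Learn per-wavelength mean and SD; zero-variance wavelengths dropped."""
    if len(training) == 0:
        raise ValueError("training set is empty")
    mu = training.values.mean(axis=0)
    sd = training.values.std(axis=0, ddof=1) if len(training) > 1 else np.zeros_like(mu)
    ok = sd > 0
    if not ok.all():
        logger.info(
            "%s: dropping %d zero-variance wavelengths", training.instrument, int((~ok).sum())
        )
    return StandardizationParams(
        wavelengths=training.wavelengths[ok],
        mean=mu[ok],
        sd=sd[ok],
        dropped_wavelengths=training.wavelengths[~ok],
    )


def apply_standardization(params: StandardizationParams, spectra: SpectraSet) -> np.ndarray:
    """Standardized covariate matrix using training-set parameters only."""
    idx = np.searchsorted(spectra.wavelengths, params.wavelengths)
    if np.any(idx >= len(spectra.wavelengths)) or np.any(
        spectra.wavelengths[idx] != params.wavelengths
    ):
        raise ValueError("spectra grid does not contain the training wavelengths")
    return (spectra.values[:, idx] - params.mean) / params.sd


def qc_report(spectra: SpectraSet) -> pd.DataFrame:
    """Per-spectrum QC table: id, replicate, GH distance, flag."""
    return pd.DataFrame(
        {
            "animal": spectra.animal,
            "replicate": spectra.replicate,
            "gh": spectra.gh if spectra.gh is not None else np.nan,
            "flagged": spectra.flags if spectra.flags is not None else False,
        }
    )


def _wavelength_label(w: float) -> str:
    return f"{w:g}"


def write_spectra_csv(spectra: SpectraSet, path) -> None:
    """Wide CSV: animal_id, instrument, replicate, one column per nm."""
    df = pd.DataFrame(spectra.values, columns=[_wavelength_label(w) for w in spectra.wavelengths])
    df.insert(0, "replicate", spectra.replicate)
    df.insert(0, "instrument", spectra.instrument)
    df.insert(0, "animal_id", spectra.animal)
    # %.17g guarantees exact float64 text round-trips
    df.to_csv(path, index=False, float_format="%.17g")


def read_spectra_csv(path, instrument: str | None = None) -> SpectraSet:
    df = pd.read_csv(path, float_precision="round_trip")
    if instrument is not None:
        df = df[df["instrument"] == instrument]
    if df.empty:
        raise ValueError(f"no spectra found in {path!r} for instrument {instrument!r}")
    meta = ["animal_id", "instrument", "replicate"]
    wl_cols = [c for c in df.columns if c not in meta]
    wavelengths = np.array([float(c) for c in wl_cols])
    return SpectraSet(
        instrument=str(df["instrument"].iloc[0]),
        wavelengths=wavelengths,
        animal=df["animal_id"].to_numpy(dtype=object),
        replicate=df["replicate"].to_numpy(dtype=int),
        values=df[wl_cols].to_numpy(dtype=float),
    )
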