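"""Synthetic pedigreed population with trait phenotypes and NIR-like spectra.

The generator emulates the study design the package targets: progeny of many
A.I. sires fattened across herds and slaughtered in day-batches, nine
meat-quality traits with additive/batch/herd/residual variance partitions,
and replicate absorbance spectra per animal on two instrument grids.

Each measured trait is paired with a *latent surface trait* — the day-1
muscle state that spectra can see before sampling, aging and transport.  The
pair is drawn from a bivariate animal model sharing herd and batch effects,
with configurable genetic and residual correlations (both 1.0 by default, in
which case latent and measured coincide).  Spectra are smooth baselines plus
per-trait Gaussian loading bumps scaled so that the best linear predictor of
each standardized latent trait from noise-free replicate-averaged spectra
attains the configured ``spectral_info``; batch-level instrument drift, white
noise, and a small rate of gross outliers complete the picture.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import InstrumentGrid, SimulationConfig, TraitSpec
from .pedigree import PedigreeTable, _mendelian_d, inbreeding_coefficients, sort_pedigree
from .spectral import SpectraSet

__all__ = [
    "SimulatedDataset",
    "simulate_trait_pair",
    "simulate_pedigree",
    "simulate_breeding_values",
    "simulate_phenotypes",
    "simulate_spectra",
    "simulate_dataset",
    "assign_groups",
]


@dataclass
class SimulatedDataset:
    """A complete synthetic study: pedigree, phenotypes, latents, spectra."""

    pedigree: PedigreeTable
    phenotypes: pd.DataFrame  # animal, herd, batch, parity_class, age_class, traits...
    latent: pd.DataFrame  # animal + per-trait latent surface values
    spectra: dict  # instrument name -> SpectraSet
    true_parameters: dict  # per trait: generating blocks, scales, corrupted spectra
    config: SimulationConfig


def simulate_pedigree(config: SimulationConfig, rng: np.random.Generator | None = None) -> PedigreeTable:
    """Two-generation pedigree: unrelated founders, progeny with one sire+dam.

    Sires are drawn uniformly; dams are used nearly one-to-one (shuffled,
    recycled only when there are more progeny than dams), mirroring a beef
    herdbook where few dams have repeat records.  Zero progeny yields a
    founders-only table.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    sires = [f"S{i + 1:04d}" for i in range(config.n_sires)]
    dams = [f"D{i + 1:04d}" for i in range(config.n_dams)]
    records = [(s, None, None) for s in sires] + [(d, None, None) for d in dams]
    if config.n_progeny > 0:
        sire_pick = rng.integers(0, config.n_sires, config.n_progeny)
        reps = int(np.ceil(config.n_progeny / config.n_dams))
        dam_pool = np.concatenate([rng.permutation(config.n_dams) for _ in range(reps)])
        dam_pick = dam_pool[: config.n_progeny]
        for i in range(config.n_progeny):
            records.append((f"P{i + 1:05d}", sires[sire_pick[i]], dams[dam_pick[i]]))
    return sort_pedigree(records)


def _psd_sqrt(G: np.ndarray, what: str = "G") -> np.ndarray:
    G = np.atleast_2d(np.asarray(G, dtype=float))
    if not np.allclose(G, G.T, atol=1e-10):
        raise ValueError(f"{what} must be symmetric")
    w, V = np.linalg.eigh(G)
    tol = 1e-8 * max(1.0, float(np.abs(w).max()))
    if w.min() < -tol:
        raise ValueError(
            f"{what} is not positive semi-definite: offending eigenvalue {w.min():.6g}"
        )
    return V @ np.diag(np.sqrt(np.clip(w, 0.0, None))) @ V.T


def simulate_breeding_values(
    pedigree: PedigreeTable, G: np.ndarray, rng: np.random.Generator | int
) -> np.ndarray:
    """Breeding values for every pedigree member under ``u ~ N(0, G ⊗ A)``.

    Founders are N(0, G); descendants get the parent average plus a
    Mendelian-sampling deviation with covariance ``d_i G`` where
    ``d_i = ½ − ¼(F_s + F_d)`` uses exact pedigree inbreeding (¾ − ¼F_p with
    one known parent, 1 with none).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    G = np.atleast_2d(np.asarray(G, dtype=float))
    t = G.shape[0]
    root = _psd_sqrt(G)
    n = len(pedigree)
    F = inbreeding_coefficients(pedigree)
    d = _mendelian_d(pedigree, F)
    z = rng.standard_normal((n, t))
    u = np.zeros((n, t))
    s, dm = pedigree.sire, pedigree.dam
    for i in range(n):
        pa = np.zeros(t)
        if s[i] >= 0:
            pa += 0.5 * u[s[i]]
        if dm[i] >= 0:
            pa += 0.5 * u[dm[i]]
        u[i] = pa + np.sqrt(d[i]) * (root @ z[i])
    return u


def assign_groups(
    n: int, k: int, rng: np.random.Generator, min_size: int = 3, max_tries: int = 1000
) -> np.ndarray:
    """Uniform random allocation of ``n`` animals to ``k`` levels, rejected
    until every level has at least ``min_size`` members; if rejection keeps
    failing, members of the largest levels are moved to deficient ones."""
    if n < k * min_size:
        raise ValueError(f"cannot place {n} animals into {k} groups of >= {min_size}")
    for _ in range(max_tries):
        g = rng.integers(0, k, n)
        counts = np.bincount(g, minlength=k)
        if counts.min() >= min_size:
            return g
    # repair: move from the largest cells into deficient ones
    for level in range(k):
        while np.bincount(g, minlength=k)[level] < min_size:
            donor = int(np.argmax(np.bincount(g, minlength=k)))
            movable = np.flatnonzero(g == donor)
            g[rng.choice(movable)] = level
    return g


def simulate_trait_pair(
    pedigree: PedigreeTable,
    blocks: dict,
    n_herds: int,
    n_batches: int,
    rng: np.random.Generator | int,
    means: tuple[float, float] = (0.0, 0.0),
) -> pd.DataFrame:
    """Simulate a bivariate record set directly from covariance blocks.

    ``blocks`` maps ``G``/``C``/``Q``/``R`` to 2×2 (or t×t) covariance
    matrices.  All pedigree non-founders get records; herd and batch levels
    are allocated uniformly with at least 3 animals per level.  Used for
    parameter-recovery studies of the REML machinery without the spectral
    stage.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    t = np.atleast_2d(blocks["G"]).shape[0]
    progeny = np.asarray(
        [i for i in range(len(pedigree)) if pedigree.sire[i] >= 0 or pedigree.dam[i] >= 0]
    )
    n = len(progeny)
    herd = assign_groups(n, n_herds, rng)
    batch = assign_groups(n, n_batches, rng)
    u = simulate_breeding_values(pedigree, blocks["G"], rng)[progeny]
    c = rng.multivariate_normal(np.zeros(t), blocks["C"], size=n_herds, method="eigh")
    q = rng.multivariate_normal(np.zeros(t), blocks["Q"], size=n_batches, method="eigh")
    e = rng.multivariate_normal(np.zeros(t), blocks["R"], size=n, method="eigh")
    y = np.asarray(means)[:t] + u + c[herd] + q[batch] + e
    out = pd.DataFrame({"animal": [pedigree.ids[i] for i in progeny], "herd": herd, "batch": batch})
    for tau in range(t):
        out[f"trait{tau + 1}"] = y[:, tau]
    return out


def _pair_blocks(trait: TraitSpec) -> dict:
    """2x2 generating covariance blocks for (measured, latent surface)."""
    V = trait.phen_var
    sa, sb, sh, se = (
        trait.f_additive * V,
        trait.f_batch * V,
        trait.f_herd * V,
        trait.f_residual * V,
    )
    rg = trait.genetic_correlation_latent
    re = trait.residual_correlation_latent
    return {
        "G": np.array([[sa, rg * sa], [rg * sa, sa]]),
        "Q": np.array([[sb, sb], [sb, sb]]),  # batch state fully shared
        "C": np.array([[sh, sh], [sh, sh]]),  # herd state fully shared
        "R": np.array([[se, re * se], [re * se, se]]),
    }


def simulate_phenotypes(
    pedigree: PedigreeTable,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    breeding_values: dict | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Phenotype and latent-surface tables for all progeny in the pedigree.

    Measured trait = mean + fixed-class effect + herd + batch + u + e; the
    latent surface trait shares the herd/batch state and is genetically and
    residually correlated with the measured trait as configured.  Dam-parity
    classes (4) shift pH; slaughter-age classes (5) shift L*; all other
    traits carry an intercept only.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)
    progeny = [i for i in range(len(pedigree)) if pedigree.sire[i] >= 0 or pedigree.dam[i] >= 0]
    progeny = np.asarray(progeny, dtype=int)
    n = len(progeny)
    if n == 0:
        raise ValueError("pedigree contains no progeny to phenotype")
    herd = assign_groups(n, config.n_herds, rng)
    batch = assign_groups(n, config.n_batches, rng)
    parity = rng.choice(4, size=n, p=[0.35, 0.30, 0.25, 0.10]) + 1
    age = rng.choice(5, size=n, p=[0.10, 0.25, 0.30, 0.25, 0.10]) + 1

    ids = [pedigree.ids[i] for i in progeny]
    pheno = pd.DataFrame(
        {"animal": ids, "herd": herd, "batch": batch, "parity_class": parity, "age_class": age}
    )
    latent = pd.DataFrame({"animal": ids})
    truth: dict = {}
    for trait in config.traits:
        blocks = _pair_blocks(trait)
        u_all = simulate_breeding_values(pedigree, blocks["G"], rng)
        if breeding_values is not None:
            breeding_values[trait.name] = u_all
        u = u_all[progeny]
        c = rng.multivariate_normal(np.zeros(2), blocks["C"], size=config.n_herds, method="eigh")
        q = rng.multivariate_normal(np.zeros(2), blocks["Q"], size=config.n_batches, method="eigh")
        e = rng.multivariate_normal(np.zeros(2), blocks["R"], size=n, method="eigh")
        sd_phen = np.sqrt(trait.phen_var)
        fixed = np.zeros(n)
        if trait.name == "pH":
            eff = config.parity_effect_sd * sd_phen * np.linspace(-0.5, 0.5, 4)
            fixed = eff[parity - 1]
        elif trait.name == "L*":
            eff = config.age_effect_sd * sd_phen * np.linspace(-0.5, 0.5, 5)
            fixed = eff[age - 1]
        base = trait.mean + fixed
        y = base + c[herd, 0] + q[batch, 0] + u[:, 0] + e[:, 0]
        z = base + c[herd, 1] + q[batch, 1] + u[:, 1] + e[:, 1]
        pheno[trait.name] = y
        latent[trait.name] = z
        truth[trait.name] = {
            "blocks": blocks,
            "phen_var": trait.phen_var,
            "fractions": trait.fractions,
            "spectral_info": trait.spectral_info,
        }
    return pheno, latent, truth


# ---------------------------------------------------------------------------
# spectra


def _loading_curves(wavelengths: np.ndarray, n_traits: int, width: float = 30.0) -> np.ndarray:
    """Unit-norm Gaussian absorbance bumps, one per trait, with fixed centers
    spread over the 950–1600 nm region shared by both instrument grids."""
    centers = np.linspace(950.0, 1600.0, n_traits)
    L = np.exp(-0.5 * ((wavelengths[:, None] - centers[None, :]) / width) ** 2)
    norms = np.linalg.norm(L, axis=0)
    if np.any(norms == 0):
        raise ValueError("a loading curve has no support on the wavelength grid")
    return L / norms


def _baseline(wavelengths: np.ndarray) -> np.ndarray:
    """Smooth fixed absorbance baseline with broad water-band-like features."""
    w = wavelengths
    return (
        0.5
        + 0.0002 * (w - w[0])
        + 0.8 * np.exp(-0.5 * ((w - 1450.0) / 120.0) ** 2)
        + 0.3 * np.exp(-0.5 * ((w - 970.0) / 80.0) ** 2)
    )


def _calibrate_scales(
    loadings: np.ndarray,
    targets: np.ndarray,
    noise_var_eff: float,
    drift_var: float = 0.0,
    tol: float = 1e-8,
) -> np.ndarray:
    """Signal amplitudes so the best linear predictor of each standardized
    latent trait from replicate-averaged spectra attains its target R².

    With spectrum ``x = Σ_t a_t z_t ℓ_t + ε`` and independent standardized
    latents, the attainable R² of trait t is
    ``1 − [(I + D_a L'Σ⁻¹L D_a)⁻¹]_tt`` where ``Σ`` is the effective noise
    covariance: white noise of variance ``noise_var_eff`` plus, when the
    instrument drifts between batches, a fully correlated offset of variance
    ``drift_var`` along the all-ones direction (handled by Woodbury).  Solved
    by a damped fixed-point iteration on ``a_t²``; cross-talk between
    overlapping loading bumps is accounted for exactly.
    """
    targets = np.clip(np.asarray(targets, dtype=float), 0.0, 0.995)
    if noise_var_eff <= 0:
        # noise-free spectra: any nonzero amplitude gives R² = 1
        return np.where(targets > 0, 1.0, 0.0)
    p = loadings.shape[0]
    gram = loadings.T @ loadings
    if drift_var > 0:
        l1 = loadings.sum(axis=0)  # L' 1
        shrink = drift_var / (noise_var_eff + drift_var * p)
        gram_eff = (gram - shrink * np.outer(l1, l1)) / noise_var_eff
    else:
        gram_eff = gram / noise_var_eff
    a2 = noise_var_eff * targets / (1.0 - targets)
    active = targets > 0
    for _ in range(500):
        a = np.sqrt(a2)
        M = np.eye(len(targets)) + a[:, None] * gram_eff * a[None, :]
        f = 1.0 - np.diag(np.linalg.inv(M))
        if np.max(np.abs(f[active] - targets[active]), initial=0.0) < tol:
            break
        ratio = np.ones_like(a2)
        ratio[active] = (targets[active] / (1.0 - targets[active])) / np.maximum(
            f[active] / (1.0 - f[active]), 1e-12
        )
        a2 *= ratio**0.7  # damping keeps the iteration stable under cross-talk
    return np.sqrt(a2) * active


def simulate_spectra(
    latent: pd.DataFrame,
    batch: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> tuple[dict, dict]:
    """Replicate spectra per instrument from the latent surface traits.

    Returns ``(spectra, info)`` where ``spectra`` maps instrument name to a
    :class:`SpectraSet` and ``info`` records the signal amplitudes and which
    (animal, replicate) spectra were corrupted into gross outliers.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed + 2)
    trait_names = [t.name for t in config.traits]
    Z = latent[trait_names].to_numpy(dtype=float)
    mu, sd = Z.mean(axis=0), Z.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (Z - mu) / sd
    n = Z.shape[0]
    targets = np.array([t.spectral_info for t in config.traits])
    reps = config.replicates_per_animal
    out: dict = {}
    info: dict = {}
    for grid in config.instruments:
        w = grid.wavelengths()
        L = _loading_curves(w, len(trait_names))
        noise_var_eff = config.noise_sd_spectral**2 / reps
        scales = _calibrate_scales(
            L, targets, noise_var_eff, drift_var=config.batch_shift_sd**2
        )
        signal = Z @ (L * scales).T  # (n, p)
        base = _baseline(w)
        shift = rng.normal(0.0, config.batch_shift_sd, size=int(batch.max()) + 1)
        clean = base[None, :] + signal + shift[batch][:, None]
        animals = np.repeat(latent["animal"].to_numpy(dtype=object), reps)
        replicate = np.tile(np.arange(1, reps + 1), n)
        values = np.repeat(clean, reps, axis=0)
        if config.noise_sd_spectral > 0:
            values = values + rng.normal(0.0, config.noise_sd_spectral, size=values.shape)
        corrupted = np.flatnonzero(rng.random(n * reps) < config.outlier_rate)
        for idx in corrupted:
            if rng.random() < 0.5:  # spike
                center = rng.integers(0, len(w))
                values[idx] += 3.0 * np.exp(-0.5 * ((np.arange(len(w)) - center) / 2.0) ** 2)
            else:  # offset
                values[idx] += 1.5
        out[grid.name] = SpectraSet(
            instrument=grid.name,
            wavelengths=w,
            animal=animals,
            replicate=replicate,
            values=values,
        )
        info[grid.name] = {
            "scales": scales,
            "loadings": L,
            "corrupted_rows": corrupted,
            "latent_mean": mu,
            "latent_sd": sd,
        }
    return out, info


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Generate a full dataset; the config (including seed) determines it."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    pedigree = simulate_pedigree(config, rng)
    pheno, latent, truth = simulate_phenotypes(pedigree, config, rng)
    batch = pheno["batch"].to_numpy()
    spectra, spec_info = simulate_spectra(latent, batch, config, rng)
    for name in spec_info:
        truth.setdefault("_spectra", {})[name] = spec_info[name]
    return SimulatedDataset(
        pedigree=pedigree,
        phenotypes=pheno,
        latent=latent,
        spectra=spectra,
        true_parameters=truth,
        config=config,
    )
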