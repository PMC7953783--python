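"""Configuration objects for the synthetic population and pipeline runs.

The synthetic generator is parameterized to emulate the study population it
stands in for: ~204 artificial-insemination sires and ~1,286 dams producing
~1,327 phenotyped young bulls, fattened on ~98 farms (herds) and slaughtered
over ~106 days (batches); nine meat-quality traits (CIELAB color L*, a*, b*,
C*, h*; pH; purge and cooking losses; Warner-Bratzler shear force) with the
published laboratory variance partitions; and five replicate spectra per
animal on two instrument grids (Vis-NIR 350–1830 nm at 1 nm, Micro-NIR
905–1649 nm at 6 nm).
"""

from __future__ import annotations

import importlib.resources as resources
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

__all__ = [
    "TraitSpec",
    "InstrumentGrid",
    "SimulationConfig",
    "default_trait_catalog",
    "DEFAULT_INSTRUMENTS",
]


@dataclass
class TraitSpec:
    """Generating parameters for one trait.

    ``fractions`` are the (additive, batch, herd, residual) shares of the
    phenotypic variance and must sum to one.  ``spectral_info`` is the
    fraction of latent-trait variance recoverable from noise-free
    replicate-averaged spectra by the best linear predictor; it is the dial
    that sets the attainable external-validation R².
    ``genetic_correlation_latent`` / ``residual_correlation_latent`` link the
    laboratory-measured trait to the day-1 muscle state that the spectra see
    (1.0 makes the latent surface trait identical to the measured trait).
    """

    name: str
    mean: float
    phen_var: float
    f_additive: float
    f_batch: float
    f_herd: float
    f_residual: float
    spectral_info: float = 0.5
    genetic_correlation_latent: float = 1.0
    residual_correlation_latent: float = 1.0

    @property
    def fractions(self) -> np.ndarray:
        return np.array([self.f_additive, self.f_batch, self.f_herd, self.f_residual])

    def validate(self) -> None:
        f = self.fractions
        if np.any(f < 0):
            raise ValueError(f"trait {self.name!r}: variance fractions must be >= 0")
        if abs(f.sum() - 1.0) > 1e-6:
            raise ValueError(
                f"trait {self.name!r}: variance fractions sum to {f.sum():.6f}, not 1"
            )
        if self.phen_var <= 0:
            raise ValueError(f"trait {self.name!r}: phenotypic variance must be > 0")
        if not 0.0 <= self.spectral_info <= 1.0:
            raise ValueError(
                f"trait {self.name!r}: spectral_info {self.spectral_info} outside [0, 1]"
            )
        for r in (self.genetic_correlation_latent, self.residual_correlation_latent):
            if not -1.0 <= r <= 1.0:
                raise ValueError(f"trait {self.name!r}: correlation {r} outside [-1, 1]")


@dataclass(frozen=True)
class InstrumentGrid:
    """Wavelength grid of a spectrometer (nm, strictly increasing)."""

    name: str
    start: float
    stop: float
    step: float

    def wavelengths(self) -> np.ndarray:
        if self.step <= 0 or self.stop <= self.start:
            raise ValueError(f"instrument {self.name!r}: grid must be strictly increasing")
        n = int(round((self.stop - self.start) / self.step)) + 1
        return self.start + self.step * np.arange(n)


#: the two portable spectrometers: 1481 and 125 points per spectrum
DEFAULT_INSTRUMENTS = (
    InstrumentGrid("vis", 350.0, 1830.0, 1.0),
    InstrumentGrid("micro", 905.0, 1649.0, 6.0),
)


def default_trait_catalog() -> list[TraitSpec]:
    """The nine-trait default parameterization shipped with the package.

    Printed variance ratios are rounded to two decimals and may sum to
    0.99–1.01; they are renormalized here so each catalog entry validates.
    """
    with resources.files("spectroselect.data").joinpath("default_traits.yaml").open() as fh:
        raw = yaml.safe_load(fh)
    catalog = []
    for name, t in raw["traits"].items():
        fr = t["fractions"]
        vals = np.array([fr["additive"], fr["batch"], fr["herd"], fr["residual"]], float)
        vals = vals / vals.sum()
        catalog.append(
            TraitSpec(
                name=name,
                mean=float(t["mean"]),
                phen_var=float(t["phen_var"]),
                f_additive=vals[0],
                f_batch=vals[1],
                f_herd=vals[2],
                f_residual=vals[3],
                spectral_info=float(t.get("spectral_info", 0.5)),
                genetic_correlation_latent=float(t.get("genetic_correlation_latent", 1.0)),
                residual_correlation_latent=float(t.get("residual_correlation_latent", 1.0)),
            )
        )
    return catalog


@dataclass
class SimulationConfig:
    """Full specification of a synthetic dataset; the seed determines it."""

    n_sires: int = 204
    n_dams: int = 1286
    n_progeny: int = 1327
    n_herds: int = 98
    n_batches: int = 106
    traits: list[TraitSpec] = field(default_factory=default_trait_catalog)
    instruments: tuple[InstrumentGrid, ...] = DEFAULT_INSTRUMENTS
    replicates_per_animal: int = 5
    noise_sd_spectral: float = 0.02  # absorbance units per wavelength
    batch_shift_sd: float = 0.02  # instrument-drift offset shared within batch
    outlier_rate: float = 0.005  # fraction of replicate spectra corrupted
    #: fixed-class effect spread, in phenotypic-SD units (dam parity acts on
    #: pH, slaughter-age class on L*)
    parity_effect_sd: float = 0.2
    age_effect_sd: float = 0.2
    seed: int = 0

    def validate(self) -> None:
        if self.n_sires < 1 or self.n_dams < 1:
            raise ValueError("need at least one sire and one dam")
        if self.n_progeny < 0:
            raise ValueError("n_progeny must be >= 0")
        if self.n_herds < 2 or self.n_batches < 2:
            raise ValueError("need at least 2 herds and 2 batches")
        if self.replicates_per_animal < 1:
            raise ValueError("replicates_per_animal must be >= 1")
        if not 0.0 <= self.outlier_rate < 1.0:
            raise ValueError("outlier_rate must be in [0, 1)")
        if self.noise_sd_spectral < 0:
            raise ValueError("noise_sd_spectral must be >= 0")
        names = [t.name for t in self.traits]
        if len(set(names)) != len(names):
            raise ValueError("duplicate trait names in catalog")
        for t in self.traits:
            t.validate()
        for g in self.instruments:
            g.wavelengths()

    def trait(self, name: str) -> TraitSpec:
        for t in self.traits:
            if t.name == name:
                return t
        raise KeyError(f"unknown trait {name!r}")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["instruments"] = [asdict(g) for g in self.instruments]
        return d

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SimulationConfig":
        kwargs = dict(raw)
        if "traits" in kwargs:
            base = {t.name: t for t in default_trait_catalog()}
            traits = []
            for item in kwargs["traits"]:
                if isinstance(item, str):
                    traits.append(base[item])
                else:
                    traits.append(TraitSpec(**item))
            kwargs["traits"] = traits
        if "instruments" in kwargs:
            grids = []
            for item in kwargs["instruments"]:
                if isinstance(item, str):
                    grids.append({g.name: g for g in DEFAULT_INSTRUMENTS}[item])
                else:
                    grids.append(InstrumentGrid(**item))
            kwargs["instruments"] = tuple(grids)
        cfg = cls(**kwargs)
        cfg.validate()
        return cfg
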