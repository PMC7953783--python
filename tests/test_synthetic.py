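"""Synthetic population generator: construction counts, determinism, genetic
and environmental variance bookkeeping, and spectral information content."""

import numpy as np
import pytest

from spectroselect.config import InstrumentGrid, SimulationConfig, TraitSpec
from spectroselect import simulate as sim
from spectroselect import pedigree as pm


def _trait(**over):
    base = dict(
        name="T", mean=0.0, phen_var=1.0,
        f_additive=0.25, f_batch=0.20, f_herd=0.05, f_residual=0.50,
    )
    base.update(over)
    return TraitSpec(**base)


MICRO = (InstrumentGrid("micro", 905, 1649, 6),)


class TestPedigreeSimulation:
    def test_counts_forced_by_construction(self):
        cfg = SimulationConfig(n_sires=2, n_dams=4, n_progeny=8, n_herds=2, n_batches=2,
                               traits=[_trait()], instruments=MICRO, seed=1)
        ped = sim.simulate_pedigree(cfg)
        assert len(ped) == 14
        assert ped.n_founders == 6

    def test_same_seed_gives_identical_tables(self):
        cfg = SimulationConfig(n_sires=5, n_dams=20, n_progeny=30, n_herds=3, n_batches=3,
                               traits=[_trait()], instruments=MICRO, seed=9)
        t1 = sim.simulate_pedigree(cfg).to_frame()
        t2 = sim.simulate_pedigree(cfg).to_frame()
        assert t1.equals(t2)

    def test_offspring_per_sire_mean(self):
        cfg = SimulationConfig(n_sires=40, n_dams=1500, n_progeny=2000, n_herds=5,
                               n_batches=5, traits=[_trait()], instruments=MICRO, seed=3)
        ped = sim.simulate_pedigree(cfg)
        counts = np.bincount(ped.sire[ped.sire >= 0], minlength=len(ped))
        per_sire = counts[counts > 0]
        assert per_sire.sum() == 2000
        assert per_sire.mean() == pytest.approx(2000 / 40)

    def test_zero_progeny_yields_founder_table(self):
        cfg = SimulationConfig(n_sires=3, n_dams=4, n_progeny=0, n_herds=2, n_batches=2,
                               traits=[_trait()], instruments=MICRO)
        ped = sim.simulate_pedigree(cfg)
        assert len(ped) == 7 and ped.n_founders == 7


class TestBreedingValues:
    def test_founder_sample_covariance_near_identity(self):
        ped = pm.sort_pedigree([(i, None, None) for i in range(5000)])
        u = sim.simulate_breeding_values(ped, np.eye(2), rng=1)
        cov = np.cov(u.T)
        assert np.abs(cov - np.eye(2)).max() < 3 * np.sqrt(2 / 5000) * 1.5

    def test_zero_G_gives_zero_breeding_values(self):
        ped = pm.sort_pedigree([(0, None, None), (1, None, None), (2, 0, 1)])
        u = sim.simulate_breeding_values(ped, np.zeros((2, 2)), rng=0)
        assert np.all(u == 0)

    def test_parent_offspring_covariance_is_half_G(self):
        # 2500 independent trios; cov(u_sire, u_kid) = G/2
        recs = []
        for k in range(2500):
            recs += [(f"s{k}", None, None), (f"d{k}", None, None), (f"o{k}", f"s{k}", f"d{k}")]
        ped = pm.sort_pedigree(recs)
        G = np.array([[1.0, 0.5], [0.5, 2.0]])
        u = sim.simulate_breeding_values(ped, G, rng=4)
        sires = [ped.index[f"s{k}"] for k in range(2500)]
        kids = [ped.index[f"o{k}"] for k in range(2500)]
        c = np.cov(u[sires, 0], u[kids, 0])[0, 1]
        assert c == pytest.approx(0.5 * G[0, 0], abs=3 * np.sqrt(2.0 / 2500) * 2)

    def test_half_sib_covariance_is_quarter_sigma_a(self):
        # paternal half sibs share cov = sigma_a / 4
        recs = [(f"s{k}", None, None) for k in range(2000)]
        for k in range(2000):
            recs += [(f"a{k}", f"s{k}", None), (f"b{k}", f"s{k}", None)]
        ped = pm.sort_pedigree(recs)
        u = sim.simulate_breeding_values(ped, np.array([[2.0]]), rng=8)
        a = [ped.index[f"a{k}"] for k in range(2000)]
        b = [ped.index[f"b{k}"] for k in range(2000)]
        c = np.cov(u[a, 0], u[b, 0])[0, 1]
        assert c == pytest.approx(0.25 * 2.0, abs=0.15)

    def test_non_psd_G_rejected_with_eigenvalue(self):
        ped = pm.sort_pedigree([(0, None, None)])
        with pytest.raises(ValueError, match="eigenvalue"):
            sim.simulate_breeding_values(ped, np.array([[1.0, 2.0], [2.0, 1.0]]), rng=0)


class TestPhenotypes:
    def _config(self, trait, n=2000, seed=2):
        return SimulationConfig(
            n_sires=50, n_dams=n, n_progeny=n, n_herds=20, n_batches=25,
            traits=[trait], instruments=MICRO, seed=seed,
        )

    def test_pure_residual_leaves_no_herd_variance(self):
        trait = _trait(f_additive=0.0, f_batch=0.0, f_herd=0.0, f_residual=1.0)
        cfg = self._config(trait)
        ped = sim.simulate_pedigree(cfg, np.random.default_rng(0))
        pheno, _, _ = sim.simulate_phenotypes(ped, cfg, np.random.default_rng(1))
        means = pheno.groupby("herd")["T"].mean()
        # between-herd spread only from residual sampling noise
        assert means.var() < 3 * 1.0 / (2000 / 20)

    def test_lightness_variance_matches_published_partition(self, trait_catalog):
        # lab L*: phenotypic variance 11.64 with fractions ~0.23/0.18/0.06/0.54
        cfg = SimulationConfig(
            n_sires=50, n_dams=2000, n_progeny=2500, n_herds=30, n_batches=40,
            traits=[trait_catalog["L*"]], instruments=MICRO, seed=6,
        )
        ped = sim.simulate_pedigree(cfg, np.random.default_rng(6))
        pheno, _, _ = sim.simulate_phenotypes(ped, cfg, np.random.default_rng(7))
        v = pheno["L*"].var()
        assert v == pytest.approx(11.64, rel=0.15)

    def test_unit_latent_correlation_when_configured(self):
        trait = _trait(genetic_correlation_latent=1.0, residual_correlation_latent=1.0)
        cfg = self._config(trait, n=500)
        ped = sim.simulate_pedigree(cfg, np.random.default_rng(0))
        bv = {}
        pheno, latent, _ = sim.simulate_phenotypes(
            ped, cfg, np.random.default_rng(1), breeding_values=bv
        )
        u = bv["T"]
        assert np.corrcoef(u[:, 0], u[:, 1])[0, 1] == pytest.approx(1.0, abs=1e-12)
        # identical partitions and unit correlations: latent == measured
        assert np.allclose(latent["T"], pheno["T"])

    def test_fraction_sum_validated(self):
        with pytest.raises(ValueError, match="sum"):
            _trait(f_residual=0.6).validate()

    def test_variance_bookkeeping_by_generating_labels(self):
        trait = _trait(f_additive=0.30, f_batch=0.25, f_herd=0.15, f_residual=0.30,
                       phen_var=4.0)
        cfg = self._config(trait, n=3000, seed=10)
        ped = sim.simulate_pedigree(cfg, np.random.default_rng(10))
        pheno, _, _ = sim.simulate_phenotypes(ped, cfg, np.random.default_rng(11))
        v = pheno["T"].var()
        se = 4.0 * np.sqrt(2 / 3000)
        assert abs(v - 4.0) < 3 * se * 3  # wide MC band: herd/batch effects are few

    def test_group_levels_respect_minimum_cell_size(self, small_dataset):
        for col in ("herd", "batch"):
            assert small_dataset.phenotypes[col].value_counts().min() >= 3


class TestSpectra:
    def test_zero_noise_replicates_identical(self):
        trait = _trait(spectral_info=0.5)
        cfg = SimulationConfig(
            n_sires=5, n_dams=40, n_progeny=60, n_herds=4, n_batches=5,
            traits=[trait], instruments=MICRO, seed=3,
            noise_sd_spectral=0.0, outlier_rate=0.0,
        )
        ds = sim.simulate_dataset(cfg)
        S = ds.spectra["micro"]
        for animal in np.unique(S.animal)[:5]:
            rows = S.values[S.animal == animal]
            assert np.allclose(rows, rows[0])

    def test_zero_spectral_info_gives_zero_signal_scale(self):
        traits = [_trait(name="A", spectral_info=0.0), _trait(name="B", spectral_info=0.6)]
        cfg = SimulationConfig(
            n_sires=5, n_dams=40, n_progeny=60, n_herds=4, n_batches=5,
            traits=traits, instruments=MICRO, seed=3,
        )
        ds = sim.simulate_dataset(cfg)
        scales = ds.true_parameters["_spectra"]["micro"]["scales"]
        assert scales[0] == 0.0 and scales[1] > 0.0

    def test_spectral_info_outside_unit_interval_rejected(self):
        with pytest.raises(ValueError, match="spectral_info"):
            _trait(spectral_info=1.2).validate()

    def test_outlier_corruption_rate(self):
        cfg = SimulationConfig(
            n_sires=10, n_dams=150, n_progeny=300, n_herds=6, n_batches=8,
            traits=[_trait(spectral_info=0.5)], instruments=MICRO,
            outlier_rate=0.02, seed=21,
        )
        ds = sim.simulate_dataset(cfg)
        n_spec = 300 * cfg.replicates_per_animal
        n_corrupt = len(ds.true_parameters["_spectra"]["micro"]["corrupted_rows"])
        se = np.sqrt(0.02 * 0.98 * n_spec)
        assert abs(n_corrupt - 0.02 * n_spec) < 4 * se

    def test_oracle_best_linear_predictor_attains_target(self):
        # closed-form check of the scale calibration, no sampling involved
        from spectroselect.simulate import _calibrate_scales, _loading_curves

        w = MICRO[0].wavelengths()
        L = _loading_curves(w, 4)
        targets = np.array([0.1, 0.3, 0.6, 0.8])
        noise = 0.02**2 / 5
        a = _calibrate_scales(L, targets, noise)
        M = np.eye(4) + (a[:, None] * (L.T @ L) * a[None, :]) / noise
        attained = 1 - np.diag(np.linalg.inv(M))
        assert np.allclose(attained, targets, atol=1e-6)


class TestInstrumentGrids:
    def test_default_grids_match_instrument_specs(self):
        from spectroselect.config import DEFAULT_INSTRUMENTS

        by_name = {g.name: g for g in DEFAULT_INSTRUMENTS}
        vis = by_name["vis"].wavelengths()
        micro = by_name["micro"].wavelengths()
        # 350-1830 nm at 1 nm and 905-1649 nm at 6 nm
        assert len(vis) == 1481 and vis[0] == 350.0 and vis[-1] == 1830.0
        assert len(micro) == 125 and micro[0] == 905.0 and micro[-1] == 1649.0

    def test_invalid_grid_rejected(self):
        from spectroselect.config import InstrumentGrid

        with pytest.raises(ValueError, match="increasing"):
            InstrumentGrid("bad", 900.0, 800.0, 6.0).wavelengths()


class TestDeterminism:
    def test_identical_config_identical_dataset(self, small_dataset):
        ds2 = sim.simulate_dataset(small_dataset.config)
        assert ds2.phenotypes.equals(small_dataset.phenotypes)
        assert np.array_equal(ds2.spectra["micro"].values, small_dataset.spectra["micro"].values)
        assert ds2.pedigree.ids == small_dataset.pedigree.ids
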