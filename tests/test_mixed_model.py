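"""Animal-model REML: design construction rules, likelihood oracles,
parameter recovery, and derived genetic parameters."""

import numpy as np
import pandas as pd
import pytest

from spectroselect import pedigree as pm
from spectroselect import mixed_model as mm
from spectroselect import simulate as sim
from spectroselect.config import SimulationConfig
from .conftest import anova_sire_variance, dense_restricted_loglik

FAST = mm.REMLOptions(tol_loglik=1e-6, flat_tol=1e-5, flat_count=2, score_mode="forward")


def _founder_pedigree(n):
    return pm.sort_pedigree([(f"a{i}", None, None) for i in range(n)])


class TestBuildDesign:
    def _data(self, n=10, herds=None, batches=None):
        rng = np.random.default_rng(0)
        return pd.DataFrame(
            {
                "animal": [f"a{i}" for i in range(n)],
                "herd": herds if herds is not None else [0] * n,
                "batch": batches if batches is not None else [0] * n,
                "parity_class": rng.integers(1, 5, n),
                "age_class": rng.integers(1, 6, n),
                "pH": rng.normal(5.5, 0.05, n),
                "PL": rng.normal(4.5, 1.0, n),
            }
        )

    def test_small_herd_records_dropped(self):
        df = self._data(10, herds=[0] * 8 + [1, 1], batches=[0] * 10)
        spec = mm.build_design(df, _founder_pedigree(10), "PL")
        assert spec.n_records == 8
        assert spec.n_dropped_records == 2
        assert spec.dropped_levels["herd"] == [1]

    def test_ph_gets_parity_contrasts(self):
        df = self._data(12)
        spec = mm.build_design(df, _founder_pedigree(12), "pH")
        # intercept + 3 treatment contrasts for 4 parity classes
        assert spec.X[0].shape[1] == 1 + len(np.unique(df["parity_class"])) - 1
        assert spec.x_labels[0][0] == "intercept"
        assert all(lbl.startswith("parity") for lbl in spec.x_labels[0][1:])

    def test_default_trait_gets_intercept_only(self):
        df = self._data(12)
        spec = mm.build_design(df, _founder_pedigree(12), "PL")
        assert spec.X[0].shape[1] == 1

    def test_predicted_trait_inherits_base_rule(self):
        df = self._data(12)
        df["pH:vis"] = df["pH"] + 0.01
        spec = mm.build_design(df, _founder_pedigree(12), ["pH", "pH:vis"])
        assert spec.X[0].shape[1] == spec.X[1].shape[1] > 1

    def test_all_records_dropped_raises(self):
        df = self._data(4, herds=[0, 1, 2, 3])
        with pytest.raises(ValueError, match="dropped"):
            mm.build_design(df, _founder_pedigree(4), "PL")

    def test_unknown_animal_rejected(self):
        df = self._data(5)
        with pytest.raises(ValueError, match="missing from pedigree"):
            mm.build_design(df, _founder_pedigree(3), "PL")


class TestREMLOracles:
    def test_grid_search_oracle_on_tiny_family(self):
        """The returned estimate maximizes the explicit dense restricted
        likelihood over a coarse (additive, residual) variance grid."""
        rng = np.random.default_rng(21)
        recs = [("s1", None, None), ("d1", None, None), ("s2", None, None), ("d2", None, None)]
        for k in range(2):
            recs += [(f"o{k}", "s1", "d1")]
        for k in range(2, 4):
            recs += [(f"o{k}", "s2", "d2")]
        ped = pm.sort_pedigree(recs)
        u = sim.simulate_breeding_values(ped, np.array([[1.0]]), rng=2)[:, 0]
        animals = list(ped.ids)
        y = u + rng.normal(0, 1.0, len(animals))
        df = pd.DataFrame({"animal": animals, "y": y})
        spec = mm.build_design(df, ped, "y", use_herd=False, use_batch=False)
        comp = mm.reml_bivariate(spec, options=mm.REMLOptions())

        A = pm.build_A(ped).A
        keep = [ped.index[a] for a in df["animal"]]
        Z = np.eye(len(ped))[keep]
        X = np.ones((len(keep), 1))
        yy = df["y"].to_numpy()

        def oracle(va, ve):
            return dense_restricted_loglik(yy, X, [Z], [va * A], ve * np.eye(len(keep)))

        best = oracle(float(comp.G[0, 0]), float(comp.R[0, 0]))
        grid = np.linspace(0.05, 4.0, 25)
        grid_max = max(oracle(va, ve) for va in grid for ve in grid)
        assert best >= grid_max - 1e-6

    def test_estimate_matches_dense_loglik(self, half_sib_study):
        """The sparse-MME likelihood agrees with the dense formula at the
        returned estimate (dual-route check on a moderate problem)."""
        ped, df, _ = half_sib_study
        sub = df.iloc[:120]
        spec = mm.build_design(sub, ped, "y", use_herd=False, use_batch=False)
        comp = mm.reml_bivariate(spec, options=FAST)
        A = pm.build_A(ped).A
        keep = [ped.index[a] for a in sub["animal"]]
        Z = np.eye(len(ped))[keep]
        X = np.ones((len(keep), 1))
        ll_dense = dense_restricted_loglik(
            sub["y"].to_numpy(), X, [Z], [comp.G[0, 0] * A],
            comp.R[0, 0] * np.eye(len(keep)),
        )
        assert comp.loglik == pytest.approx(ll_dense, abs=1e-5)

    def test_balanced_half_sib_matches_anova(self, half_sib_study):
        ped, df, (va, ve) = half_sib_study
        spec = mm.build_design(df, ped, "y", use_herd=False, use_batch=False)
        comp = mm.reml_bivariate(spec, options=FAST)
        sigma_a_anova = 4 * anova_sire_variance(
            df.sort_values(["sire"])["y"].to_numpy().reshape(50, 20)
        )
        se = np.sqrt(comp.param_cov(["G[0,0]"])[0, 0])
        assert abs(comp.G[0, 0] - sigma_a_anova) < 2 * se

    def test_null_components_recovered_near_zero(self):
        # data generated with G = C = Q = 0: pure residual
        rng = np.random.default_rng(31)
        cfg = SimulationConfig(n_sires=20, n_dams=150, n_progeny=300, n_herds=10,
                               n_batches=12, instruments=(), seed=1)
        ped = sim.simulate_pedigree(cfg, rng)
        blocks = {
            "G": np.zeros((2, 2)), "C": np.zeros((2, 2)), "Q": np.zeros((2, 2)),
            "R": np.array([[1.0, 0.3], [0.3, 1.0]]),
        }
        df = sim.simulate_trait_pair(ped, blocks, 10, 12, rng)
        spec = mm.build_design(df, ped, ["trait1", "trait2"])
        comp = mm.reml_bivariate(spec, options=FAST)
        se = np.sqrt(np.diag(comp.asy_cov))
        for k, name in enumerate(comp.param_names):
            label = name[0]
            if label == "R":
                continue
            i, j = int(name[2]), int(name[4])
            assert abs(comp.block(label)[i, j]) < max(2 * se[k], 0.05)

    def test_monotone_likelihood_trace(self, half_sib_study):
        ped, df, _ = half_sib_study
        spec = mm.build_design(df, ped, "y", use_herd=False, use_batch=False)
        comp = mm.reml_bivariate(spec, options=FAST)
        assert np.all(np.diff(comp.loglik_trace) >= -1e-9)

    def test_missing_trait_records_handled(self):
        rng = np.random.default_rng(41)
        cfg = SimulationConfig(n_sires=15, n_dams=100, n_progeny=200, n_herds=8,
                               n_batches=10, instruments=(), seed=2)
        ped = sim.simulate_pedigree(cfg, rng)
        blocks = {
            "G": np.array([[0.3, 0.2], [0.2, 0.3]]),
            "C": 0.05 * np.ones((2, 2)),
            "Q": 0.1 * np.ones((2, 2)),
            "R": np.array([[0.55, 0.2], [0.2, 0.55]]),
        }
        df = sim.simulate_trait_pair(ped, blocks, 8, 10, rng)
        df.loc[df.sample(30, random_state=1).index, "trait2"] = np.nan
        spec = mm.build_design(df, ped, ["trait1", "trait2"])
        comp = mm.reml_bivariate(spec, options=FAST)
        assert comp.converged
        assert spec.n_records == len(df)
        assert np.isfinite(comp.loglik)


class TestDerivedParameters:
    @pytest.mark.parametrize(
        "ratio_a, ratio_e, expected",
        [(0.23, 0.54, 0.30), (0.16, 0.37, 0.31)],
    )
    def test_intraherd_heritability_worked_examples(self, ratio_a, ratio_e, expected):
        # the published h2 values derive from unrounded variance components,
        # so agreement is to within the two-decimal rounding of the ratios
        h2, _ = mm.intraherd_heritability(ratio_a, ratio_e)
        assert abs(h2 - expected) <= 0.015

    def test_zero_additive_variance_gives_zero(self):
        assert mm.intraherd_heritability(0.0, 1.0)[0] == 0.0

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            mm.intraherd_heritability(0.0, 0.0)

    def test_delta_method_se_positive(self):
        h2, se = mm.intraherd_heritability(0.25, 0.5, np.array([[0.01, 0.0], [0.0, 0.02]]))
        assert se > 0

    def _components(self, G, R):
        n = 12
        return mm.BivariateVarianceComponents(
            traits=["m", "p"],
            G=np.asarray(G, float),
            C=np.zeros((2, 2)),
            Q=np.zeros((2, 2)),
            R=np.asarray(R, float),
            asy_cov=0.01 * np.eye(n),
            param_names=[f"{b}[{i},{j}]" for b in "CQGR" for i, j in [(0, 0), (0, 1), (1, 1)]],
            loglik=0.0,
            loglik_trace=[0.0],
            n_iter=1,
            converged=True,
            n_records=100,
        )

    def test_diagonal_G_gives_zero_genetic_correlation(self):
        comp = self._components([[1.0, 0.0], [0.0, 2.0]], [[1.0, 0.5], [0.5, 1.0]])
        assert mm.correlations(comp)["r_a"] == 0.0

    def test_closed_form_correlation(self):
        comp = self._components([[1.0, 0.5], [0.5, 1.0]], [[1.0, 0.25], [0.25, 1.0]])
        out = mm.correlations(comp)
        assert out["r_a"] == pytest.approx(0.5)
        assert out["r_e"] == pytest.approx(0.25)
        assert not out["r_a_clipped"]

    def test_zero_variance_correlation_undefined(self):
        comp = self._components([[0.0, 0.0], [0.0, 1.0]], [[1.0, 0.0], [0.0, 1.0]])
        with pytest.raises(ZeroDivisionError):
            mm.correlations(comp)

    def test_variance_ratios_sum_to_one(self):
        comp = self._components([[1.0, 0.5], [0.5, 1.0]], [[1.0, 0.25], [0.25, 1.0]])
        vr = mm.variance_ratios(comp, 0)
        total = (
            vr["ratio_additive"] + vr["ratio_batch"] + vr["ratio_herd"] + vr["ratio_residual"]
        )
        assert total == pytest.approx(1.0, abs=1e-6)
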