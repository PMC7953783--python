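"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from spectroselect.config import InstrumentGrid, SimulationConfig, default_trait_catalog
from spectroselect import pedigree as pedmod
from spectroselect import simulate as sim


@pytest.fixture(scope="session")
def trait_catalog():
    return {t.name: t for t in default_trait_catalog()}


@pytest.fixture(scope="session")
def micro_grid():
    return InstrumentGrid("micro", 905.0, 1649.0, 6.0)


@pytest.fixture(scope="session")
def small_dataset(trait_catalog, micro_grid):
    """A small but complete synthetic study (Micro grid only)."""
    cfg = SimulationConfig(
        n_sires=25,
        n_dams=200,
        n_progeny=400,
        n_herds=12,
        n_batches=16,
        traits=[trait_catalog["L*"], trait_catalog["pH"], trait_catalog["WBSF"]],
        instruments=(micro_grid,),
        seed=123,
    )
    return sim.simulate_dataset(cfg)


@pytest.fixture(scope="session")
def random_pedigree_200():
    rng = np.random.default_rng(5)
    recs = []
    for i in range(200):
        if i < 25:
            recs.append((i, None, None))
        else:
            s, d = rng.integers(0, i, 2)
            recs.append((i, int(s), int(d)))
    return pedmod.sort_pedigree(recs)


# ---------------------------------------------------------------------------
# independent oracles


def gene_drop_kinship(pedigree, n_rep: int, seed: int) -> np.ndarray:
    """Monte-Carlo kinship by gene dropping: founders get unique allele
    labels, descendants inherit one random allele from each parent, and
    kinship(i, j) is the probability that random alleles drawn from i and j
    are identical by descent.  Fully independent of the tabular A method."""
    rng = np.random.default_rng(seed)
    n = len(pedigree)
    alleles = np.zeros((n, 2, n_rep), dtype=np.int32)
    next_label = 0
    s, d = pedigree.sire, pedigree.dam
    for i in range(n):
        for slot, parent in enumerate((s[i], d[i])):
            if parent < 0:
                alleles[i, slot] = next_label
                next_label += 1
            else:
                pick = rng.integers(0, 2, n_rep)
                alleles[i, slot] = alleles[parent, pick, np.arange(n_rep)]
    phi = np.zeros((n, n))
    for i in range(n):
        for j in range(i, n):
            same = np.zeros(n_rep)
            for a in range(2):
                for b in range(2):
                    same += alleles[i, a] == alleles[j, b]
            phi[i, j] = phi[j, i] = same.mean() / 4.0
    return phi


def dense_restricted_loglik(y, X, Z_blocks, cov_blocks, R) -> float:
    """Explicit dense REML log-likelihood (up to the usual constant):
    -0.5 [log|V| + log|X'V⁻¹X| + y'Py].  Brute-force oracle for tiny n,
    independent of the sparse mixed-model-equations path."""
    V = np.asarray(R, dtype=float).copy()
    for Z, K in zip(Z_blocks, cov_blocks):
        V += Z @ K @ Z.T
    Vinv = np.linalg.inv(V)
    XtVin = X.T @ Vinv
    XtVX = XtVin @ X
    P = Vinv - XtVin.T @ np.linalg.solve(XtVX, XtVin)
    _, ldV = np.linalg.slogdet(V)
    _, ldX = np.linalg.slogdet(XtVX)
    return -0.5 * (ldV + ldX + float(y @ P @ y))


def anova_sire_variance(y_matrix: np.ndarray) -> float:
    """Balanced one-way ANOVA sire variance component (Henderson method 1):
    y_matrix is (sires, progeny-per-sire)."""
    k = y_matrix.shape[1]
    ms_between = k * np.var(y_matrix.mean(axis=1), ddof=1)
    ms_within = np.mean(np.var(y_matrix, axis=1, ddof=1))
    return (ms_between - ms_within) / k


@pytest.fixture(scope="session")
def half_sib_study():
    """Balanced paternal half-sib design: 50 sires x 20 progeny, additive
    and residual variance only (no herd/batch)."""
    rng = np.random.default_rng(17)
    n_sires, n_prog = 50, 20
    va, ve = 1.0, 3.0
    recs = [(f"S{i}", None, None) for i in range(n_sires)]
    rows = []
    for i in range(n_sires):
        us = rng.normal(0, np.sqrt(va))
        for j in range(n_prog):
            aid = f"P{i}_{j}"
            recs.append((aid, f"S{i}", None))
            u = 0.5 * us + rng.normal(0, np.sqrt(0.75 * va))
            rows.append({"animal": aid, "sire": i, "y": 10 + u + rng.normal(0, np.sqrt(ve))})
    ped = pedmod.sort_pedigree(recs)
    df = pd.DataFrame(rows)
    return ped, df, (va, ve)
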