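"""Bivariate animal-model REML for measured and spectra-predicted traits.

The observation model for a trait pair is

    y = Xβ + W₁c + W₂q + Zu + e

with fixed effects β (dam-parity classes for pH, slaughter-age classes for
L*, an intercept otherwise), random herd effects c ~ N(0, C ⊗ I), random
slaughter-batch effects q ~ N(0, Q ⊗ I), additive-genetic animal effects
u ~ N(0, G ⊗ A) with A the pedigree numerator relationship matrix, and
residuals e ~ N(0, R ⊗ I); C, Q, G, R are 2×2 (co)variance blocks.  Records
in herd or batch levels with fewer than 3 observations are dropped before
analysis.

Estimation maximizes the restricted log-likelihood with Newton steps using
the average-information (AI) matrix, a finite-difference score, and
step-halving so that the accepted likelihood trace is monotone
non-decreasing; interim non-PSD blocks are bent to the nearest PSD matrix.
The inverse AI matrix at convergence is the asymptotic covariance of the
estimates, from which heritability and correlation standard errors follow by
the delta method.  Everything is computed through sparse mixed-model
equations; animals missing one trait of the pair are handled by per-animal
residual covariance restricted to the observed traits (missing at random).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.linalg import splu

from .pedigree import PedigreeTable, RelationshipMatrix, build_A_inverse

logger = logging.getLogger(__name__)

__all__ = [
    "MixedModelSpec",
    "BivariateVarianceComponents",
    "REMLOptions",
    "REMLConvergenceError",
    "build_design",
    "reml_bivariate",
    "intraherd_heritability",
    "correlations",
    "variance_ratios",
]

#: which phenotype column provides the fixed classification for which trait;
#: a predicted trait named e.g. ``"pH:vis"`` inherits the rule of its base
FIXED_CLASS_RULES = {"pH": "parity_class", "L*": "age_class"}


class REMLConvergenceError(RuntimeError):
    """Raised when REML does not converge; carries the last iterate."""

    def __init__(self, message, components=None, trace=None):
        super().__init__(message)
        self.components = components
        self.trace = trace


@dataclass
class MixedModelSpec:
    """Design of a (bivariate) animal-model analysis, ready for REML."""

    traits: list
    y: np.ndarray  # (n, t) observations, NaN = missing
    X: list  # per trait: dense (n, p_tau) fixed design
    x_labels: list  # per trait: column labels
    herd: np.ndarray | None  # (n,) codes or None if herd effect omitted
    batch: np.ndarray | None
    animal_idx: np.ndarray  # (n,) index into the pedigree
    pedigree: PedigreeTable
    n_herds: int = 0
    n_batches: int = 0
    n_dropped_records: int = 0
    dropped_levels: dict = field(default_factory=dict)

    @property
    def n_records(self) -> int:
        return self.y.shape[0]

    @property
    def n_traits(self) -> int:
        return self.y.shape[1]


def _class_design(codes: np.ndarray, prefix: str) -> tuple[np.ndarray, list]:
    """Treatment-coded dummies (first level as reference) plus intercept."""
    levels = np.unique(codes)
    X = [np.ones(len(codes))]
    labels = ["intercept"]
    for lev in levels[1:]:
        X.append((codes == lev).astype(float))
        labels.append(f"{prefix}[{lev}]")
    return np.column_stack(X), labels


def build_design(
    data: pd.DataFrame,
    pedigree: PedigreeTable,
    traits,
    use_herd: bool = True,
    use_batch: bool = True,
    min_cell: int = 3,
    fixed_rules: dict | None = None,
) -> MixedModelSpec:
    """Assemble the mixed-model design for one trait or a trait pair.

    ``data`` needs columns ``animal``, ``herd``/``batch`` (if used), the
    trait columns, and any fixed classification columns the rules call for.
    Herd and batch levels with fewer than ``min_cell`` records are dropped
    (iterated until stable, counts logged); every remaining animal must
    appear in the pedigree.
    """
    if isinstance(traits, str):
        traits = [traits]
    traits = list(traits)
    if not 1 <= len(traits) <= 2:
        raise ValueError("supports one trait or a trait pair")
    rules = dict(FIXED_CLASS_RULES) if fixed_rules is None else dict(fixed_rules)
    df = data.copy()
    missing_cols = [t for t in traits if t not in df.columns]
    if missing_cols:
        raise KeyError(f"trait columns not found: {missing_cols}")
    df = df[df[traits].notna().any(axis=1)]

    dropped = 0
    dropped_levels: dict = {"herd": [], "batch": []}
    changed = True
    while changed:
        changed = False
        for col, using in (("herd", use_herd), ("batch", use_batch)):
            if not using:
                continue
            counts = df[col].value_counts()
            small = counts[counts < min_cell].index.tolist()
            if small:
                before = len(df)
                df = df[~df[col].isin(small)]
                dropped += before - len(df)
                dropped_levels[col].extend(small)
                changed = True
    if df.empty:
        raise ValueError("all records dropped by the minimum-cell-size rule")
    if dropped:
        logger.info(
            "minimum cell size %d: dropped %d records (%d herd, %d batch levels)",
            min_cell, dropped, len(dropped_levels["herd"]), len(dropped_levels["batch"]),
        )

    unknown = [a for a in df["animal"] if a not in pedigree.index]
    if unknown:
        raise ValueError(f"animals with records missing from pedigree: {unknown[:5]}")
    animal_idx = np.array([pedigree.index[a] for a in df["animal"]], dtype=int)

    y = df[traits].to_numpy(dtype=float)
    X, labels = [], []
    for t in traits:
        base = t.split(":")[0]
        rule_col = rules.get(base)
        if rule_col is not None:
            if rule_col not in df.columns:
                raise KeyError(f"fixed classification column {rule_col!r} required for {t!r}")
            Xt, lt = _class_design(df[rule_col].to_numpy(), rule_col)
        else:
            Xt, lt = np.ones((len(df), 1)), ["intercept"]
        X.append(Xt)
        labels.append(lt)

    def _codes(col):
        levels = {v: i for i, v in enumerate(pd.unique(df[col]))}
        return df[col].map(levels).to_numpy(dtype=int), len(levels)

    herd = batch = None
    n_herds = n_batches = 0
    if use_herd:
        herd, n_herds = _codes("herd")
    if use_batch:
        batch, n_batches = _codes("batch")
    return MixedModelSpec(
        traits=traits,
        y=y,
        X=X,
        x_labels=labels,
        herd=herd,
        batch=batch,
        animal_idx=animal_idx,
        pedigree=pedigree,
        n_herds=n_herds,
        n_batches=n_batches,
        n_dropped_records=dropped,
        dropped_levels=dropped_levels,
    )


# ---------------------------------------------------------------------------
# parameter bookkeeping


def _vech_indices(t: int) -> list:
    return [(i, j) for i in range(t) for j in range(i, t)]


def _vech(M: np.ndarray, t: int) -> np.ndarray:
    return np.array([M[i, j] for i, j in _vech_indices(t)])

def _unvech(v: np.ndarray, t: int) -> np.ndarray:
    M = np.zeros((t, t))
    for k, (i, j) in enumerate(_vech_indices(t)):
        M[i, j] = M[j, i] = v[k]
    return M


def _bend_psd(M: np.ndarray, floor_frac: float = 1e-8, min_floor: float = 0.0) -> np.ndarray:
    """Clip negative eigenvalues: nearest PSD matrix with a small floor."""
    w, V = np.linalg.eigh(M)
    floor = max(floor_frac * max(np.abs(w).max(), 1e-12), min_floor)
    if w.min() >= floor:
        return M
    w = np.clip(w, floor, None)
    return V @ np.diag(w) @ V.T


@dataclass
class BivariateVarianceComponents:
    """REML estimates for a trait (pair): covariance blocks and uncertainty."""

    traits: list
    G: np.ndarray  # additive genetic
    C: np.ndarray  # herd
    Q: np.ndarray  # batch
    R: np.ndarray  # residual
    asy_cov: np.ndarray  # covariance of vech(G),vech(C),vech(Q),vech(R)
    param_names: list
    loglik: float
    loglik_trace: list
    n_iter: int
    converged: bool
    n_records: int

    @property
    def phenotypic(self) -> np.ndarray:
        return self.G + self.C + self.Q + self.R

    def block(self, name: str) -> np.ndarray:
        return {"G": self.G, "C": self.C, "Q": self.Q, "R": self.R}[name]

    def param_cov(self, names) -> np.ndarray:
        idx = [self.param_names.index(n) for n in names]
        return self.asy_cov[np.ix_(idx, idx)]


@dataclass
class REMLOptions:
    max_iter: int = 100
    tol_loglik: float = 1e-8
    tol_param: float = 1e-6
    #: relative finite-difference step for the score; large enough that
    #: factorization round-off does not dominate the difference quotient
    fd_step: float = 1e-3
    #: "central" (default, more accurate) or "forward" (half the cost)
    score_mode: str = "central"
    max_halvings: int = 18
    #: declare convergence after this many consecutive nearly-flat steps
    flat_tol: float = 1e-7
    flat_count: int = 3
    verbose: bool = False


class _REMLProblem:
    """Precomputed sparse structure for repeated likelihood evaluations."""

    def __init__(self, spec: MixedModelSpec, ainv: RelationshipMatrix):
        self.spec = spec
        t = spec.n_traits
        self.t = t
        n = spec.n_records
        m = len(spec.pedigree)
        self.m = m
        if ainv.A_inv is None or ainv.logdet is None:
            raise ValueError("need the sparse A inverse with its log-determinant")
        self.Ainv = ainv.A_inv.tocsr()
        self.logdetA = ainv.logdet

        # effect layout: [fixed blocks per trait | herd*t | batch*t | animal*t]
        self.p_fixed = [X.shape[1] for X in spec.X]
        p_all = int(sum(self.p_fixed))
        self.offsets = {}
        off = p_all
        self.random_effects = []  # (name, n_levels, Kinv or None, logdetK)
        if spec.herd is not None:
            self.offsets["herd"] = off
            self.random_effects.append(("herd", spec.n_herds, None, 0.0))
            off += spec.n_herds * t
        if spec.batch is not None:
            self.offsets["batch"] = off
            self.random_effects.append(("batch", spec.n_batches, None, 0.0))
            off += spec.n_batches * t
        self.offsets["animal"] = off
        self.random_effects.append(("animal", m, self.Ainv, self.logdetA))
        off += m * t
        self.n_eff = off

        # per-trait observation design rows mapped into the full effect space
        mask = np.isfinite(spec.y)
        self.mask = mask
        W = []
        for tau in range(t):
            rows, cols, vals = [], [], []
            fixed_off = int(sum(self.p_fixed[:tau]))
            Xt = spec.X[tau]
            for r in range(n):
                for j in range(Xt.shape[1]):
                    if Xt[r, j] != 0.0:
                        rows.append(r)
                        cols.append(fixed_off + j)
                        vals.append(Xt[r, j])
                if spec.herd is not None:
                    rows.append(r)
                    cols.append(self.offsets["herd"] + spec.herd[r] * t + tau)
                    vals.append(1.0)
                if spec.batch is not None:
                    rows.append(r)
                    cols.append(self.offsets["batch"] + spec.batch[r] * t + tau)
                    vals.append(1.0)
                rows.append(r)
                cols.append(self.offsets["animal"] + spec.animal_idx[r] * t + tau)
                vals.append(1.0)
            W.append(
                sparse.coo_matrix((vals, (rows, cols)), shape=(n, self.n_eff)).tocsr()
            )
        self.W = W
        self.y = np.nan_to_num(spec.y, nan=0.0)

        # group animals by observation pattern; pre-contract cross-products
        patterns = {}
        for r in range(n):
            key = tuple(bool(v) for v in mask[r])
            patterns.setdefault(key, []).append(r)
        self.patterns = {k: np.asarray(v) for k, v in patterns.items()}
        self.K = {}  # (pattern, s, tau) -> sparse cross-product
        self.Wty = {}  # (pattern, s, tau) -> vector W_s' y_tau over pattern rows
        self.yy = {}  # (pattern, s, tau) -> y_s' y_tau
        for key, rows in self.patterns.items():
            sel = np.zeros(n)
            sel[rows] = 1.0
            D = sparse.diags(sel)
            for s in range(t):
                if not key[s]:
                    continue
                WsD = self.W[s].T @ D
                for tau in range(s, t):
                    if not key[tau]:
                        continue
                    self.K[(key, s, tau)] = (WsD @ self.W[tau]).tocsr()
                    self.Wty[(key, s, tau)] = WsD @ self.y[:, tau]
                    if s != tau:
                        self.Wty[(key, tau, s)] = (self.W[tau].T @ D) @ self.y[:, s]
                    self.yy[(key, s, tau)] = float(
                        np.dot(self.y[rows, s], self.y[rows, tau])
                    )
        # identity kron patterns for Gamma inverse
        self.block_names = [name for name, *_ in self.random_effects] + ["residual"]

    # -- parameter vector <-> blocks ------------------------------------
    def n_params(self) -> int:
        return (len(self.random_effects) + 1) * len(_vech_indices(self.t))

    def unpack(self, theta: np.ndarray) -> dict:
        t = self.t
        k = len(_vech_indices(t))
        blocks = {}
        for i, (name, *_rest) in enumerate(self.random_effects):
            blocks[name] = _unvech(theta[i * k : (i + 1) * k], t)
        blocks["residual"] = _unvech(theta[-k:], t)
        return blocks

    def pack(self, blocks: dict) -> np.ndarray:
        t = self.t
        parts = [_vech(blocks[name], t) for name, *_ in self.random_effects]
        parts.append(_vech(blocks["residual"], t))
        return np.concatenate(parts)

    def param_names(self) -> list:
        names = []
        label = {"animal": "G", "herd": "C", "batch": "Q", "residual": "R"}
        for name, *_ in self.random_effects:
            for i, j in _vech_indices(self.t):
                names.append(f"{label.get(name, name)}[{i},{j}]")
        for i, j in _vech_indices(self.t):
            names.append(f"R[{i},{j}]")
        return names

    # -- likelihood ------------------------------------------------------
    def _rinv_pattern(self, R: np.ndarray, key) -> np.ndarray:
        obs = [i for i, o in enumerate(key) if o]
        Rsub = R[np.ix_(obs, obs)]
        Rinv = np.linalg.inv(Rsub)
        out = np.zeros((self.t, self.t))
        out[np.ix_(obs, obs)] = Rinv
        return out

    def _logdet_pattern(self, R: np.ndarray, key) -> float:
        obs = [i for i, o in enumerate(key) if o]
        sign, ld = np.linalg.slogdet(R[np.ix_(obs, obs)])
        if sign <= 0:
            raise np.linalg.LinAlgError("residual block not positive definite")
        return ld

    def assemble(self, blocks: dict):
        """Coefficient matrix, right-hand side, y'R⁻¹y and log|R|+log|Γ|."""
        t = self.t
        R = blocks["residual"]
        M = sparse.csr_matrix((self.n_eff, self.n_eff))
        rhs = np.zeros(self.n_eff)
        yry = 0.0
        logdet_R = 0.0
        for key, rows in self.patterns.items():
            rinv = self._rinv_pattern(R, key)
            logdet_R += len(rows) * self._logdet_pattern(R, key)
            for s in range(t):
                if not key[s]:
                    continue
                for tau in range(t):
                    if not key[tau]:
                        continue
                    if rinv[s, tau] == 0.0:
                        continue
                    Kst = self.K[(key, s, tau)] if s <= tau else self.K[(key, tau, s)].T
                    M = M + rinv[s, tau] * Kst
                    rhs = rhs + rinv[s, tau] * self.Wty[(key, s, tau)]
                    yy = self.yy[(key, s, tau)] if s <= tau else self.yy[(key, tau, s)]
                    yry += rinv[s, tau] * yy
        # Gamma inverse and its log determinant
        logdet_G = 0.0
        Gi_blocks = []
        for name, n_lev, Kinv, logdetK in self.random_effects:
            Sigma = blocks[name]
            sign, ld = np.linalg.slogdet(Sigma)
            if sign <= 0:
                raise np.linalg.LinAlgError(f"{name} covariance block not positive definite")
            Sinv = np.linalg.inv(Sigma)
            if Kinv is None:
                Gi = sparse.kron(sparse.eye(n_lev), Sinv, format="csr")
                logdet_G += n_lev * ld
            else:
                Gi = sparse.kron(Kinv, Sinv, format="csr")
                logdet_G += n_lev * ld + t * logdetK
            Gi_blocks.append(Gi)
        Gi_full = sparse.block_diag(
            [sparse.csr_matrix((int(sum(self.p_fixed)),) * 2)] + Gi_blocks, format="csr"
        )
        M = (M + Gi_full).tocsc()
        return M, rhs, yry, logdet_R + logdet_G

    def loglik(self, theta: np.ndarray, want_solution: bool = False):
        """Restricted log-likelihood (up to a constant); optionally with the
        MME solution and factorization for AI computations."""
        blocks = self.unpack(theta)
        M, rhs, yry, logdets = self.assemble(blocks)
        # symmetric minimum-degree ordering: the MME are SPD and COLAMD
        # fills in badly against the dense intercept columns
        lu = splu(M, permc_spec="MMD_AT_PLUS_A", options={"SymmetricMode": True})
        diag_u = lu.U.diagonal()
        if np.any(diag_u == 0):
            raise np.linalg.LinAlgError("singular mixed-model equations")
        logdet_M = float(np.sum(np.log(np.abs(diag_u))))
        sol = lu.solve(rhs)
        ypy = yry - float(rhs @ sol)
        ll = -0.5 * (logdets + logdet_M + ypy)
        if want_solution:
            return ll, sol, lu, blocks
        return ll

    # -- average information ---------------------------------------------
    def ai_matrix(self, theta: np.ndarray):
        """AI matrix (average of observed and expected information) plus the
        score-free byproducts at theta: AI_kl = ½ f_k' P f_l with
        f_k = (∂V/∂θ_k) P y, computed via one MME solve per parameter."""
        t = self.t
        ll, sol, lu, blocks = self.loglik(theta, want_solution=True)
        n = self.spec.n_records
        R = blocks["residual"]
        # residuals e = y - W sol per trait; Py = R^{-1} e (pattern-wise)
        E = np.zeros((n, t))
        for tau in range(t):
            E[:, tau] = self.y[:, tau] - self.W[tau] @ sol
        E[~self.mask] = 0.0
        Py = np.zeros((n, t))
        for key, rows in self.patterns.items():
            rinv = self._rinv_pattern(R, key)
            Py[rows] = E[rows] @ rinv.T
        Py[~self.mask] = 0.0

        vech_idx = _vech_indices(t)
        k_per = len(vech_idx)
        n_par = self.n_params()
        F = np.zeros((n, t, n_par))  # f_k as per-record per-trait data vectors
        # random-effect parameters: f_k = Z_r (I ⊗ E_ij Σ^{-1}) u_r
        for b_i, (name, n_lev, _Kinv, _ld) in enumerate(self.random_effects):
            Sigma = blocks[name]
            Sinv = np.linalg.inv(Sigma)
            off = self.offsets[name if name != "animal" else "animal"]
            U = sol[off : off + n_lev * t].reshape(n_lev, t)
            TU = U @ Sinv.T  # level-major; rows are Σ^{-1} u_l
            if name == "herd":
                level_of = self.spec.herd
            elif name == "batch":
                level_of = self.spec.batch
            else:
                level_of = self.spec.animal_idx
            for k_i, (i, j) in enumerate(vech_idx):
                par = b_i * k_per + k_i
                # (E_ij Σ^{-1} u)_tau at the record's level
                vals = np.zeros((n_lev, t))
                vals[:, i] += TU[:, j]
                if i != j:
                    vals[:, j] += TU[:, i]
                F[:, :, par] = vals[level_of]
        # residual parameters: f_k per record = E_ij (R^{-1} e)
        for k_i, (i, j) in enumerate(vech_idx):
            par = len(self.random_effects) * k_per + k_i
            vals = np.zeros((n, t))
            vals[:, i] += Py[:, j]
            if i != j:
                vals[:, j] += Py[:, i]
            F[:, :, par] = vals
        F[~self.mask] = 0.0

        # P f_l via MME solves: P f = R^{-1}(f - W s_f)
        AI = np.zeros((n_par, n_par))
        RHS = np.zeros((self.n_eff, n_par))
        YRF = np.zeros((n_par, n_par))  # f_k' R^{-1} f_l accumulated
        Rinv_F = np.zeros_like(F)
        for key, rows in self.patterns.items():
            rinv = self._rinv_pattern(R, key)
            for par in range(n_par):
                Rinv_F[rows, :, par] = F[rows, :, par] @ rinv.T
        Rinv_F[~self.mask] = 0.0
        for par in range(n_par):
            for tau in range(t):
                RHS[:, par] += self.W[tau].T @ Rinv_F[:, tau, par]
        S = lu.solve(RHS)
        for k in range(n_par):
            for l in range(k, n_par):
                YRF[k, l] = YRF[l, k] = float(np.sum(F[:, :, k] * Rinv_F[:, :, l]))
        AI = 0.5 * (YRF - RHS.T @ S)
        AI = 0.5 * (AI + AI.T)
        return AI, ll


def _start_values(problem: _REMLProblem) -> np.ndarray:
    """Neutral interior start: 40% of phenotypic variance to residual, 20%
    to additive, and 20% each to batch and herd (shares of omitted effects
    fall to the residual); covariances start at zero."""
    spec = problem.spec
    t = problem.t
    vp = np.array(
        [np.nanvar(np.where(problem.mask[:, tau], spec.y[:, tau], np.nan)) for tau in range(t)]
    )
    vp[~np.isfinite(vp) | (vp <= 0)] = 1.0
    shares = {"animal": 0.2, "herd": 0.2, "batch": 0.2}
    blocks = {}
    used = 0.0
    for name, *_ in problem.random_effects:
        blocks[name] = np.diag(shares[name] * vp)
        used += shares[name]
    blocks["residual"] = np.diag((1.0 - used) * vp)
    return problem.pack(blocks)


def reml_bivariate(
    spec: MixedModelSpec,
    a_inverse: RelationshipMatrix | None = None,
    options: REMLOptions | None = None,
    start: np.ndarray | None = None,
) -> BivariateVarianceComponents:
    """AI-REML estimation of {G, C, Q, R} for the trait (pair) in ``spec``.

    Newton steps use the average-information matrix with a central
    finite-difference score; steps are halved until the restricted likelihood
    does not decrease, and interim blocks are bent to PSD.  Convergence
    requires |Δ logL| < ``tol_loglik`` and a maximum relative parameter
    change < ``tol_param``.  Raises :class:`REMLConvergenceError` (carrying
    the last iterate and likelihood trace) otherwise.
    """
    options = options or REMLOptions()
    if a_inverse is None:
        a_inverse = build_A_inverse(spec.pedigree)
    t = spec.n_traits

    # internal scaling: per-trait SD -> parameters O(1)
    sd = np.array([np.sqrt(np.nanvar(spec.y[:, tau])) for tau in range(t)])
    sd[~np.isfinite(sd) | (sd <= 0)] = 1.0
    scaled_spec = MixedModelSpec(
        traits=spec.traits,
        y=spec.y / sd,
        X=spec.X,
        x_labels=spec.x_labels,
        herd=spec.herd,
        batch=spec.batch,
        animal_idx=spec.animal_idx,
        pedigree=spec.pedigree,
        n_herds=spec.n_herds,
        n_batches=spec.n_batches,
        n_dropped_records=spec.n_dropped_records,
        dropped_levels=spec.dropped_levels,
    )
    problem = _REMLProblem(scaled_spec, a_inverse)

    theta0 = (
        _start_values(problem)
        if start is None
        else problem.pack({k: v / np.outer(sd, sd) for k, v in start.items()})
        if isinstance(start, dict)
        else np.asarray(start, dtype=float)
    )

    t_ = t
    vech_idx = _vech_indices(t_)
    k_per = len(vech_idx)
    n_blocks = len(problem.random_effects) + 1
    n_par = problem.n_params()

    # --- Cholesky parameterization: Σ = L L' per block -------------------
    # keeps every block PSD without bending and turns singular optima
    # (correlations of ±1, common for herd/batch blocks of a measured trait
    # and its prediction) into smooth stationary points.
    tril_idx = [(i, j) for i in range(t_) for j in range(i + 1)]
    k_chol = len(tril_idx)

    def _chol_of(M: np.ndarray) -> np.ndarray:
        Mb = _bend_psd(M, min_floor=1e-10)
        L = np.linalg.cholesky(Mb + 1e-12 * np.trace(Mb) * np.eye(t_))
        return np.array([L[i, j] for i, j in tril_idx])

    def _block_of(c: np.ndarray) -> np.ndarray:
        L = np.zeros((t_, t_))
        for k, (i, j) in enumerate(tril_idx):
            L[i, j] = c[k]
        return L @ L.T

    def _pack_chol(theta_vec: np.ndarray) -> np.ndarray:
        blocks = problem.unpack(theta_vec)
        parts = [_chol_of(blocks[name]) for name, *_ in problem.random_effects]
        parts.append(_chol_of(blocks["residual"]))
        return np.concatenate(parts)

    def _theta_from_chol(c_vec: np.ndarray) -> np.ndarray:
        parts = []
        for b in range(n_blocks):
            parts.append(_vech(_block_of(c_vec[b * k_chol : (b + 1) * k_chol]), t_))
        return np.concatenate(parts)

    def _floor_residual(c_vec: np.ndarray) -> np.ndarray:
        # keep the residual block strictly PD so R^{-1} stays finite, and
        # bound every factor entry: on SD-scaled data no component should
        # exceed a few times the phenotypic variance
        out = np.clip(c_vec, -2.5, 2.5)
        off = (n_blocks - 1) * k_chol
        for k, (i, j) in enumerate(tril_idx):
            if i == j and abs(out[off + k]) < 1e-4:
                out[off + k] = 1e-4 if out[off + k] >= 0 else -1e-4
        return out

    def _jacobian(c_vec: np.ndarray) -> np.ndarray:
        """d vech(Σ)/d chol params, block diagonal."""
        J = np.zeros((n_par, n_blocks * k_chol))
        for b in range(n_blocks):
            c = c_vec[b * k_chol : (b + 1) * k_chol]
            L = np.zeros((t_, t_))
            for k, (i, j) in enumerate(tril_idx):
                L[i, j] = c[k]
            for k, (i, j) in enumerate(tril_idx):
                dL = np.zeros((t_, t_))
                dL[i, j] = 1.0
                dS = dL @ L.T + L @ dL.T
                for v, (a, bb) in enumerate(vech_idx):
                    J[b * k_per + v, b * k_chol + k] = dS[a, bb]
        return J

    def _loglik_c(c_vec: np.ndarray) -> float:
        return problem.loglik(_theta_from_chol(_floor_residual(c_vec)))

    cvec = _floor_residual(_pack_chol(theta0))
    ll = _loglik_c(cvec)
    trace = [ll]
    converged = False
    n_c = n_blocks * k_chol
    n_flat = 0
    lam = 1e-4  # Levenberg damping, adapted by step success
    it = 0
    for it in range(1, options.max_iter + 1):
        theta = _theta_from_chol(_floor_residual(cvec))
        AI, _ = problem.ai_matrix(theta)
        J = _jacobian(cvec)
        AIc = J.T @ AI @ J
        # finite-difference score in Cholesky coordinates
        g = np.zeros(n_c)
        for k in range(n_c):
            h = options.fd_step * max(abs(cvec[k]), 0.1)
            cp = cvec.copy()
            cp[k] += h
            try:
                lp = _loglik_c(cp)
                if options.score_mode == "forward":
                    g[k] = (lp - ll) / h
                else:
                    cm = cvec.copy()
                    cm[k] -= h
                    g[k] = (lp - _loglik_c(cm)) / (2 * h)
            except np.linalg.LinAlgError:
                g[k] = 0.0
        damp = max(np.trace(AIc) / n_c, 1.0)
        AIr = AIc + lam * damp * np.eye(n_c)
        try:
            step = np.linalg.solve(AIr, g)
        except np.linalg.LinAlgError:
            step = g / max(np.abs(np.diag(AIr)).max(), 1.0)
        # trust region: factor entries live on the SD scale, so a move of
        # 0.5 per coordinate is already large
        biggest = np.abs(step).max()
        if biggest > 0.5:
            step = step * (0.5 / biggest)

        def _backtrack(direction):
            alpha = 1.0
            for _ in range(options.max_halvings):
                cand = _floor_residual(cvec + alpha * direction)
                try:
                    ll_new = _loglik_c(cand)
                except np.linalg.LinAlgError:
                    ll_new = -np.inf
                # a decrease below round-off resolution still counts
                if np.isfinite(ll_new) and ll_new >= ll - 1e-9:
                    return cand, ll_new, True, alpha
                alpha *= 0.5
            return cvec, ll, False, 0.0

        cand, ll_new, improved, alpha = _backtrack(step)
        if not improved:
            fallback = g / np.maximum(np.abs(np.diag(AIr)), 1e-6)
            cand, ll_new, improved, alpha = _backtrack(fallback)
        # Levenberg adaptation: loosen damping on clean steps, tighten when
        # the line search had to cut the step
        if improved and alpha == 1.0:
            lam = max(lam / 3.0, 1e-10)
        elif improved:
            lam = min(lam * 5.0, 1e4)
        if not improved:
            # neither the damped Newton nor the gradient direction improves
            # the likelihood at numerical resolution: the iterate is a
            # maximum for all practical purposes, unless this happens right
            # at the start (which signals a degenerate setup)
            if it > 2:
                converged = True
                break
            _raise_nonconvergence(problem, _theta_from_chol(cvec), sd, trace, it)
        rel_change = np.max(np.abs(cand - cvec) / np.maximum(np.abs(cvec), 0.05))
        d_ll = ll_new - ll
        cvec, ll = cand, max(ll_new, ll)
        trace.append(ll)
        if options.verbose:
            logger.info("REML iter %d: logL=%.6f dLL=%.3g", it, ll, d_ll)
        if abs(d_ll) < options.tol_loglik and rel_change < options.tol_param:
            converged = True
            break
        n_flat = n_flat + 1 if abs(d_ll) < options.flat_tol else 0
        if n_flat >= options.flat_count:
            converged = True
            break
    theta = _theta_from_chol(_floor_residual(cvec))
    if not converged:
        _raise_nonconvergence(problem, theta, sd, trace, it)

    # report the likelihood on the natural scale: scaling trait tau by
    # 1/sd_tau shifts the restricted likelihood by (N_tau - p_tau) log sd_tau
    n_obs = problem.mask.sum(axis=0)
    ll_shift = float(
        sum((n_obs[tau] - spec.X[tau].shape[1]) * np.log(sd[tau]) for tau in range(t))
    )
    ll = ll - ll_shift
    trace = [v - ll_shift for v in trace]

    AI, _ = problem.ai_matrix(theta)
    AIr = AI + 1e-10 * np.eye(n_par) * max(np.trace(AI) / n_par, 1.0)
    try:
        cov_scaled = np.linalg.inv(AIr)
    except np.linalg.LinAlgError:
        cov_scaled = np.linalg.pinv(AIr)

    # back-transform to trait units
    vech_idx = _vech_indices(t)
    scale = []
    for _ in range(len(problem.random_effects) + 1):
        scale.extend(sd[i] * sd[j] for i, j in vech_idx)
    scale = np.asarray(scale)
    theta_nat = theta * scale
    cov_nat = cov_scaled * np.outer(scale, scale)
    blocks = problem.unpack(theta_nat)
    zero = np.zeros((t, t))
    return BivariateVarianceComponents(
        traits=list(spec.traits),
        G=blocks["animal"],
        C=blocks.get("herd", zero.copy()),
        Q=blocks.get("batch", zero.copy()),
        R=blocks["residual"],
        asy_cov=cov_nat,
        param_names=problem.param_names(),
        loglik=float(ll),
        loglik_trace=[float(v) for v in trace],
        n_iter=it,
        converged=converged,
        n_records=spec.n_records,
    )


def _raise_nonconvergence(problem, theta, sd, trace, it):
    t = problem.t
    vech_idx = _vech_indices(t)
    scale = []
    for _ in range(len(problem.random_effects) + 1):
        scale.extend(sd[i] * sd[j] for i, j in vech_idx)
    blocks = problem.unpack(theta * np.asarray(scale))
    raise REMLConvergenceError(
        f"REML did not converge after {it} iterations "
        f"(last logL {trace[-1]:.6f}); inspect .components and .trace",
        components=blocks,
        trace=[float(v) for v in trace],
    )


# ---------------------------------------------------------------------------
# derived genetic parameters


def intraherd_heritability(
    sigma2_a: float, sigma2_e: float, cov: np.ndarray | None = None
) -> tuple[float, float | None]:
    """Intra-herd heritability h² = σ²ₐ/(σ²ₐ + σ²ₑ) with a delta-method SE.

    The denominator excludes herd and batch variance, matching heritability
    under models that treat contemporary groups as fixed.  ``cov`` is the
    2×2 covariance of (σ²ₐ, σ²ₑ); the SE is ``None`` without it.
    """
    if sigma2_a < 0:
        raise ValueError("additive variance must be >= 0")
    denom = sigma2_a + sigma2_e
    if denom <= 0:
        raise ZeroDivisionError("sigma2_a + sigma2_e must be > 0")
    h2 = sigma2_a / denom
    se = None
    if cov is not None:
        grad = np.array([sigma2_e, -sigma2_a]) / denom**2
        var = float(grad @ np.asarray(cov) @ grad)
        se = float(np.sqrt(max(var, 0.0)))
    return h2, se


def _correlation_with_se(block: np.ndarray, cov: np.ndarray | None):
    v1, c12, v2 = block[0, 0], block[0, 1], block[1, 1]
    if v1 <= 0 or v2 <= 0:
        raise ZeroDivisionError("correlation undefined: zero variance component")
    r = c12 / np.sqrt(v1 * v2)
    clipped = bool(abs(r) > 1)
    r_clip = float(np.clip(r, -1.0, 1.0))
    se = None
    if cov is not None:
        grad = np.array([-r / (2 * v1), 1.0 / np.sqrt(v1 * v2), -r / (2 * v2)])
        var = float(grad @ np.asarray(cov) @ grad)
        se = float(np.sqrt(max(var, 0.0)))
    return r_clip, se, clipped


def correlations(components: BivariateVarianceComponents) -> dict:
    """Additive-genetic and residual correlations of the trait pair.

    ``r = cov / √(var₁·var₂)`` from the G and R blocks; delta-method SEs from
    the asymptotic covariance; estimates outside [−1, 1] are clipped and
    flagged.
    """
    if components.G.shape != (2, 2):
        raise ValueError("correlations need a bivariate analysis")
    out = {}
    for label, name in (("r_a", "G"), ("r_e", "R")):
        pars = [f"{name}[0,0]", f"{name}[0,1]", f"{name}[1,1]"]
        cov = components.param_cov(pars)
        r, se, clipped = _correlation_with_se(components.block(name), cov)
        out[label] = r
        out[f"{label}_se"] = se
        out[f"{label}_clipped"] = clipped
    return out


def variance_ratios(components: BivariateVarianceComponents, trait_index: int = 0) -> dict:
    """Per-trait variance components as fractions of phenotypic variance
    (additive/batch/herd/residual; sums to 1 by construction) plus h²±SE."""
    i = trait_index
    vp = components.phenotypic[i, i]
    pars = [f"G[{i},{i}]", f"R[{i},{i}]"]
    h2, se = intraherd_heritability(
        components.G[i, i], components.R[i, i], components.param_cov(pars)
    )
    return {
        "phenotypic_variance": float(vp),
        "ratio_additive": float(components.G[i, i] / vp),
        "ratio_batch": float(components.Q[i, i] / vp),
        "ratio_herd": float(components.C[i, i] / vp),
        "ratio_residual": float(components.R[i, i] / vp),
        "h2": float(h2),
        "h2_se": se,
    }
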