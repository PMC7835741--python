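"""Single-step GBLUP core: H inverse, REML variance components, MME solver.

The single-trait animal model is

    y = X b + Z_inc a + e,    a ~ N(0, K sigma_a^2),  e ~ N(0, I sigma_e^2)

with K either the pedigree relationship matrix A (pedigree BLUP) or the
combined pedigree-genomic matrix H (ssGBLUP).  H never needs to be formed:
its inverse is A^-1 with (G^-1 - A22^-1) added into the genotyped block.

Variance components come from average-information REML.  The implementation
rotates the problem into the eigenbasis of M = Z_inc K Z_inc', after which
every AI/EM iteration costs O(n p^2): with V = sigma_a^2 M + sigma_e^2 I and
M = U diag(lam) U', all P-weighted traces and quadratic forms reduce to
diagonal arithmetic.  Negative/out-of-bounds AI steps fall back to an EM
update; convergence is relative parameter change < tol.  The standard error
of h^2 comes from the inverse AI matrix by the delta method.

``em_reml`` is a deliberately independent second route (classical MME-based
EM-REML) used to cross-check the AI implementation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.sparse as sp

from .pedigree import Pedigree


@dataclass
class ModelSpec:
    """Response, fixed-effect design and record->animal incidence."""

    y: np.ndarray
    X: np.ndarray
    animal_index: np.ndarray  # record -> position in the relationship structure
    n_animals: int
    fixed_names: list[str]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float).ravel()
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.animal_index = np.asarray(self.animal_index, dtype=np.int64)
        n = len(self.y)
        if self.X.shape[0] != n or len(self.animal_index) != n:
            raise ValueError("rows of y, X and animal_index must agree")
        if self.animal_index.min() < 0 or self.animal_index.max() >= self.n_animals:
            raise ValueError("record maps to an animal outside the relationship structure")


@dataclass
class VarianceComponents:
    sigma_a2: float
    sigma_e2: float
    h2: float
    se_h2: float
    converged: bool
    n_iterations: int

    @property
    def sigma_p2(self) -> float:
        return self.sigma_a2 + self.sigma_e2

    @property
    def ratio(self) -> float:
        """Shrinkage ratio sigma_e^2 / sigma_a^2 used in the MME."""
        return self.sigma_e2 / self.sigma_a2


@dataclass
class MmeSolution:
    b_hat: np.ndarray
    a_hat: np.ndarray
    fixed_names: list[str]
    condition_estimate: float


def design_matrices(
    records: pd.DataFrame, response: str, fixed_factors: tuple[str, ...]
) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Full-rank fixed-effect design: intercept + drop-first dummy coding."""
    y = np.asarray(records[response], dtype=float)
    cols = [np.ones(len(records))]
    names = ["intercept"]
    for factor in fixed_factors:
        dummies = pd.get_dummies(records[factor].astype("category"), drop_first=True)
        for level in dummies.columns:
            cols.append(dummies[level].to_numpy(dtype=float))
            names.append(f"{factor}[{level}]")
    X = np.column_stack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("fixed-effect design is rank deficient after drop-first coding")
    return y, X, names


def build_model(
    pheno: pd.DataFrame,
    ped: Pedigree,
    response: str = "phenotype",
    fixed_factors: tuple[str, ...] = ("sex", "birth_year", "farm"),
    id_col: str = "id",
) -> ModelSpec:
    """Wire a phenotype table to a pedigree-ordered relationship structure."""
    fixed = tuple(f for f in fixed_factors if f in pheno.columns)
    y, X, names = design_matrices(pheno, response, fixed)
    idx = ped.positions([str(v).strip() for v in pheno[id_col]])
    return ModelSpec(y=y, X=X, animal_index=idx, n_animals=ped.n, fixed_names=names)


def build_H_inverse(
    A_inv,
    genotyped_positions,
    G_inv: np.ndarray,
    A22_inv: np.ndarray,
) -> np.ndarray:
    """H^-1 = A^-1 + [0 0; 0 G^-1 - A22^-1] over the genotyped block (dense).

    ``genotyped_positions`` give each genotyped animal's row in the pedigree
    ordering, listed in the order of G's rows.
    """
    idx = np.asarray(genotyped_positions, dtype=np.int64)
    H_inv = np.asarray(A_inv.todense() if sp.issparse(A_inv) else A_inv, dtype=float).copy()
    if idx.size:
        G_inv = np.asarray(G_inv, dtype=float)
        A22_inv = np.asarray(A22_inv, dtype=float)
        if G_inv.shape != (idx.size, idx.size) or A22_inv.shape != G_inv.shape:
            raise ValueError("G^-1 / A22^-1 dimensions do not match the genotyped set")
        H_inv[np.ix_(idx, idx)] += G_inv - A22_inv
    return 0.5 * (H_inv + H_inv.T)


def relationship_from_inverse(K_inv) -> np.ndarray:
    """Dense K from its (sparse or dense) inverse via a symmetric solve."""
    Kd = np.asarray(K_inv.todense() if sp.issparse(K_inv) else K_inv, dtype=float)
    c, low = la.cho_factor(Kd, check_finite=False)
    K = la.cho_solve((c, low), np.eye(Kd.shape[0]), check_finite=False)
    return 0.5 * (K + K.T)


class _RotatedReml:
    """Shared machinery for REML in the eigenbasis of M = Z_inc K Z_inc'."""

    def __init__(self, model: ModelSpec, K: np.ndarray):
        M = K[np.ix_(model.animal_index, model.animal_index)]
        lam, U = la.eigh(M)
        self.lam = np.clip(lam, 0.0, None)
        self.yt = U.T @ model.y
        self.Xt = U.T @ model.X
        self.n, self.p = self.Xt.shape

    def weights(self, sa: float, se: float) -> np.ndarray:
        return 1.0 / (sa * self.lam + se)

    def stats(self, sa: float, se: float):
        """P-projected quantities for the current (sigma_a2, sigma_e2)."""
        w = self.weights(sa, se)
        WX = self.Xt * w[:, None]
        XtWX = self.Xt.T @ WX
        c = la.cho_factor(XtWX, check_finite=False)

        def P(v: np.ndarray) -> np.ndarray:
            wv = w * v
            return wv - WX @ la.cho_solve(c, self.Xt.T @ wv, check_finite=False)

        Py = P(self.yt)
        # tr(P S) for S = diag(s): sum(w s) - tr((X'WX)^-1 X'W S W X)
        def trPS(s) -> float:
            s_col = np.atleast_1d(s)[:, None] if np.ndim(s) else s
            core = WX.T @ (WX * s_col)
            return float(np.sum(w * s) - np.trace(la.cho_solve(c, core, check_finite=False)))

        return w, P, Py, trPS


def aireml(
    model: ModelSpec,
    K_inv=None,
    K: np.ndarray | None = None,
    init: tuple[float, float] | None = None,
    tol: float = 1e-8,
    max_iter: int = 50,
) -> VarianceComponents:
    """Average-information REML for (sigma_a2, sigma_e2) with EM fallback.

    Accepts either the relationship matrix ``K`` or its inverse ``K_inv``
    (A^-1 or H^-1; dense or sparse).  Raises only on structural problems;
    non-convergence is reported through the returned ``converged`` flag.
    """
    if K is None:
        if K_inv is None:
            raise ValueError("provide K or K_inv")
        K = relationship_from_inverse(K_inv)
    rot = _RotatedReml(model, np.asarray(K, dtype=float))
    vary = float(np.var(model.y))
    floor = 1e-10 * vary
    sa, se = init if init is not None else (vary / 2.0, vary / 2.0)
    n = rot.n
    converged = False
    it = 0
    AI = np.eye(2)
    for it in range(1, max_iter + 1):
        w, P, Py, trPS = rot.stats(sa, se)
        trPM = trPS(rot.lam)
        trP = trPS(1.0)
        MPy = rot.lam * Py
        yPMPy = float(Py @ MPy)
        yPPy = float(Py @ Py)
        score = np.array([-0.5 * (trPM - yPMPy), -0.5 * (trP - yPPy)])
        PMPy = P(MPy)
        PPy = P(Py)
        AI = 0.5 * np.array(
            [
                [float(MPy @ PMPy), float(MPy @ PPy)],
                [float(PMPy @ Py), float(PPy @ Py)],
            ]
        )
        AI = 0.5 * (AI + AI.T)
        new = None
        try:
            step = la.solve(AI, score, assume_a="sym")
            if np.all(np.isfinite(step)):
                # step-halve an out-of-bounds AI update instead of discarding it
                for kappa in (1.0, 0.5, 0.25, 0.125, 0.0625):
                    cand = np.array([sa, se]) + kappa * step
                    if np.all(cand > floor):
                        new = cand
                        break
        except la.LinAlgError:
            new = None
        if new is None:
            # EM fallback keeps the iterate in the parameter space
            new = np.array(
                [
                    sa + (sa * sa / n) * (yPMPy - trPM),
                    se + (se * se / n) * (yPPy - trP),
                ]
            )
        new = np.maximum(new, floor)
        rel = np.max(np.abs(new - [sa, se]) / np.maximum(np.abs([sa, se]), floor))
        sa, se = float(new[0]), float(new[1])
        if rel < tol:
            converged = True
            break
    h2 = sa / (sa + se)
    se_h2 = float("nan")
    try:
        AI_inv = la.inv(AI)
        g = np.array([se, -sa]) / (sa + se) ** 2
        var_h2 = float(g @ AI_inv @ g)
        if var_h2 >= 0:
            se_h2 = float(np.sqrt(var_h2))
    except la.LinAlgError:
        pass
    return VarianceComponents(
        sigma_a2=sa, sigma_e2=se, h2=h2, se_h2=se_h2, converged=converged, n_iterations=it
    )


def _incidence(model: ModelSpec) -> sp.csr_matrix:
    n = len(model.y)
    return sp.csr_matrix(
        (np.ones(n), (np.arange(n), model.animal_index)), shape=(n, model.n_animals)
    )


def em_reml(
    model: ModelSpec,
    K_inv,
    init: tuple[float, float] | None = None,
    tol: float = 1e-10,
    max_iter: int = 20000,
) -> VarianceComponents:
    """Classical EM-REML on the dense mixed-model equations.

    Independent of :func:`aireml` by construction (no eigenrotation, no AI
    matrix): each round solves Henderson's MME at the current variance ratio
    and updates sigma_a2 = (u' K^-1 u + sigma_e2 tr(K^-1 C^uu)) / q,
    sigma_e2 = (y'y - b'X'y - u'Z'y) / (n - rank(X)).  Slow but transparent;
    intended for modest problem sizes.
    """
    y, X = model.y, model.X
    n, p = X.shape
    q = model.n_animals
    Kinv = np.asarray(K_inv.todense() if sp.issparse(K_inv) else K_inv, dtype=float)
    Z = _incidence(model).toarray()
    XtX, XtZ, ZtZ = X.T @ X, X.T @ Z, Z.T @ Z
    Xty, Zty, yty = X.T @ y, Z.T @ y, float(y @ y)
    vary = float(np.var(y))
    sa, se = init if init is not None else (vary / 2.0, vary / 2.0)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        ratio = se / sa
        C = np.block([[XtX, XtZ], [XtZ.T, ZtZ + Kinv * ratio]])
        rhs = np.concatenate([Xty, Zty])
        C_inv = la.inv(C)
        sol = C_inv @ rhs
        b, u = sol[:p], sol[p:]
        Cuu = C_inv[p:, p:]
        sa_new = float(u @ Kinv @ u + se * np.trace(Kinv @ Cuu)) / q
        se_new = float(yty - b @ Xty - u @ Zty) / (n - p)
        rel = max(abs(sa_new - sa) / max(sa, 1e-12), abs(se_new - se) / max(se, 1e-12))
        sa, se = sa_new, se_new
        if rel < tol:
            converged = True
            break
    h2 = sa / (sa + se)
    return VarianceComponents(
        sigma_a2=sa, sigma_e2=se, h2=h2, se_h2=float("nan"),
        converged=converged, n_iterations=it,
    )


def solve_mme(model: ModelSpec, K_inv, vc: VarianceComponents) -> MmeSolution:
    """Henderson's mixed-model equations at fixed variance components.

    [X'X  X'Z          ] [b]   [X'y]
    [Z'X  Z'Z + K^-1 r ] [a] = [Z'y],   r = sigma_e2 / sigma_a2.

    Fixed effects are identified by the full-rank drop-first coding built in
    :func:`design_matrices`.  Returns estimates for every animal in the
    relationship structure, phenotyped or not.
    """
    if vc.sigma_a2 <= 0 or vc.sigma_e2 <= 0:
        raise ValueError("variance components must be positive to assemble the MME")
    y, X = model.y, model.X
    n, p = X.shape
    q = model.n_animals
    Kinv = np.asarray(K_inv.todense() if sp.issparse(K_inv) else K_inv, dtype=float)
    idx = model.animal_index
    XtZ = np.zeros((p, q))
    np.add.at(XtZ.T, idx, X)
    ZtZ_diag = np.bincount(idx, minlength=q).astype(float)
    Zty = np.bincount(idx, weights=y, minlength=q)
    C = np.empty((p + q, p + q))
    C[:p, :p] = X.T @ X
    C[:p, p:] = XtZ
    C[p:, :p] = XtZ.T
    C[p:, p:] = Kinv * vc.ratio
    C[p + np.arange(q), p + np.arange(q)] += ZtZ_diag
    rhs = np.concatenate([X.T @ y, Zty])
    try:
        cf = la.cho_factor(C, check_finite=False)
        sol = la.cho_solve(cf, rhs, check_finite=False)
        cond = float(np.abs(np.diag(cf[0])).max() / np.abs(np.diag(cf[0])).min()) ** 2
    except la.LinAlgError as exc:
        raise ValueError("singular MME coefficient matrix") from exc
    return MmeSolution(
        b_hat=sol[:p], a_hat=sol[p:], fixed_names=model.fixed_names,
        condition_estimate=cond,
    )
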