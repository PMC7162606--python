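"""Mixed-model machinery: MME solvers, AI-REML, pedigree BLUP.

The animal model is y = Xb + Zu + e with u ~ N(0, sigma2_u * K) where K is
the pedigree relationship A or the single-step hybrid H.  Multi-trait
evaluation stacks three population-specific traits (Line1, Line2, F1) with
u3 ~ N(0, G0 (x) K) and a diagonal residual covariance (traits are recorded
on different animals, so residual covariances are inestimable and fixed at
zero).

REML is computed by maximising the restricted likelihood of the marginal
phenotype covariance V(theta) over recorded animals with an
average-information algorithm (EM-free; step halving keeps iterates inside
the parameter space).  This is algebraically the same objective the
MME-based AI-REML programs maximise, and is tractable dense at the record
counts used here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "VarianceComponents",
    "MMESolution",
    "build_fixed_design",
    "solve_single_trait",
    "solve_multi_trait",
    "reml_estimate",
    "pedigree_blup_ebv",
]

TRAIT_ORDER = ("Line1", "Line2", "F1")


@dataclass
class VarianceComponents:
    """Estimated (co)variance components and derived genetic parameters."""

    sigma2_u: np.ndarray  # per-trait additive variances
    sigma2_e: np.ndarray  # per-trait residual variances
    G0: np.ndarray | None = None  # 3x3 additive covariance (multi-trait)
    R0: np.ndarray | None = None  # diagonal residual covariance
    h2: np.ndarray | None = None
    r_g: np.ndarray | None = None  # genetic correlation matrix
    se_h2: np.ndarray | None = None
    se_r_g: np.ndarray | None = None
    n_iter: int = 0
    converged: bool = False
    boundary: bool = False
    loglik: float = np.nan

    @property
    def vp(self) -> np.ndarray:
        return self.sigma2_u + self.sigma2_e

    def lam(self, trait: int = 0) -> float:
        return float(self.sigma2_e[trait] / self.sigma2_u[trait])


@dataclass
class MMESolution:
    """Solutions of the mixed-model equations."""

    fixed: pd.Series
    gebv: pd.Series | pd.DataFrame  # indexed by animal id
    convergence: dict = field(default_factory=dict)


def build_fixed_design(
    df: pd.DataFrame, effects: tuple[str, ...]
) -> tuple[np.ndarray, list[str]]:
    """Intercept plus drop-first dummy coding for each categorical effect."""
    cols = [np.ones(len(df))]
    names = ["mean"]
    for eff in effects:
        levels = pd.unique(df[eff])
        for lev in levels[1:]:
            cols.append((df[eff] == lev).to_numpy(dtype=float))
            names.append(f"{eff}:{lev}")
    return np.column_stack(cols), names


def solve_single_trait(
    records: pd.DataFrame,
    ped_labels: np.ndarray,
    K_inv,
    varcomp: VarianceComponents | float,
    fixed_effects: tuple[str, ...] = ("sex", "population"),
    response: str = "phenotype",
) -> MMESolution:
    """Solve the single-trait animal-model MME.

    ``K_inv`` is the sparse pedigree A^-1 or a dense H^-1 over
    ``ped_labels``; ``varcomp`` supplies lambda = sigma2_e / sigma2_u (a
    bare float is accepted as lambda).  Animals without records receive
    breeding values through relationships.
    """
    lam = varcomp if isinstance(varcomp, (int, float)) else varcomp.lam()
    pos = {int(v): k for k, v in enumerate(ped_labels)}
    ridx = np.array([pos[int(i)] for i in records["id"]])
    y = records[response].to_numpy(dtype=float)
    X, fnames = build_fixed_design(records, fixed_effects)
    n_ped = len(ped_labels)
    p = X.shape[1]
    XtX = X.T @ X
    XtZ = np.zeros((p, n_ped))  # scatter-add: records onto animals
    np.add.at(XtZ.T, ridx, X)
    ztz = np.bincount(ridx, minlength=n_ped).astype(float)
    rhs1 = X.T @ y
    rhs2 = np.zeros(n_ped)
    np.add.at(rhs2, ridx, y)
    if sp.issparse(K_inv):
        # random-mating pedigrees factor poorly (fill-in), so the SPD MME is
        # solved by Jacobi-preconditioned conjugate gradients instead
        C22 = (sp.diags(ztz) + lam * K_inv).tocsr()
        sol = _solve_mme_cg(XtX, XtZ, C22, rhs1, rhs2)
        b, u = sol[:p], sol[p:]
        resid = np.linalg.norm(
            np.concatenate(
                [XtX @ b + XtZ @ u - rhs1, XtZ.T @ b + C22 @ u - rhs2]
            )
        )
    else:
        C = np.zeros((p + n_ped, p + n_ped))
        C[:p, :p] = XtX
        C[:p, p:] = XtZ
        C[p:, :p] = XtZ.T
        C[p:, p:] = lam * np.asarray(K_inv)
        C[p:, p:][np.diag_indices(n_ped)] += ztz
        rhs = np.concatenate([rhs1, rhs2])
        sol = _solve_dense_sym(C, rhs)
        resid = np.linalg.norm(C @ sol - rhs)
    rel = resid / max(
        np.linalg.norm(np.concatenate([rhs1, rhs2])), 1e-300
    )
    return MMESolution(
        fixed=pd.Series(sol[:p], index=fnames),
        gebv=pd.Series(sol[p:], index=np.asarray(ped_labels), name="gebv"),
        convergence={"relative_residual": float(rel)},
    )


def _solve_mme_cg(
    XtX: np.ndarray,
    XtZ: np.ndarray,
    C22: sp.spmatrix,
    rhs1: np.ndarray,
    rhs2: np.ndarray,
    rtol: float = 1e-10,
) -> np.ndarray:
    p, n = XtZ.shape
    diag = np.concatenate([np.maximum(np.diag(XtX), 1e-12), C22.diagonal()])
    Minv = 1.0 / diag

    def matvec(x):
        b, u = x[:p], x[p:]
        return np.concatenate(
            [XtX @ b + XtZ @ u, XtZ.T @ b + C22 @ u]
        )

    A = spla.LinearOperator((p + n, p + n), matvec=matvec)
    M = spla.LinearOperator((p + n, p + n), matvec=lambda x: Minv * x)
    rhs = np.concatenate([rhs1, rhs2])
    sol, info = spla.cg(A, rhs, rtol=rtol, atol=0.0, maxiter=20 * (p + n), M=M)
    if info != 0:
        raise np.linalg.LinAlgError(f"MME conjugate gradient failed (info={info})")
    return sol


def _solve_dense_sym(C: np.ndarray, rhs: np.ndarray) -> np.ndarray:
    try:
        c = sla.cho_factor(C, lower=True, check_finite=False)
        return sla.cho_solve(c, rhs, check_finite=False)
    except sla.LinAlgError:
        # singular fixed-effects block (confounded levels): minimum-norm fix
        sol, *_ = np.linalg.lstsq(C, rhs, rcond=None)
        return sol


def solve_multi_trait(
    records: pd.DataFrame,
    ped_labels: np.ndarray,
    K_inv,
    varcomp: VarianceComponents,
    fixed_effects: tuple[str, ...] = ("sex",),
    response: str = "phenotype",
    trait_col: str = "trait",
) -> MMESolution:
    """Three-trait animal model: records carry a trait index 0..T-1.

    Fixed effects are nested within trait; u is ordered trait-major
    (all animals trait 0, then trait 1, ...).  Returns a DataFrame of
    per-animal, per-trait breeding values.
    """
    G0 = np.asarray(varcomp.G0, dtype=float)
    R0 = np.asarray(varcomp.R0, dtype=float)
    T = G0.shape[0]
    G0_inv = _pd_inverse_with_bending(G0)
    r_diag = np.diag(R0)
    pos = {int(v): k for k, v in enumerate(ped_labels)}
    ridx = np.array([pos[int(i)] for i in records["id"]])
    trait = records[trait_col].to_numpy(dtype=int)
    y = records[response].to_numpy(dtype=float)
    n_ped = len(ped_labels)
    rinv = 1.0 / r_diag[trait]

    X_blocks, fnames = [], []
    for t in range(T):
        sub = records[trait == t]
        Xt, nt = build_fixed_design(sub, fixed_effects)
        X_blocks.append(Xt)
        fnames += [f"t{t}:{n}" for n in nt]
    p_per = [b.shape[1] for b in X_blocks]
    p = sum(p_per)
    nrec = len(records)
    X = np.zeros((nrec, p))
    off = 0
    for t in range(T):
        X[trait == t, off : off + p_per[t]] = X_blocks[t]
        off += p_per[t]

    # Z maps records to (trait-major) genetic effects
    ucol = trait * n_ped + ridx
    Z = sp.csr_matrix(
        (np.ones(nrec), (np.arange(nrec), ucol)), shape=(nrec, T * n_ped)
    )
    Rinv = sp.diags(rinv)
    XtRX = X.T @ (X * rinv[:, None])
    XtRZ = (Z.T @ (X * rinv[:, None])).T
    ZtRZ = (Z.T @ Rinv @ Z).toarray()
    Kinv_dense = np.asarray(K_inv.todense() if sp.issparse(K_inv) else K_inv)
    Ku = np.kron(G0_inv, Kinv_dense)
    C = np.zeros((p + T * n_ped, p + T * n_ped))
    C[:p, :p] = XtRX
    C[:p, p:] = XtRZ
    C[p:, :p] = XtRZ.T
    C[p:, p:] = ZtRZ + Ku
    rhs = np.concatenate([X.T @ (y * rinv), Z.T @ (y * rinv)])
    sol = _solve_dense_sym(C, rhs)
    rel = np.linalg.norm(C @ sol - rhs) / max(np.linalg.norm(rhs), 1e-300)
    u = sol[p:].reshape(T, n_ped).T
    return MMESolution(
        fixed=pd.Series(sol[:p], index=fnames),
        gebv=pd.DataFrame(
            u, index=np.asarray(ped_labels), columns=list(TRAIT_ORDER)[:T]
        ),
        convergence={"relative_residual": float(rel)},
    )


def _pd_inverse_with_bending(M: np.ndarray) -> np.ndarray:
    w, V = np.linalg.eigh(M)
    floor = max(M.trace() * 1e-8, 1e-12)
    if w[0] < floor:
        warnings.warn(
            f"covariance matrix bent: smallest eigenvalue {w[0]:.3e}",
            stacklevel=2,
        )
        w = np.maximum(w, floor)
    return (V / w) @ V.T


# ---------------------------------------------------------------------------
# REML


def _variance_masks(A_rr: np.ndarray, trait: np.ndarray, T: int):
    """dV/dtheta masks for V = sum g0_ts (A o I_t I_s') + sum r_t diag(I_t)."""
    n = len(trait)
    ind = [(trait == t).astype(float) for t in range(T)]
    derivs = []
    labels = []
    for t in range(T):
        for s in range(t, T):
            mask = np.outer(ind[t], ind[s])
            if t != s:
                mask = mask + mask.T
            derivs.append(A_rr * mask)
            labels.append(("g", t, s))
    for t in range(T):
        derivs.append(np.diag(ind[t]))
        labels.append(("r", t))
    return derivs, labels


def _assemble_V(theta, derivs):
    V = np.zeros_like(derivs[0])
    for th, dV in zip(theta, derivs):
        V += th * dV
    return V


def _theta_valid(theta, labels, T) -> bool:
    G0 = np.zeros((T, T))
    R = np.zeros(T)
    for th, lab in zip(theta, labels):
        if lab[0] == "g":
            _, t, s = lab
            G0[t, s] = G0[s, t] = th
        else:
            R[lab[1]] = th
    if np.any(R <= 0) or np.any(np.diag(G0) <= 0):
        return False
    try:
        np.linalg.cholesky(G0 + np.eye(T) * G0.trace() * 1e-10)
    except np.linalg.LinAlgError:
        return False
    return True


def _restricted_loglik(theta, derivs, X, y):
    V = _assemble_V(theta, derivs)
    try:
        c = sla.cho_factor(V, lower=True, check_finite=False)
    except sla.LinAlgError:
        return -np.inf, None, None
    logdetV = 2.0 * np.sum(np.log(np.diag(c[0])))
    Vinv_y = sla.cho_solve(c, y, check_finite=False)
    Vinv_X = sla.cho_solve(c, X, check_finite=False)
    XtVinvX = X.T @ Vinv_X
    sign, logdetX = np.linalg.slogdet(XtVinvX)
    if sign <= 0:
        return -np.inf, None, None
    beta = np.linalg.solve(XtVinvX, X.T @ Vinv_y)
    Py = Vinv_y - Vinv_X @ beta
    ll = -0.5 * (logdetV + logdetX + y @ Py)
    Vinv = sla.cho_solve(c, np.eye(len(y)), check_finite=False)
    P = Vinv - Vinv_X @ np.linalg.solve(XtVinvX, Vinv_X.T)
    return ll, P, Py


def _score_vec(derivs, P, Py) -> np.ndarray:
    """REML score dl/dtheta_i = -0.5 [tr(P dVi) - y'P dVi P y]."""
    return np.array(
        [-0.5 * (np.sum(P * dV) - Py @ (dV @ Py)) for dV in derivs]
    )


def _maximise_restricted(theta0, labels, T, derivs, X, y, max_iter, tol):
    """Quasi-Newton maximisation of the restricted log-likelihood over the
    Cholesky factor of G0 and log residual variances (no PSD boundary)."""
    import scipy.optimize as opt

    tril = [(a, b) for a in range(T) for b in range(a + 1)]
    nL = len(tril)
    gpos = {}
    rpos = {}
    for i, lab in enumerate(labels):
        if lab[0] == "g":
            gpos[(lab[1], lab[2])] = i
        else:
            rpos[lab[1]] = i

    def unpack(phi):
        L = np.zeros((T, T))
        for k, (a, b) in enumerate(tril):
            L[a, b] = phi[k]
        G0 = L @ L.T
        theta = np.empty(len(labels))
        for (t, s), i in gpos.items():
            theta[i] = G0[t, s]
        for t, i in rpos.items():
            theta[i] = np.exp(phi[nL + t])
        return theta, L

    def negll(phi):
        theta, L = unpack(phi)
        ll, P, Py = _restricted_loglik(theta, derivs, X, y)
        if not np.isfinite(ll):
            return 1e12, np.zeros_like(phi)
        s = _score_vec(derivs, P, Py)
        g = np.zeros_like(phi)
        for k, (a, b) in enumerate(tril):
            acc = 0.0
            for (t, u), i in gpos.items():
                if t == u:
                    d = 2.0 * L[t, b] if t == a else 0.0
                else:
                    d = (L[u, b] if t == a else 0.0) + (
                        L[t, b] if u == a else 0.0
                    )
                acc += s[i] * d
            g[k] = acc
        for t, i in rpos.items():
            g[nL + t] = s[i] * theta[i]
        return -ll, -g

    G0s = np.zeros((T, T))
    rs = np.zeros(T)
    for (t, s), i in gpos.items():
        G0s[t, s] = G0s[s, t] = theta0[i]
    for t, i in rpos.items():
        rs[t] = theta0[i]
    L0 = np.linalg.cholesky(G0s + np.eye(T) * max(G0s.trace(), 1e-12) * 1e-9)
    phi0 = np.concatenate([[L0[a, b] for a, b in tril], np.log(rs)])
    res = opt.minimize(
        negll, phi0, jac=True, method="L-BFGS-B",
        options={"maxiter": max_iter, "ftol": 1e-13, "gtol": 1e-7},
    )
    theta, _ = unpack(res.x)
    return theta, -float(res.fun), int(res.nit), bool(res.success)


def reml_estimate(
    records: pd.DataFrame,
    A_rr: np.ndarray,
    fixed_effects: tuple[str, ...] = ("sex",),
    response: str = "phenotype",
    trait_col: str | None = None,
    n_traits: int | None = None,
    max_iter: int = 200,
    tol: float = 1e-8,
    start_h2: float = 0.33,
) -> VarianceComponents:
    """AI-REML for the single- or multi-trait animal model.

    ``A_rr`` is the (pedigree) relationship among the recorded animals, in
    record order.  With ``trait_col`` given, fits the T-trait model with a
    full additive covariance G0 and diagonal residual R0; fixed effects are
    nested within trait.
    """
    y = records[response].to_numpy(dtype=float)
    n = len(y)
    A_rr = np.asarray(A_rr, dtype=float)
    if A_rr.shape != (n, n):
        raise ValueError("A_rr must be n_records x n_records in record order")
    if trait_col is None:
        trait = np.zeros(n, dtype=int)
        T = 1
        X, _ = build_fixed_design(records, fixed_effects)
    else:
        trait = records[trait_col].to_numpy(dtype=int)
        T = n_traits or int(trait.max()) + 1
        blocks, p_per = [], []
        for t in range(T):
            Xt, _ = build_fixed_design(records[trait == t], fixed_effects)
            blocks.append(Xt)
            p_per.append(Xt.shape[1])
        X = np.zeros((n, sum(p_per)))
        off = 0
        for t in range(T):
            X[trait == t, off : off + p_per[t]] = blocks[t]
            off += p_per[t]

    derivs, labels = _variance_masks(A_rr, trait, T)
    # starting values: split each trait's phenotypic variance by start_h2
    vart = np.array([max(np.var(y[trait == t]), 1e-10) for t in range(T)])
    theta = []
    for lab in labels:
        if lab[0] == "g":
            _, t, s = lab
            if t == s:
                theta.append(start_h2 * vart[t])
            else:
                theta.append(0.5 * start_h2 * np.sqrt(vart[t] * vart[s]))
        else:
            theta.append((1 - start_h2) * vart[lab[1]])
    theta = np.array(theta)

    ll, P, Py = _restricted_loglik(theta, derivs, X, y)
    if not np.isfinite(ll):
        raise RuntimeError("REML starting values give singular V")

    # The restricted likelihood is maximised in a boundary-free
    # parameterisation (G0 = L L' with free Cholesky entries, log residual
    # variances): genetic correlations of selected-line data sit at or very
    # near |r_g| = 1, where naive AI updates stall on the PSD boundary.
    # The average-information matrix is evaluated at the optimum for
    # standard errors.
    theta, ll, n_eval, converged = _maximise_restricted(
        theta, labels, T, derivs, X, y, max_iter=max_iter, tol=tol
    )
    it = n_eval
    _, P, Py = _restricted_loglik(theta, derivs, X, y)
    q = len(theta)
    w = [dV @ Py for dV in derivs]
    Pw = [P @ wi for wi in w]
    AI = np.empty((q, q))
    for i in range(q):
        for j in range(i, q):
            AI[i, j] = AI[j, i] = 0.5 * (w[i] @ Pw[j])
    if not converged:
        warnings.warn("REML did not converge; returning last iterate", stacklevel=2)

    G0 = np.zeros((T, T))
    R = np.zeros(T)
    for th, lab in zip(theta, labels):
        if lab[0] == "g":
            _, t, s = lab
            G0[t, s] = G0[s, t] = th
        else:
            R[lab[1]] = th
    boundary = bool(np.any(np.diag(G0) < 1e-4 * vart) or np.any(R < 1e-4 * vart))
    su = np.diag(G0).copy()
    h2 = su / (su + R)
    denom = np.sqrt(np.outer(su, su))
    r_g = G0 / np.where(denom > 0, denom, np.inf)
    np.fill_diagonal(r_g, 1.0)

    se_h2 = se_rg = None
    try:
        cov_theta = np.linalg.inv(AI + np.eye(len(theta)) * AI.trace() * 1e-10)
        se_h2, se_rg = _delta_method_se(theta, labels, cov_theta, T)
    except np.linalg.LinAlgError:
        pass
    return VarianceComponents(
        sigma2_u=su,
        sigma2_e=R,
        G0=G0 if T > 1 else None,
        R0=np.diag(R) if T > 1 else None,
        h2=h2,
        r_g=r_g if T > 1 else None,
        se_h2=se_h2,
        se_r_g=se_rg,
        n_iter=it,
        converged=converged,
        boundary=boundary,
        loglik=float(ll),
    )


def _delta_method_se(theta, labels, cov, T):
    idx = {lab: k for k, lab in enumerate(labels)}
    se_h2 = np.zeros(T)
    for t in range(T):
        ig, ir = idx[("g", t, t)], idx[("r", t)]
        g, r = theta[ig], theta[ir]
        vp = g + r
        grad = np.zeros(len(theta))
        grad[ig] = r / vp**2
        grad[ir] = -g / vp**2
        se_h2[t] = np.sqrt(max(grad @ cov @ grad, 0.0))
    se_rg = np.zeros((T, T))
    for t in range(T):
        for s in range(t + 1, T):
            ic = idx[("g", t, s)]
            it_, is_ = idx[("g", t, t)], idx[("g", s, s)]
            c, gt, gs = theta[ic], theta[it_], theta[is_]
            denom = np.sqrt(gt * gs)
            grad = np.zeros(len(theta))
            grad[ic] = 1.0 / denom
            grad[it_] = -0.5 * c / (denom * gt)
            grad[is_] = -0.5 * c / (denom * gs)
            se_rg[t, s] = se_rg[s, t] = np.sqrt(max(grad @ cov @ grad, 0.0))
    return se_h2, se_rg


def pedigree_blup_ebv(
    records: pd.DataFrame,
    ped_labels: np.ndarray,
    A_inv: sp.spmatrix,
    sigma2_u: float,
    sigma2_e: float,
    fixed_effects: tuple[str, ...] = ("sex",),
    response: str = "phenotype",
) -> pd.Series:
    """Pedigree BLUP EBVs at fixed (true) variance components.

    Used for within-line truncation selection during the breeding
    simulation.
    """
    lam = sigma2_e / sigma2_u
    sol = solve_single_trait(
        records, ped_labels, A_inv, lam, fixed_effects=fixed_effects,
        response=response,
    )
    return sol.gebv
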