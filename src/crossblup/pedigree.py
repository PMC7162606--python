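"""Pedigree utilities: ordering, inbreeding, Henderson's sparse A-inverse.

Pedigrees are pandas DataFrames with integer columns ``id``, ``sire``,
``dam`` (0 = unknown parent).  Internally animals are handled as 0-based
indices into the topologically ordered pedigree (-1 = unknown).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.sparse as sp

try:
    from numba import njit

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*a, **k):
        def deco(f):
            return f
        return deco if not (a and callable(a[0])) else a[0]

__all__ = [
    "PedigreeError",
    "topological_order",
    "parent_indices",
    "inbreeding_from_indices",
    "inbreeding",
    "a_inverse_from_indices",
    "a_inverse",
    "mendelian_variances",
    "tabular_A",
    "a_submatrix",
    "truncate_generations",
]


class PedigreeError(ValueError):
    pass


def topological_order(ped: pd.DataFrame) -> pd.DataFrame:
    """Return the pedigree reordered parents-before-offspring.

    Raises :class:`PedigreeError` on cycles (an animal its own ancestor),
    naming the ids involved.
    """
    ids = ped["id"].to_numpy()
    if len(np.unique(ids)) != len(ids):
        raise PedigreeError("duplicate ids in pedigree")
    pos = {int(i): k for k, i in enumerate(ids)}
    sire = ped["sire"].to_numpy()
    dam = ped["dam"].to_numpy()
    n = len(ids)
    state = np.zeros(n, dtype=np.int8)  # 0 unvisited, 1 in-stack, 2 done
    order: list[int] = []
    for start in range(n):
        if state[start]:
            continue
        stack = [(start, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                state[node] = 2
                order.append(node)
                continue
            if state[node] == 2:
                continue
            if state[node] == 1:
                continue
            state[node] = 1
            stack.append((node, True))
            for p in (sire[node], dam[node]):
                if p == 0:
                    continue
                k = pos.get(int(p))
                if k is None:
                    raise PedigreeError(f"parent {p} of {ids[node]} not in pedigree")
                if state[k] == 1:
                    raise PedigreeError(
                        f"pedigree cycle involving ids {ids[k]} and {ids[node]}"
                    )
                if state[k] == 0:
                    stack.append((k, False))
    return ped.iloc[order].reset_index(drop=True)


def parent_indices(ped: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    """0-based (sire, dam) index arrays for an ordered pedigree; -1 unknown."""
    pos = {int(i): k for k, i in enumerate(ped["id"].to_numpy())}
    def idx(col):
        out = np.empty(len(ped), dtype=np.int64)
        for k, p in enumerate(ped[col].to_numpy()):
            if p == 0:
                out[k] = -1
            else:
                j = pos.get(int(p), -2)
                if j == -2:
                    raise PedigreeError(f"parent {p} missing from pedigree")
                if j >= k:
                    raise PedigreeError(
                        "pedigree not ordered parents-before-offspring"
                    )
                out[k] = j
        return out
    return idx("sire"), idx("dam")


@njit(cache=False)
def _inbreeding_ldl(sire: np.ndarray, dam: np.ndarray, F: np.ndarray, start: int):
    """Inbreeding via the A = L D L' identity: A_ii = sum_j L_ij^2 D_j.

    For each animal the ancestor-contribution vector L is accumulated by a
    downward scan (parents receive half the descendant's coefficient), and
    D_j uses the already-computed parental F.  Entries before ``start`` in F
    are trusted as precomputed (incremental use during simulation).
    """
    n = sire.shape[0]
    L = np.zeros(n)
    for i in range(start, n):
        if sire[i] < 0 or dam[i] < 0:
            F[i] = 0.0
            continue
        L[i] = 1.0
        aii = 0.0
        for j in range(i, -1, -1):
            lj = L[j]
            if lj == 0.0:
                continue
            L[j] = 0.0
            s, d = sire[j], dam[j]
            fs = F[s] if s >= 0 else -1.0
            fd = F[d] if d >= 0 else -1.0
            aii += lj * lj * (0.5 - 0.25 * (fs + fd))
            if s >= 0:
                L[s] += 0.5 * lj
            if d >= 0:
                L[d] += 0.5 * lj
        F[i] = aii - 1.0
    return F


def inbreeding_from_indices(
    sire: np.ndarray,
    dam: np.ndarray,
    F_prefix: np.ndarray | None = None,
) -> np.ndarray:
    """Inbreeding coefficients; ``F_prefix`` (if given) is reused for the
    leading animals and only the remainder is computed."""
    n = len(sire)
    F = np.zeros(n)
    start = 0
    if F_prefix is not None:
        start = len(F_prefix)
        F[:start] = F_prefix
    return _inbreeding_ldl(
        np.ascontiguousarray(sire, dtype=np.int64),
        np.ascontiguousarray(dam, dtype=np.int64),
        F,
        start,
    )


def inbreeding(ped: pd.DataFrame) -> pd.Series:
    """Per-individual inbreeding coefficient F (founders 0)."""
    ped = topological_order(ped)
    s, d = parent_indices(ped)
    F = inbreeding_from_indices(s, d)
    return pd.Series(F, index=ped["id"].to_numpy(), name="F")


def a_inverse_from_indices(
    sire: np.ndarray, dam: np.ndarray, F: np.ndarray | None = None
) -> sp.csr_matrix:
    """Henderson's sparse A^-1 with Mendelian-sampling variances from F."""
    n = len(sire)
    alpha = 1.0 / mendelian_variances(sire, dam, F)
    rows, cols, vals = [], [], []
    i = np.arange(n)
    rows.append(i); cols.append(i); vals.append(alpha)
    for par in (sire, dam):
        m = par >= 0
        rows.append(i[m]); cols.append(par[m]); vals.append(-0.5 * alpha[m])
        rows.append(par[m]); cols.append(i[m]); vals.append(-0.5 * alpha[m])
        rows.append(par[m]); cols.append(par[m]); vals.append(0.25 * alpha[m])
    m2 = (sire >= 0) & (dam >= 0)
    rows.append(sire[m2]); cols.append(dam[m2]); vals.append(0.25 * alpha[m2])
    rows.append(dam[m2]); cols.append(sire[m2]); vals.append(0.25 * alpha[m2])
    Ainv = sp.coo_matrix(
        (np.concatenate(vals), (np.concatenate(rows), np.concatenate(cols))),
        shape=(n, n),
    )
    return Ainv.tocsr()


def a_inverse(ped: pd.DataFrame) -> tuple[sp.csr_matrix, np.ndarray]:
    """(sparse A^-1, ordered id labels) for a pedigree DataFrame."""
    ped = topological_order(ped)
    s, d = parent_indices(ped)
    return a_inverse_from_indices(s, d), ped["id"].to_numpy()


def tabular_A(sire: np.ndarray, dam: np.ndarray) -> np.ndarray:
    """Dense numerator relationship matrix by the tabular recursion.

    Quadratic memory; intended for pedigrees up to a few thousand animals.
    """
    n = len(sire)
    if n > 20000:
        raise MemoryError("tabular_A is dense; pedigree too large")
    A = np.zeros((n, n))
    for i in range(n):
        s, d = sire[i], dam[i]
        row = np.zeros(i)
        if s >= 0:
            row += 0.5 * A[s, :i]
        if d >= 0:
            row += 0.5 * A[d, :i]
        A[i, :i] = row
        A[:i, i] = row
        A[i, i] = 1.0 + (0.5 * A[s, d] if (s >= 0 and d >= 0) else 0.0)
    return A


@njit(cache=False)
def _a_times_dense(sire, dam, D, V):
    """A @ V via the gene-flow decomposition A = T D T' (Colleau 2002).

    T = (I - P)^-1 with P the half-parent incidence; both triangular solves
    are plain substitutions, so the cost is O(n_animals * n_columns) with no
    fill-in.
    """
    n, m = V.shape
    W = V.copy()
    # W <- T' V : row i collects half of each child's row (descending)
    for i in range(n - 1, -1, -1):
        s, d_ = sire[i], dam[i]
        if s >= 0:
            for j in range(m):
                W[s, j] += 0.5 * W[i, j]
        if d_ >= 0:
            for j in range(m):
                W[d_, j] += 0.5 * W[i, j]
    # W <- D W
    for i in range(n):
        for j in range(m):
            W[i, j] *= D[i]
    # W <- T W (ascending)
    for i in range(n):
        s, d_ = sire[i], dam[i]
        if s >= 0:
            for j in range(m):
                W[i, j] += 0.5 * W[s, j]
        if d_ >= 0:
            for j in range(m):
                W[i, j] += 0.5 * W[d_, j]
    return W


def mendelian_variances(
    sire: np.ndarray, dam: np.ndarray, F: np.ndarray | None = None
) -> np.ndarray:
    """Per-animal Mendelian-sampling variances from parental inbreeding."""
    if F is None:
        F = inbreeding_from_indices(sire, dam)
    n = len(sire)
    Fs = np.where(sire >= 0, F[np.maximum(sire, 0)], 0.0)
    Fd = np.where(dam >= 0, F[np.maximum(dam, 0)], 0.0)
    both = (sire >= 0) & (dam >= 0)
    one_s = (sire >= 0) & ~both
    one_d = (dam >= 0) & ~both
    dvar = np.ones(n)
    dvar[both] = 0.5 - 0.25 * (Fs[both] + Fd[both])
    dvar[one_s] = 0.75 - 0.25 * Fs[one_s]
    dvar[one_d] = 0.75 - 0.25 * Fd[one_d]
    return dvar


def a_submatrix(ped: pd.DataFrame, ids: np.ndarray) -> pd.DataFrame:
    """A restricted to ``ids`` without forming the dense n x n matrix."""
    ped = topological_order(ped)
    labels = ped["id"].to_numpy()
    pos = {int(v): k for k, v in enumerate(labels)}
    try:
        sel = np.array([pos[int(i)] for i in ids])
    except KeyError as e:
        raise PedigreeError(f"id {e} not in pedigree") from None
    s, d = parent_indices(ped)
    D = mendelian_variances(s, d)
    V = np.zeros((len(labels), len(sel)))
    V[sel, np.arange(len(sel))] = 1.0
    cols = _a_times_dense(s, d, D, V)
    sub = cols[sel, :]
    sub = 0.5 * (sub + sub.T)
    return pd.DataFrame(sub, index=np.asarray(ids), columns=np.asarray(ids))


def truncate_generations(
    ped: pd.DataFrame, anchor_ids: np.ndarray, n_generations: int = 5
) -> pd.DataFrame:
    """Restrict a pedigree to ``anchor_ids`` plus up to ``n_generations`` of
    ancestors; parents outside the kept set become unknown (0)."""
    ped = topological_order(ped)
    pos = {int(v): k for k, v in enumerate(ped["id"].to_numpy())}
    s, d = parent_indices(ped)
    keep = set()
    frontier = {pos[int(i)] for i in anchor_ids}
    for _ in range(n_generations + 1):
        keep |= frontier
        nxt = set()
        for k in frontier:
            for p in (s[k], d[k]):
                if p >= 0 and p not in keep:
                    nxt.add(int(p))
        frontier = nxt
        if not frontier:
            break
    kept = ped.iloc[sorted(keep)].copy()
    kept_ids = set(kept["id"].astype(int))
    for col in ("sire", "dam"):
        vals = kept[col].astype(int)
        kept[col] = np.where(vals.isin(kept_ids), vals, 0)
    return kept.reset_index(drop=True)
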