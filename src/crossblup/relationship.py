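"""Relationship matrices for single-step evaluation: A, A22, G and H^-1.

``G`` follows VanRaden: G = Z D Z' / k with Z = M - P, P holding twice the
allele frequency of the counted allele and k = 2 * sum_j p_j (1 - p_j).
``H^-1`` carries the genotyped-block correction
tau * (0.95 G + 0.05 A22)^-1 - omega * A22^-1 on top of the sparse pedigree
A^-1; blending G with a share of A22 guarantees invertibility and restores
pedigree scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as sla
import scipy.sparse as sp

from . import pedigree as pedmod
from .pedigree import PedigreeError, a_inverse, a_submatrix, inbreeding, tabular_A

__all__ = [
    "RelationshipMatrix",
    "BlendParams",
    "build_A",
    "inbreeding",
    "extract_A22",
    "allele_frequencies",
    "build_G",
    "blend_H_inverse",
    "TAU_BOUNDS",
    "OMEGA_BOUNDS",
]

TAU_BOUNDS = (0.9, 2.5)
OMEGA_BOUNDS = (0.5, 1.2)


@dataclass
class RelationshipMatrix:
    """Labeled dense symmetric relationship matrix with provenance."""

    labels: np.ndarray
    values: np.ndarray
    kind: str  # A | A22 | G | G_blended | Hinv
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels),) * 2:
            raise ValueError("matrix shape inconsistent with labels")

    def loc(self, i, j) -> float:
        li = int(np.flatnonzero(self.labels == i)[0])
        lj = int(np.flatnonzero(self.labels == j)[0])
        return float(self.values[li, lj])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass(frozen=True)
class BlendParams:
    """tau/omega scaling of the genotyped-block correction in H^-1."""

    tau: float = 1.0
    omega: float = 1.0
    g_share: float = 0.95
    a_share: float = 0.05

    def __post_init__(self):
        if abs(self.g_share + self.a_share - 1.0) > 1e-12:
            raise ValueError("g_share + a_share must equal 1")
        if not (TAU_BOUNDS[0] <= self.tau <= TAU_BOUNDS[1]):
            raise ValueError(
                f"tau={self.tau} outside grid bounds {TAU_BOUNDS}"
            )
        if not (OMEGA_BOUNDS[0] <= self.omega <= OMEGA_BOUNDS[1]):
            raise ValueError(
                f"omega={self.omega} outside grid bounds {OMEGA_BOUNDS}"
            )


def build_A(ped: pd.DataFrame) -> RelationshipMatrix:
    """Dense pedigree relationship matrix (Henderson tabular recursion)."""
    ped = pedmod.topological_order(ped)
    s, d = pedmod.parent_indices(ped)
    return RelationshipMatrix(
        labels=ped["id"].to_numpy(), values=tabular_A(s, d), kind="A"
    )


def extract_A22(A: RelationshipMatrix, genotyped_ids) -> RelationshipMatrix:
    """Principal submatrix of A for the genotyped animals, in given order."""
    pos = {int(v): k for k, v in enumerate(A.labels)}
    try:
        sel = np.array([pos[int(i)] for i in genotyped_ids])
    except KeyError as e:
        raise KeyError(f"genotyped id {e} not in A labels") from None
    return RelationshipMatrix(
        labels=np.asarray(genotyped_ids),
        values=A.values[np.ix_(sel, sel)],
        kind="A22",
        provenance={"parent_kind": A.kind},
    )


def allele_frequencies(dosages: np.ndarray) -> np.ndarray:
    """Counted-allele frequency per SNP from a 0/1/2 dosage matrix."""
    dosages = np.asarray(dosages)
    if dosages.ndim != 2 or dosages.size == 0:
        raise ValueError("empty genotype matrix")
    return dosages.mean(axis=0) / 2.0


def build_G(
    dosages: np.ndarray,
    allele_freqs: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    freq_source: str = "observed",
) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix with optional diagonal weights.

    ``allele_freqs`` defaults to the observed frequencies of the supplied
    animals; scenario code passes the designated source population's
    frequencies explicitly.
    """
    M = np.asarray(dosages, dtype=float)
    if M.ndim != 2 or M.size == 0:
        raise ValueError("empty genotype matrix")
    n, m = M.shape
    p = allele_frequencies(M) if allele_freqs is None else np.asarray(allele_freqs, float)
    if len(p) != m:
        raise ValueError("allele frequency length mismatch")
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError(
            "fixed locus (p in {0,1}) reached G construction; run QC first"
        )
    k = 2.0 * np.sum(p * (1.0 - p))
    if k <= 0:
        raise ValueError("scale parameter k is zero")
    Z = M - 2.0 * p
    if weights is None:
        G = Z @ Z.T / k
        wsrc = "identity"
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != m or np.any(w < 0):
            raise ValueError("weights must be nonnegative, one per SNP")
        G = (Z * w) @ Z.T / k
        wsrc = "diagonal"
    if labels is None:
        labels = np.arange(n)
    return RelationshipMatrix(
        labels=np.asarray(labels),
        values=G,
        kind="G",
        provenance={"k": k, "freq_source": freq_source, "weights": wsrc},
    )


def blend_H_inverse(
    A_inv: sp.spmatrix,
    A22: RelationshipMatrix | np.ndarray,
    G: RelationshipMatrix | np.ndarray,
    params: BlendParams,
    genotyped_index: np.ndarray,
) -> RelationshipMatrix:
    """Dense H^-1 = A^-1 + block[tau*(0.95G + 0.05A22)^-1 - omega*A22^-1].

    ``genotyped_index`` gives the 0-based rows of the genotyped animals in
    the ordering of ``A_inv``.  Blending is applied before inversion.
    """
    A22v = A22.values if isinstance(A22, RelationshipMatrix) else np.asarray(A22)
    Gv = G.values if isinstance(G, RelationshipMatrix) else np.asarray(G)
    if A22v.shape != Gv.shape:
        raise ValueError("G and A22 not conformable")
    n = A_inv.shape[0]
    gi = np.asarray(genotyped_index)
    if gi.max() >= n:
        raise ValueError("genotyped index outside pedigree ordering")
    Gb = params.g_share * Gv + params.a_share * A22v
    Gb_inv = _spd_inverse(Gb, "blended G")
    A22_inv = _spd_inverse(A22v, "A22")
    H = np.asarray(A_inv.todense() if sp.issparse(A_inv) else A_inv, dtype=float).copy()
    H[np.ix_(gi, gi)] += params.tau * Gb_inv - params.omega * A22_inv
    labels = (
        G.labels
        if isinstance(G, RelationshipMatrix)
        else np.arange(len(gi))
    )
    return RelationshipMatrix(
        labels=np.arange(n),
        values=H,
        kind="Hinv",
        provenance={
            "tau": params.tau,
            "omega": params.omega,
            "g_share": params.g_share,
            "genotyped_labels": np.asarray(labels),
        },
    )


def _spd_inverse(M: np.ndarray, name: str) -> np.ndarray:
    """Inverse via Cholesky; reports the smallest eigenvalue on failure."""
    try:
        c, low = sla.cho_factor(M, lower=True, check_finite=False)
    except sla.LinAlgError:
        w = np.linalg.eigvalsh(M)
        raise np.linalg.LinAlgError(
            f"{name} matrix not positive definite "
            f"(smallest eigenvalue {w[0]:.3e}, condition {w[-1] / max(w[0], 1e-300):.3e})"
        ) from None
    inv = sla.cho_solve((c, low), np.eye(M.shape[0]), check_finite=False)
    return 0.5 * (inv + inv.T)
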