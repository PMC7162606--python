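"""Weighted single-step GBLUP: SNP-effect back-solving and variance weights.

From the GEBVs of a designated weight-source population, SNP effects are
back-solved as u_hat = lambda * D * Z' * G^-1 * GEBV with Z the centred
dosage matrix and lambda = 1/k the SNP-to-genetic variance ratio implied by
G = Z D Z'/k (so that Z u_hat reconstructs the genomic GEBVs).  Weights for
the next iteration are the implied SNP variances d_j = u_j^2 * 2 p_j (1-p_j),
normalised to mean one.  The schedule is two iterations: identity weights
(plain ssGBLUP), then one weighted re-solve.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla

from .relationship import RelationshipMatrix

__all__ = ["SnpWeightSet", "backsolve_snp_effects", "snp_weights"]


@dataclass
class SnpWeightSet:
    weights: np.ndarray
    source_population: str = ""
    iteration: int = 1
    normalization: str = "mean=1"

    def __post_init__(self):
        w = np.asarray(self.weights, dtype=float)
        if np.any(w < 0):
            raise ValueError("SNP weights must be nonnegative")
        self.weights = w


def backsolve_snp_effects(
    gebv: np.ndarray,
    G: RelationshipMatrix | np.ndarray,
    Z: np.ndarray,
    weights: np.ndarray | None = None,
    k: float | None = None,
) -> np.ndarray:
    """u_hat = (1/k) * D * Z' * G^-1 * GEBV for the weight-source animals.

    ``G`` must have been built from the same Z, D and k; then
    Z @ u_hat == GEBV (the genomic breeding values decompose exactly onto
    the markers).
    """
    if isinstance(G, RelationshipMatrix):
        if k is None:
            k = G.provenance.get("k")
        G = G.values
    G = np.asarray(G, dtype=float)
    Z = np.asarray(Z, dtype=float)
    gebv = np.asarray(gebv, dtype=float)
    n, m = Z.shape
    if G.shape != (n, n) or len(gebv) != n:
        raise ValueError("dimension mismatch between GEBVs, G and Z")
    if k is None:
        raise ValueError("scale parameter k required")
    try:
        c = sla.cho_factor(G, lower=True, check_finite=False)
        Ginv_g = sla.cho_solve(c, gebv, check_finite=False)
    except sla.LinAlgError:
        raise np.linalg.LinAlgError("G is singular; blend before back-solving") from None
    u = (Z.T @ Ginv_g) / k
    if weights is not None:
        u = np.asarray(weights, dtype=float) * u
    return u


def snp_weights(
    effects: np.ndarray,
    allele_freqs: np.ndarray,
    source_population: str = "",
    iteration: int = 2,
    normalize: bool = True,
) -> SnpWeightSet:
    """d_j = u_j^2 * 2 p_j (1 - p_j), normalised to mean one.

    Fixed loci (p in {0,1}) receive weight zero with a warning; no weight
    ceiling is applied.
    """
    u = np.asarray(effects, dtype=float)
    p = np.asarray(allele_freqs, dtype=float)
    if u.shape != p.shape:
        raise ValueError("effects and allele frequencies must align")
    het = 2.0 * p * (1.0 - p)
    fixed = (p <= 0) | (p >= 1)
    if fixed.any():
        warnings.warn(
            f"{int(fixed.sum())} fixed loci receive zero weight", stacklevel=2
        )
        het = np.where(fixed, 0.0, het)
    d = u * u * het
    norm = "raw"
    if normalize and d.mean() > 0:
        d = d / d.mean()
        norm = "mean=1"
    return SnpWeightSet(
        weights=d,
        source_population=source_population,
        iteration=iteration,
        normalization=norm,
    )
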