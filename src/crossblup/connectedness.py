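"""Population-connectedness diagnostics.

Linkage disequilibrium between loci A and B is D = f(AB) - f(A)f(B) from
phased haplotypes, r^2 = D^2 / (f(A)f(a)f(B)f(b)) and the signed
r = sign(D) sqrt(r^2).  Consistency of gametic phase between two
populations is the Pearson correlation of their signed r values over
shared SNP pairs, binned by physical distance (1 cM = 1 Mb).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PhaseConsistencyProfile",
    "ld_r2",
    "signed_r_pairs",
    "adjacent_ld_profile",
    "phase_consistency",
    "minor_allele_recode",
    "pca_of_G",
    "pca_leading_share",
    "allele_freq_correlation",
]


def minor_allele_recode(haplotypes: np.ndarray) -> np.ndarray:
    """Flip allele labels so the counted allele is this population's minor
    allele.

    Mirrors workflows that compute frequencies and LD independently per
    population (each dataset's A1 is its own minor allele): where the minor
    allele differs between two populations, their signed r values flip sign
    relative to a consistently labelled coding.
    """
    h = np.asarray(haplotypes).copy()
    flip = h.mean(axis=0) > 0.5
    h[:, flip] = 1 - h[:, flip]
    return h


def ld_r2(haplotypes: np.ndarray, locus_i: int, locus_j: int) -> tuple[float, float]:
    """(r^2, signed r) between two loci from a (2n, m) phased 0/1 matrix."""
    h = np.asarray(haplotypes)
    a = h[:, locus_i].astype(float)
    b = h[:, locus_j].astype(float)
    pa, pb = a.mean(), b.mean()
    if pa in (0.0, 1.0) or pb in (0.0, 1.0):
        raise ValueError("LD undefined for a monomorphic locus")
    D = (a * b).mean() - pa * pb
    denom = pa * (1 - pa) * pb * (1 - pb)
    r2 = D * D / denom
    return float(r2), float(np.sign(D) * np.sqrt(r2))


def _pair_offsets(chrom: np.ndarray, pos: np.ndarray, max_dist: float):
    """(i, j) index pairs with j > i, same chromosome, pos_j - pos_i <= max_dist."""
    out_i, out_j = [], []
    m = len(pos)
    for d in range(1, m):
        i = np.arange(m - d)
        j = i + d
        same = chrom[i] == chrom[j]
        if not same.any():
            break
        dist = pos[j] - pos[i]
        if dist[same].min() > max_dist + 1e-9:
            break
        ok = same & (dist <= max_dist + 1e-9)
        if ok.any():
            out_i.append(i[ok])
            out_j.append(j[ok])
    if not out_i:
        return np.zeros(0, int), np.zeros(0, int)
    return np.concatenate(out_i), np.concatenate(out_j)


def signed_r_pairs(
    haplotypes: np.ndarray,
    chrom: np.ndarray,
    pos: np.ndarray,
    pairs: tuple[np.ndarray, np.ndarray],
) -> np.ndarray:
    """Vectorised signed r for given locus pairs; NaN where monomorphic."""
    h = np.asarray(haplotypes, dtype=float)
    i, j = pairs
    p = h.mean(axis=0)
    fab = np.einsum("ki,ki->i", h[:, i], h[:, j]) / h.shape[0]
    D = fab - p[i] * p[j]
    denom = p[i] * (1 - p[i]) * p[j] * (1 - p[j])
    with np.errstate(invalid="ignore", divide="ignore"):
        r = D / np.sqrt(denom)
    r[denom <= 0] = np.nan
    return r


def adjacent_ld_profile(
    haplotypes: np.ndarray,
    chrom: np.ndarray,
    pos_cm: np.ndarray,
    max_distance_cM: float = 0.05,
) -> float:
    """Mean r^2 over adjacent polymorphic-SNP pairs within the distance cap."""
    h = np.asarray(haplotypes, dtype=float)
    p = h.mean(axis=0)
    poly = (p > 0) & (p < 1)
    idx = np.flatnonzero(poly)
    if len(idx) < 2:
        raise ValueError("fewer than two polymorphic SNPs")
    i = idx[:-1]
    j = idx[1:]
    ok = (chrom[i] == chrom[j]) & (pos_cm[j] - pos_cm[i] <= max_distance_cM + 1e-9)
    i, j = i[ok], j[ok]
    if len(i) == 0:
        raise ValueError("no adjacent SNP pairs within the distance cap")
    r = signed_r_pairs(h, chrom, pos_cm, (i, j))
    return float(np.nanmean(r * r))


@dataclass
class PhaseConsistencyProfile:
    pair: tuple[str, str]
    bin_edges_kb: np.ndarray
    correlation_per_bin: np.ndarray  # NaN where < 3 pairs
    n_pairs_per_bin: np.ndarray

    def at(self, max_kb: float) -> float:
        """Correlation in the bin whose upper edge is ``max_kb``."""
        k = int(np.argmin(np.abs(self.bin_edges_kb[1:] - max_kb)))
        return float(self.correlation_per_bin[k])


def phase_consistency(
    haps_a: np.ndarray,
    haps_b: np.ndarray,
    chrom: np.ndarray,
    pos_cm: np.ndarray,
    bin_edges_kb: np.ndarray | None = None,
    pair_names: tuple[str, str] = ("A", "B"),
) -> PhaseConsistencyProfile:
    """Per-bin Pearson correlation of signed r between two populations.

    Distances use the 1 cM = 1 Mb equivalence; default bins are 60 kb steps
    up to 1 Mb.  Pairs monomorphic in either population are dropped; bins
    with fewer than 3 usable pairs report NaN.
    """
    if bin_edges_kb is None:
        bin_edges_kb = np.arange(0.0, 1001.0, 60.0)
    bin_edges_kb = np.asarray(bin_edges_kb, dtype=float)
    pos_kb = np.asarray(pos_cm, dtype=float) * 1000.0
    i, j = _pair_offsets(np.asarray(chrom), pos_kb, bin_edges_kb[-1])
    dist = pos_kb[j] - pos_kb[i]
    ra = signed_r_pairs(haps_a, chrom, pos_kb, (i, j))
    rb = signed_r_pairs(haps_b, chrom, pos_kb, (i, j))
    ok = ~(np.isnan(ra) | np.isnan(rb))
    which = np.digitize(dist, bin_edges_kb[1:-1], right=True)
    nbins = len(bin_edges_kb) - 1
    corr = np.full(nbins, np.nan)
    counts = np.zeros(nbins, dtype=int)
    for b in range(nbins):
        m = ok & (which == b)
        counts[b] = int(m.sum())
        if counts[b] >= 3:
            x, y = ra[m], rb[m]
            if np.std(x) > 0 and np.std(y) > 0:
                corr[b] = float(np.corrcoef(x, y)[0, 1])
    return PhaseConsistencyProfile(
        pair=pair_names,
        bin_edges_kb=bin_edges_kb,
        correlation_per_bin=corr,
        n_pairs_per_bin=counts,
    )


def pca_of_G(G: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a genomic relationship matrix.

    Returns (scores, variance fractions): scores are eigenvector columns
    scaled by sqrt(eigenvalue), components in decreasing order; fractions
    are eigenvalues over their sum (tiny negative eigenvalues clipped).
    """
    Gv = np.asarray(G, dtype=float)
    if not np.all(np.isfinite(Gv)):
        raise ValueError("non-finite entries in G")
    w, V = np.linalg.eigh(0.5 * (Gv + Gv.T))
    order = np.argsort(w)[::-1]
    w = np.maximum(w[order], 0.0)
    V = V[:, order]
    total = w.sum()
    if total <= 0:
        raise ValueError("G has no positive eigenvalues")
    return V * np.sqrt(w), w / total


def pca_leading_share(G: np.ndarray, n_components: int = 10) -> float:
    """Share of the first axis among the leading ``n_components``
    eigenvalues of G.

    GWAS toolkits extract a fixed number of principal components (ten by
    default) and variance percentages quoted from such output are relative
    to the extracted set, not to the full trace; this reproduces that
    convention.
    """
    import scipy.sparse.linalg as spla

    Gv = np.asarray(G, dtype=float)
    n = Gv.shape[0]
    if n <= max(2 * n_components, 50):
        w = np.sort(np.linalg.eigvalsh(Gv))[::-1][:n_components]
    else:
        w = np.sort(spla.eigsh(Gv, k=n_components, return_eigenvectors=False))[::-1]
    w = np.maximum(w, 0.0)
    if w.sum() <= 0:
        raise ValueError("G has no positive leading eigenvalues")
    return float(w[0] / w.sum())


def allele_freq_correlation(freqs_a: np.ndarray, freqs_b: np.ndarray) -> float:
    """Pearson correlation of counted-allele frequencies over common SNPs."""
    a = np.asarray(freqs_a, dtype=float)
    b = np.asarray(freqs_b, dtype=float)
    if a.shape != b.shape or a.size < 3:
        raise ValueError("need >= 3 common SNPs with aligned frequencies")
    return float(np.corrcoef(a, b)[0, 1])
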