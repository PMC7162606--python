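"""Genotype quality control, per population, then intersected.

Filters follow the strict readings: keep a SNP iff MAF > 0.05 and the
absolute difference between observed and Hardy-Weinberg expected
heterozygote frequency is < 0.15.  Only SNPs passing in every population
are kept for downstream analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = [
    "QCReport",
    "maf_filter",
    "hwe_departure_filter",
    "intersect_populations",
    "qc_population",
    "run_qc",
    "MAF_MIN",
    "HWE_DEV_MAX",
]

MAF_MIN = 0.05
HWE_DEV_MAX = 0.15


@dataclass
class QCReport:
    population: str
    n_input: int
    n_maf_fail: int
    n_hwe_fail: int
    kept: np.ndarray  # SNP indices retained, in map order
    thresholds: tuple[float, float] = (MAF_MIN, HWE_DEV_MAX)

    @property
    def n_kept(self) -> int:
        return len(self.kept)


def _check(dosages: np.ndarray) -> np.ndarray:
    d = np.asarray(dosages)
    if d.ndim != 2 or d.size == 0:
        raise ValueError("empty genotype matrix")
    return d


def maf_filter(dosages: np.ndarray, threshold: float = MAF_MIN) -> np.ndarray:
    """Boolean keep-mask: minor allele frequency strictly above threshold."""
    d = _check(dosages)
    if not (0 <= threshold < 0.5):
        raise ValueError("MAF threshold must be in [0, 0.5)")
    p = d.mean(axis=0) / 2.0
    maf = np.minimum(p, 1.0 - p)
    return maf > threshold


def hwe_departure_filter(dosages: np.ndarray, max_dev: float = HWE_DEV_MAX) -> np.ndarray:
    """Keep-mask: |observed het freq - 2p(1-p)| strictly below ``max_dev``."""
    d = _check(dosages)
    if not (0 < max_dev < 1):
        raise ValueError("HWE deviation bound must be in (0, 1)")
    p = d.mean(axis=0) / 2.0
    h_obs = (d == 1).mean(axis=0)
    return np.abs(h_obs - 2.0 * p * (1.0 - p)) < max_dev


def qc_population(
    dosages: np.ndarray,
    population: str = "",
    maf_min: float = MAF_MIN,
    hwe_dev_max: float = HWE_DEV_MAX,
) -> QCReport:
    """Apply MAF then HWE filters; a SNP failing both counts once (MAF)."""
    d = _check(dosages)
    keep_maf = maf_filter(d, maf_min)
    keep_hwe = hwe_departure_filter(d, hwe_dev_max)
    n_maf = int((~keep_maf).sum())
    n_hwe = int((keep_maf & ~keep_hwe).sum())
    kept = np.flatnonzero(keep_maf & keep_hwe)
    return QCReport(
        population=population,
        n_input=d.shape[1],
        n_maf_fail=n_maf,
        n_hwe_fail=n_hwe,
        kept=kept,
        thresholds=(maf_min, hwe_dev_max),
    )


def intersect_populations(*kept_sets: np.ndarray) -> np.ndarray:
    """Common SNP indices across populations, preserving map order."""
    if len(kept_sets) < 2:
        raise ValueError("need at least two populations to intersect")
    common = np.asarray(kept_sets[0])
    for s in kept_sets[1:]:
        common = np.intersect1d(common, np.asarray(s))
    if common.size == 0:
        warnings.warn("no SNPs shared across populations after QC", stacklevel=2)
    return np.sort(common)


def run_qc(
    dosages_by_population: dict[str, np.ndarray],
    maf_min: float = MAF_MIN,
    hwe_dev_max: float = HWE_DEV_MAX,
) -> tuple[dict[str, QCReport], np.ndarray]:
    """Per-population QC followed by the cross-population intersection."""
    reports = {
        name: qc_population(d, name, maf_min, hwe_dev_max)
        for name, d in dosages_by_population.items()
    }
    common = intersect_populations(*[r.kept for r in reports.values()])
    return reports, common
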