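"""Readers/writers for on-disk artifacts and run configuration.

Genotypes travel as PLINK text .ped/.map pairs (alleles coded 1/2) or as a
flat 0/1/2 dosage matrix with a header row of SNP names.  Pedigrees and
phenotypes are CSV; configuration round-trips through YAML.  All writers
use stable ordering and fixed float formatting so identical inputs produce
identical files.
"""

from __future__ import annotations

import dataclasses
import hashlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .pedigree import PedigreeError, topological_order

__all__ = [
    "write_pedigree",
    "read_pedigree",
    "write_plink",
    "read_plink",
    "write_dosage_matrix",
    "read_dosage_matrix",
    "read_genotypes",
    "write_phenotypes",
    "write_config",
    "read_config",
    "config_hash",
    "write_run_log",
]

PED_COLUMNS = ["id", "sire", "dam", "sex", "generation", "population"]


def write_pedigree(ped: pd.DataFrame, path) -> None:
    ped[PED_COLUMNS].to_csv(path, index=False)


def read_pedigree(path) -> pd.DataFrame:
    """Read and topologically validate a pedigree CSV (0 = unknown parent)."""
    ped = pd.read_csv(path)
    missing = [c for c in ("id", "sire", "dam") if c not in ped.columns]
    if missing:
        raise PedigreeError(f"pedigree file lacks columns {missing}")
    for c in ("id", "sire", "dam"):
        ped[c] = ped[c].astype(int)
    return topological_order(ped)


def write_plink(
    dosages: np.ndarray,
    ids: np.ndarray,
    snp_map: pd.DataFrame,
    prefix,
    sex: np.ndarray | None = None,
    phenotype: np.ndarray | None = None,
) -> None:
    """PLINK text pair: dosage d encodes as genotypes {0:'2 2', 1:'1 2', 2:'1 1'}.

    Allele 1 is the counted allele.  ``snp_map`` needs columns snp, chrom,
    pos_cm, pos_bp.
    """
    prefix = Path(prefix)
    dosages = np.asarray(dosages)
    n, m = dosages.shape
    if len(ids) != n or len(snp_map) != m:
        raise ValueError("dosage matrix inconsistent with ids or map")
    sex_code = np.ones(n, dtype=int)
    if sex is not None:
        sex_code = np.where(np.asarray(sex) == "M", 1, 2)
    phen = np.full(n, -9.0) if phenotype is None else np.asarray(phenotype)
    allele_strings = {0: "2 2", 1: "1 2", 2: "1 1"}
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i in range(n):
            geno = " ".join(allele_strings[int(d)] for d in dosages[i])
            fh.write(f"0 {ids[i]} 0 0 {sex_code[i]} {phen[i]:.6g} {geno}\n")
    with open(prefix.with_suffix(".map"), "w") as fh:
        for _, r in snp_map.iterrows():
            fh.write(
                f"{int(r['chrom'])} {r['snp']} {r['pos_cm']:.6f} {int(r['pos_bp'])}\n"
            )


def read_plink(prefix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """(dosage DataFrame indexed by id, map DataFrame).

    Counted allele is '1'; heterozygotes may be coded '1 2' or '2 1'.
    """
    prefix = Path(prefix)
    snp_map = pd.read_csv(
        prefix.with_suffix(".map"),
        sep=r"\s+",
        names=["chrom", "snp", "pos_cm", "pos_bp"],
    )
    ids, rows = [], []
    with open(prefix.with_suffix(".ped")) as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6 + 2 * len(snp_map):
                raise ValueError(
                    f"{prefix}.ped line {ln}: expected "
                    f"{6 + 2 * len(snp_map)} fields, got {len(parts)}"
                )
            ids.append(int(parts[1]))
            alleles = parts[6:]
            dos = []
            for j in range(len(snp_map)):
                a, b = alleles[2 * j], alleles[2 * j + 1]
                if a not in "12" or b not in "12":
                    raise ValueError(
                        f"{prefix}.ped line {ln}: unknown allele code {a}/{b}"
                    )
                dos.append((a == "1") + (b == "1"))
            rows.append(dos)
    geno = pd.DataFrame(rows, index=ids, columns=snp_map["snp"])
    geno.index.name = "id"
    return geno, snp_map


def write_dosage_matrix(dosages: np.ndarray, ids, snp_names, path) -> None:
    df = pd.DataFrame(np.asarray(dosages), index=ids, columns=snp_names)
    df.index.name = "id"
    df.to_csv(path, sep="\t")


def read_dosage_matrix(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="id")
    bad = ~df.isin([0, 1, 2]).all(axis=None)
    if bad:
        raise ValueError(f"{path}: dosages must be coded 0/1/2")
    return df


def read_genotypes(path, dialect: str = "plink"):
    """Dispatch on dialect: 'plink' (.ped/.map prefix) or 'matrix' (TSV)."""
    if dialect == "plink":
        return read_plink(path)
    if dialect == "matrix":
        df = read_dosage_matrix(path)
        return df, None
    raise ValueError(f"unknown genotype dialect {dialect!r}")


def write_phenotypes(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False, float_format="%.8g")


def write_matrix_triplets(matrix, path, kind: str = "") -> None:
    """Labeled lower-triangle triplet text (id_i, id_j, value).

    The layout mirrors the triplet files animal-breeding tools exchange;
    entries are written row-major over the lower triangle with stable float
    formatting.
    """
    from .relationship import RelationshipMatrix

    if isinstance(matrix, RelationshipMatrix):
        labels, values, kind = matrix.labels, matrix.values, matrix.kind
    else:
        values = np.asarray(matrix)
        labels = np.arange(1, len(values) + 1)
    with open(path, "w") as fh:
        if kind:
            fh.write(f"# kind: {kind}\n")
        for i in range(len(labels)):
            for j in range(i + 1):
                fh.write(f"{labels[i]} {labels[j]} {values[i, j]:.10g}\n")


def read_matrix_triplets(path):
    """Read a labeled lower-triangle triplet file back into a
    RelationshipMatrix (symmetrised)."""
    from .relationship import RelationshipMatrix

    kind = ""
    ids_i, ids_j, vals = [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if "kind:" in line:
                    kind = line.split("kind:")[1].strip()
                continue
            a, b, v = line.split()
            ids_i.append(int(a))
            ids_j.append(int(b))
            vals.append(float(v))
    labels = sorted(set(ids_i) | set(ids_j))
    pos = {v: k for k, v in enumerate(labels)}
    M = np.zeros((len(labels), len(labels)))
    for a, b, v in zip(ids_i, ids_j, vals):
        M[pos[a], pos[b]] = v
        M[pos[b], pos[a]] = v
    return RelationshipMatrix(labels=np.array(labels), values=M, kind=kind or "A")


def _to_plain(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_plain(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_plain(v) for v in obj]
    return obj


def write_config(config, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(config), fh, sort_keys=True)


def read_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def config_hash(config) -> str:
    blob = yaml.safe_dump(_to_plain(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_run_log(path, seed: int, config, timings: dict | None = None) -> None:
    import platform
    import sys

    entry = {
        "seed": int(seed),
        "config_hash": config_hash(config),
        "python": sys.version.split()[0],
        "platform": platform.platform(),
        "numpy": np.__version__,
        "timings_s": _to_plain(timings or {}),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(entry, fh, sort_keys=True)
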