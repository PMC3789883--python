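"""Readers and writers for the external file formats.

Formats: delimited dosage matrix (one row per individual), BIM-like SNP map
(chromosome, id, position), one-label-per-line phenotype, BED3+1 gene
coordinates, GMT gene sets, and YAML run configuration.  BED input is
0-based half-open and converted to 1-based inclusive at this boundary;
everything downstream is 1-based inclusive.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .data import (
    GeneSet,
    GeneSetCollection,
    GeneTable,
    GenotypeData,
    RunConfig,
    SnpMap,
)

logger = logging.getLogger(__name__)

__all__ = [
    "read_genotypes",
    "write_genotypes",
    "read_snp_map",
    "read_gmt",
    "write_gmt",
    "read_bed_genes",
    "write_bed_genes",
    "read_config",
    "write_config",
]


class LoadError(ValueError):
    """Raised when an input file cannot be reconciled with its companions."""


def read_snp_map(path: str | Path) -> SnpMap:
    t = pd.read_csv(
        path,
        sep=r"\s+",
        header=None,
        names=["chromosome", "snp_id", "position"],
        dtype={"chromosome": str, "snp_id": str, "position": np.int64},
    )
    return SnpMap(t[["snp_id", "chromosome", "position"]]).sort().validate()


def read_genotypes(
    dosage_path: str | Path,
    map_path: str | Path,
    pheno_path: str | Path | None = None,
) -> GenotypeData:
    """Load a dosage matrix with its SNP map and (optionally) phenotype.

    Missing dosage cells (empty / NA) are replaced by the per-SNP mean of
    the observed values; a SNP with no observed values is filled with 0.
    """
    snp_map = read_snp_map(map_path)
    X = pd.read_csv(
        dosage_path, sep=r"\s+", header=None, float_precision="round_trip"
    ).to_numpy(np.float64)
    if X.shape[1] != snp_map.n_snps:
        raise LoadError(
            f"{dosage_path}: matrix has {X.shape[1]} columns but map "
            f"{map_path} lists {snp_map.n_snps} SNPs"
        )
    n_missing = int(np.isnan(X).sum())
    if n_missing:
        col_mean = np.nanmean(np.where(np.isnan(X).all(0), 0.0, X), axis=0)
        col_mean = np.nan_to_num(col_mean)
        ii, jj = np.nonzero(np.isnan(X))
        X[ii, jj] = col_mean[jj]
        logger.info("mean-filled %d missing dosage cells", n_missing)

    phenotype = None
    if pheno_path is not None:
        raw = Path(pheno_path).read_text().split()
        if len(raw) != X.shape[0]:
            raise LoadError(
                f"{pheno_path}: {len(raw)} labels for {X.shape[0]} individuals"
            )
        try:
            phenotype = np.array([int(v) for v in raw])
        except ValueError as e:
            raise ValueError(f"{pheno_path}: non-integer label: {e}") from None
        if not np.all(np.isin(phenotype, [0, 1])):
            bad = phenotype[~np.isin(phenotype, [0, 1])][0]
            raise ValueError(f"{pheno_path}: phenotype label {bad} not in {{0,1}}")
    return GenotypeData(dosages=X, snp_map=snp_map, phenotype=phenotype)


def write_genotypes(
    data: GenotypeData,
    dosage_path: str | Path,
    map_path: str | Path,
    pheno_path: str | Path | None = None,
) -> None:
    np.savetxt(dosage_path, data.dosages, fmt="%.17g", delimiter="\t")
    t = data.snp_map.table
    t[["chromosome", "snp_id", "position"]].to_csv(
        map_path, sep="\t", header=False, index=False
    )
    if pheno_path is not None and data.phenotype is not None:
        Path(pheno_path).write_text(
            "\n".join(str(int(v)) for v in data.phenotype) + "\n"
        )


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: set_id <tab> description <tab> gene ids...

    Duplicate gene ids within a line are dropped (first occurrence kept);
    duplicate set ids across lines and empty sets are errors.
    """
    sets: dict[str, GeneSet] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}:{lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            set_id, desc = fields[0], fields[1]
            genes = tuple(dict.fromkeys(g for g in fields[2:] if g))
            if set_id in sets:
                raise ValueError(f"{path}:{lineno}: duplicate set id {set_id!r}")
            if not genes:
                raise ValueError(f"{path}:{lineno}: gene set {set_id!r} is empty")
            sets[set_id] = GeneSet(name=set_id, source=desc, gene_ids=genes)
    return GeneSetCollection(sets=sets)


def write_gmt(coll: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for sid in coll:
            gs = coll[sid]
            fh.write("\t".join([sid, gs.source, *gs.gene_ids]) + "\n")


def read_bed_genes(path: str | Path) -> GeneTable:
    """Read gene coordinates from BED3+1 (chrom, start, end, gene_id).

    BED is 0-based half-open; internal coordinates are 1-based inclusive,
    so (start, end) maps to (start + 1, end).
    """
    t = pd.read_csv(
        path,
        sep="\t",
        header=None,
        names=["chromosome", "start", "end", "gene_id"],
        dtype={"chromosome": str, "start": np.int64, "end": np.int64,
               "gene_id": str},
    )
    if (t["start"] < 0).any():
        bad = t.loc[t["start"] < 0].iloc[0]
        raise ValueError(f"{path}: negative BED start for {bad['gene_id']!r}")
    if (t["end"] <= t["start"]).any():
        bad = t.loc[t["end"] <= t["start"]].iloc[0]
        raise ValueError(
            f"{path}: BED end <= start for gene {bad['gene_id']!r}"
        )
    out = t.assign(start=t["start"] + 1)[["gene_id", "chromosome", "start", "end"]]
    return GeneTable(out)


def write_bed_genes(genes: GeneTable, path: str | Path) -> None:
    t = genes.table
    bed = pd.DataFrame(
        {
            "chromosome": t["chromosome"],
            "start": t["start"] - 1,
            "end": t["end"],
            "gene_id": t["gene_id"],
        }
    )
    bed.to_csv(path, sep="\t", header=False, index=False)


def read_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    fields = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("theta0_grid", "theta_grid"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return RunConfig(**raw)


def write_config(cfg: RunConfig, path: str | Path) -> None:
    d = dataclasses.asdict(cfg)
    d["theta0_grid"] = list(d["theta0_grid"])
    d["theta_grid"] = list(d["theta_grid"])
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
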