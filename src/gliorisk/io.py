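"""Reading and writing the pipeline's on-disk formats.

Single-cell cohorts are stored 10x-style (matrix.mtx + features.tsv +
barcodes.tsv) with a cells.csv sidecar for patient/label metadata and a
gene_positions.tsv (gene, chrom, start; 1-based) for CNV scoring.  Gene
sets travel as GMT, tabular results as CSV/TSV.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

__all__ = [
    "write_sc_cohort",
    "read_sc_cohort",
    "write_bulk_cohort",
    "read_bulk_cohort",
    "read_gmt",
    "write_gmt",
    "read_gene_positions",
]


def write_sc_cohort(sc: ad.AnnData, outdir: str | Path) -> Path:
    """Write a single-cell cohort as 10x-style MTX plus metadata sidecars."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    # 10x convention: genes x cells
    mat = sparse.csr_matrix(np.asarray(sc.X).T)
    spio.mmwrite(outdir / "matrix.mtx", mat)
    pd.DataFrame({"gene": sc.var_names}).to_csv(
        outdir / "features.tsv", sep="\t", header=False, index=False
    )
    pd.DataFrame({"barcode": sc.obs_names}).to_csv(
        outdir / "barcodes.tsv", sep="\t", header=False, index=False
    )
    sc.obs.to_csv(outdir / "cells.csv")
    pos = sc.var[["chrom", "start"]].copy()
    pos.index.name = "gene"
    pos.to_csv(outdir / "gene_positions.tsv", sep="\t")
    if "truth" in sc.uns:
        with open(outdir / "truth.json", "w") as fh:
            json.dump(sc.uns["truth"], fh, indent=1)
    return outdir


def read_sc_cohort(indir: str | Path) -> ad.AnnData:
    indir = Path(indir)
    mat = spio.mmread(indir / "matrix.mtx").T.tocsr()
    genes = pd.read_csv(indir / "features.tsv", sep="\t", header=None)[0]
    barcodes = pd.read_csv(indir / "barcodes.tsv", sep="\t", header=None)[0]
    obs = pd.read_csv(indir / "cells.csv", index_col=0)
    obs = obs.reindex(barcodes).fillna("")
    var = pd.DataFrame(index=genes)
    pos_path = indir / "gene_positions.tsv"
    if pos_path.exists():
        pos = pd.read_csv(pos_path, sep="\t", index_col=0)
        var = pos.reindex(genes)
    var.index.name = None
    obs.index.name = None
    adata = ad.AnnData(
        X=np.asarray(mat.todense(), dtype=np.int32), obs=obs, var=var
    )
    truth_path = indir / "truth.json"
    if truth_path.exists():
        adata.uns["truth"] = json.loads(truth_path.read_text())
    return adata


def write_bulk_cohort(bulk, outdir: str | Path) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bulk.expression.to_csv(outdir / "expression.csv")
    clin = bulk.clinical.copy()
    clin.index.name = "sample_id"
    clin.to_csv(outdir / "clinical.csv")
    if bulk.true_proportions is not None:
        bulk.true_proportions.to_csv(outdir / "true_proportions.csv")
    return outdir


def read_bulk_cohort(indir: str | Path):
    from .simulate import BulkCohort

    indir = Path(indir)
    expression = pd.read_csv(indir / "expression.csv", index_col=0)
    clinical = pd.read_csv(indir / "clinical.csv", index_col=0)
    props_path = indir / "true_proportions.csv"
    props = pd.read_csv(props_path, index_col=0) if props_path.exists() else None
    return BulkCohort(expression=expression, clinical=clinical, true_proportions=props)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT file into {set name: gene list} (description field ignored)."""
    sets: dict[str, list[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line[:80]!r}")
        sets[fields[0]] = [g for g in fields[2:] if g]
    return sets


def write_gmt(sets: dict[str, list[str]], path: str | Path,
              description: str = "gliorisk") -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, description, *genes]) + "\n")
    return path


def read_gene_positions(path: str | Path) -> pd.DataFrame:
    """Gene-position TSV with columns gene, chrom, start (1-based)."""
    pos = pd.read_csv(path, sep="\t")
    pos = pos.set_index(pos.columns[0])
    if not {"chrom", "start"} <= set(pos.columns):
        raise ValueError("gene-position table needs columns: gene, chrom, start")
    return pos
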