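"""Readers and writers for the plain-text formats the pipeline touches.

GWAS summary statistics, gene annotations, gene sets and panels travel as
TSV/BED; expression matrices as MatrixMarket triplets (genes x cells, as in
the usual 10x-style layout) with ``genes.tsv``, ``barcodes.tsv`` and
``cell_meta.tsv`` companions.
"""

from __future__ import annotations

from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .cellstate import GenePanel
from .mapping import GeneSetCatalog, MarkerEffects, read_bed_genes, read_gff3_genes

__all__ = [
    "read_gwas_tsv", "write_gwas_tsv",
    "read_annotation", "write_bed",
    "read_gene_sets", "write_gene_sets",
    "read_panels", "write_panels",
    "read_mtx_bundle", "write_mtx_bundle",
]


def read_gwas_tsv(path, trait_id: str | None = None, chrom_order=None) -> MarkerEffects:
    """Read a summary-statistics TSV with header columns marker, chrom, pos, b."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, float_precision="round_trip")
    required = {"marker", "chrom", "pos", "b"}
    if missing := required - set(df.columns):
        raise ValueError(f"GWAS TSV {path} missing columns: {sorted(missing)}")
    tid = trait_id if trait_id is not None else Path(path).stem
    return MarkerEffects.from_frame(df, trait_id=tid, chrom_order=chrom_order)


def write_gwas_tsv(effects: MarkerEffects, path) -> None:
    # %.17g keeps the effect sizes bit-exact through the text round trip
    effects.to_frame().to_csv(path, sep="\t", index=False, float_format="%.17g")


def read_annotation(path) -> pd.DataFrame:
    """Read gene intervals from BED (.bed) or GFF3 (anything else)."""
    path = Path(path)
    if path.suffix.lower() == ".bed":
        return read_bed_genes(path)
    return read_gff3_genes(path)


def write_bed(annotation: pd.DataFrame, path) -> None:
    """Write the annotation frame as BED6 (0-based half-open, as stored)."""
    bed = annotation[["chrom", "start", "end", "gene_id"]].copy()
    bed["score"] = 0
    bed["strand"] = annotation.get("strand", ".")
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_gene_sets(path, provenance: str = "") -> GeneSetCatalog:
    """Read a two-column TSV (set_id, gene_id) into a catalog."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"set_id", "gene_id"} <= set(df.columns):
        raise ValueError(f"gene-set TSV {path} needs columns set_id, gene_id")
    sets = {sid: grp["gene_id"].tolist() for sid, grp in df.groupby("set_id", sort=False)}
    return GeneSetCatalog(sets, provenance=provenance)


def write_gene_sets(catalog: GeneSetCatalog, path) -> None:
    rows = [(sid, g) for sid, genes in catalog for g in genes]
    pd.DataFrame(rows, columns=["set_id", "gene_id"]).to_csv(path, sep="\t", index=False)


def read_panels(path) -> list[GenePanel]:
    """Read a two-column TSV (panel_id, gene_id) into gene panels."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"panel_id", "gene_id"} <= set(df.columns):
        raise ValueError(f"panel TSV {path} needs columns panel_id, gene_id")
    return [
        GenePanel(pid, grp["gene_id"].tolist())
        for pid, grp in df.groupby("panel_id", sort=False)
    ]


def write_panels(panels, path) -> None:
    rows = [(p.panel_id, g) for p in panels for g in p.genes]
    pd.DataFrame(rows, columns=["panel_id", "gene_id"]).to_csv(path, sep="\t", index=False)


def write_mtx_bundle(adata: ad.AnnData, outdir, layer: str | None = None) -> None:
    """Write matrix.mtx + genes.tsv + barcodes.tsv + cell_meta.tsv.

    The matrix is written genes x cells; the metadata TSV carries the full
    ``obs`` frame with ``cell_id`` as first column.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    X = adata.layers[layer] if layer else adata.X
    M = sp.coo_matrix(X).T  # genes x cells
    scipy.io.mmwrite(str(outdir / "matrix.mtx"), M)
    pd.Series(adata.var_names).to_csv(outdir / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(outdir / "barcodes.tsv", sep="\t", index=False, header=False)
    meta = adata.obs.reset_index().rename(columns={adata.obs.index.name or "index": "cell_id"})
    meta.to_csv(outdir / "cell_meta.tsv", sep="\t", index=False)


def read_mtx_bundle(outdir) -> ad.AnnData:
    """Read the bundle written by :func:`write_mtx_bundle` back into AnnData."""
    outdir = Path(outdir)
    M = sp.csr_matrix(scipy.io.mmread(str(outdir / "matrix.mtx")).T)
    genes = pd.read_csv(outdir / "genes.tsv", sep="\t", header=None)[0].astype(str)
    barcodes = pd.read_csv(outdir / "barcodes.tsv", sep="\t", header=None)[0].astype(str)
    adata = ad.AnnData(
        X=M,
        obs=pd.DataFrame(index=pd.Index(barcodes, name="cell_id")),
        var=pd.DataFrame(index=pd.Index(genes, name="gene_id")),
    )
    meta_path = outdir / "cell_meta.tsv"
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", dtype={"cell_id": str}).set_index("cell_id")
        adata.obs = meta.loc[adata.obs_names]
    return adata
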