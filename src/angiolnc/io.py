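"""Readers and writers for the pipeline's interchange formats.

Plain-text formats only: TSV for contrast tables, DE tables, marker
panels, gene sets, gene models and ligand-receptor pair lists; MatrixMarket
triplets (plus genes/barcodes TSV and a cell-metadata TSV) for counts;
BED6 for peaks; JSON for ground truth and network summaries. Every writer
has a matching reader and generated data round-trip losslessly.

Gene-model TSV columns: ``gene_id, chrom, strand, tss, exon_starts,
exon_ends`` with comma-separated 0-based half-open exon coordinates.
"""

from __future__ import annotations

import json
from pathlib import Path

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .genome import GeneModel, GenomicInterval
from .scrna import MarkerPanel, make_cell_dataset
from .simulate import SyntheticTruth

__all__ = [
    "read_contrast_table",
    "write_contrast_table",
    "read_cell_dataset",
    "write_cell_dataset",
    "read_marker_panel",
    "write_marker_panel",
    "read_gene_models",
    "write_gene_models",
    "read_peaks_bed",
    "write_peaks_bed",
    "read_gene_set",
    "write_gene_set",
    "read_lr_pairs",
    "write_lr_pairs",
    "read_truth",
    "write_truth",
]


# -- contrast / DE tables ---------------------------------------------------

def write_contrast_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_contrast_table(path) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "log2fc", "pvalue", "padj"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"{path}: missing column(s) {sorted(missing)}")
    return table


# -- cell datasets ----------------------------------------------------------

def write_cell_dataset(adata: ad.AnnData, out_dir) -> None:
    """Write counts as MTX triplet plus genes/barcodes and metadata TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    X = adata.X if sp.issparse(adata.X) else sp.csr_matrix(np.asarray(adata.X))
    # MTX convention: genes as rows, cells as columns
    scipy.io.mmwrite(out / "matrix.mtx", X.T.astype(int))
    pd.Series(adata.var_names).to_csv(out / "genes.tsv", sep="\t", index=False, header=False)
    pd.Series(adata.obs_names).to_csv(out / "barcodes.tsv", sep="\t", index=False, header=False)
    adata.obs.to_csv(out / "cell_meta.tsv", sep="\t")


def read_cell_dataset(in_dir) -> ad.AnnData:
    """Rebuild the AnnData from an MTX triplet directory.

    QC metadata are recomputed from the counts (they are derived
    quantities); cluster and true-type labels are restored from the
    metadata TSV when present.
    """
    src = Path(in_dir)
    X = scipy.io.mmread(src / "matrix.mtx").T.tocsr()
    genes = pd.read_csv(src / "genes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(src / "barcodes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    meta_path = src / "cell_meta.tsv"
    clusters = None
    true_type = None
    if meta_path.exists():
        meta = pd.read_csv(meta_path, sep="\t", index_col=0)
        if "cluster" in meta.columns:
            clusters = meta.loc[barcodes, "cluster"].tolist()
        if "true_type" in meta.columns:
            true_type = meta.loc[barcodes, "true_type"].tolist()
    adata = make_cell_dataset(
        np.asarray(X.todense()), genes, cell_ids=barcodes, cluster_labels=clusters
    )
    if true_type is not None:
        adata.obs["true_type"] = true_type
    return adata


# -- marker panels ----------------------------------------------------------

def write_marker_panel(panel: MarkerPanel, path) -> None:
    rows = [(t, g) for t, genes in panel for g in genes]
    pd.DataFrame(rows, columns=["cell_type", "gene_id"]).to_csv(path, sep="\t", index=False)


def read_marker_panel(path) -> MarkerPanel:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"cell_type", "gene_id"} <= set(df.columns):
        raise ValueError(f"{path}: marker panel needs cell_type and gene_id columns")
    markers: dict[str, list[str]] = {}
    for _, row in df.iterrows():  # file order defines tie-break order
        markers.setdefault(row["cell_type"], []).append(row["gene_id"])
    return MarkerPanel(markers)


# -- gene models and peaks --------------------------------------------------

def write_gene_models(genes: list[GeneModel], path) -> None:
    rows = []
    for g in genes:
        rows.append(
            {
                "gene_id": g.gene_id,
                "chrom": g.chrom,
                "strand": g.strand,
                "tss": g.tss,
                "exon_starts": ",".join(str(s) for s, _ in g.exons),
                "exon_ends": ",".join(str(e) for _, e in g.exons),
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_models(path) -> list[GeneModel]:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    genes = []
    for _, row in df.iterrows():
        starts = [int(x) for x in str(row["exon_starts"]).split(",")]
        ends = [int(x) for x in str(row["exon_ends"]).split(",")]
        gene = GeneModel(
            gene_id=row["gene_id"],
            chrom=row["chrom"],
            strand=row["strand"],
            exons=tuple(zip(starts, ends)),
        )
        if "tss" in df.columns and int(row["tss"]) != gene.tss:
            raise ValueError(
                f"{path}: gene {gene.gene_id} tss column ({row['tss']}) "
                f"inconsistent with strand/exons (expected {gene.tss})"
            )
        genes.append(gene)
    return genes


def write_peaks_bed(peaks: list[GenomicInterval], path) -> None:
    with open(path, "w") as fh:
        for i, p in enumerate(peaks, start=1):
            name = p.name or f"peak{i:04d}"
            strand = p.strand or "."
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t0\t{strand}\n")


def read_peaks_bed(path) -> list[GenomicInterval]:
    peaks = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: malformed BED line {line!r}")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            name = parts[3] if len(parts) > 3 else None
            strand = parts[5] if len(parts) > 5 and parts[5] in "+-" else None
            peaks.append(GenomicInterval(chrom, start, end, strand=strand, name=name))
    return peaks


# -- gene sets and LR pairs -------------------------------------------------

def write_gene_set(genes, path) -> None:
    pd.DataFrame({"gene_id": sorted(str(g) for g in genes)}).to_csv(path, sep="\t", index=False)


def read_gene_set(path) -> set[str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "gene_id" not in df.columns:
        raise ValueError(f"{path}: gene set file needs a gene_id column")
    return set(df["gene_id"])


def write_lr_pairs(pairs, path) -> None:
    pd.DataFrame(
        [(p.ligand, p.receptor) for p in pairs], columns=["ligand", "receptor"]
    ).to_csv(path, sep="\t", index=False)


def read_lr_pairs(path):
    from .comms import LRPair

    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"ligand", "receptor"} <= set(df.columns):
        raise ValueError(f"{path}: pair list needs ligand and receptor columns")
    return [LRPair(row["ligand"], row["receptor"]) for _, row in df.iterrows()]


# -- ground truth -----------------------------------------------------------

def write_truth(truth: SyntheticTruth, path) -> None:
    payload = {
        "planted_candidate_ids": sorted(truth.planted_candidate_ids),
        "cell_true_type": list(truth.cell_true_type),
        "planted_rescued_ids": sorted(truth.planted_rescued_ids),
        "peak_true_category": list(truth.peak_true_category),
        "active_lr_pairs": sorted(list(p) for p in truth.active_lr_pairs),
        "mito_outlier_cells": sorted(truth.mito_outlier_cells),
        "multiplet_cells": sorted(truth.multiplet_cells),
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)


def read_truth(path) -> SyntheticTruth:
    with open(path) as fh:
        d = json.load(fh)
    return SyntheticTruth(
        planted_candidate_ids=frozenset(d.get("planted_candidate_ids", [])),
        cell_true_type=list(d.get("cell_true_type", [])),
        planted_rescued_ids=frozenset(d.get("planted_rescued_ids", [])),
        peak_true_category=list(d.get("peak_true_category", [])),
        active_lr_pairs=frozenset(tuple(p) for p in d.get("active_lr_pairs", [])),
        mito_outlier_cells=frozenset(d.get("mito_outlier_cells", [])),
        multiplet_cells=frozenset(d.get("multiplet_cells", [])),
    )
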