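"""Single-cell QC, normalization, and GMM+Fisher cluster annotation.

The annotation algorithm mirrors a marker-panel workflow for vascular
tissue: endothelial cells (Cdh5, Pecam1), vascular smooth muscle cells
(Acta2), macrophages (Itgam, Adgre1, Fcgr1), and fibroblasts (S100a4).
For each cell type the panel is averaged into one meta-marker per cell, a
two-component Gaussian mixture splits cells into marker-high and
marker-low sets, and each pre-computed cluster is tested for enrichment of
marker-high cells with a one-sided Fisher's exact test; the cell type with
the smallest p-value is assigned to the cluster.

Cells are held in an :class:`anndata.AnnData` with integer counts in
``X``, per-cell QC metadata in ``obs`` (``n_genes_expressed``,
``mito_fraction``) and optional cluster ids in ``obs['cluster']``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import anndata as ad
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .gmm import GMMFit, binarize_high, fit_gmm_1d

__all__ = [
    "MarkerPanel",
    "AnnotationResult",
    "make_cell_dataset",
    "qc_filter",
    "log_normalize",
    "meta_marker",
    "fisher_one_sided",
    "annotate_clusters",
    "cluster_cells_basic",
]

logger = logging.getLogger(__name__)

#: Default vascular marker panel (mouse gene symbols).
DEFAULT_PANEL: dict[str, list[str]] = {
    "EC": ["Cdh5", "Pecam1"],
    "VSMC": ["Acta2"],
    "Macrophage": ["Itgam", "Adgre1", "Fcgr1"],
    "Fibroblast": ["S100a4"],
}


@dataclass
class MarkerPanel:
    """Ordered mapping of cell type -> marker gene list.

    Declaration order matters: it breaks ties when two cell types reach
    the same enrichment p-value for a cluster.
    """

    markers: dict[str, list[str]]

    def __post_init__(self) -> None:
        if not self.markers:
            raise ValueError("marker panel is empty")
        for cell_type, genes in self.markers.items():
            if not genes:
                raise ValueError(f"marker list for {cell_type!r} is empty")

    @property
    def cell_types(self) -> list[str]:
        return list(self.markers)

    def __iter__(self):
        return iter(self.markers.items())

    @classmethod
    def default(cls) -> "MarkerPanel":
        return cls({k: list(v) for k, v in DEFAULT_PANEL.items()})


@dataclass
class AnnotationResult:
    """Cluster-by-cell-type Fisher p-values and the per-cluster assignment."""

    p_matrix: pd.DataFrame  # rows: cluster ids, columns: cell types
    assignment: dict[str, str]
    gmm_fits: dict[str, GMMFit] | None = None


def _dense(X) -> np.ndarray:
    return np.asarray(X.todense()) if sp.issparse(X) else np.asarray(X)


def make_cell_dataset(
    counts: np.ndarray,
    gene_ids: list[str],
    cell_ids: list[str] | None = None,
    mito_prefix: str = "mt-",
    cluster_labels=None,
) -> ad.AnnData:
    """Build the AnnData container, computing QC metadata from counts."""
    counts = np.asarray(counts)
    n_cells, n_genes = counts.shape
    if len(gene_ids) != n_genes:
        raise ValueError("gene_ids length does not match counts")
    if cell_ids is None:
        cell_ids = [f"cell{i}" for i in range(n_cells)]
    mito_mask = np.array([g.lower().startswith(mito_prefix.lower()) for g in gene_ids])
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, counts[:, mito_mask].sum(axis=1) / totals, 0.0)
    obs = pd.DataFrame(
        {
            "n_genes_expressed": (counts > 0).sum(axis=1),
            "mito_fraction": mito_frac,
        },
        index=pd.Index(cell_ids, name="cell_id"),
    )
    if cluster_labels is not None:
        obs["cluster"] = [str(c) for c in cluster_labels]
    adata = ad.AnnData(
        X=sp.csr_matrix(counts),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(gene_ids, name="gene_id")),
    )
    adata.var["mito"] = mito_mask
    return adata


def qc_filter(
    ds: ad.AnnData, max_genes: int = 3000, max_mito: float = 0.25
) -> ad.AnnData:
    """Remove multiplet-like and dying cells.

    Drops cells with *over* ``max_genes`` expressed genes (potential
    multiplets) or a mitochondrial read fraction *over* ``max_mito``
    (low-quality/dying cells). Both comparisons are strict, so boundary
    cells are kept. The gene set is unchanged and the filter is
    idempotent.
    """
    ng = ds.obs["n_genes_expressed"].to_numpy()
    mito = ds.obs["mito_fraction"].to_numpy()
    keep = (ng <= max_genes) & (mito <= max_mito)
    if not keep.any():
        warnings.warn("qc_filter removed every cell", stacklevel=2)
    return ds[keep].copy()


def log_normalize(ds, scale: float = 10_000.0) -> np.ndarray:
    """Library-size normalize and natural-log transform counts.

    Per cell: ``ln(1 + count * scale / cell_total)``. Scale-invariant with
    respect to per-cell sequencing depth. Cells with zero total counts
    cannot be normalized and raise an error naming them.
    """
    if isinstance(ds, ad.AnnData):
        counts = _dense(ds.X)
        names = list(ds.obs_names)
    else:
        counts = np.asarray(ds, dtype=float)
        names = [str(i) for i in range(counts.shape[0])]
    if (counts < 0).any():
        raise ValueError("counts must be nonnegative")
    totals = counts.sum(axis=1)
    zero = np.flatnonzero(totals == 0)
    if zero.size:
        raise ValueError(
            f"cell(s) with zero total counts cannot be normalized: "
            f"{[names[i] for i in zero[:5]]}"
        )
    return np.log1p(counts * (scale / totals[:, None]))


def meta_marker(normalized: np.ndarray, gene_ids: list[str], panel_genes: list[str]) -> np.ndarray:
    """Average the normalized expression of a marker panel per cell."""
    index = {g: i for i, g in enumerate(gene_ids)}
    missing = [g for g in panel_genes if g not in index]
    if missing:
        raise KeyError(f"marker gene(s) absent from dataset: {missing}")
    cols = [index[g] for g in panel_genes]
    return np.asarray(normalized)[:, cols].mean(axis=1)


def fisher_one_sided(a: int, b: int, c: int, d: int) -> float:
    """One-sided (enrichment) Fisher's exact p for the 2x2 table [[a,b],[c,d]].

    ``a`` = in-cluster & marker-high, ``b`` = in-cluster & low, ``c`` =
    out-of-cluster & high, ``d`` = out & low. Returns the hypergeometric
    upper-tail probability P(X >= a) with margins fixed.
    """
    for v in (a, b, c, d):
        if int(v) != v or v < 0:
            raise ValueError(f"table entries must be nonnegative integers, got {v!r}")
    a, b, c, d = int(a), int(b), int(c), int(d)
    if a == 0:
        return 1.0  # P(X >= 0) = 1, including the empty table
    total = a + b + c + d
    # X ~ Hypergeom(N=total, K=a+c highs, n=a+b draws); P(X >= a)
    p = float(stats.hypergeom.sf(a - 1, total, a + c, a + b))
    return min(p, 1.0)


def annotate_clusters(
    ds: ad.AnnData,
    panel: MarkerPanel,
    scale: float = 10_000.0,
    gmm_tol: float = 1e-6,
    gmm_max_iter: int = 500,
    seed: int | None = None,
) -> AnnotationResult:
    """Assign a cell type to every cluster via GMM binarization + Fisher.

    For each cell type: average its markers into a meta-marker, fit a
    two-component Gaussian mixture across all cells, flag marker-high
    cells, and Fisher-test each cluster for enrichment of high cells.
    Each cluster receives the cell type with the lowest p-value; exact
    ties go to the type declared first in the panel.
    """
    if "cluster" not in ds.obs:
        raise ValueError("dataset has no 'cluster' labels; run clustering first")
    clusters = ds.obs["cluster"].astype(str)
    normalized = log_normalize(ds, scale=scale)
    gene_ids = list(ds.var_names)

    high_flags: dict[str, np.ndarray] = {}
    fits: dict[str, GMMFit] = {}
    for cell_type, genes in panel:
        mm = meta_marker(normalized, gene_ids, genes)
        fit = fit_gmm_1d(mm, tol=gmm_tol, max_iter=gmm_max_iter, seed=seed)
        fits[cell_type] = fit
        high_flags[cell_type] = binarize_high(fit, mm)

    cluster_ids = sorted(clusters.unique())
    p = pd.DataFrame(index=cluster_ids, columns=panel.cell_types, dtype=float)
    for cid in cluster_ids:
        in_cluster = (clusters == cid).to_numpy()
        if in_cluster.sum() < 2:
            warnings.warn(f"cluster {cid!r} has fewer than 2 cells", stacklevel=2)
        for cell_type in panel.cell_types:
            high = high_flags[cell_type]
            a = int((in_cluster & high).sum())
            b = int((in_cluster & ~high).sum())
            c = int((~in_cluster & high).sum())
            d = int((~in_cluster & ~high).sum())
            p.at[cid, cell_type] = fisher_one_sided(a, b, c, d)

    assignment: dict[str, str] = {}
    for cid in cluster_ids:
        row = p.loc[cid]
        best = panel.cell_types[0]
        for cell_type in panel.cell_types:  # declaration order breaks ties
            if row[cell_type] < row[best]:
                best = cell_type
        assignment[cid] = best
    return AnnotationResult(p_matrix=p, assignment=assignment, gmm_fits=fits)


def cluster_cells_basic(
    normalized: np.ndarray, k: int, n_pcs: int = 15, seed: int = 0
) -> np.ndarray:
    """Plumbing clustering: PCA to ``n_pcs`` then seeded k-means.

    Exists so the pipeline can run end-to-end on synthetic data without an
    external graph-clustering tool; cluster labels from any method can be
    supplied instead via ``obs['cluster']``.
    """
    from sklearn.cluster import KMeans
    from sklearn.decomposition import PCA

    X = np.asarray(normalized, dtype=float)
    if k > X.shape[0]:
        raise ValueError(f"k={k} exceeds the number of cells ({X.shape[0]})")
    if k == 1:
        return np.zeros(X.shape[0], dtype=int)
    n_pcs = min(n_pcs, X.shape[0] - 1, X.shape[1])
    pcs = PCA(n_components=n_pcs, svd_solver="full", random_state=seed).fit_transform(X)
    km = KMeans(n_clusters=k, n_init=10, random_state=seed)
    return km.fit_predict(pcs)
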