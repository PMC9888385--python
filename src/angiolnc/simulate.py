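"""Synthetic-data generators with known ground truth.

Every downstream stage of the pipeline is exercised on data produced
here: three bulk contrast tables with planted divergently regulated
genes; a cell-by-gene count matrix with marker-elevated cell populations
and planted QC outliers; a toy genome with gene models and peaks planted
per feature category; and a three-group knockout/overexpression rescue
design with planted rescued genes.

Counts follow a negative-binomial model (var = mu + phi * mu^2), the
standard overdispersed RNA-seq assumption. All generators draw from
independent substreams of one global seed (see
:class:`~angiolnc.config.SimulationConfig`), so identical configs give
byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import SimulationConfig
from .diffexp import bh_adjust
from .genome import GeneModel, GenomicInterval
from .scrna import MarkerPanel, make_cell_dataset

__all__ = [
    "SyntheticTruth",
    "gen_contrast_tables",
    "gen_cell_dataset",
    "gen_genome_fixture",
    "gen_rescue_design",
]

#: Mitochondrial gene names used by the cell generator (mouse-style).
MITO_GENES = (
    "mt-Nd1", "mt-Nd2", "mt-Co1", "mt-Co2", "mt-Atp6",
    "mt-Co3", "mt-Nd4", "mt-Nd5", "mt-Nd6", "mt-Cytb",
)
# fixed relative abundances of the mito genes (sum to 1)
_MITO_PROPS = np.array([0.18, 0.14, 0.13, 0.11, 0.10, 0.09, 0.08, 0.07, 0.06, 0.04])

#: Library-size boost applied to planted multiplet-like cells.
MULTIPLET_BOOST = 6.0


@dataclass
class SyntheticTruth:
    """Ground truth planted by the generators."""

    planted_candidate_ids: frozenset[str] = frozenset()
    cell_true_type: list[str] = field(default_factory=list)
    planted_rescued_ids: frozenset[str] = frozenset()
    peak_true_category: list[str] = field(default_factory=list)
    active_lr_pairs: frozenset[tuple[str, str]] = frozenset()
    mito_outlier_cells: frozenset[str] = frozenset()
    multiplet_cells: frozenset[str] = frozenset()


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Negative-binomial counts with var = mu + phi * mu^2 (Poisson at phi=0)."""
    mean = np.asarray(mean, dtype=float)
    if dispersion < 0:
        raise ValueError("dispersion must be >= 0")
    if dispersion == 0:
        return rng.poisson(mean)
    size = 1.0 / dispersion
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(size, size / (size + mean[pos]))
    return out


# ---------------------------------------------------------------------------
# contrast tables


def gen_contrast_tables(
    cfg: SimulationConfig,
) -> tuple[tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame], SyntheticTruth]:
    """Three contrast tables (Hx, HG, TNF) with planted divergent genes.

    Planted genes receive a significant effect of ``effect_size`` in the
    hypoxia contrast and the opposite sign in both diabetic contrasts
    (half mirrored); background genes carry independent noise only.
    Observed log2FCs are the true effects plus N(0, noise_sd) noise, and
    p-values are two-sided z-tests treating ``noise_sd`` as the known
    standard error, BH-adjusted per table.
    """
    rng = cfg.rng("contrasts")
    n, k = cfg.n_genes, cfg.n_planted
    genes = [f"lnc{i:05d}" for i in range(1, n + 1)]
    planted_idx = rng.choice(n, size=k, replace=False)
    hx_sign = np.where(rng.random(k) < 0.5, 1.0, -1.0)

    true = {name: np.zeros(n) for name in ("hx", "hg", "tnf")}
    true["hx"][planted_idx] = hx_sign * cfg.effect_size
    true["hg"][planted_idx] = -hx_sign * cfg.effect_size
    true["tnf"][planted_idx] = -hx_sign * cfg.effect_size

    tables = []
    for name in ("hx", "hg", "tnf"):
        obs = true[name] + rng.normal(0.0, cfg.noise_sd, size=n)
        if cfg.noise_sd > 0:
            pvals = 2.0 * stats.norm.sf(np.abs(obs) / cfg.noise_sd)
        else:
            pvals = np.where(obs != 0, 0.0, 1.0)
        tables.append(
            pd.DataFrame(
                {
                    "gene_id": genes,
                    "log2fc": obs,
                    "pvalue": pvals,
                    "padj": bh_adjust(pvals),
                }
            )
        )
    truth = SyntheticTruth(
        planted_candidate_ids=frozenset(genes[i] for i in planted_idx)
    )
    return (tables[0], tables[1], tables[2]), truth


# ---------------------------------------------------------------------------
# single-cell dataset


def gen_cell_dataset(cfg: SimulationConfig, panel: MarkerPanel | None = None):
    """Cell-by-gene counts with marker-elevated populations and QC outliers.

    One population of ``n_cells_per_type`` cells per panel cell type.
    Marker genes of a cell's own type have their count means multiplied by
    ``exp(marker_elevation)``. A ``mito_outlier_rate`` fraction of cells
    get a mitochondrial fraction drawn above the 25% QC cutoff (normal
    cells draw from Beta(2, 38), clipped below the cutoff, so the cutoff
    exactly separates planted outliers); a ``multiplet_rate`` fraction get a
    6-fold library boost that pushes them over 3,000 expressed genes.
    Cluster labels in ``obs['cluster']`` are set to the true type, since
    clustering itself is pluggable input for the annotation stage.
    """
    if panel is None:
        panel = MarkerPanel.default()
    marker_genes: list[str] = []
    for _, gl in panel:
        for g in gl:
            if g in marker_genes:
                raise ValueError(f"marker gene {g!r} appears in two panels")
            marker_genes.append(g)

    n_mito = len(MITO_GENES)
    n_background = cfg.n_cell_genes - n_mito - len(marker_genes)
    if n_background < 1:
        raise ValueError("n_cell_genes too small for the panel plus mito genes")
    background = [f"g{i:05d}" for i in range(1, n_background + 1)]
    gene_ids = list(MITO_GENES) + marker_genes + background
    marker_col = {g: gene_ids.index(g) for g in marker_genes}

    rng = cfg.rng("cells")
    types = panel.cell_types
    n_cells = cfg.n_cells_per_type * len(types)
    cell_types = np.repeat(types, cfg.n_cells_per_type)

    # per-gene base means: background lognormal, markers at a common
    # baseline so the marker-low component is nonzero
    base = np.empty(len(gene_ids))
    base[:n_mito] = 0.0  # mito counts are allocated afterwards
    base[n_mito : n_mito + len(marker_genes)] = 2.0
    base[n_mito + len(marker_genes):] = rng.lognormal(np.log(0.5), 1.0, n_background)

    mean = np.tile(base, (n_cells, 1))
    for cell_type, genes in panel:
        rows = cell_types == cell_type
        for g in genes:
            mean[rows, marker_col[g]] *= np.exp(cfg.marker_elevation)

    is_multiplet = rng.random(n_cells) < cfg.multiplet_rate
    mean[is_multiplet] *= MULTIPLET_BOOST

    counts = _nb_draw(rng, mean, cfg.nb_dispersion_sc)

    # mitochondrial counts: normal cells Beta(2, 38) clipped at the 25%
    # cutoff; planted outliers Uniform(0.30, 0.60)
    is_mito_out = rng.random(n_cells) < cfg.mito_outlier_rate
    frac = np.minimum(rng.beta(2.0, 38.0, n_cells), 0.24)
    frac[is_mito_out] = rng.uniform(0.30, 0.60, int(is_mito_out.sum()))
    non_mito_total = counts[:, n_mito:].sum(axis=1)
    # floor keeps the realized fraction at or below the target, so normal
    # cells (clipped at 0.24) can never cross the 25% QC cutoff
    mito_total = np.floor(frac / (1.0 - frac) * non_mito_total).astype(np.int64)
    counts[:, :n_mito] = rng.multinomial(mito_total, _MITO_PROPS)

    cell_ids = [f"cell{i:04d}" for i in range(1, n_cells + 1)]
    adata = make_cell_dataset(
        counts, gene_ids, cell_ids=cell_ids, cluster_labels=cell_types
    )
    adata.obs["true_type"] = list(cell_types)
    truth = SyntheticTruth(
        cell_true_type=list(cell_types),
        mito_outlier_cells=frozenset(np.array(cell_ids)[is_mito_out]),
        multiplet_cells=frozenset(np.array(cell_ids)[is_multiplet]),
    )
    return adata, truth


# ---------------------------------------------------------------------------
# genome fixture

_GENE_LEN = 12_000
_GAP = 14_000
_PEAK_LEN = 200


def gen_genome_fixture(
    cfg: SimulationConfig,
    n_peaks: int = 200,
    proportions: dict[str, float] | None = None,
    n_fixture_genes: int = 20,
    window: int = 3000,
    chrom_length: int | None = None,
):
    """Toy chromosome with non-overlapping genes and category-planted peaks.

    Genes alternate strand and carry three exons (the middle one far
    enough from both span ends to sit outside any promoter window), so
    each category has unambiguous room: promoter peaks are planted inside
    TSS +/- window, exon peaks inside the middle exon, intron peaks in the
    first intron beyond the window, and intergenic peaks in the middle of
    inter-gene gaps. The planted label follows the same priority rules the
    classifier uses, so classification recovers it exactly.
    """
    if proportions is None:
        proportions = {"promoter": 0.5, "intron": 0.2, "intergenic": 0.2, "exon": 0.1}
    unknown = set(proportions) - {"promoter", "exon", "intron", "intergenic"}
    if unknown:
        raise ValueError(f"unknown peak categories: {sorted(unknown)}")
    if abs(sum(proportions.values()) - 1.0) > 1e-9:
        raise ValueError("category proportions must sum to 1")

    required = n_fixture_genes * (_GENE_LEN + _GAP) + _GAP
    if chrom_length is None:
        chrom_length = required
    elif chrom_length < required:
        raise ValueError(
            f"chromosome of length {chrom_length} too short for "
            f"{n_fixture_genes} genes (need >= {required})"
        )

    rng = cfg.rng("genome")
    chrom = "chrS"
    genes: list[GeneModel] = []
    for i in range(n_fixture_genes):
        start = _GAP + i * (_GENE_LEN + _GAP)
        strand = "+" if i % 2 == 0 else "-"
        exons = (
            (start, start + 500),
            (start + 5500, start + 6500),
            (start + _GENE_LEN - 500, start + _GENE_LEN),
        )
        genes.append(
            GeneModel(gene_id=f"gene{i + 1:03d}", chrom=chrom, strand=strand, exons=exons)
        )

    # largest-remainder allocation of peak counts to categories
    cats = ["promoter", "exon", "intron", "intergenic"]
    raw = {c: proportions.get(c, 0.0) * n_peaks for c in cats}
    alloc = {c: int(np.floor(raw[c])) for c in cats}
    for c in sorted(cats, key=lambda c: raw[c] - alloc[c], reverse=True):
        if sum(alloc.values()) == n_peaks:
            break
        alloc[c] += 1

    peaks: list[GenomicInterval] = []
    categories: list[str] = []
    counter = 0
    for cat in cats:
        for _ in range(alloc[cat]):
            counter += 1
            if cat == "intergenic":
                gap_i = int(rng.integers(0, n_fixture_genes + 1))
                gap_start = gap_i * (_GENE_LEN + _GAP)
                lo = gap_start + window + 100
                hi = gap_start + _GAP - window - 100 - _PEAK_LEN
            else:
                g = genes[int(rng.integers(0, n_fixture_genes))]
                s = g.span[0]
                if cat == "promoter":
                    lo = max(0, g.tss - window)
                    hi = g.tss + window - _PEAK_LEN
                elif cat == "exon":
                    lo, hi = s + 5550, s + 6450 - _PEAK_LEN
                else:  # intron 1, clear of both promoter windows and exons
                    lo, hi = s + 3600, s + 5400 - _PEAK_LEN
            pos = int(rng.integers(lo, hi + 1))
            peaks.append(
                GenomicInterval(
                    chrom=chrom, start=pos, end=pos + _PEAK_LEN,
                    name=f"peak{counter:04d}",
                )
            )
            categories.append(cat)

    truth = SyntheticTruth(peak_true_category=list(categories))
    return genes, peaks, truth


# ---------------------------------------------------------------------------
# rescue design


def gen_rescue_design(cfg: SimulationConfig):
    """Three-group rescue experiment (WT+GFP, KO+GFP, KO+OE) with planted genes.

    Planted rescued genes have their mean halved ``effect_size`` times in
    the knockout (down KO vs. WT by ``effect_size`` log2 units) and fully
    restored in the overexpression group (up OE vs. KO by the same
    amount); all other genes share one mean across groups. Counts are
    negative binomial with the bulk dispersion, ``n_replicates`` columns
    per group.
    """
    rng = cfg.rng("rescue")
    n, k = cfg.n_genes, cfg.n_planted
    genes = [f"g{i:05d}" for i in range(1, n + 1)]
    planted_idx = rng.choice(n, size=k, replace=False)
    base = rng.lognormal(np.log(200.0), 0.5, n)

    mean_wt = base.copy()
    mean_ko = base.copy()
    mean_ko[planted_idx] = base[planted_idx] / 2.0**cfg.effect_size
    mean_oe = base.copy()  # OE restores planted genes to the WT level

    reps = cfg.n_replicates
    groups = {}
    for name, mu in (("wt_gfp", mean_wt), ("ko_gfp", mean_ko), ("ko_leene", mean_oe)):
        groups[name] = _nb_draw(rng, np.tile(mu[:, None], (1, reps)), cfg.nb_dispersion_bulk)

    truth = SyntheticTruth(
        planted_rescued_ids=frozenset(genes[i] for i in planted_idx)
    )
    return groups, genes, truth
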