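"""QC filtering, normalization, meta-markers, Fisher test, annotation."""

import math
from fractions import Fraction
from math import comb

import numpy as np
import pytest

from angiolnc import (
    MarkerPanel,
    SimulationConfig,
    annotate_clusters,
    cluster_cells_basic,
    fisher_one_sided,
    gen_cell_dataset,
    log_normalize,
    make_cell_dataset,
    meta_marker,
    qc_filter,
)


# -- QC ---------------------------------------------------------------------

def _qc_example():
    """5 cells: gene counts 100/3500/2000/3001/50, mito .10/.10/.30/.20/.26."""
    n_genes = 4000
    gene_counts = [100, 3500, 2000, 3001, 50]
    mito_fracs = [0.10, 0.10, 0.30, 0.20, 0.26]
    counts = np.zeros((5, n_genes), dtype=int)
    for i, (ng, mf) in enumerate(zip(gene_counts, mito_fracs)):
        counts[i, 10 : 10 + ng - 1] = 1  # ng-1 non-mito genes expressed
        # a single mito gene carries the whole mito fraction
        non_mito = ng - 1
        counts[i, 0] = round(mf / (1 - mf) * non_mito)
    genes = [f"mt-g{i}" if i < 10 else f"g{i}" for i in range(n_genes)]
    ds = make_cell_dataset(counts, genes, cell_ids=[f"c{i}" for i in range(1, 6)])
    # the constructed mito fractions must hit the intended values
    # small integer totals quantize the fraction; each stays on its side of 25%
    assert np.allclose(ds.obs["mito_fraction"], mito_fracs, atol=0.006)
    assert ds.obs["n_genes_expressed"].tolist() == gene_counts
    return ds


def test_qc_worked_example_keeps_only_first_cell():
    ds = qc_filter(_qc_example(), max_genes=3000, max_mito=0.25)
    assert list(ds.obs_names) == ["c1"]


def test_qc_boundary_cells_kept():
    counts = np.zeros((1, 4000), dtype=int)
    counts[0, 10:3009] = 1  # 2999 non-mito genes
    counts[0, 10] = 2  # non-mito total 3000
    counts[0, 0] = 1000  # mito fraction exactly 1000/4000 = 0.25; 3000 genes
    ds = make_cell_dataset(counts, [f"mt-g{i}" if i < 10 else f"g{i}" for i in range(4000)])
    assert ds.obs["n_genes_expressed"].iloc[0] == 3000
    assert ds.obs["mito_fraction"].iloc[0] == 0.25
    kept = qc_filter(ds, max_genes=3000, max_mito=0.25)
    assert kept.n_obs == 1


def test_qc_identity_and_idempotence(tiny_adata):
    once = qc_filter(tiny_adata, max_genes=10, max_mito=0.9)
    assert once.n_obs == tiny_adata.n_obs  # all pass
    twice = qc_filter(qc_filter(tiny_adata, max_genes=3, max_mito=0.2), max_genes=3, max_mito=0.2)
    ref = qc_filter(tiny_adata, max_genes=3, max_mito=0.2)
    assert list(twice.obs_names) == list(ref.obs_names)


def test_qc_empty_result_warns(tiny_adata):
    with pytest.warns(UserWarning, match="every cell"):
        out = qc_filter(tiny_adata, max_genes=0, max_mito=0.0)
    assert out.n_obs == 0


# -- normalization ----------------------------------------------------------

def test_log_normalize_closed_form():
    counts = np.array([[10, 9990], [0, 5]])
    norm = log_normalize(counts, scale=10_000)
    assert norm[0, 0] == pytest.approx(math.log(11))
    assert norm[1, 0] == 0.0  # zero count stays zero


def test_log_normalize_depth_invariance():
    counts = np.array([[3, 7, 0, 10]])
    assert np.allclose(log_normalize(counts), log_normalize(counts * 2))


def test_log_normalize_zero_total_cell_named():
    counts = np.array([[1, 2], [0, 0]])
    with pytest.raises(ValueError, match="1"):
        log_normalize(counts)


# -- meta-markers -----------------------------------------------------------

def test_meta_marker_mean_identity_symmetry():
    norm = np.array([[1.0, 3.0, 9.0], [2.0, 4.0, 9.0]])
    genes = ["a", "b", "c"]
    np.testing.assert_allclose(meta_marker(norm, genes, ["a", "b"]), [2.0, 3.0])
    np.testing.assert_allclose(meta_marker(norm, genes, ["c"]), norm[:, 2])
    np.testing.assert_allclose(
        meta_marker(norm, genes, ["b", "a"]), meta_marker(norm, genes, ["a", "b"])
    )
    with pytest.raises(KeyError, match="zz"):
        meta_marker(norm, genes, ["a", "zz"])


# -- Fisher -----------------------------------------------------------------

def fisher_oracle(a, b, c, d) -> Fraction:
    """Exhaustive hypergeometric enumeration, exact rational arithmetic."""
    n1, k, total = a + b, a + c, a + b + c + d
    denom = comb(total, n1)
    num = sum(
        comb(k, x) * comb(total - k, n1 - x)
        for x in range(a, min(n1, k) + 1)
    )
    return Fraction(num, denom)


def test_fisher_spot_value_and_edge_cases():
    assert fisher_one_sided(3, 1, 1, 3) == pytest.approx(17 / 70)
    assert fisher_one_sided(0, 5, 2, 7) == 1.0  # P(X >= 0)
    # extremal table: a at its margin-allowed maximum
    p_extreme = fisher_one_sided(4, 0, 0, 4)
    assert p_extreme == pytest.approx(float(fisher_oracle(4, 0, 0, 4)))
    assert p_extreme <= fisher_one_sided(3, 1, 1, 3)
    with pytest.raises(ValueError):
        fisher_one_sided(-1, 0, 0, 0)
    with pytest.raises(ValueError):
        fisher_one_sided(0.5, 0, 0, 0)


def test_fisher_matches_enumeration_on_random_tables():
    rng = np.random.default_rng(5)
    for _ in range(50):
        a, b, c, d = rng.integers(0, 30, size=4)
        expected = float(fisher_oracle(int(a), int(b), int(c), int(d)))
        assert fisher_one_sided(int(a), int(b), int(c), int(d)) == pytest.approx(
            expected, rel=1e-12
        )


# -- annotation -------------------------------------------------------------

def test_annotation_recovers_types_on_synthetic_data(panel):
    cfg = SimulationConfig(seed=4)
    adata, truth = gen_cell_dataset(cfg, panel)
    result = annotate_clusters(adata, panel)
    assert all(result.assignment[t] == t for t in panel.cell_types)
    # assignment is the argmin of each row of the p-matrix
    for cid, cell_type in result.assignment.items():
        assert result.p_matrix.loc[cid].min() == result.p_matrix.loc[cid, cell_type]


def test_single_type_panel_assigns_that_type(panel):
    cfg = SimulationConfig(seed=4, n_cells_per_type=50, n_cell_genes=500)
    adata, _ = gen_cell_dataset(cfg, panel)
    solo = MarkerPanel({"EC": ["Cdh5", "Pecam1"]})
    result = annotate_clusters(adata, solo)
    assert set(result.assignment.values()) == {"EC"}


def test_annotation_equivariant_under_cluster_relabeling(panel):
    cfg = SimulationConfig(seed=4, n_cells_per_type=50, n_cell_genes=500)
    adata, _ = gen_cell_dataset(cfg, panel)
    ref = annotate_clusters(adata, panel)
    mapping = {"EC": "c1", "VSMC": "c2", "Macrophage": "c3", "Fibroblast": "c4"}
    adata.obs["cluster"] = [mapping[c] for c in adata.obs["cluster"]]
    renamed = annotate_clusters(adata, panel)
    for old, new in mapping.items():
        assert renamed.assignment[new] == ref.assignment[old]


def test_annotation_requires_cluster_labels(tiny_adata, panel):
    assert "cluster" not in tiny_adata.obs
    with pytest.raises(ValueError, match="cluster"):
        annotate_clusters(tiny_adata, panel)


# -- basic clustering -------------------------------------------------------

def test_basic_clustering_separates_two_populations():
    from sklearn.metrics import adjusted_rand_score

    rng = np.random.default_rng(0)
    pop1 = rng.normal(0, 1, (100, 30))
    pop2 = rng.normal(4, 1, (100, 30))
    X = np.vstack([pop1, pop2])
    labels = cluster_cells_basic(X, k=2, seed=0)
    truth = [0] * 100 + [1] * 100
    assert adjusted_rand_score(truth, labels) >= 0.95
    # determinism
    assert (labels == cluster_cells_basic(X, k=2, seed=0)).all()
    # trivial and error cases
    assert set(cluster_cells_basic(X, k=1, seed=0)) == {0}
    with pytest.raises(ValueError, match="k="):
        cluster_cells_basic(X[:3], k=5, seed=0)
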