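import numpy as np
import pandas as pd
import pytest

from angiolnc import MarkerPanel, SimulationConfig, make_cell_dataset


@pytest.fixture
def panel() -> MarkerPanel:
    return MarkerPanel.default()


@pytest.fixture
def small_cfg() -> SimulationConfig:
    """A light configuration for fast unit tests (not the study conditions)."""
    return SimulationConfig(
        n_genes=200,
        n_planted=5,
        n_cells_per_type=40,
        n_cell_genes=300,
        seed=0,
    )


@pytest.fixture
def tiny_adata():
    """Five hand-built cells over 6 genes (one mitochondrial)."""
    counts = np.array(
        [
            [5, 0, 3, 2, 0, 1],
            [1, 1, 1, 1, 1, 1],
            [0, 0, 10, 0, 0, 0],
            [2, 2, 2, 2, 2, 2],
            [0, 9, 0, 0, 1, 0],
        ]
    )
    genes = ["mt-Nd1", "Cdh5", "Pecam1", "Acta2", "Itgam", "S100a4"]
    return make_cell_dataset(counts, genes)


def contrast_frame(genes, log2fc, padj, pvalue=None) -> pd.DataFrame:
    """Helper to assemble a contrast table with consistent columns."""
    padj = np.asarray(padj, dtype=float)
    if pvalue is None:
        pvalue = padj * 0.5  # any value <= padj satisfies the BH invariant
    return pd.DataFrame(
        {"gene_id": list(genes), "log2fc": log2fc, "pvalue": pvalue, "padj": padj}
    )
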