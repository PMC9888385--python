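"""Desk-scale differential expression and multiple-testing utilities.

``de_test_simple`` is a deliberately simple two-group test for bulk
counts — median-of-ratios size factors, pooled two-sample t on log2
normalized counts, Benjamini-Hochberg adjustment — intended for synthetic desk-scale
experiments where the integration logic downstream, not the DE engine, is
under study. ``sc_deg_count`` is the single-cell analogue: per cell type,
a Wilcoxon rank-sum test per gene between two conditions with a fold-change
cutoff on the difference of mean log-normalized expression.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = ["bh_adjust", "de_test_simple", "size_factors", "sc_deg_count"]


def bh_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment of p-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p.ravel(), method="fdr_bh")[1].reshape(p.shape)


def size_factors(counts: np.ndarray) -> np.ndarray:
    """Median-of-ratios size factors (one per sample/column).

    The reference is the per-gene geometric mean across samples, computed
    over genes expressed in every sample; each sample's factor is the
    median ratio of its counts to the reference.
    """
    counts = np.asarray(counts, dtype=float)
    positive = (counts > 0).all(axis=1)
    if not positive.any():
        raise ValueError("no gene has positive counts in every sample")
    log_ref = np.log(counts[positive]).mean(axis=1)
    sf = np.exp(np.median(np.log(counts[positive]) - log_ref[:, None], axis=0))
    return sf


def de_test_simple(
    counts_a: np.ndarray,
    counts_b: np.ndarray,
    gene_ids: list[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Two-group differential expression (B relative to A).

    Parameters are genes-by-replicates count matrices with >= 2 replicates
    each. Returns a DataFrame with columns ``gene_id, log2fc, pvalue,
    padj, direction`` where ``log2fc`` is the log2 ratio of size-factor-
    normalized mean counts (B over A, with a 0.5 pseudocount) and
    ``direction`` is ``up``/``down`` for genes at ``padj < alpha`` (empty
    otherwise).

    The per-gene test is Student's pooled two-sample t on log2 normalized
    counts: with the small, balanced replicate numbers typical of bulk
    designs the pooled test holds its nominal level, whereas the Welch
    approximation is noticeably conservative below n=5 per group.
    """
    A = np.asarray(counts_a, dtype=float)
    B = np.asarray(counts_b, dtype=float)
    if A.ndim != 2 or B.ndim != 2 or A.shape[0] != B.shape[0]:
        raise ValueError("count matrices must be genes x replicates over one universe")
    if A.shape[1] < 2 or B.shape[1] < 2:
        raise ValueError("each group needs >= 2 replicates")
    if A.shape[0] != len(gene_ids):
        raise ValueError("gene_ids length does not match counts")

    sf = size_factors(np.hstack([A, B]))
    normA = A / sf[: A.shape[1]]
    normB = B / sf[A.shape[1]:]

    log2fc = np.log2(normB.mean(axis=1) + 0.5) - np.log2(normA.mean(axis=1) + 0.5)

    logA = np.log2(normA + 1.0)
    logB = np.log2(normB + 1.0)
    identical = (logA.var(axis=1) == 0) & (logB.var(axis=1) == 0) & (
        logA.mean(axis=1) == logB.mean(axis=1)
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        _, pvals = stats.ttest_ind(logB, logA, axis=1, equal_var=True)
    pvals = np.where(identical | np.isnan(pvals), 1.0, pvals)

    padj = bh_adjust(pvals)
    direction = np.where(
        padj < alpha, np.where(log2fc > 0, "up", "down"), ""
    )
    direction = np.where((padj < alpha) & (log2fc == 0), "", direction)
    return pd.DataFrame(
        {
            "gene_id": gene_ids,
            "log2fc": log2fc,
            "pvalue": pvals,
            "padj": padj,
            "direction": direction,
        }
    )


def sc_deg_count(
    normalized: np.ndarray,
    gene_ids: list[str],
    cell_type_labels,
    condition_labels,
    ref_condition: str | None = None,
    logfc_cutoff: float = 0.25,
    alpha: float = 0.05,
) -> dict[str, dict]:
    """Per-cell-type DEG counting between two conditions.

    For each cell type, a Wilcoxon rank-sum test per gene compares the two
    conditions on ``normalized`` (log-normalized, natural-log scale)
    expression, with BH adjustment within the type. A gene is a DEG iff
    ``padj < alpha`` and the absolute difference of mean log expression
    (test condition minus ``ref_condition``) exceeds ``logfc_cutoff``.

    Returns ``{cell_type: {"n_up": int, "n_down": int, "table":
    DataFrame}}``; a type present in only one condition is skipped with a
    warning.
    """
    X = np.asarray(normalized, dtype=float)
    types = np.asarray([str(t) for t in cell_type_labels])
    conds = np.asarray([str(c) for c in condition_labels])
    cond_names = sorted(set(conds))
    if len(cond_names) != 2:
        raise ValueError(f"need exactly 2 conditions, got {cond_names}")
    if ref_condition is None:
        ref_condition = cond_names[0]
    if ref_condition not in cond_names:
        raise ValueError(f"ref_condition {ref_condition!r} not among {cond_names}")
    test_condition = next(c for c in cond_names if c != ref_condition)

    out: dict[str, dict] = {}
    for cell_type in sorted(set(types)):
        ref_mask = (types == cell_type) & (conds == ref_condition)
        test_mask = (types == cell_type) & (conds == test_condition)
        if ref_mask.sum() == 0 or test_mask.sum() == 0:
            warnings.warn(
                f"cell type {cell_type!r} absent from one condition; skipped",
                stacklevel=2,
            )
            continue
        ref_X = X[ref_mask]
        test_X = X[test_mask]
        logfc = test_X.mean(axis=0) - ref_X.mean(axis=0)
        pvals = np.ones(X.shape[1])
        for j in range(X.shape[1]):
            a, b = test_X[:, j], ref_X[:, j]
            if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
                continue  # no variation at all: not testable, keep p = 1
            pvals[j] = stats.ranksums(a, b).pvalue
        padj = bh_adjust(pvals)
        is_deg = (padj < alpha) & (np.abs(logfc) > logfc_cutoff)
        table = pd.DataFrame(
            {
                "gene_id": gene_ids,
                "logfc": logfc,
                "pvalue": pvals,
                "padj": padj,
                "deg": is_deg,
            }
        )
        out[cell_type] = {
            "n_up": int((is_deg & (logfc > 0)).sum()),
            "n_down": int((is_deg & (logfc < 0)).sum()),
            "table": table,
        }
    return out
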