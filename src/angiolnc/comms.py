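"""Permutation-based ligand-receptor interaction inference between cell types.

The interaction score for a (ligand, receptor) pair between a sender and a
receiver cell type is the average of the ligand's mean expression in
sender cells and the receptor's mean expression in receiver cells. Its
significance is assessed against a null built by globally shuffling the
cell-type labels (type sizes preserved), with the add-one estimator

    p = (1 + #{null >= observed}) / (n_perm + 1),

one-sided for enrichment, so p is never 0 and never below
1/(n_perm + 1). This is a deliberately simple, fully specified statistic
in the style of permutation-based cell-communication tools; complexes of
multiple subunits and expression-fraction thresholds are out of scope
(single-gene ligands and receptors only).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

__all__ = [
    "LRPair",
    "InteractionResult",
    "pair_score",
    "permutation_p",
    "score_pairs",
    "interaction_network",
    "network_delta",
]


@dataclass(frozen=True)
class LRPair:
    ligand: str
    receptor: str


@dataclass
class InteractionResult:
    pair: LRPair
    sender: str
    receiver: str
    score: float
    p: float = float("nan")
    n_perm: int = 0

    @property
    def edge(self) -> tuple[str, str, str, str]:
        return (self.sender, self.receiver, self.pair.ligand, self.pair.receptor)


def _column(normalized: np.ndarray, gene_ids: list[str], gene: str) -> np.ndarray:
    try:
        j = gene_ids.index(gene)
    except ValueError:
        raise KeyError(f"gene {gene!r} absent from the expression universe") from None
    return np.asarray(normalized, dtype=float)[:, j]


def pair_score(
    normalized: np.ndarray,
    gene_ids: list[str],
    type_labels,
    pair: LRPair,
    sender: str,
    receiver: str,
) -> float:
    """(mean ligand in sender + mean receptor in receiver) / 2.

    Autocrine signalling (sender == receiver) uses the same formula. A
    gene that is silent in its population simply contributes 0 to its
    term. Only sender/receiver cells enter the score.
    """
    labels = np.asarray([str(t) for t in type_labels])
    for t in (sender, receiver):
        if (labels == t).sum() == 0:
            raise ValueError(f"cell type {t!r} has no cells")
    lig = _column(normalized, gene_ids, pair.ligand)
    rec = _column(normalized, gene_ids, pair.receptor)
    return 0.5 * (lig[labels == sender].mean() + rec[labels == receiver].mean())


def permutation_p(
    normalized: np.ndarray,
    gene_ids: list[str],
    type_labels,
    pair: LRPair,
    sender: str,
    receiver: str,
    n_perm: int = 1000,
    seed: int = 0,
) -> InteractionResult:
    """Score a pair and test it against a label-permutation null."""
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    labels = np.asarray([str(t) for t in type_labels])
    observed = pair_score(normalized, gene_ids, labels, pair, sender, receiver)

    lig = _column(normalized, gene_ids, pair.ligand)
    rec = _column(normalized, gene_ids, pair.receptor)
    n_send = int((labels == sender).sum())
    n_recv = int((labels == receiver).sum())

    rng = np.random.default_rng(seed)
    n_cells = labels.size
    # permute labels by permuting cell indices; only the sender/receiver
    # masks matter, so draw permuted index arrays once per permutation
    null = np.empty(n_perm)
    for i in range(n_perm):
        perm = rng.permutation(n_cells)
        permuted = labels[perm]
        null[i] = 0.5 * (
            lig[permuted == sender].sum() / n_send
            + rec[permuted == receiver].sum() / n_recv
        )
    # >= with fp tolerance so the all-constant case counts every draw
    p = (1 + int((null >= observed - 1e-12).sum())) / (n_perm + 1)
    return InteractionResult(
        pair=pair, sender=sender, receiver=receiver,
        score=observed, p=p, n_perm=n_perm,
    )


def score_pairs(
    normalized: np.ndarray,
    gene_ids: list[str],
    type_labels,
    tasks: list[tuple[LRPair, str, str]],
    n_perm: int = 1000,
    seed: int = 0,
    share_permutations: bool = False,
) -> list[InteractionResult]:
    """Batch scoring of many (pair, sender, receiver) tasks.

    With ``share_permutations=True`` one set of label permutations is
    reused across all tasks (cheaper, results correlated across tasks);
    otherwise each task draws its own permutations from a task-specific
    substream of ``seed``.
    """
    results = []
    if share_permutations:
        labels = np.asarray([str(t) for t in type_labels])
        rng = np.random.default_rng(seed)
        perms = [labels[rng.permutation(labels.size)] for _ in range(n_perm)]
        for pair, sender, receiver in tasks:
            obs = pair_score(normalized, gene_ids, labels, pair, sender, receiver)
            lig = _column(normalized, gene_ids, pair.ligand)
            rec = _column(normalized, gene_ids, pair.receptor)
            null = np.array(
                [
                    0.5 * (lig[p == sender].mean() + rec[p == receiver].mean())
                    for p in perms
                ]
            )
            p_val = (1 + int((null >= obs - 1e-12).sum())) / (n_perm + 1)
            results.append(
                InteractionResult(pair, sender, receiver, obs, p_val, n_perm)
            )
    else:
        for i, (pair, sender, receiver) in enumerate(tasks):
            sub = np.random.default_rng(
                np.random.SeedSequence([int(seed), i])
            ).integers(2**31)
            results.append(
                permutation_p(
                    normalized, gene_ids, type_labels, pair, sender, receiver,
                    n_perm=n_perm, seed=int(sub),
                )
            )
    return results


def interaction_network(results: list[InteractionResult], alpha: float = 0.05) -> dict:
    """Turn significant interactions into a directed multigraph summary.

    Edges are (sender -> receiver) labeled by the ligand-receptor pair;
    nodes are the cell types participating in at least one significant
    edge. The summary reports node/edge counts, per-type in/out degree,
    and the labeled edge set (for network comparisons).
    """
    g = nx.MultiDiGraph()
    edges = set()
    for r in results:
        if r.p < alpha:
            g.add_edge(r.sender, r.receiver, key=f"{r.pair.ligand}->{r.pair.receptor}")
            edges.add(r.edge)
    return {
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
        "out_degree": {n: d for n, d in g.out_degree()},
        "in_degree": {n: d for n, d in g.in_degree()},
        "edges": edges,
        "alpha": alpha,
    }


def network_delta(summary_a: dict, summary_b: dict) -> dict:
    """Edges gained and lost going from network A to network B."""
    ea, eb = set(summary_a["edges"]), set(summary_b["edges"])
    return {"gained": eb - ea, "lost": ea - eb}
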