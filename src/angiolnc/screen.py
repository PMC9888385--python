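"""Divergent-regulation lncRNA screen.

Identifies transcripts regulated in opposite directions by a proangiogenic
stimulus (hypoxia vs. normoxia, "Hx") and by diabetes-mimicking stimuli
(high glucose vs. normal glucose, "HG"; TNF-alpha vs. untreated control,
"TNF"), then ranks them by a divergence score

    D = |FC_Hx - FC_HG| + |FC_Hx - FC_TNF|

where FC is the log2 fold change of the treatment over its control. D is
large for genes pushed one way by hypoxia and the other way by the diabetic
stimuli, and zero for genes that respond identically to all three.

A contrast table is a :class:`pandas.DataFrame` with columns
``gene_id, log2fc, pvalue, padj`` (one row per gene, gene_id unique).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import pandas as pd

__all__ = [
    "CandidateRecord",
    "validate_contrast_table",
    "filter_opposite_pattern",
    "divergence_score",
    "rank_candidates",
    "run_screen",
]

logger = logging.getLogger(__name__)

CONTRAST_COLUMNS = ("gene_id", "log2fc", "pvalue", "padj")

GROUP_UP = "hx_up_diabetic_down"
GROUP_DOWN = "hx_down_diabetic_up"


@dataclass
class CandidateRecord:
    """One screened lncRNA candidate."""

    gene_id: str
    group: str
    score: float = float("nan")
    rank: int = 0


def validate_contrast_table(table: pd.DataFrame, name: str = "contrast") -> pd.DataFrame:
    """Check a contrast table's schema and invariants; return it indexed by gene."""
    missing = [c for c in CONTRAST_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{name} table missing column(s): {missing}")
    if table["gene_id"].duplicated().any():
        dup = table.loc[table["gene_id"].duplicated(), "gene_id"].iloc[0]
        raise ValueError(f"{name} table has duplicate gene_id {dup!r}")
    if table["padj"].isna().any():
        raise ValueError(f"{name} table has missing padj values")
    padj = table["padj"].to_numpy(float)
    if (padj < 0).any() or (padj > 1).any():
        raise ValueError(f"{name} table has padj outside [0, 1]")
    return table.set_index("gene_id", drop=False)


def filter_opposite_pattern(
    hx: pd.DataFrame,
    hg: pd.DataFrame,
    tnf: pd.DataFrame,
    alpha: float = 0.05,
) -> list[CandidateRecord]:
    """Select genes significant in Hx and oppositely regulated by HG and/or TNF.

    A gene is a candidate when

    * ``padj < alpha`` in the Hx contrast, and
    * ``padj < alpha`` in at least one diabetic contrast (HG, TNF), and
    * every *significant* diabetic log2FC has sign opposite to the Hx
      log2FC (a non-significant diabetic contrast neither qualifies nor
      vetoes the gene).

    The candidate's group records the hypoxia direction:
    ``hx_up_diabetic_down`` for Hx-induced genes, ``hx_down_diabetic_up``
    for Hx-suppressed ones. Zero log2FC in a significant contrast counts as
    neither sign and excludes the gene.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    hx = validate_contrast_table(hx, "hx")
    hg = validate_contrast_table(hg, "hg")
    tnf = validate_contrast_table(tnf, "tnf")

    shared = hx.index.intersection(hg.index).intersection(tnf.index)
    if len(shared) == 0:
        raise ValueError("contrast tables share no genes")

    out: list[CandidateRecord] = []
    for gene in shared:
        hx_fc = hx.at[gene, "log2fc"]
        if hx.at[gene, "padj"] >= alpha or hx_fc == 0:
            continue
        sig_opposite = 0
        vetoed = False
        for tab in (hg, tnf):
            if tab.at[gene, "padj"] < alpha:
                fc = tab.at[gene, "log2fc"]
                if fc * hx_fc < 0:
                    sig_opposite += 1
                else:
                    vetoed = True  # significant same-sign (or zero) response
        if vetoed or sig_opposite == 0:
            continue
        group = GROUP_UP if hx_fc > 0 else GROUP_DOWN
        out.append(CandidateRecord(gene_id=str(gene), group=group))
    return out


def divergence_score(fc_hx: float, fc_hg: float, fc_tnf: float) -> float:
    """Divergence D = |FC_Hx - FC_HG| + |FC_Hx - FC_TNF| (log2FC units)."""
    for v in (fc_hx, fc_hg, fc_tnf):
        if not math.isfinite(v):
            raise ValueError(f"non-finite log2 fold change: {v!r}")
    return abs(fc_hx - fc_hg) + abs(fc_hx - fc_tnf)


def rank_candidates(
    records: list[CandidateRecord],
    hx: pd.DataFrame,
    hg: pd.DataFrame,
    tnf: pd.DataFrame,
) -> list[CandidateRecord]:
    """Score and rank candidates by descending divergence.

    Genes missing from any table cannot be scored; they are dropped with a
    warning rather than imputed. Ties in D are broken lexicographically by
    gene_id; ranks are 1..n.
    """
    hx = validate_contrast_table(hx, "hx")
    hg = validate_contrast_table(hg, "hg")
    tnf = validate_contrast_table(tnf, "tnf")

    scored: list[CandidateRecord] = []
    for rec in records:
        g = rec.gene_id
        if not (g in hx.index and g in hg.index and g in tnf.index):
            logger.warning("gene %s missing from a contrast table; dropped from ranking", g)
            continue
        score = divergence_score(
            hx.at[g, "log2fc"], hg.at[g, "log2fc"], tnf.at[g, "log2fc"]
        )
        scored.append(CandidateRecord(gene_id=g, group=rec.group, score=score))

    scored.sort(key=lambda r: (-r.score, r.gene_id))
    for i, rec in enumerate(scored, start=1):
        rec.rank = i
    return scored


def run_screen(
    hx: pd.DataFrame,
    hg: pd.DataFrame,
    tnf: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Full screen: filter, score, rank; return a tidy candidate table.

    Columns: gene_id, group, score, rank plus the three per-contrast
    log2fc and padj columns.
    """
    records = filter_opposite_pattern(hx, hg, tnf, alpha=alpha)
    ranked = rank_candidates(records, hx, hg, tnf)
    hx_i = hx.set_index("gene_id")
    hg_i = hg.set_index("gene_id")
    tnf_i = tnf.set_index("gene_id")
    rows = []
    for rec in ranked:
        g = rec.gene_id
        rows.append(
            {
                "gene_id": g,
                "group": rec.group,
                "score": rec.score,
                "rank": rec.rank,
                "log2fc_hx": hx_i.at[g, "log2fc"],
                "padj_hx": hx_i.at[g, "padj"],
                "log2fc_hg": hg_i.at[g, "log2fc"],
                "padj_hg": hg_i.at[g, "padj"],
                "log2fc_tnf": tnf_i.at[g, "log2fc"],
                "padj_tnf": tnf_i.at[g, "padj"],
            }
        )
    cols = [
        "gene_id", "group", "score", "rank",
        "log2fc_hx", "padj_hx", "log2fc_hg", "padj_hg", "log2fc_tnf", "padj_tnf",
    ]
    return pd.DataFrame(rows, columns=cols)
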