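"""Gene-set integration: rescued genes, regulome, and direct targets.

Implements the set logic of a knockout/overexpression rescue study:

* *rescued genes* — down in knockout vs. wild type and up again when the
  transcript is re-expressed in the knockout;
* *regulome* — genes both downregulated on knockdown and bound by the
  transcript in their genomic loci;
* *putative direct targets* — genes consistently, positively regulated in
  vitro and in vivo that also show binding.

Cross-species id mapping (human/mouse) is the caller's responsibility: a
two-column conversion table can be applied with :func:`map_ids` before
intersecting.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "GeneSetReport",
    "rescued_genes",
    "regulome_intersection",
    "putative_direct_targets",
    "map_ids",
]


@dataclass
class GeneSetReport:
    """A named gene set with the provenance of the inputs that produced it."""

    set_name: str
    members: frozenset[str]
    provenance: dict[str, object] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.members)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"gene_id": sorted(self.members), "set_name": self.set_name})


def _direction_set(de: pd.DataFrame, direction: str, alpha: float) -> set[str]:
    if "direction" not in de.columns:
        raise ValueError("DE table lacks a 'direction' column")
    mask = (de["padj"] < alpha) & (de["direction"] == direction)
    return set(de.loc[mask, "gene_id"].astype(str))


def rescued_genes(
    de_wt_vs_ko: pd.DataFrame,
    de_ko_vs_oe: pd.DataFrame,
    alpha: float = 0.05,
) -> GeneSetReport:
    """Genes lost on knockout and restored by overexpression.

    ``de_wt_vs_ko`` is the KO-relative-to-WT contrast (rescued genes are
    *down*), ``de_ko_vs_oe`` the OE-relative-to-KO contrast (rescued genes
    are *up*), both at ``padj < alpha``.
    """
    down_ko = _direction_set(de_wt_vs_ko, "down", alpha)
    up_oe = _direction_set(de_ko_vs_oe, "up", alpha)
    members = frozenset(down_ko & up_oe)
    return GeneSetReport(
        set_name="rescued",
        members=members,
        provenance={
            "down_in_ko_vs_wt": sorted(down_ko),
            "up_in_oe_vs_ko": sorted(up_oe),
            "alpha": alpha,
        },
    )


def regulome_intersection(kd_down: set[str], bound: set[str]) -> GeneSetReport:
    """Genes positively regulated (down on knockdown) and bound at their loci."""
    kd_down = {str(g) for g in kd_down}
    bound = {str(g) for g in bound}
    return GeneSetReport(
        set_name="regulome",
        members=frozenset(kd_down & bound),
        provenance={"n_kd_down": len(kd_down), "n_bound": len(bound)},
    )


def putative_direct_targets(
    in_vitro: set[str], in_vivo: set[str], bound: set[str]
) -> GeneSetReport:
    """Triple intersection: regulated in vitro, in vivo, and bound."""
    sets = [
        {str(g) for g in in_vitro},
        {str(g) for g in in_vivo},
        {str(g) for g in bound},
    ]
    return GeneSetReport(
        set_name="putative_direct_targets",
        members=frozenset(sets[0] & sets[1] & sets[2]),
        provenance={
            "n_in_vitro": len(sets[0]),
            "n_in_vivo": len(sets[1]),
            "n_bound": len(sets[2]),
        },
    )


def map_ids(genes: set[str], mapping: pd.DataFrame, src: str, dst: str) -> set[str]:
    """Translate gene ids through a two-column conversion table.

    ``mapping`` must contain columns ``src`` and ``dst`` (e.g. mouse_id,
    human_id). Genes without an entry are dropped; one-to-many entries map
    to all listed partners.
    """
    for col in (src, dst):
        if col not in mapping.columns:
            raise ValueError(f"mapping table lacks column {col!r}")
    sub = mapping[mapping[src].astype(str).isin({str(g) for g in genes})]
    return set(sub[dst].astype(str))
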