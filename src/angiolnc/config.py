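"""Simulation configuration shared by all synthetic-data generators.

A single :class:`SimulationConfig` drives every generator in
:mod:`angiolnc.simulate`. One global integer seed is expanded into
independent substreams (one per generator) so that changing, say, the
cell-dataset draw does not perturb the contrast tables.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np

__all__ = ["SimulationConfig", "substream"]

# fixed stream ids so each generator gets a reproducible, independent RNG
_STREAMS = {
    "contrasts": 1,
    "cells": 2,
    "genome": 3,
    "rescue": 4,
    "misc": 5,
}


def substream(seed: int, name: str) -> np.random.Generator:
    """Return the seeded RNG substream for a named generator."""
    try:
        sid = _STREAMS[name]
    except KeyError:
        raise KeyError(f"unknown stream {name!r}; one of {sorted(_STREAMS)}") from None
    return np.random.default_rng(np.random.SeedSequence([int(seed), sid]))


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study conditions.

    Attributes
    ----------
    n_genes
        Size of the gene universe for bulk contrast tables and the rescue
        design.
    n_planted
        Number of genes carrying a planted effect (divergently regulated
        lncRNAs, or rescued genes, depending on the generator).
    effect_size
        Planted effect in log2 fold-change units.
    noise_sd
        Standard deviation of the per-gene log2FC measurement noise in the
        contrast tables.
    alpha_sig
        Nominal significance level the downstream screens will use; stored
        here so a simulated study is self-describing.
    n_cells_per_type
        Cells drawn per cell type by the single-cell generator.
    marker_elevation
        Natural-log shift applied to a cell type's own marker genes
        (count means multiplied by ``exp(marker_elevation)``).
    mito_outlier_rate
        Probability that a cell is a planted high-mitochondrial outlier
        (fraction drawn above the 25% QC cutoff).
    seed
        Global integer seed; all generator substreams derive from it.
    n_cell_genes
        Gene-universe size for the single-cell generator (separate from
        ``n_genes`` so that multiplet outliers can exceed the 3,000
        expressed-gene QC cutoff).
    multiplet_rate
        Probability that a cell is a planted multiplet-like outlier with a
        boosted library size.
    nb_dispersion_bulk, nb_dispersion_sc
        Negative-binomial dispersions (var = mu + phi * mu^2) for bulk and
        single-cell counts.
    n_replicates
        Replicates per group in the three-group rescue design.
    """

    n_genes: int = 1000
    n_planted: int = 10
    effect_size: float = 2.0
    noise_sd: float = 0.25
    alpha_sig: float = 0.05
    n_cells_per_type: int = 200
    marker_elevation: float = 2.0
    mito_outlier_rate: float = 0.05
    seed: int = 0
    n_cell_genes: int = 4000
    multiplet_rate: float = 0.02
    nb_dispersion_bulk: float = 0.01
    nb_dispersion_sc: float = 0.5
    n_replicates: int = 4

    def __post_init__(self) -> None:
        if self.n_planted > self.n_genes:
            raise ValueError(
                f"n_planted ({self.n_planted}) exceeds n_genes ({self.n_genes})"
            )
        if self.n_planted < 0 or self.n_genes <= 0:
            raise ValueError("gene counts must be nonnegative (n_genes > 0)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for name in ("alpha_sig", "mito_outlier_rate", "multiplet_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.n_replicates < 2:
            raise ValueError("n_replicates must be >= 2")

    def rng(self, stream: str) -> np.random.Generator:
        return substream(self.seed, stream)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        bad = set(d) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        return cls(**d)
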