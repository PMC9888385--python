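"""Peak-to-gene-feature classification and bound-gene derivation.

Peaks (e.g. from ChIRP-seq of a chromatin-bound lncRNA) are classified
against stranded gene models into four mutually exclusive categories:

* ``promoter`` — the peak overlaps the TSS +/- *window* (default 3 kb);
* ``exon`` — otherwise, the peak overlaps an exon;
* ``intron`` — otherwise, the peak overlaps the gene span;
* ``intergenic`` — none of the above.

All coordinates are 0-based half-open (BED convention); the promoter
window is closed on both ends in base space. Overlap everywhere means at
least one shared base; in particular a bound-gene call requires a 1-base
overlap of the peak with the gene span, strand-agnostic. Strand enters
only through TSS placement (span start on ``+``, span end - 1 on ``-``).
"""

from __future__ import annotations

from dataclasses import dataclass

from intervaltree import IntervalTree

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "PeakAnnotationRecord",
    "PeakAnnotator",
    "classify_peak",
    "annotate_peaks",
    "bound_genes",
    "CATEGORIES",
]

CATEGORIES = ("promoter", "exon", "intron", "intergenic")
_PRIORITY = {"promoter": 0, "exon": 1, "intron": 2}


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval, optionally stranded."""

    chrom: str
    start: int
    end: int
    strand: str | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"malformed interval {self.chrom}:{self.start}-{self.end} "
                "(need 0 <= start < end)"
            )
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"strand must be '+', '-' or None, got {self.strand!r}")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True)
class GeneModel:
    """Stranded gene structure: span, TSS, and sorted non-overlapping exons."""

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"gene {self.gene_id}: strand must be '+' or '-'")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id}: needs at least one exon")
        prev_end = -1
        for s, e in self.exons:
            if not (0 <= s < e):
                raise ValueError(f"gene {self.gene_id}: malformed exon ({s}, {e})")
            if s < prev_end:
                raise ValueError(f"gene {self.gene_id}: exons overlap or are unsorted")
            prev_end = e

    @property
    def span(self) -> tuple[int, int]:
        return (self.exons[0][0], self.exons[-1][1])

    @property
    def tss(self) -> int:
        s, e = self.span
        return s if self.strand == "+" else e - 1

    def promoter_window(self, window: int) -> tuple[int, int]:
        """Half-open interval covering TSS +/- window bases (closed in base space)."""
        return (max(0, self.tss - window), self.tss + window + 1)


@dataclass
class PeakAnnotationRecord:
    peak: GenomicInterval
    category: str
    gene_id: str | None = None


def _tss_distance(peak: GenomicInterval, gene: GeneModel) -> int:
    if peak.start <= gene.tss < peak.end:
        return 0
    return min(abs(gene.tss - peak.start), abs(gene.tss - (peak.end - 1)))


class PeakAnnotator:
    """Interval-tree index over gene models for repeated peak classification."""

    def __init__(self, genes: list[GeneModel], window: int = 3000) -> None:
        if window < 0:
            raise ValueError("window must be >= 0")
        self.window = window
        self.genes = {g.gene_id: g for g in genes}
        self._promoter: dict[str, IntervalTree] = {}
        self._exon: dict[str, IntervalTree] = {}
        self._span: dict[str, IntervalTree] = {}
        for g in genes:
            ps, pe = g.promoter_window(window)
            self._promoter.setdefault(g.chrom, IntervalTree()).addi(ps, pe, g.gene_id)
            for s, e in g.exons:
                self._exon.setdefault(g.chrom, IntervalTree()).addi(s, e, g.gene_id)
            s, e = g.span
            self._span.setdefault(g.chrom, IntervalTree()).addi(s, e, g.gene_id)

    def _hits(self, trees: dict[str, IntervalTree], peak: GenomicInterval) -> set[str]:
        tree = trees.get(peak.chrom)
        if tree is None:
            return set()
        return {iv.data for iv in tree.overlap(peak.start, peak.end)}

    def classify(self, peak: GenomicInterval) -> PeakAnnotationRecord:
        """Classify one peak; priority promoter > exon > intron > intergenic.

        Among genes matching at the winning priority, the gene with the
        nearest TSS is reported (ties broken by gene_id).
        """
        for category, trees in (
            ("promoter", self._promoter),
            ("exon", self._exon),
            ("intron", self._span),
        ):
            hits = self._hits(trees, peak)
            if hits:
                gene = min(
                    (self.genes[g] for g in hits),
                    key=lambda g: (_tss_distance(peak, g), g.gene_id),
                )
                return PeakAnnotationRecord(peak=peak, category=category, gene_id=gene.gene_id)
        return PeakAnnotationRecord(peak=peak, category="intergenic", gene_id=None)

    def bound_genes(self, peaks: list[GenomicInterval]) -> set[str]:
        """Gene ids whose span shares >= 1 base with any peak."""
        out: set[str] = set()
        for peak in peaks:
            out |= self._hits(self._span, peak)
        return out


def classify_peak(
    peak: GenomicInterval, genes: list[GeneModel], window: int = 3000
) -> PeakAnnotationRecord:
    return PeakAnnotator(genes, window=window).classify(peak)


def annotate_peaks(
    peaks: list[GenomicInterval], genes: list[GeneModel], window: int = 3000
) -> tuple[list[PeakAnnotationRecord], dict[str, float] | None]:
    """Classify every peak and summarise category proportions.

    Returns the per-peak records and a category -> proportion mapping
    (``None`` when there are no peaks, since proportions are undefined).
    """
    annotator = PeakAnnotator(genes, window=window)
    records = [annotator.classify(p) for p in peaks]
    if not records:
        return records, None
    counts = {c: 0 for c in CATEGORIES}
    for r in records:
        counts[r.category] += 1
    n = len(records)
    return records, {c: counts[c] / n for c in CATEGORIES}


def bound_genes(peaks: list[GenomicInterval], genes: list[GeneModel]) -> set[str]:
    return PeakAnnotator(genes, window=0).bound_genes(peaks)
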